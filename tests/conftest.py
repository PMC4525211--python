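import numpy as np
import pytest

from chriplex.annotation import Annotation, TranscriptModel


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def toy_annotation():
    """Two transcripts on chr1 (one per strand) and one on chr2."""
    return Annotation(
        [
            TranscriptModel(
                transcript_id="txA",
                gene_id="geneA",
                chrom="chr1",
                strand="+",
                exons=((100, 200), (300, 400)),
                biotype="lncRNA_annotated",
            ),
            TranscriptModel(
                transcript_id="txB",
                gene_id="geneB",
                chrom="chr1",
                strand="-",
                exons=((1000, 1150), (1300, 1450)),
                biotype="lncRNA_annotated",
            ),
            TranscriptModel(
                transcript_id="txC",
                gene_id="geneC",
                chrom="chr2",
                strand="+",
                exons=((50, 2050),),
                biotype="coding",
            ),
        ]
    )


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
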