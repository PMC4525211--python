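"""Transcript models and coordinate arithmetic.

All internal coordinates are 0-based half-open; conversion to/from the
1-based closed GTF convention happens only in :mod:`chriplex.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from chriplex.sequtils import revcomp

BIOTYPES = (
    "lncRNA_annotated",
    "lncRNA_novel_intergenic",
    "lncRNA_novel_intronic",
    "coding",
    "other",
)

LNCRNA_BIOTYPES = frozenset(b for b in BIOTYPES if b.startswith("lncRNA"))


@dataclass(frozen=True)
class TranscriptModel:
    """An annotated multi-exon transcript.

    ``exons`` are genomic 0-based half-open intervals, sorted by start and
    non-overlapping regardless of strand. For minus-strand transcripts the
    first exon in transcript (5'->3') order is the *last* genomic exon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if start < 0 or start >= end:
                raise ValueError(
                    f"{self.transcript_id}: bad exon interval [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted at {start}"
                )
            prev_end = end
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    def exons_in_transcript_order(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def contains(self, position: int) -> bool:
        """True if *position* falls inside the exon union."""
        return self.exon_index(position) is not None

    def exon_index(self, position: int) -> int | None:
        """Index (in transcript 5'->3' order) of the exon containing *position*."""
        for i, (start, end) in enumerate(self.exons_in_transcript_order()):
            if start <= position < end:
                return i
        return None

    def genome_to_transcript(self, position: int) -> int | None:
        """Map a genomic position to a 0-based spliced-transcript coordinate."""
        offset = 0
        for start, end in self.exons_in_transcript_order():
            if start <= position < end:
                if self.strand == "+":
                    return offset + (position - start)
                return offset + (end - 1 - position)
            offset += end - start
        return None

    def transcript_to_genome(self, position: int) -> int:
        """Map a 0-based spliced-transcript coordinate to a genomic position."""
        if position < 0 or position >= self.exonic_length:
            raise IndexError(
                f"{self.transcript_id}: transcript position {position} out of "
                f"range [0, {self.exonic_length})"
            )
        offset = 0
        for start, end in self.exons_in_transcript_order():
            length = end - start
            if position < offset + length:
                within = position - offset
                if self.strand == "+":
                    return start + within
                return end - 1 - within
            offset += length
        raise AssertionError("unreachable")

    def spliced_sequence(self, chrom_seq: str) -> str:
        """Spliced transcript sequence (5'->3') extracted from *chrom_seq*."""
        parts = [chrom_seq[s:e] for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class Annotation:
    """A collection of transcripts with id-based lookup."""

    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tx in self.transcripts:
            if tx.transcript_id in seen:
                raise ValueError(f"duplicated transcript id {tx.transcript_id!r}")
            seen.add(tx.transcript_id)
        self._by_id = {tx.transcript_id: tx for tx in self.transcripts}

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def ids(self) -> list[str]:
        return [tx.transcript_id for tx in self.transcripts]

    def by_chrom(self) -> dict[str, list[TranscriptModel]]:
        out: dict[str, list[TranscriptModel]] = {}
        for tx in self.transcripts:
            out.setdefault(tx.chrom, []).append(tx)
        return out
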