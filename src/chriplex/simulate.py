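"""Synthetic data generation with planted ground truth.

Every downstream stage of the pipeline can be exercised without any
external download: transcripts with known fold enrichment in the two
pull-downs, pileups with planted strand-aware T-to-C crosslink sites,
peaks carrying polypurine tracts at their summits, and gene universes with
planted overlapping subsets.

All randomness flows from one seed; each stage derives a child generator
deterministically (``default_rng([seed, stage])``) so stages can be
regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from chriplex.annotation import Annotation, TranscriptModel
from chriplex.peaks import Peak
from chriplex.sequtils import complement

BASES = np.array(list("ACGT"))

# child-generator ids, one per stage
_STAGE_GENOME = 1
_STAGE_COUNTS = 2
_STAGE_PILEUP = 3
_STAGE_PEAKS = 4
_STAGE_GENES = 5


class CapacityError(ValueError):
    """Raised when a configuration cannot be placed on the genome."""


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 50
    n_enriched: int = 10
    enrichment_fold: float = 4.0
    depth_mean: float = 100.0
    conversion_rate: float = 0.5
    background_error_rate: float = 0.001
    n_peaks: int = 20
    n_triplex_peaks: int = 10
    tract_length: int = 20
    genome_length: int = 200_000
    universe_size: int = 1000
    n_deregulated: int = 100
    n_peak_genes: int = 100
    planted_overlap: int = 30
    # paper gives no noise model; negative binomial is the accepted default
    dispersion: float = 0.1
    n_single_enriched: int = 0  # decoys enriched in exactly one pull-down
    n_crosslink_transcripts: int = 10
    n_crosslink_sites: int = 3  # planted sites per chosen transcript
    peak_width: int = 1000
    n_h3k4me1_overlap: int = 5
    n_h3k4me1_extra: int = 5
    with_n_runs: bool = False  # inject N runs to exercise scanner robustness

    def __post_init__(self) -> None:
        counts = {
            "n_transcripts": self.n_transcripts,
            "n_enriched": self.n_enriched,
            "n_peaks": self.n_peaks,
            "n_triplex_peaks": self.n_triplex_peaks,
            "tract_length": self.tract_length,
            "genome_length": self.genome_length,
            "universe_size": self.universe_size,
            "n_deregulated": self.n_deregulated,
            "n_peak_genes": self.n_peak_genes,
            "planted_overlap": self.planted_overlap,
            "n_single_enriched": self.n_single_enriched,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name, value in (
            ("conversion_rate", self.conversion_rate),
            ("background_error_rate", self.background_error_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.enrichment_fold <= 0 or self.depth_mean <= 0:
            raise ValueError("enrichment_fold and depth_mean must be positive")
        if self.n_enriched + self.n_single_enriched > self.n_transcripts:
            raise ValueError("n_enriched + n_single_enriched exceeds n_transcripts")
        if self.n_triplex_peaks > self.n_peaks:
            raise ValueError("n_triplex_peaks exceeds n_peaks")
        if self.planted_overlap > min(self.n_deregulated, self.n_peak_genes):
            raise ValueError("planted_overlap exceeds a planted set size")
        if max(self.n_deregulated, self.n_peak_genes) > self.universe_size:
            raise ValueError("planted gene sets exceed the universe")


@dataclass
class GroundTruth:
    enriched_transcript_ids: set[str] = field(default_factory=set)
    single_enriched_ids: set[str] = field(default_factory=set)
    crosslink_sites: dict[str, list[int]] = field(default_factory=dict)
    crosslink_sites_genomic: dict[str, list[tuple[str, int]]] = field(
        default_factory=dict
    )
    triplex_peak_ids: set[str] = field(default_factory=set)
    deregulated_genes: set[str] = field(default_factory=set)
    peak_associated_genes: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        raw = asdict(self)
        for key in (
            "enriched_transcript_ids",
            "single_enriched_ids",
            "triplex_peak_ids",
            "deregulated_genes",
            "peak_associated_genes",
        ):
            raw[key] = sorted(raw[key])
        raw["crosslink_sites_genomic"] = {
            k: [[c, p] for c, p in v]
            for k, v in raw["crosslink_sites_genomic"].items()
        }
        return json.dumps(raw, indent=2, sort_keys=True)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            enriched_transcript_ids=self.enriched_transcript_ids
            | other.enriched_transcript_ids,
            single_enriched_ids=self.single_enriched_ids | other.single_enriched_ids,
            crosslink_sites={**self.crosslink_sites, **other.crosslink_sites},
            crosslink_sites_genomic={
                **self.crosslink_sites_genomic,
                **other.crosslink_sites_genomic,
            },
            triplex_peak_ids=self.triplex_peak_ids | other.triplex_peak_ids,
            deregulated_genes=self.deregulated_genes | other.deregulated_genes,
            peak_associated_genes=self.peak_associated_genes
            | other.peak_associated_genes,
        )


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def generate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], Annotation]:
    """Random genome plus non-overlapping multi-exon transcripts.

    Raises :class:`CapacityError` when the annotated span cannot fit in
    ``genome_length``.
    """
    rng = _rng(config, _STAGE_GENOME)
    seq = _random_sequence(rng, config.genome_length)
    if config.with_n_runs:
        chars = list(seq)
        for _ in range(max(1, config.genome_length // 50_000)):
            start = int(rng.integers(0, max(1, config.genome_length - 50)))
            for i in range(start, min(start + 20, config.genome_length)):
                chars[i] = "N"
        seq = "".join(chars)

    structures = []
    total_span = 0
    for _ in range(config.n_transcripts):
        n_exons = int(rng.integers(1, 5))
        exon_lengths = rng.integers(100, 401, size=n_exons)
        intron_lengths = rng.integers(50, 201, size=max(0, n_exons - 1))
        span = int(exon_lengths.sum() + intron_lengths.sum())
        structures.append((exon_lengths, intron_lengths, span))
        total_span += span + 100  # minimum inter-transcript gap

    if total_span > config.genome_length:
        raise CapacityError(
            f"{config.n_transcripts} transcripts need about {total_span} bp "
            f"but genome_length is {config.genome_length}"
        )

    slack = config.genome_length - total_span
    gap_extras = (
        rng.multinomial(slack, np.ones(config.n_transcripts) / config.n_transcripts)
        if config.n_transcripts
        else np.array([], dtype=int)
    )
    transcripts: list[TranscriptModel] = []
    cursor = 0
    for i, (exon_lengths, intron_lengths, span) in enumerate(structures):
        cursor += 100 + int(gap_extras[i])
        exons = []
        pos = cursor
        for j, exon_len in enumerate(exon_lengths):
            exons.append((pos, pos + int(exon_len)))
            pos += int(exon_len)
            if j < len(intron_lengths):
                pos += int(intron_lengths[j])
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lncRNA_annotated" if rng.random() < 0.7 else "coding"
        transcripts.append(
            TranscriptModel(
                transcript_id=f"tx{i:04d}",
                gene_id=f"gene{i:04d}",
                chrom="chr1",
                strand=strand,
                exons=tuple(exons),
                biotype=biotype,
            )
        )
        cursor = pos
    return {"chr1": seq}, Annotation(transcripts)


def simulate_chrip_counts(
    config: SimulationConfig,
    annotation: Annotation,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial read counts for input and the two pull-downs.

    Expected input count is ``depth_mean`` scaled by exonic length in kb.
    Planted enriched transcripts get ``enrichment_fold`` times that mean in
    BOTH pull-downs; ``n_single_enriched`` decoys get the fold in exactly
    one pull-down (alternating between the two).
    """
    rng = _rng(config, _STAGE_COUNTS)
    ids = annotation.ids()
    if config.n_enriched + config.n_single_enriched > len(ids):
        raise ValueError("not enough transcripts to plant the configured sets")
    chosen = rng.choice(
        len(ids), size=config.n_enriched + config.n_single_enriched, replace=False
    )
    enriched = {ids[i] for i in chosen[: config.n_enriched]}
    single = {ids[i] for i in chosen[config.n_enriched:]}
    single_sorted = sorted(single)
    single_ezh2 = set(single_sorted[::2])  # alternate which pull-down is enriched

    def _nb(mean: float) -> int:
        if mean <= 0:
            return 0
        if config.dispersion <= 0:
            return int(rng.poisson(mean))
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mean / shape)
        return int(rng.poisson(lam))

    rows = []
    for tid in ids:
        base = config.depth_mean * annotation[tid].exonic_length / 1000.0
        fold_k27 = fold_ezh2 = 1.0
        if tid in enriched:
            fold_k27 = fold_ezh2 = config.enrichment_fold
        elif tid in single:
            if tid in single_ezh2:
                fold_ezh2 = config.enrichment_fold
            else:
                fold_k27 = config.enrichment_fold
        rows.append(
            {
                "transcript_id": tid,
                "input": _nb(base),
                "h3k27me3": _nb(base * fold_k27),
                "ezh2": _nb(base * fold_ezh2),
            }
        )
    counts = pd.DataFrame(rows).set_index("transcript_id")
    truth = GroundTruth(
        enriched_transcript_ids=enriched, single_enriched_ids=single
    )
    return counts, truth


def simulate_conversion_pileup(
    config: SimulationConfig,
    annotation: Annotation,
    genome: Mapping[str, str],
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-position base counts per sample with planted EZH2 crosslink sites.

    Sites are planted on T positions of the transcript strand (template
    A positions in genome coordinates for minus-strand transcripts); in
    the EZH2 sample each covering read converts with ``conversion_rate``.
    Background substitutions hit every sample uniformly over the 12
    substitution types at ``background_error_rate`` per read-base.
    """
    rng = _rng(config, _STAGE_PILEUP)
    ids = annotation.ids()
    n_pick = min(config.n_crosslink_transcripts, len(ids))
    picked = [ids[i] for i in rng.choice(len(ids), size=n_pick, replace=False)]

    truth = GroundTruth()
    planted_genomic: dict[tuple[str, int], str] = {}  # (chrom,pos) -> genome alt base
    for tid in picked:
        tx = annotation[tid]
        spliced = tx.spliced_sequence(genome[tx.chrom])
        t_positions = [i for i, b in enumerate(spliced) if b == "T"]
        if not t_positions:
            continue
        k = min(config.n_crosslink_sites, len(t_positions))
        sites = sorted(
            int(p) for p in rng.choice(t_positions, size=k, replace=False)
        )
        truth.crosslink_sites[tid] = sites
        genomic = []
        for s in sites:
            gpos = tx.transcript_to_genome(s)
            ref = genome[tx.chrom][gpos]
            if (tx.strand == "+" and ref != "T") or (tx.strand == "-" and ref != "A"):
                raise ValueError(
                    f"planted site {tid}:{s} does not sit on a transcript-strand T"
                )
            # transcript T>C expressed in genome coordinates
            planted_genomic[(tx.chrom, gpos)] = "C" if tx.strand == "+" else "G"
            genomic.append((tx.chrom, gpos))
        truth.crosslink_sites_genomic[tid] = genomic

    samples = ("input", "ezh2", "h3k27me3")
    pileups: dict[str, list[dict]] = {s: [] for s in samples}
    for tx in annotation:
        chrom_seq = genome[tx.chrom]
        for exon_start, exon_end in tx.exons:
            for pos in range(exon_start, exon_end):
                ref = chrom_seq[pos]
                for sample in samples:
                    coverage = int(rng.poisson(config.depth_mean))
                    counts = {b: 0 for b in "ACGT"}
                    if ref in counts:
                        counts[ref] = coverage
                    n_err = (
                        rng.binomial(coverage, config.background_error_rate)
                        if coverage
                        else 0
                    )
                    for _ in range(int(n_err)):
                        alt = str(BASES[rng.integers(0, 4)])
                        if alt == ref or ref not in counts:
                            continue
                        counts[ref] -= 1
                        counts[alt] += 1
                    if sample == "ezh2":
                        alt = planted_genomic.get((tx.chrom, pos))
                        if alt is not None and ref in counts:
                            n_conv = rng.binomial(counts[ref], config.conversion_rate)
                            counts[ref] -= int(n_conv)
                            counts[alt] += int(n_conv)
                    pileups[sample].append(
                        {
                            "chrom": tx.chrom,
                            "pos": pos,
                            "ref": ref,
                            "countA": counts["A"],
                            "countC": counts["C"],
                            "countG": counts["G"],
                            "countT": counts["T"],
                        }
                    )
    frames = {
        s: pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "countA", "countC", "countG", "countT"]
        )
        for s, rows in pileups.items()
    }
    return frames, truth


def simulate_peaks(
    config: SimulationConfig,
    genome: Mapping[str, str],
) -> tuple[list[Peak], list[Peak], GroundTruth, dict[str, str]]:
    """Peaks with polypurine tracts planted at designated summits.

    Returns peaks, H3K4me1 intervals, ground truth, and the genome with
    the tracts written into its sequence.
    """
    rng = _rng(config, _STAGE_PEAKS)
    chrom = sorted(genome)[0]
    seq = list(genome[chrom])
    chrom_len = len(seq)
    width = config.peak_width
    spacing = width + 4 * 200 + 100  # keep flank windows of neighbours disjoint
    if config.tract_length > width:
        raise CapacityError("tract_length exceeds peak width")
    if config.n_peaks * spacing > chrom_len - 2 * spacing:
        raise CapacityError(
            f"{config.n_peaks} peaks at spacing {spacing} do not fit in {chrom_len} bp"
        )

    positions = np.sort(
        rng.choice(
            np.arange(1, (chrom_len - 2 * spacing) // spacing),
            size=config.n_peaks,
            replace=False,
        )
    )
    peaks: list[Peak] = []
    for i, slot in enumerate(positions):
        start = int(slot) * spacing
        summit = start + width // 2
        peaks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=start + width,
                summit=summit,
                sample="chop",
                score=float(rng.integers(10, 1000)),
                name=f"peak{i:04d}",
            )
        )

    triplex_idx = rng.choice(config.n_peaks, size=config.n_triplex_peaks, replace=False)
    truth = GroundTruth()
    ga = np.array(["G", "A"])
    for i in triplex_idx:
        peak = peaks[int(i)]
        tract = "".join(ga[rng.integers(0, 2, size=config.tract_length)])
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            tract = "".join(complement(b) for b in tract)[::-1]
        lo = peak.summit - config.tract_length // 2
        seq[lo : lo + config.tract_length] = list(tract)
        truth.triplex_peak_ids.add(peak.name)

    n_overlap = min(config.n_h3k4me1_overlap, config.n_peaks)
    overlap_idx = rng.choice(config.n_peaks, size=n_overlap, replace=False)
    marks: list[Peak] = []
    for j, i in enumerate(sorted(int(x) for x in overlap_idx)):
        peak = peaks[i]
        start = peak.summit - 150
        marks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=start + 300,
                summit=start + 150,
                sample="h3k4me1",
                name=f"mark{j:04d}",
            )
        )
    for j in range(config.n_h3k4me1_extra):
        # drop extras into inter-peak gaps so they never touch a peak
        slot = int(rng.integers(0, (chrom_len - 2 * spacing) // spacing))
        start = slot * spacing + width + 500
        marks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=start + 300,
                summit=start + 150,
                sample="h3k4me1",
                name=f"mark{len(marks):04d}",
            )
        )
    marks.sort(key=lambda p: p.start)
    return peaks, marks, truth, {**genome, chrom: "".join(seq)}


def simulate_gene_sets(config: SimulationConfig) -> tuple[set[str], GroundTruth]:
    """Gene universe with planted overlapping deregulated/peak-associated sets."""
    rng = _rng(config, _STAGE_GENES)
    universe = {f"g{i:05d}" for i in range(config.universe_size)}
    ordered = sorted(universe)
    perm = rng.permutation(config.universe_size)
    overlap = {ordered[i] for i in perm[: config.planted_overlap]}
    dereg_only = {
        ordered[i]
        for i in perm[
            config.planted_overlap : config.n_deregulated
        ]
    }
    peak_only = {
        ordered[i]
        for i in perm[
            config.n_deregulated : config.n_deregulated
            + config.n_peak_genes
            - config.planted_overlap
        ]
    }
    truth = GroundTruth(
        deregulated_genes=overlap | dereg_only,
        peak_associated_genes=overlap | peak_only,
    )
    return universe, truth
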