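"""Triplex-forming oligo (TFO) and triplex target site (TrTS) prediction.

Detection core only: motif-alphabet window scanning with length, error-rate,
consecutive-error and guanine-content constraints; Hoogsteen triad matching
of TFOs against the purine strand of TrTS duplexes; and summit-versus-flank
TrTS density over peak sets. Windows must begin and end on canonical bases
(a boundary error only inflates the error rate at constant score). A hit is
*maximal*: it is reported iff it is not properly contained in another
window satisfying all constraints.

Motif alphabets (third strand): purine {G, A} binding antiparallel,
pyrimidine {C, T} binding parallel, mixed {G, T} tried in both orientations.
Canonical triads: purine A.A-T / G.G-C; pyrimidine T.A-T / C.G-C;
mixed G.G-C / T.A-T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from chriplex.sequtils import normalize_rna, revcomp

logger = logging.getLogger(__name__)

MOTIF_ALPHABETS: Mapping[str, frozenset[str]] = {
    "purine": frozenset("GA"),
    "pyrimidine": frozenset("CT"),
    "mixed": frozenset("GT"),
}

#: canonical (third-strand base, duplex purine-strand base) pairs per motif
TRIAD_TABLE: Mapping[str, frozenset[tuple[str, str]]] = {
    "purine": frozenset({("A", "A"), ("G", "G")}),
    "pyrimidine": frozenset({("T", "A"), ("C", "G")}),
    "mixed": frozenset({("G", "G"), ("T", "A")}),
}

#: binding orientation of the third strand relative to the purine strand
MOTIF_ORIENTATIONS: Mapping[str, tuple[str, ...]] = {
    "purine": ("antiparallel",),
    "pyrimidine": ("parallel",),
    "mixed": ("parallel", "antiparallel"),
}


@dataclass(frozen=True)
class TriplexParams:
    min_length: int = 15
    max_error_rate: float = 0.20
    max_consecutive_errors: int = 1
    min_guanine_fraction: float = 0.1
    motifs: tuple[str, ...] = ("purine", "pyrimidine", "mixed")

    def __post_init__(self) -> None:
        if not 0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must lie in [0, 0.5)")
        if self.min_length < 5:
            raise ValueError("min_length must be >= 5")
        unknown = set(self.motifs) - set(MOTIF_ALPHABETS)
        if unknown:
            raise ValueError(f"unknown motifs: {sorted(unknown)}")


@dataclass(frozen=True)
class TFOHit:
    source_id: str
    start: int
    end: int
    motif: str
    sequence_annotated: str
    score: int
    error_positions: tuple[int, ...]
    guanine_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def sequence(self) -> str:
        return self.sequence_annotated.upper()


@dataclass(frozen=True)
class TrTSHit:
    chrom: str
    start: int
    end: int
    purine_strand: str
    score: int
    error_positions: tuple[int, ...]  # offsets along the purine strand, 5'->3'
    sequence: str = ""  # purine-strand sequence, 5'->3'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TriplexMatch:
    tfo: TFOHit
    trts: TrTSHit
    orientation: str
    matched_length: int
    triad_errors: int
    score: int
    offset: int = 0  # oriented-TFO start relative to the TrTS purine strand


def score_tfo_sequence(
    sequence: str, motif: str
) -> tuple[int, tuple[int, ...], str]:
    """Score a sequence against a motif's canonical alphabet.

    Returns ``(score, error_positions, annotated)`` where score is the
    number of canonical positions, and the annotated sequence lowercases
    every non-canonical base. Input is case-insensitive; U is read as T.
    """
    if motif not in MOTIF_ALPHABETS:
        raise ValueError(f"unknown motif {motif!r}")
    if not sequence:
        raise ValueError("empty sequence")
    seq = normalize_rna(sequence)
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    alphabet = MOTIF_ALPHABETS[motif]
    errors = tuple(i for i, base in enumerate(seq) if base not in alphabet)
    error_set = set(errors)
    annotated = "".join(
        b.lower() if i in error_set else b for i, b in enumerate(seq)
    )
    return len(seq) - len(errors), errors, annotated


def _window_valid(
    n_errors: int, n_g: int, length: int, params: TriplexParams
) -> bool:
    return (
        length >= params.min_length
        and n_errors <= params.max_error_rate * length
        and n_g >= params.min_guanine_fraction * length
    )


def _maximal_windows(
    seq: str, alphabet: frozenset[str], params: TriplexParams
) -> list[tuple[int, int]]:
    """Maximal windows of *seq* satisfying the motif constraints.

    For each start the longest valid end is found (the consecutive-error
    cap gives a hard stop); candidates contained in an earlier candidate
    are then suppressed in one left-to-right sweep.
    """
    n = len(seq)
    is_error = [base not in alphabet for base in seq]
    is_g = [base == "G" for base in seq]
    candidates: list[tuple[int, int]] = []
    for i in range(n):
        if is_error[i]:  # hits start on a canonical base
            continue
        errors = 0
        run = 0
        gs = 0
        best_end = -1
        for j in range(i, n):
            if is_error[j]:
                errors += 1
                run += 1
                if run > params.max_consecutive_errors:
                    break
            else:
                run = 0
            if is_g[j]:
                gs += 1
            if not is_error[j] and _window_valid(errors, gs, j - i + 1, params):
                best_end = j + 1
        if best_end >= 0:
            candidates.append((i, best_end))
    maximal: list[tuple[int, int]] = []
    max_end = -1
    for start, end in candidates:  # starts strictly increasing
        if end > max_end:
            maximal.append((start, end))
            max_end = end
    return maximal


def find_tfos(
    rna_sequence: str,
    params: TriplexParams = TriplexParams(),
    source_id: str = "rna",
) -> list[TFOHit]:
    """Scan an RNA for maximal triplex-forming-oligo windows.

    Overlapping maximal hits of different motifs are all reported; output
    is sorted by (start, motif).
    """
    seq = normalize_rna(rna_sequence)
    hits: list[TFOHit] = []
    for motif in params.motifs:
        alphabet = MOTIF_ALPHABETS[motif]
        for start, end in _maximal_windows(seq, alphabet, params):
            window = seq[start:end]
            score, errors, annotated = score_tfo_sequence(window, motif)
            hits.append(
                TFOHit(
                    source_id=source_id,
                    start=start,
                    end=end,
                    motif=motif,
                    sequence_annotated=annotated,
                    score=score,
                    error_positions=errors,
                    guanine_fraction=window.count("G") / len(window),
                )
            )
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def find_trts(
    dna_sequence: str,
    params: TriplexParams = TriplexParams(),
    chrom: str = "seq",
    offset: int = 0,
) -> list[TrTSHit]:
    """Scan duplex DNA for maximal polypurine triplex target sites.

    Both strands are scanned; coordinates are always reported on the +
    strand of the reference, with ``purine_strand`` recording which strand
    carries the tract. ``offset`` shifts reported coordinates (scanning an
    extracted interval).
    """
    seq = dna_sequence.upper()
    alphabet = MOTIF_ALPHABETS["purine"]
    hits: list[TrTSHit] = []
    for start, end in _maximal_windows(seq, alphabet, params):
        window = seq[start:end]
        errors = tuple(i for i, b in enumerate(window) if b not in alphabet)
        hits.append(
            TrTSHit(
                chrom=chrom,
                start=offset + start,
                end=offset + end,
                purine_strand="+",
                score=len(window) - len(errors),
                error_positions=errors,
                sequence=window,
            )
        )
    rc = revcomp(seq)
    n = len(seq)
    for start, end in _maximal_windows(rc, alphabet, params):
        window = rc[start:end]
        errors = tuple(i for i, b in enumerate(window) if b not in alphabet)
        hits.append(
            TrTSHit(
                chrom=chrom,
                start=offset + n - end,
                end=offset + n - start,
                purine_strand="-",
                score=len(window) - len(errors),
                error_positions=errors,
                sequence=window,
            )
        )
    hits.sort(key=lambda h: (h.start, h.end, h.purine_strand))
    return hits


def match_tfo_trts(
    tfo: TFOHit,
    trts: TrTSHit,
    params: TriplexParams = TriplexParams(),
) -> list[TriplexMatch]:
    """Ungapped Hoogsteen alignment of a TFO against a TrTS purine strand.

    Every sliding offset with overlap >= ``min_length`` is evaluated in the
    motif's canonical orientation(s); each non-canonical triad counts one
    error; alignments with error rate above ``max_error_rate`` are
    discarded. Matches are returned best-first.
    """
    if not trts.sequence:
        raise ValueError("TrTS hit carries no purine-strand sequence")
    tfo_seq = tfo.sequence
    duplex = trts.sequence.upper()
    triads = TRIAD_TABLE[tfo.motif]
    matches: list[TriplexMatch] = []
    for orientation in MOTIF_ORIENTATIONS[tfo.motif]:
        third = tfo_seq if orientation == "parallel" else tfo_seq[::-1]
        for off in range(-len(third) + 1, len(duplex)):
            lo = max(0, off)
            hi = min(len(duplex), off + len(third))
            overlap = hi - lo
            if overlap < params.min_length:
                continue
            errors = sum(
                1
                for k in range(lo, hi)
                if (third[k - off], duplex[k]) not in triads
            )
            if errors > params.max_error_rate * overlap:
                continue
            matches.append(
                TriplexMatch(
                    tfo=tfo,
                    trts=trts,
                    orientation=orientation,
                    matched_length=overlap,
                    triad_errors=errors,
                    score=overlap - errors,
                    offset=off,
                )
            )
    matches.sort(key=lambda m: (-m.score, m.triad_errors, m.orientation, m.offset))
    return matches


@dataclass
class DensityResult:
    per_peak: pd.DataFrame
    n_summit_greater: int
    n_flank_greater: int
    n_ties: int
    direction: str
    p_value: float


def summit_flank_density(
    peaks: Sequence,
    genome: Mapping[str, str],
    params: TriplexParams = TriplexParams(),
    window: int = 200,
) -> DensityResult:
    """Compare TrTS counts at peak summits (+/- *window* bp) versus flanks.

    The summit window is ``[summit - window, summit + window)``; the flanks
    are the adjacent windows of the same total width on either side. TrTS
    hits are assigned to a window by their start coordinate. The aggregate
    is a one-sided paired sign test across peaks (summit > flank).
    """
    rows = []
    for peak in peaks:
        summit = getattr(peak, "summit", None)
        if summit is None:
            raise ValueError(f"peak {peak!r} has no summit")
        chrom_seq = genome[peak.chrom]
        lo = summit - 2 * window
        hi = summit + 2 * window
        if lo < 0 or hi > len(chrom_seq):
            logger.warning(
                "summit windows of peak at %s:%d clipped to chromosome bounds",
                peak.chrom,
                summit,
            )
            lo = max(lo, 0)
            hi = min(hi, len(chrom_seq))
        hits = find_trts(chrom_seq[lo:hi], params, chrom=peak.chrom, offset=lo)
        n_summit = sum(
            1 for h in hits if summit - window <= h.start < summit + window
        )
        n_left = sum(
            1 for h in hits if summit - 2 * window <= h.start < summit - window
        )
        n_right = sum(
            1 for h in hits if summit + window <= h.start < summit + 2 * window
        )
        rows.append(
            {
                "chrom": peak.chrom,
                "summit": summit,
                "count_summit": n_summit,
                "count_flanks": n_left + n_right,
                "count_total": n_summit + n_left + n_right,
            }
        )
    per_peak = pd.DataFrame(
        rows, columns=["chrom", "summit", "count_summit", "count_flanks", "count_total"]
    )
    if len(per_peak):
        greater = int((per_peak.count_summit > per_peak.count_flanks).sum())
        lesser = int((per_peak.count_summit < per_peak.count_flanks).sum())
    else:
        greater = lesser = 0
    ties = len(per_peak) - greater - lesser
    n_informative = greater + lesser
    if n_informative:
        p = float(
            stats.binomtest(greater, n_informative, 0.5, alternative="greater").pvalue
        )
    else:
        p = 1.0
    direction = (
        "summit" if greater > lesser else "flank" if lesser > greater else "none"
    )
    return DensityResult(
        per_peak=per_peak,
        n_summit_greater=greater,
        n_flank_greater=lesser,
        n_ties=ties,
        direction=direction,
        p_value=p,
    )


def tfo_table(hits: Iterable[TFOHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source_id": h.source_id,
                "start": h.start,
                "end": h.end,
                "motif": h.motif,
                "sequence": h.sequence_annotated,
                "score": h.score,
                "errors": len(h.error_positions),
                "guanine_fraction": h.guanine_fraction,
            }
            for h in hits
        ]
    )


def trts_table(hits: Iterable[TrTSHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "purine_strand": h.purine_strand,
                "score": h.score,
                "errors": len(h.error_positions),
                "sequence": h.sequence,
            }
            for h in hits
        ]
    )
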