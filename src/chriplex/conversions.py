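"""Crosslink-site calling from per-position base counts.

Single-nucleotide transitions are called from pileup-style tables, filtered
by supporting-read depth, reduced to pull-down-specific events by set
subtraction, tabulated as a 12-type substitution spectrum, and mapped onto
spliced transcripts with strand-aware re-expression (a genomic A>G inside a
minus-strand exon is a transcript-strand T>C).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from chriplex.annotation import Annotation
from chriplex.sequtils import VALID_BASES, complement

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: the 12 ordered substitution types
SUBSTITUTION_TYPES = tuple(
    f"{ref}>{alt}" for ref in BASES for alt in BASES if ref != alt
)

PILEUP_COLUMNS = ("chrom", "pos", "ref", "countA", "countC", "countG", "countT")

EventKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class ConversionEvent:
    chrom: str
    position: int  # 0-based genomic
    genome_ref_base: str
    genome_alt_base: str
    depth: int  # reads supporting the alternative base
    sample: str

    def __post_init__(self) -> None:
        if self.genome_ref_base == self.genome_alt_base:
            raise ValueError("alt base equals ref base")
        if self.depth < 1:
            raise ValueError("event depth must be >= 1")

    @property
    def key(self) -> EventKey:
        """Strand-naive genomic identity used for all set operations."""
        return (self.chrom, self.position, self.genome_ref_base, self.genome_alt_base)

    @property
    def substitution(self) -> str:
        return f"{self.genome_ref_base}>{self.genome_alt_base}"

    def transcript_strand_substitution(self, strand: str) -> str:
        """Substitution re-expressed on a transcript's strand."""
        if strand == "+":
            return self.substitution
        return f"{complement(self.genome_ref_base)}>{complement(self.genome_alt_base)}"


@dataclass
class SubstitutionSpectrum:
    sample: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        full = {t: 0 for t in SUBSTITUTION_TYPES}
        full.update(self.counts)
        if set(full) != set(SUBSTITUTION_TYPES):
            raise ValueError("unknown substitution type in spectrum")
        if any(v < 0 for v in full.values()):
            raise ValueError("negative substitution count")
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def strand_collapsed(self) -> dict[str, int]:
        """6-category view merging each type with its reverse-strand complement."""
        out: dict[str, int] = {}
        for sub, n in self.counts.items():
            ref, alt = sub.split(">")
            mirror = f"{complement(ref)}>{complement(alt)}"
            label = min(sub, mirror)
            out[label] = out.get(label, 0) + n
        return out


def call_conversions(
    pileup: pd.DataFrame,
    sample: str,
    min_alt_depth: int = 2,
    depth_mode: str = "alt",
) -> list[ConversionEvent]:
    """Call transition events from a per-position base-count table.

    Parameters
    ----------
    pileup
        Columns ``chrom, pos, ref, countA, countC, countG, countT``
        (0-based positions).
    min_alt_depth
        Inclusive depth threshold. With ``depth_mode="alt"`` (default) it
        applies to reads supporting the alternative base; with
        ``depth_mode="total"`` it applies to total coverage at the
        position (any alt-supporting read then qualifies).

    Positions whose reference base is not one of A/C/G/T are skipped and
    counted in a logged message. A position may yield several events when
    more than one alternative base passes the threshold.
    """
    if depth_mode not in ("alt", "total"):
        raise ValueError(f"depth_mode must be 'alt' or 'total', got {depth_mode!r}")
    missing = [c for c in PILEUP_COLUMNS if c not in pileup.columns]
    if missing:
        raise KeyError(f"pileup table lacks columns: {missing}")

    events: list[ConversionEvent] = []
    n_skipped = 0
    multi_alt = 0
    for row in pileup.itertuples(index=False):
        ref = str(row.ref).upper()
        if ref not in VALID_BASES:
            n_skipped += 1
            continue
        counts = {
            "A": int(row.countA),
            "C": int(row.countC),
            "G": int(row.countG),
            "T": int(row.countT),
        }
        total = sum(counts.values())
        hits = 0
        for alt in BASES:
            if alt == ref or counts[alt] < 1:
                continue
            if depth_mode == "alt" and counts[alt] < min_alt_depth:
                continue
            if depth_mode == "total" and total < min_alt_depth:
                continue
            events.append(
                ConversionEvent(
                    chrom=str(row.chrom),
                    position=int(row.pos),
                    genome_ref_base=ref,
                    genome_alt_base=alt,
                    depth=counts[alt],
                    sample=sample,
                )
            )
            hits += 1
        if hits > 1:
            multi_alt += 1
    if n_skipped:
        logger.info("skipped %d pileup positions with non-ACGT reference", n_skipped)
    if multi_alt:
        logger.info("%d positions yielded more than one alt-base event", multi_alt)
    return events


def sample_specific_events(
    ezh2_events: Sequence[ConversionEvent],
    input_events: Sequence[ConversionEvent],
    h3k27me3_events: Sequence[ConversionEvent],
) -> list[ConversionEvent]:
    """EZH2 events whose genomic key appears in neither comparison sample.

    Satisfies |specific| = |ezh2| - |ezh2 & (input | h3k27me3)| with keys
    compared strand-naively in genome coordinates.
    """
    seen = {e.key for e in input_events} | {e.key for e in h3k27me3_events}
    return [e for e in ezh2_events if e.key not in seen]


def substitution_spectrum(
    events: Iterable[ConversionEvent], sample: str | None = None
) -> SubstitutionSpectrum:
    """Tabulate called events over the 12 substitution types."""
    events = list(events)
    if sample is None:
        sample = events[0].sample if events else "unknown"
    counts = Counter(e.substitution for e in events)
    return SubstitutionSpectrum(sample=sample, counts=dict(counts))


def map_events_to_transcripts(
    events: Sequence[ConversionEvent],
    annotation: Annotation,
) -> tuple[dict[str, list[tuple[int, str, int]]], list[ConversionEvent]]:
    """Assign events to every transcript whose exon union contains them.

    Returns
    -------
    mapping
        transcript id -> list of ``(exon index in transcript order,
        transcript-strand substitution, depth)``.
    unassigned
        Events outside the exon union of every transcript.
    """
    by_chrom = annotation.by_chrom()
    mapping: dict[str, list[tuple[int, str, int]]] = {}
    unassigned: list[ConversionEvent] = []
    for event in events:
        hit = False
        for tx in by_chrom.get(event.chrom, ()):  # small annotations: linear scan
            idx = tx.exon_index(event.position)
            if idx is None:
                continue
            sub = event.transcript_strand_substitution(tx.strand)
            mapping.setdefault(tx.transcript_id, []).append((idx, sub, event.depth))
            hit = True
        if not hit:
            unassigned.append(event)
    return mapping, unassigned


def contact_site_transcripts(
    mapping: dict[str, list[tuple[int, str, int]]],
    substitution: str = "T>C",
) -> set[str]:
    """Transcripts carrying >= 1 mapped event of the given transcript-strand class."""
    return {
        tid
        for tid, rows in mapping.items()
        if any(sub == substitution for _, sub, _ in rows)
    }
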