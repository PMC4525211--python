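"""Dual pull-down enrichment calling over RPKM-quantified transcripts.

A transcript is called repressive-chromatin enriched only when its
pull-down/input fold change reaches the threshold in *both* the H3K27me3
and the EZH2 samples (inclusive comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from chriplex.annotation import Annotation, LNCRNA_BIOTYPES

SAMPLES = ("input", "h3k27me3", "ezh2")

DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class EnrichmentRecord:
    transcript_id: str
    rpkm_input: float
    rpkm_h3k27me3: float
    rpkm_ezh2: float
    fc_h3k27me3: float
    fc_ezh2: float
    enriched_h3k27me3: bool
    enriched_ezh2: bool
    enriched_dual: bool


@dataclass(frozen=True)
class OverlapTestResult:
    overlap_k: int
    set_a_size: int
    set_b_size: int
    universe_size: int
    p_value: float
    log10_p: float = 0.0  # survives underflow of p_value for tiny tails


def quantify_rpkm(
    counts: pd.DataFrame,
    annotation: Annotation,
) -> pd.DataFrame:
    """Convert a per-transcript read-count table to RPKM.

    Parameters
    ----------
    counts
        DataFrame indexed by transcript id with one integer column per
        sample. Totals per sample are taken from the table itself (the
        table is assumed to hold all counted reads).
    annotation
        Source of exonic lengths (exon-union length per transcript).

    Returns
    -------
    DataFrame of the same shape holding RPKM values.
    """
    unknown = [tid for tid in counts.index if tid not in annotation]
    if unknown:
        raise KeyError(
            "count table contains transcript ids absent from the annotation: "
            + ", ".join(map(str, unknown[:10]))
            + ("..." if len(unknown) > 10 else "")
        )
    lengths_kb = pd.Series(
        {tid: annotation[tid].exonic_length / 1000.0 for tid in counts.index},
        dtype=float,
    )
    rpkm = pd.DataFrame(index=counts.index, dtype=float)
    for sample in counts.columns:
        total = float(counts[sample].sum())
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total mapped reads")
        rpkm[sample] = counts[sample] / (lengths_kb * (total / 1e6))
    return rpkm


def fold_change(
    rpkm_pulldown: float, rpkm_input: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Pseudocount-stabilized pull-down/input RPKM ratio."""
    return (rpkm_pulldown + pseudocount) / (rpkm_input + pseudocount)


def call_dual_enriched(
    rpkm: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    annotation: Annotation | None = None,
    lncrna_only: bool = False,
) -> tuple[set[str], list[EnrichmentRecord]]:
    """Call transcripts enriched >= *fold_threshold* in both pull-downs.

    Parameters
    ----------
    rpkm
        RPKM table with columns ``input``, ``h3k27me3``, ``ezh2``.
    fold_threshold
        Inclusive minimum fold change required in each pull-down.
    pseudocount
        RPKM added to numerator and denominator of every fold change.
    annotation, lncrna_only
        When ``lncrna_only`` is set, the returned enriched set is
        restricted to lncRNA biotypes; records are still produced for
        every transcript so coding transcripts stay available as
        negative controls.

    Returns
    -------
    (enriched transcript ids, EnrichmentRecord list)
    """
    if fold_threshold < 0:
        raise ValueError(f"fold_threshold must be >= 0, got {fold_threshold}")
    missing = [s for s in SAMPLES if s not in rpkm.columns]
    if missing:
        raise KeyError(f"RPKM table lacks required sample columns: {missing}")
    if lncrna_only and annotation is None:
        raise ValueError("lncrna_only requires an annotation")

    records: list[EnrichmentRecord] = []
    enriched: set[str] = set()
    for tid, row in rpkm.iterrows():
        fc_k27 = fold_change(row["h3k27me3"], row["input"], pseudocount)
        fc_ezh2 = fold_change(row["ezh2"], row["input"], pseudocount)
        hit_k27 = fc_k27 >= fold_threshold
        hit_ezh2 = fc_ezh2 >= fold_threshold
        dual = hit_k27 and hit_ezh2
        records.append(
            EnrichmentRecord(
                transcript_id=str(tid),
                rpkm_input=float(row["input"]),
                rpkm_h3k27me3=float(row["h3k27me3"]),
                rpkm_ezh2=float(row["ezh2"]),
                fc_h3k27me3=fc_k27,
                fc_ezh2=fc_ezh2,
                enriched_h3k27me3=hit_k27,
                enriched_ezh2=hit_ezh2,
                enriched_dual=dual,
            )
        )
        if dual:
            if lncrna_only and annotation is not None:
                if annotation[str(tid)].biotype not in LNCRNA_BIOTYPES:
                    continue
            enriched.add(str(tid))
    return enriched, records


def records_to_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate EnrichmentRecords for TSV output."""
    return pd.DataFrame([r.__dict__ for r in records]).set_index("transcript_id")


def hypergeometric_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
) -> OverlapTestResult:
    """Upper-tail hypergeometric test P(X >= |a & b|).

    X ~ Hypergeometric(|universe|, |a|, |b|). Elements outside the
    universe are an error: silently shrinking the universe would bias P.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    stray = (a | b) - u
    if stray:
        raise ValueError(
            "sets contain elements outside the universe: "
            + ", ".join(sorted(map(str, stray))[:10])
        )
    k = len(a & b)
    # survival function in log space guards the tiny-tail regime
    logp = float(stats.hypergeom.logsf(k - 1, len(u), len(a), len(b)))
    p = float(math.exp(min(logp, 0.0))) if math.isfinite(logp) else 0.0
    return OverlapTestResult(
        overlap_k=k,
        set_a_size=len(a),
        set_b_size=len(b),
        universe_size=len(u),
        p_value=min(p, 1.0),
        log10_p=min(logp, 0.0) / math.log(10) if math.isfinite(logp) else -math.inf,
    )


def overlap_result_to_dict(result: OverlapTestResult) -> Mapping[str, float]:
    return dict(result.__dict__)
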