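"""Peak-to-gene association via basal-plus-extension regulatory domains,
interval intersection, Fisher gene-set enrichment and a GA-content surrogate
motif statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chriplex.annotation import Annotation
from chriplex.sequtils import max_run_in_alphabet

logger = logging.getLogger(__name__)

GA_ALPHABET = frozenset("GA")


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    sample: str = "peak"
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.name} at {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if not self.start <= self.summit < self.end:
            raise ValueError(
                f"peak {self.name}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    basal: tuple[int, int]
    extended: tuple[int, int]

    def __post_init__(self) -> None:
        bs, be = self.basal
        es, ee = self.extended
        if not (es <= bs and be <= ee):
            raise ValueError(f"{self.gene_id}: basal not contained in extended")
        if not bs <= self.tss < be:
            raise ValueError(f"{self.gene_id}: basal does not contain the TSS")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        object.__setattr__(self, "genes", frozenset(self.genes))


def canonical_tss(annotation: Annotation) -> dict[str, tuple[str, int, str]]:
    """One TSS per gene: the 5'-most TSS among its transcripts on the gene strand."""
    out: dict[str, tuple[str, int, str]] = {}
    for tx in annotation:
        cur = out.get(tx.gene_id)
        if cur is None:
            out[tx.gene_id] = (tx.chrom, tx.tss, tx.strand)
            continue
        chrom, tss, strand = cur
        if tx.chrom != chrom:
            logger.warning("gene %s spans chromosomes; keeping first", tx.gene_id)
            continue
        if (strand == "+" and tx.tss < tss) or (strand == "-" and tx.tss > tss):
            out[tx.gene_id] = (chrom, tx.tss, strand)
    return out


def build_regulatory_domains(
    annotation: Annotation,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    The basal domain spans ``basal_up`` upstream to ``basal_down``
    downstream of the TSS, oriented by strand. Each side is then extended
    to the nearer of ``max_extension`` from the TSS or the neighbouring
    gene's basal-domain boundary, never shrinking below the basal domain.
    Domains may overlap.
    """
    tss_map = canonical_tss(annotation)
    basal_of: dict[str, tuple[int, int]] = {}
    for gene_id, (chrom, tss, strand) in tss_map.items():
        if strand == "+":
            basal = (tss - basal_up, tss + basal_down)
        else:
            basal = (tss - basal_down + 1, tss + basal_up + 1)
        basal_of[gene_id] = basal

    by_chrom: dict[str, list[str]] = {}
    for gene_id, (chrom, _, _) in tss_map.items():
        by_chrom.setdefault(chrom, []).append(gene_id)

    domains: list[RegulatoryDomain] = []
    for chrom, gene_ids in by_chrom.items():
        chrom_len = None if chrom_sizes is None else chrom_sizes.get(chrom)
        for gene_id in gene_ids:
            _, tss, strand = tss_map[gene_id]
            bs, be = basal_of[gene_id]
            left_stop = max(
                (basal_of[g][1] for g in gene_ids if g != gene_id and basal_of[g][1] <= bs),
                default=0,
            )
            right_stop = min(
                (basal_of[g][0] for g in gene_ids if g != gene_id and basal_of[g][0] >= be),
                default=chrom_len if chrom_len is not None else tss + max_extension,
            )
            es = max(tss - max_extension, left_stop, 0)
            ee = min(tss + max_extension, right_stop)
            es = min(es, bs)
            ee = max(ee, be)
            bs_clip, es_clip = max(bs, 0), max(es, 0)
            if chrom_len is not None:
                be = min(be, chrom_len)
                ee = min(ee, chrom_len)
            domains.append(
                RegulatoryDomain(
                    gene_id=gene_id,
                    chrom=chrom,
                    tss=tss,
                    strand=strand,
                    basal=(bs_clip, be),
                    extended=(es_clip, ee),
                )
            )
    domains.sort(key=lambda d: (d.chrom, d.tss, d.gene_id))
    return domains


@dataclass
class PeakAssociation:
    peak_genes: dict[int, set[str]]  # peak index -> associated gene ids
    promoter_peaks: list[int]
    distal_peaks: list[int]
    unassociated_peaks: list[int]

    @property
    def associated_genes(self) -> set[str]:
        genes: set[str] = set()
        for g in self.peak_genes.values():
            genes |= g
        return genes


def associate_peaks(
    peaks: Sequence[Peak],
    domains: Sequence[RegulatoryDomain],
    by_overlap: bool = False,
) -> PeakAssociation:
    """Associate peaks with genes whose extended domain contains the summit.

    A peak is classed "promoter" iff its summit lies inside at least one
    basal domain, else "distal"; the two classes partition the associated
    peaks. With ``by_overlap`` a peak associates by any interval overlap
    with the extended domain instead of summit containment.
    """
    peak_genes: dict[int, set[str]] = {}
    promoter: list[int] = []
    distal: list[int] = []
    unassociated: list[int] = []
    for i, peak in enumerate(peaks):
        genes: set[str] = set()
        in_basal = False
        for dom in domains:
            if dom.chrom != peak.chrom:
                continue
            es, ee = dom.extended
            if by_overlap:
                associated = peak.start < ee and es < peak.end
            else:
                associated = es <= peak.summit < ee
            if associated:
                genes.add(dom.gene_id)
            bs, be = dom.basal
            if bs <= peak.summit < be:
                in_basal = True
        if genes:
            peak_genes[i] = genes
            (promoter if in_basal else distal).append(i)
        else:
            unassociated.append(i)
    return PeakAssociation(
        peak_genes=peak_genes,
        promoter_peaks=promoter,
        distal_peaks=distal,
        unassociated_peaks=unassociated,
    )


def intersect_with_marks(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    min_overlap_bp: int = 1,
) -> tuple[list[Peak], dict[str, int]]:
    """Peaks of A sharing >= *min_overlap_bp* with >= 1 interval of B.

    Returns the overlapping subset of A plus symmetric counts for both
    directions.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    for name, group in (("A", peaks_a), ("B", peaks_b)):
        for p in group:
            if p.start >= p.end:
                raise ValueError(
                    f"malformed interval in set {name}: {p.chrom}:{p.start}-{p.end}"
                )

    def _hits(query: Sequence[Peak], subject: Sequence[Peak]) -> list[Peak]:
        by_chrom: dict[str, list[Peak]] = {}
        for p in subject:
            by_chrom.setdefault(p.chrom, []).append(p)
        for group in by_chrom.values():
            group.sort(key=lambda p: p.start)
        out = []
        for q in query:
            group = by_chrom.get(q.chrom, [])
            starts = [p.start for p in group]
            # sorted sweep: only intervals starting before q.end can overlap
            idx = int(np.searchsorted(starts, q.end - min_overlap_bp, side="right"))
            if any(
                min(q.end, p.end) - max(q.start, p.start) >= min_overlap_bp
                for p in group[:idx]
            ):
                out.append(q)
        return out

    a_hits = _hits(peaks_a, peaks_b)
    b_hits = _hits(peaks_b, peaks_a)
    counts = {
        "a_total": len(peaks_a),
        "b_total": len(peaks_b),
        "a_overlapping_b": len(a_hits),
        "b_overlapping_a": len(b_hits),
    }
    return a_hits, counts


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted q-values, monotone and capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        q = min(1.0, p_values[i] * m / rank)
        running_min = min(running_min, q)
        adjusted[i] = running_min
    return adjusted


def fisher_gene_set_enrichment(
    query: GeneSet,
    pathway_sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of *query* in each pathway.

    For each pathway the 2x2 table (in-query & in-pathway, in-query only,
    in-pathway only, neither) is tested for enrichment (greater); raw
    p-values are primary, a Benjamini-Hochberg column is included.
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    stray = query.genes - u
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:10]}")
    rows = []
    for pathway in pathway_sets:
        outside = pathway.genes - u
        if outside:
            raise ValueError(
                f"pathway {pathway.name!r} has genes outside universe: "
                f"{sorted(outside)[:10]}"
            )
        k = len(query.genes & pathway.genes)
        table = [
            [k, len(query.genes) - k],
            [len(pathway.genes) - k, len(u) - len(query.genes) - len(pathway.genes) + k],
        ]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "pathway": pathway.name,
                "overlap": k,
                "query_size": len(query.genes),
                "pathway_size": len(pathway.genes),
                "odds_ratio": float(odds),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "pathway", "overlap", "query_size", "pathway_size", "odds_ratio", "p_value",
        ],
    )
    out["p_adjusted"] = benjamini_hochberg(list(out["p_value"])) if len(out) else []
    return out


def ga_content_enrichment(
    peak_sequences: Sequence[str],
    n_shuffles: int,
    seed: int,
) -> dict[str, float]:
    """GA-run-length enrichment against per-sequence mononucleotide shuffles.

    Statistic: mean (over sequences) maximal run length in the {G, A}
    alphabet. The null shuffles each sequence's letters independently;
    empirical p = (1 + #null >= observed) / (1 + n_shuffles).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not peak_sequences:
        raise ValueError("no sequences supplied")
    rng = np.random.default_rng(seed)
    seqs = [s.upper() for s in peak_sequences]
    observed = float(
        np.mean([max_run_in_alphabet(s, GA_ALPHABET) for s in seqs])
    )
    arrays = [np.frombuffer(s.encode(), dtype=np.uint8).copy() for s in seqs]
    n_ge = 0
    for _ in range(n_shuffles):
        total = 0.0
        for arr in arrays:
            rng.shuffle(arr)
            total += max_run_in_alphabet(arr.tobytes().decode(), GA_ALPHABET)
        if total / len(arrays) >= observed:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_shuffles)
    return {
        "statistic": observed,
        "p_value": p,
        "n_shuffles": n_shuffles,
        "n_sequences": len(seqs),
    }
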