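"""Independent brute-force oracles used to cross-check the implementations.

Every function here enumerates the definition literally and stays
independent of the code paths it validates.
"""

from __future__ import annotations

import itertools
import math

PURINE = frozenset("GA")
ALPHABETS = {
    "purine": frozenset("GA"),
    "pyrimidine": frozenset("CT"),
    "mixed": frozenset("GT"),
}
TRIADS = {
    "purine": {("A", "A"), ("G", "G")},
    "pyrimidine": {("T", "A"), ("C", "G")},
    "mixed": {("G", "G"), ("T", "A")},
}
ORIENTATIONS = {
    "purine": ("antiparallel",),
    "pyrimidine": ("parallel",),
    "mixed": ("parallel", "antiparallel"),
}

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _longest_error_run(window: str, alphabet: frozenset[str]) -> int:
    best = cur = 0
    for b in window:
        cur = cur + 1 if b not in alphabet else 0
        best = max(best, cur)
    return best


def enumerate_windows(seq, alphabet, min_length, max_error_rate,
                      max_consecutive_errors, min_guanine_fraction):
    """All (start, end) windows satisfying every constraint literally."""
    valid = []
    n = len(seq)
    for i in range(n):
        for j in range(i + min_length, n + 1):
            w = seq[i:j]
            if w[0] not in alphabet or w[-1] not in alphabet:
                continue  # boundary bases must be canonical
            n_err = sum(1 for b in w if b not in alphabet)
            if n_err > max_error_rate * len(w):
                continue
            if _longest_error_run(w, alphabet) > max_consecutive_errors:
                continue
            if w.count("G") < min_guanine_fraction * len(w):
                continue
            valid.append((i, j))
    return valid


def maximal_windows_oracle(seq, alphabet, params):
    """Valid windows not properly contained in another valid window."""
    valid = enumerate_windows(
        seq, alphabet, params.min_length, params.max_error_rate,
        params.max_consecutive_errors, params.min_guanine_fraction,
    )
    valid_set = set(valid)
    return sorted(
        w for w in valid
        if not any(
            o != w and o[0] <= w[0] and o[1] >= w[1] for o in valid_set
        )
    )


def tfo_hits_oracle(seq, params):
    """Expected (start, end, motif) tuples of find_tfos."""
    seq = seq.upper().replace("U", "T")
    out = []
    for motif in params.motifs:
        for start, end in maximal_windows_oracle(seq, ALPHABETS[motif], params):
            out.append((start, end, motif))
    return sorted(out)


def trts_hits_oracle(seq, params):
    """Expected (start, end, purine_strand) tuples of find_trts."""
    seq = seq.upper()
    out = [
        (s, e, "+") for s, e in maximal_windows_oracle(seq, PURINE, params)
    ]
    rc = revcomp(seq)
    n = len(seq)
    out += [
        (n - e, n - s, "-") for s, e in maximal_windows_oracle(rc, PURINE, params)
    ]
    return sorted(out)


def match_oracle(tfo_seq, motif, duplex_seq, min_length, max_error_rate):
    """All (orientation, offset, matched_length, errors) passing the gates."""
    triads = TRIADS[motif]
    out = []
    for orientation in ORIENTATIONS[motif]:
        third = tfo_seq if orientation == "parallel" else tfo_seq[::-1]
        for off in range(-len(third) + 1, len(duplex_seq)):
            pairs = [
                (third[k - off], duplex_seq[k])
                for k in range(max(0, off), min(len(duplex_seq), off + len(third)))
            ]
            if len(pairs) < min_length:
                continue
            errors = sum(1 for p in pairs if p not in triads)
            if errors > max_error_rate * len(pairs):
                continue
            out.append((orientation, off, len(pairs), errors))
    return sorted(out)


def hypergeom_upper_tail_oracle(universe_size, a_size, b_size, k):
    """P(|A & B| >= k) by enumerating every size-b subset of the universe."""
    universe = list(range(universe_size))
    a = set(universe[:a_size])
    n_total = 0
    n_hit = 0
    for b in itertools.combinations(universe, b_size):
        n_total += 1
        if len(a & set(b)) >= k:
            n_hit += 1
    return n_hit / n_total


def fisher_one_sided_oracle(k, q, p, u):
    """P(X >= k) for X ~ Hypergeom(u, q, p): Fisher one-sided enrichment p.

    q = query size, p = pathway size, u = universe size.
    """
    total = math.comb(u, p)
    acc = 0
    for x in range(k, min(q, p) + 1):
        acc += math.comb(q, x) * math.comb(u - q, p - x)
    return acc / total


def quadratic_intersection_oracle(intervals_a, intervals_b, min_overlap_bp=1):
    """Indices of A sharing >= min_overlap_bp with any interval of B."""
    hits = []
    for i, (chrom_a, sa, ea) in enumerate(intervals_a):
        for chrom_b, sb, eb in intervals_b:
            if chrom_a == chrom_b and min(ea, eb) - max(sa, sb) >= min_overlap_bp:
                hits.append(i)
                break
    return hits


def association_oracle(peaks, domains):
    """All-pairs summit containment: peak index -> set of gene ids."""
    out = {}
    for i, (chrom, summit) in enumerate(peaks):
        genes = {
            gene_id
            for gene_id, dchrom, (es, ee) in domains
            if dchrom == chrom and es <= summit < ee
        }
        if genes:
            out[i] = genes
    return out
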