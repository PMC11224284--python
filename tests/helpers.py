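"""Independent oracles and fixture builders shared across the test suite.

Everything here is deliberately naive — direct enumeration, exact rational
arithmetic, brute-force pair counting — and never calls the code paths it is
used to check.
"""

from __future__ import annotations

import math
from fractions import Fraction

from tcrscreen import ClonotypeRecord, Repertoire

_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def int_to_cdr3(i: int, prefix: str = "CASS") -> str:
    """Deterministic distinct CDR3 string for index i."""
    digits = []
    i += 1
    while i:
        digits.append(_LETTERS[i % 20])
        i //= 20
    return prefix + "".join(digits) + "F"


def make_repertoire(
    counts,
    sample_id: str = "s",
    phenotype: str = "unknown",
    vj_pairs=None,
) -> Repertoire:
    """Repertoire with the given clone sizes; distinct CDR3s per clone.

    ``vj_pairs`` optionally assigns (V, J) per clone; defaults to one shared
    pair so V-J structure does not interfere with count-based indices.
    """
    records = []
    for i, c in enumerate(counts):
        v, j = vj_pairs[i] if vj_pairs else ("TRBV1", "TRBJ1-1")
        records.append(ClonotypeRecord(int_to_cdr3(i), v, j, int(c)))
    return Repertoire.from_records(sample_id, phenotype, records)


def membership_repertoire(keys, sample_id="s", phenotype="unknown") -> Repertoire:
    """Repertoire containing exactly the given canonical-style keys (count 1)."""
    records = []
    for k in keys:
        cdr3, v, j = k.split("_")
        records.append(ClonotypeRecord(cdr3, v, j, 1))
    return Repertoire.from_records(sample_id, phenotype, records)


# --- Fisher's exact test: exhaustive hypergeometric enumeration, exact rationals


def exact_fisher_p(a: int, b: int, c: int, d: int, alternative: str = "two_sided") -> float:
    r, n = a + b, a + b + c + d
    k = a + c
    denom = math.comb(n, k)
    lo, hi = max(0, k - (n - r)), min(k, r)

    def pmf(x: int) -> Fraction:
        return Fraction(math.comb(r, x) * math.comb(n - r, k - x), denom)

    if alternative == "case_enriched":
        return float(sum(pmf(x) for x in range(a, hi + 1)))
    p_obs = pmf(a)
    return float(sum(p for x in range(lo, hi + 1) if (p := pmf(x)) <= p_obs))


# --- diversity indices: independent brute-force summations from raw counts


def brute_shannon(counts) -> float:
    total = sum(counts)
    h = 0.0
    for c in counts:
        p = c / total
        if p > 0:
            h -= p * math.log(p)
    return h


def brute_simpson(counts) -> float:
    total = sum(counts)
    return sum((c / total) ** 2 for c in counts)


def brute_clonality(counts) -> float:
    n = len(counts)
    if n <= 1:
        return 0.0
    return 1.0 - brute_shannon(counts) / math.log(n)


def brute_singleton(counts) -> float:
    n = len(counts)
    if n <= 1:
        return 0.0
    return sum(1 for c in counts if c == 1) / (n - 1)


def brute_hvj(records) -> float:
    usage: dict[tuple, int] = {}
    for rec in records:
        usage[(rec.v_gene, rec.j_gene)] = usage.get((rec.v_gene, rec.j_gene), 0) + rec.count
    return brute_shannon(list(usage.values()))


# --- AUC: all-pairs Mann-Whitney with ties counted one half


def pairwise_auc(scores, labels) -> float:
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
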