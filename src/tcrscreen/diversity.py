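"""Repertoire diversity indices.

Six sample-level indices summarise how clonal a TCR repertoire is: Shannon
entropy (nats), Simpson concentration and its inverse, clonality
(1 − H/ln richness), Shannon entropy over V–J gene-combination usage (Hvj),
and the singleton ratio n1/(n−1).  All frequencies are template-count
weighted: p_i = count_i / total_count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .repertoire_io import Repertoire

_FREQ_TOL = 1e-9


class DiversityDomainError(ValueError):
    pass


@dataclass(frozen=True)
class DiversityProfile:
    """The six indices plus richness for one repertoire."""

    shannon: float
    simpson: float
    invsimpson: float
    clonality: float
    hvj: float
    singleton_ratio: float
    richness: int

    #: fixed column order used by feature tables and TSV exports
    FIELDS = ("clonality", "shannon", "invsimpson", "hvj", "singleton_ratio", "simpson")


def _check_frequencies(frequencies: Sequence[float]) -> np.ndarray:
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0:
        raise DiversityDomainError("empty frequency vector")
    if np.any(p < 0):
        raise DiversityDomainError("negative frequency")
    if abs(p.sum() - 1.0) > _FREQ_TOL:
        raise DiversityDomainError(f"frequencies sum to {p.sum()}, not 1")
    return p


def shannon_index(frequencies: Sequence[float]) -> float:
    """Shannon entropy H' = −Σ p_i ln p_i in nats, with 0·ln 0 ≡ 0."""
    p = _check_frequencies(frequencies)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson_indices(frequencies: Sequence[float]) -> tuple[float, float]:
    """(Simpson Σp², inverse Simpson 1/Σp²)."""
    p = _check_frequencies(frequencies)
    s = float((p * p).sum())
    return s, 1.0 / s


def _frequencies(repertoire: Repertoire) -> np.ndarray:
    counts = np.asarray(repertoire.counts(), dtype=float)
    return counts / counts.sum()


def clonality_index(repertoire: Repertoire) -> float:
    """Clonality = 1 − H'/ln(richness); 0 = perfectly even, 1 = monoclonal.

    A single-clonotype repertoire returns 0 by convention (the formula is
    undefined there; 0 is the no-amplification-information value).
    """
    n = repertoire.richness
    if n == 0:
        raise DiversityDomainError("empty repertoire")
    if n == 1:
        return 0.0
    h = shannon_index(_frequencies(repertoire))
    return 1.0 - h / math.log(n)


def hvj_index(repertoire: Repertoire) -> float:
    """Shannon entropy of count-weighted (V family, J gene) usage frequencies."""
    if repertoire.richness == 0:
        raise DiversityDomainError("empty repertoire")
    usage: dict[tuple[str, str], int] = {}
    for rec in repertoire.records.values():
        pair = (rec.v_gene, rec.j_gene)
        usage[pair] = usage.get(pair, 0) + rec.count
    counts = np.asarray(list(usage.values()), dtype=float)
    return shannon_index(counts / counts.sum())


def singleton_ratio(
    repertoire: Repertoire,
    denominator: Literal["n_minus_1", "n"] = "n_minus_1",
) -> float:
    """Singleton ratio n1/(n−1): count-1 clonotypes over richness minus one.

    The n−1 denominator is the published form and can exceed 1 (e.g. two
    singletons give 2/1 = 2); ``denominator="n"`` switches to n1/n.  A
    single-clonotype repertoire returns 0.
    """
    n = repertoire.richness
    if n == 0:
        raise DiversityDomainError("empty repertoire")
    if n == 1:
        return 0.0
    n1 = sum(1 for r in repertoire.records.values() if r.count == 1)
    return n1 / (n - 1 if denominator == "n_minus_1" else n)


def diversity_profile(
    repertoire: Repertoire,
    singleton_denominator: Literal["n_minus_1", "n"] = "n_minus_1",
) -> DiversityProfile:
    """All six indices from count-derived frequencies p_i = count_i/total."""
    if repertoire.richness == 0:
        raise DiversityDomainError("empty repertoire")
    p = _frequencies(repertoire)
    shannon = shannon_index(p)
    simpson, invsimpson = simpson_indices(p)
    return DiversityProfile(
        shannon=shannon,
        simpson=simpson,
        invsimpson=invsimpson,
        clonality=clonality_index(repertoire),
        hvj=hvj_index(repertoire),
        singleton_ratio=singleton_ratio(repertoire, singleton_denominator),
        richness=repertoire.richness,
    )
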