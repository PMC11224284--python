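"""Disease-associated clonotype screening by Fisher's exact test.

Each clonotype observed in the training cohort gets a 2×2 presence/absence
table (cases with/without, controls with/without) and an exact P-value.
Screening filters to a P-value cutoff; a ladder of cutoffs (default
0.1, 1e-2, 1e-3, 1e-4) yields nested candidate sets.  Presence means the
canonical key occurs with count >= 1; no multiple-testing correction is
applied — the cutoff ladder is the control mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from scipy import stats

from .repertoire_io import Repertoire

DEFAULT_CUTOFFS = (0.1, 1e-2, 1e-3, 1e-4)

Alternative = Literal["two_sided", "case_enriched"]


@dataclass(frozen=True)
class ContingencyTable:
    """Presence counts: a cases with the clone, b without; c/d for controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell in contingency table")

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    key: str
    table: ContingencyTable
    p_value: float


def fisher_exact_p(table: ContingencyTable, alternative: Alternative = "two_sided") -> float:
    """Exact hypergeometric P-value of a 2×2 presence table.

    ``two_sided`` sums the probabilities of all tables with the same margins
    whose probability does not exceed the observed table's; ``case_enriched``
    is the upper tail P(X >= a).
    """
    t = [[table.a, table.b], [table.c, table.d]]
    if alternative == "two_sided":
        return float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    if alternative == "case_enriched":
        return float(stats.fisher_exact(t, alternative="greater").pvalue)
    raise ValueError(f"unknown alternative {alternative!r}")


def presence_counts(cohort: Sequence[Repertoire], key: str) -> ContingencyTable:
    """2×2 presence table for one clonotype key over a labelled cohort."""
    if not cohort:
        raise ValueError("empty cohort")
    cases = [r for r in cohort if r.phenotype == "case"]
    controls = [r for r in cohort if r.phenotype == "control"]
    if not cases or not controls:
        raise ValueError("cohort must contain both phenotypes")
    a = sum(1 for r in cases if key in r.records)
    c = sum(1 for r in controls if key in r.records)
    return ContingencyTable(a, len(cases) - a, c, len(controls) - c)


def _all_results(
    cohort: Sequence[Repertoire], alternative: Alternative
) -> list[AssociationResult]:
    cases = [r for r in cohort if r.phenotype == "case"]
    controls = [r for r in cohort if r.phenotype == "control"]
    if not cases or not controls:
        raise ValueError("cohort must contain both phenotypes")
    n_case, n_ctrl = len(cases), len(controls)

    case_hits: dict[str, int] = {}
    ctrl_hits: dict[str, int] = {}
    for r in cases:
        for k in r.records:
            case_hits[k] = case_hits.get(k, 0) + 1
    for r in controls:
        for k in r.records:
            ctrl_hits[k] = ctrl_hits.get(k, 0) + 1

    # margins are fixed cohort-wide, so p-values depend only on (a, c): memoize
    p_cache: dict[tuple[int, int], float] = {}
    results = []
    for key in set(case_hits) | set(ctrl_hits):
        a = case_hits.get(key, 0)
        c = ctrl_hits.get(key, 0)
        p = p_cache.get((a, c))
        table = ContingencyTable(a, n_case - a, c, n_ctrl - c)
        if p is None:
            p = fisher_exact_p(table, alternative)
            p_cache[(a, c)] = p
        results.append(AssociationResult(key, table, p))
    results.sort(key=lambda r: (r.p_value, r.key))
    return results


def screen(
    cohort: Sequence[Repertoire],
    cutoff: float,
    alternative: Alternative = "two_sided",
) -> list[AssociationResult]:
    """All clonotypes observed in the training cohort with p_value < cutoff.

    The filter is strict (p < cutoff), except that a cutoff >= 1 returns every
    observed key (keys with p exactly 1 included).  Results are sorted by
    ascending p-value, ties broken lexicographically by key.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    results = _all_results(cohort, alternative)
    if cutoff >= 1.0:
        return results
    return [r for r in results if r.p_value < cutoff]


def threshold_traverse(
    cohort: Sequence[Repertoire],
    cutoffs: Iterable[float] = DEFAULT_CUTOFFS,
    alternative: Alternative = "two_sided",
) -> dict[float, set[str]]:
    """Key sets at a descending ladder of cutoffs, from one shared p-value pass.

    Output sets are nested: the set at a smaller cutoff is a subset of the set
    at any larger one.
    """
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs, reverse=True):
        raise ValueError("cutoffs must be sorted descending")
    results = _all_results(cohort, alternative)
    out: dict[float, set[str]] = {}
    for c in cutoffs:
        if c >= 1.0:
            out[c] = {r.key for r in results}
        else:
            out[c] = {r.key for r in results if r.p_value < c}
    return out


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "key": r.key,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "p_value": r.p_value,
            }
            for r in results
        ],
        columns=["key", "a", "b", "c", "d", "p_value"],
    )


def write_results(results: Sequence[AssociationResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
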