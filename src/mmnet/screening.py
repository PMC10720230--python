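"""Pairwise comorbidity screening: 2x2 counts, odds ratios, edge selection.

Every unordered pair of diseases that co-occurs in at least one baseline
record is a candidate comorbidity pattern.  For each pattern the 2x2
patient-level contingency table is tallied, the odds ratio estimated, and
three selection criteria applied: OR > 1, a Bonferroni-adjusted Wald
p-value, and a pattern-prevalence floor of 1 in 10,000 inpatients.

With a single binary covariate the unadjusted logistic-regression odds
ratio equals the contingency cross-product ratio (n11*n00)/(n10*n01) and
the Wald standard error of the log odds ratio is
sqrt(1/n11 + 1/n10 + 1/n01 + 1/n00), so the closed form is computed
directly; a regression fit serves as the independent oracle in the tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import Cohort

__all__ = [
    "PairwiseCounts",
    "PatternResult",
    "SelectionReport",
    "bonferroni_n",
    "disease_prevalence",
    "enumerate_patterns",
    "estimate_or",
    "fisher_p",
    "patterns_to_frame",
    "screen_cohort",
    "select_edges",
]

PREVALENCE_FLOOR = 1e-4  # "common pattern" floor: > 1 per 10,000 inpatients


@dataclass(frozen=True)
class PairwiseCounts:
    """Patient-level 2x2 contingency counts for one unordered disease pair."""

    pair: tuple[str, str]
    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        if self.pair[0] > self.pair[1]:
            n10, n01 = self.n10, self.n01
            object.__setattr__(self, "pair", (self.pair[1], self.pair[0]))
            object.__setattr__(self, "n10", n01)
            object.__setattr__(self, "n01", n10)

    @property
    def n_inpatients(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def frequency(self) -> int:
        """Number of inpatients whose baseline record contains both diseases."""
        return self.n11

    @property
    def prevalence(self) -> float:
        return self.n11 / self.n_inpatients


@dataclass
class PatternResult:
    """Odds ratio, p-value, and selection status for one pattern."""

    counts: PairwiseCounts
    odds_ratio: float
    p_value: float
    zero_cell: bool = False
    selected: bool = False
    bonferroni_n: int | None = None
    alpha_adjusted: float | None = None


@dataclass
class SelectionReport:
    """Counts of patterns failing each selection criterion."""

    n_patterns: int = 0
    n_selected: int = 0
    failed_or: int = 0
    failed_p: int = 0
    failed_prevalence: int = 0
    bonferroni_n: int = 0
    alpha_adjusted: float = float("nan")


def disease_prevalence(cohort: Cohort) -> dict[str, tuple[int, float]]:
    """Per-disease record count and prevalence (count / n_inpatients)."""
    n = cohort.n_inpatients
    counts: dict[str, int] = {}
    for rec in cohort.records:
        for code in rec.codes:
            counts[code] = counts.get(code, 0) + 1
    return {code: (c, c / n) for code, c in sorted(counts.items())}


def _indicator_matrix(cohort: Cohort) -> tuple[np.ndarray, list[str]]:
    codes = sorted({c for rec in cohort.records for c in rec.codes})
    index = {c: j for j, c in enumerate(codes)}
    x = np.zeros((cohort.n_inpatients, len(codes)), dtype=bool)
    for i, rec in enumerate(cohort.records):
        for c in rec.codes:
            x[i, index[c]] = True
    return x, codes


def enumerate_patterns(cohort: Cohort) -> list[PairwiseCounts]:
    """All unordered pairs co-occurring in >= 1 record, with 2x2 counts.

    Counts are at patient level: each baseline record contributes to the
    cell matching its presence/absence of the two diseases, so the four
    cells of every pattern sum to ``n_inpatients``.
    """
    x, codes = _indicator_matrix(cohort)
    if not codes:
        return []
    n = x.shape[0]
    co = x.T.astype(np.int64) @ x
    margins = np.diag(co)
    out = []
    ii, jj = np.nonzero(np.triu(co, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        n11 = int(co[i, j])
        out.append(PairwiseCounts(
            pair=(codes[i], codes[j]), n11=n11,
            n10=int(margins[i]) - n11, n01=int(margins[j]) - n11,
            n00=n - int(margins[i]) - int(margins[j]) + n11))
    return out


def _or_wald(n11: float, n10: float, n01: float, n00: float
             ) -> tuple[float, float]:
    oddsr = (n11 * n00) / (n10 * n01)
    se = math.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
    z = math.log(oddsr) / se
    return oddsr, 2.0 * stats.norm.sf(abs(z))


def estimate_or(counts: PairwiseCounts) -> tuple[float, float]:
    """Odds ratio and two-sided Wald p-value for one 2x2 table.

    Equals the exponentiated slope and Wald test of an unadjusted logistic
    regression of one disease's presence on the other's; symmetric in the
    two diseases.  Tables with any zero cell get the Haldane-Anscombe
    correction (+0.5 to all four cells) to keep the estimate finite.
    """
    if counts.n_inpatients == 0:
        raise ValueError("empty contingency table")
    cells = (counts.n11, counts.n10, counts.n01, counts.n00)
    if min(cells) == 0:
        cells = tuple(c + 0.5 for c in cells)
    return _or_wald(*cells)


def fisher_p(counts: PairwiseCounts) -> float:
    """Two-sided Fisher exact p-value for one 2x2 table.

    Exact p-values are valid at any threshold, so Bonferroni selection
    built on them keeps the family-wise error at or below alpha; offered
    as an alternative to the default Wald p, which is mildly
    anti-conservative at the extreme thresholds Bonferroni implies.
    """
    table = [[counts.n11, counts.n10], [counts.n01, counts.n00]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _results(patterns: list[PairwiseCounts],
             p_method: str = "wald") -> list[PatternResult]:
    if p_method not in ("wald", "fisher"):
        raise ValueError(f"unknown p_method: {p_method!r}")
    out = []
    for counts in patterns:
        oddsr, p = estimate_or(counts)
        if p_method == "fisher":
            p = fisher_p(counts)
        zero = min(counts.n11, counts.n10, counts.n01, counts.n00) == 0
        out.append(PatternResult(counts=counts, odds_ratio=oddsr, p_value=p,
                                 zero_cell=zero))
    return out


def bonferroni_n(results: list[PatternResult]) -> int:
    """N = number of enumerated patterns with OR > 1 (per cohort/stratum)."""
    return sum(1 for r in results if r.odds_ratio > 1.0)


def select_edges(
    results: list[PatternResult],
    n_inpatients: int | None = None,
    alpha: float = 0.05,
    prevalence_floor: float = PREVALENCE_FLOOR,
) -> tuple[list[PatternResult], SelectionReport]:
    """Flag patterns meeting all three criteria (strict inequalities).

    selected iff OR > 1 and p < alpha/N and prevalence > prevalence_floor,
    with N the count of OR > 1 patterns in this result set.
    """
    n_tests = bonferroni_n(results)
    report = SelectionReport(n_patterns=len(results), bonferroni_n=n_tests)
    if n_tests == 0:
        if results:
            warnings.warn("no pattern has OR > 1; nothing can be selected",
                          stacklevel=2)
        for r in results:
            r.selected = False
            r.bonferroni_n = 0
            r.alpha_adjusted = None
        report.failed_or = len(results)
        return results, report
    threshold = alpha / n_tests
    report.alpha_adjusted = threshold
    for r in results:
        denom = n_inpatients if n_inpatients is not None else r.counts.n_inpatients
        prevalence = r.counts.frequency / denom
        ok_or = r.odds_ratio > 1.0
        ok_p = r.p_value < threshold
        ok_prev = prevalence > prevalence_floor
        r.selected = ok_or and ok_p and ok_prev
        r.bonferroni_n = n_tests
        r.alpha_adjusted = threshold
        if not ok_or:
            report.failed_or += 1
        elif not ok_p:
            report.failed_p += 1
        elif not ok_prev:
            report.failed_prevalence += 1
    report.n_selected = sum(r.selected for r in results)
    return results, report


def screen_cohort(cohort: Cohort, alpha: float = 0.05,
                  prevalence_floor: float = PREVALENCE_FLOOR,
                  p_method: str = "wald"
                  ) -> tuple[list[PatternResult], SelectionReport]:
    """Enumerate, estimate, and select in one pass over a cohort.

    ``p_method`` chooses the selection p-value: ``"wald"`` (default, the
    unadjusted logistic-regression Wald test) or ``"fisher"`` (exact).
    """
    results = _results(enumerate_patterns(cohort), p_method=p_method)
    return select_edges(results, n_inpatients=cohort.n_inpatients,
                        alpha=alpha, prevalence_floor=prevalence_floor)


def patterns_to_frame(results: list[PatternResult]):
    """Pattern table as a DataFrame (one row per enumerated pattern)."""
    import pandas as pd

    rows = []
    for r in results:
        c = r.counts
        rows.append({
            "code_i": c.pair[0], "code_j": c.pair[1],
            "n11": c.n11, "n10": c.n10, "n01": c.n01, "n00": c.n00,
            "frequency": c.frequency, "prevalence": c.prevalence,
            "odds_ratio": r.odds_ratio, "p_value": r.p_value,
            "bonferroni_n": r.bonferroni_n, "selected": r.selected,
            "zero_cell_flag": r.zero_cell,
        })
    frame = pd.DataFrame(rows, columns=[
        "code_i", "code_j", "n11", "n10", "n01", "n00", "frequency",
        "prevalence", "odds_ratio", "p_value", "bonferroni_n", "selected",
        "zero_cell_flag"])
    return frame.sort_values(["code_i", "code_j"]).reset_index(drop=True)
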