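"""Pattern enumeration, odds-ratio estimation, and the three-rule selection."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmnet.cohort import Cohort
from mmnet.screening import (PairwiseCounts, bonferroni_n, disease_prevalence,
                             enumerate_patterns, estimate_or,
                             patterns_to_frame, screen_cohort, select_edges)
from mmnet.simulate import SyntheticCohortConfig, example_catalog, generate_cohort
from tests.conftest import make_record


def logistic_oracle(n11, n10, n01, n00):
    """Unadjusted logistic regression of disease j on disease i (statsmodels)."""
    import statsmodels.api as sm

    x = np.array([1, 1, 0, 0], dtype=float)
    y = np.array([1, 0, 1, 0], dtype=float)
    weights = np.array([n11, n10, n01, n00], dtype=float)
    model = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial(),
                   freq_weights=weights)
    fit = model.fit()
    return math.exp(fit.params[1]), fit.pvalues[1]


def test_disease_prevalence_counts(tiny_cohort):
    prev = disease_prevalence(tiny_cohort)
    assert prev["A00"] == (2, 0.5)
    assert prev["I10"] == (1, 0.25)
    assert "Z99" not in prev
    total = sum(count for count, _ in prev.values())
    assert total == sum(len(r.codes) for r in tiny_cohort.records)


def test_enumerate_patterns_direct_count(tiny_cohort):
    patterns = {c.pair: c for c in enumerate_patterns(tiny_cohort)}
    assert set(patterns) == {("A00", "B00")}
    c = patterns[("A00", "B00")]
    assert (c.n11, c.n10, c.n01, c.n00) == (1, 1, 1, 1)
    assert c.frequency == 1 and c.prevalence == 0.25


def test_enumerate_patterns_combinatorial_conservation():
    records = [make_record("P1", codes=("A00", "B00", "C00", "D10")),
               make_record("P2", codes=("A00", "B00")),
               make_record("P3", codes=("I10",))]
    cohort = Cohort(records=records)
    patterns = enumerate_patterns(cohort)
    total = sum(c.frequency for c in patterns)
    expected = sum(math.comb(len(r.codes), 2) for r in records)
    assert total == expected == 7


def test_enumerate_patterns_no_multimorbid_record_gives_empty():
    cohort = Cohort([make_record("P1", codes=("A00",)),
                     make_record("P2", codes=("B00",))])
    assert enumerate_patterns(cohort) == []


def test_estimate_or_cross_product_and_wald():
    counts = PairwiseCounts(pair=("A00", "B00"), n11=10, n10=20, n01=30, n00=40)
    oddsr, p = estimate_or(counts)
    assert oddsr == pytest.approx(400 / 600)
    z = math.log(2 / 3) / math.sqrt(1 / 10 + 1 / 20 + 1 / 30 + 1 / 40)
    from scipy.stats import norm
    assert p == pytest.approx(2 * norm.sf(abs(z)))
    assert p == pytest.approx(0.374, abs=5e-3)


def test_estimate_or_matches_logistic_regression_oracle():
    for cells in [(10, 20, 30, 40), (55, 13, 21, 200), (5, 5, 5, 5)]:
        counts = PairwiseCounts(("A00", "B00"), *cells)
        oddsr, p = estimate_or(counts)
        oracle_or, oracle_p = logistic_oracle(*cells)
        assert oddsr == pytest.approx(oracle_or, abs=1e-6, rel=1e-6)
        assert p == pytest.approx(oracle_p, abs=1e-6)


def test_estimate_or_symmetric_balanced_table():
    counts = PairwiseCounts(("A00", "B00"), n11=25, n10=25, n01=25, n00=25)
    oddsr, p = estimate_or(counts)
    assert oddsr == pytest.approx(1.0)
    assert p == pytest.approx(1.0)


def test_estimate_or_symmetry_under_role_swap():
    a = PairwiseCounts(("A00", "B00"), n11=12, n10=7, n01=31, n00=100)
    b = PairwiseCounts(("B00", "A00"), n11=12, n10=7, n01=31, n00=100)
    # canonical ordering transposes the table, so the two must agree
    assert estimate_or(a) == estimate_or(b)


def test_estimate_or_zero_cell_haldane_correction():
    counts = PairwiseCounts(("A00", "B00"), n11=5, n10=0, n01=3, n00=92)
    oddsr, p = estimate_or(counts)
    expected = (5.5 * 92.5) / (0.5 * 3.5)
    assert oddsr == pytest.approx(expected)
    assert math.isfinite(p)


def test_bonferroni_n_counts_or_above_one():
    results = []
    for oddsr in [0.5, 1.0, 2.0, 3.0]:
        counts = PairwiseCounts(("A00", "B00"), 1, 1, 1, 1)
        from mmnet.screening import PatternResult
        results.append(PatternResult(counts=counts, odds_ratio=oddsr,
                                     p_value=0.5))
    assert bonferroni_n(results) == 2


def test_select_edges_prevalence_floor_boundary():
    # denominators mirror a large-population screen: 18/184133 fails the
    # >1/10,000 floor, 19/184133 passes it
    n = 184_133
    assert 18 / n < 1e-4 < 19 / n
    from mmnet.screening import PatternResult
    results = []
    for n11 in (18, 19):
        counts = PairwiseCounts(("A00", "B00"), n11, 1000, 1000, n - 2000 - n11)
        oddsr, p = estimate_or(counts)
        results.append(PatternResult(counts=counts, odds_ratio=oddsr, p_value=p))
    flagged, report = select_edges(results, n_inpatients=n)
    assert [r.selected for r in flagged] == [False, True]
    assert report.failed_prevalence == 1


def test_select_edges_clear_signal_selected():
    from mmnet.screening import PatternResult
    counts = PairwiseCounts(("A00", "B00"), 100, 100, 100, 9700)
    results = [PatternResult(counts=counts, odds_ratio=5.0, p_value=1e-10)]
    flagged, _ = select_edges(results, n_inpatients=10_000)
    assert flagged[0].selected
    assert flagged[0].alpha_adjusted == pytest.approx(0.05)


def test_select_edges_all_or_below_one_warns():
    from mmnet.screening import PatternResult
    counts = PairwiseCounts(("A00", "B00"), 5, 50, 50, 5)
    results = [PatternResult(counts=counts, odds_ratio=0.5, p_value=0.01)]
    with pytest.warns(UserWarning):
        flagged, report = select_edges(results, n_inpatients=110)
    assert not flagged[0].selected
    assert report.bonferroni_n == 0


@given(alpha=st.floats(0.001, 0.05), floor=st.floats(1e-4, 0.02))
@settings(max_examples=30, deadline=None)
def test_selection_monotone_in_alpha_and_floor(alpha, floor):
    config = SyntheticCohortConfig(
        n_patients=2000, diseases=example_catalog(6, 0.15),
        planted_pairs=(("A10", "C10", 4.0),), seed=9)
    cohort, _ = generate_cohort(config)
    loose, _ = screen_cohort(cohort, alpha=0.05, prevalence_floor=1e-4)
    tight, _ = screen_cohort(cohort, alpha=alpha, prevalence_floor=floor)
    loose_set = {r.counts.pair for r in loose if r.selected}
    tight_set = {r.counts.pair for r in tight if r.selected}
    assert tight_set <= loose_set


def test_fisher_exact_selection_controls_family_wise_error():
    """Exact p-values make Bonferroni selection valid: over null cohorts
    the probability of selecting any edge stays at or below alpha (plus
    simulation tolerance at this reduced replicate count)."""
    import warnings

    from mmnet.simulate import null_cohort

    diseases = example_catalog(15, 0.10)
    reps, hits = 40, 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(reps):
            cohort = null_cohort(5_000, diseases, seed=500 + seed)
            results, _ = screen_cohort(cohort, p_method="fisher")
            if any(r.selected for r in results):
                hits += 1
    assert hits / reps <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / reps)


def test_fisher_p_matches_scipy_and_keeps_planted_signal():
    from scipy.stats import fisher_exact

    counts = PairwiseCounts(("A00", "B00"), 40, 160, 160, 9640)
    from mmnet.screening import fisher_p
    expected = fisher_exact([[40, 160], [160, 9640]])[1]
    assert fisher_p(counts) == pytest.approx(expected)
    with pytest.raises(ValueError):
        from mmnet.screening import _results
        _results([counts], p_method="exact-ish")


def test_pattern_frame_schema_and_order():
    config = SyntheticCohortConfig(
        n_patients=500, diseases=example_catalog(5, 0.2), seed=2)
    cohort, _ = generate_cohort(config)
    results, _ = screen_cohort(cohort)
    frame = patterns_to_frame(results)
    assert list(frame.columns) == [
        "code_i", "code_j", "n11", "n10", "n01", "n00", "frequency",
        "prevalence", "odds_ratio", "p_value", "bonferroni_n", "selected",
        "zero_cell_flag"]
    assert (frame["code_i"] <= frame["code_j"]).all()
    assert (frame[["n11", "n10", "n01", "n00"]].sum(axis=1)
            == cohort.n_inpatients).all()
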