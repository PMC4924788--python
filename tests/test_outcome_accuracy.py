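"""Per-class PPV and the rank-sum / chi-squared tests."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency, mannwhitneyu

from amlbench import (
    chi_squared_association,
    class_accuracy_study,
    per_class_accuracy,
    wilcoxon_rank_sum,
)
from amlbench.synthetic_data import _logistic, _standardize
from conftest import make_sc1_set


# -- per-class PPV -----------------------------------------------------------


def test_ppv_worked_example():
    # 4 predicted CR of which 3 truly CR
    truth = [1, 1, 1, 0, 0, 0]
    pred = [1, 1, 1, 1, 0, 0]
    ppv_cr, ppv_res = per_class_accuracy(truth, pred)
    assert ppv_cr == pytest.approx(0.75)
    assert ppv_res == pytest.approx(1.0)


def test_ppv_perfect_predictions():
    y = ["CR", "Resistant", "CR", "Resistant"]
    assert per_class_accuracy(y, y) == (1.0, 1.0)


def test_ppv_undefined_when_class_never_predicted():
    ppv_cr, ppv_res = per_class_accuracy([1, 0, 1], [1, 1, 1])
    assert math.isnan(ppv_res)
    assert ppv_cr == pytest.approx(2 / 3)


def test_ppv_counting_identity():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = rng.integers(5, 50)
        y = rng.integers(0, 2, n)
        p = rng.integers(0, 2, n)
        ppv_cr, ppv_res = per_class_accuracy(y, p)
        n_pred_cr = (p == 1).sum()
        n_pred_res = (p == 0).sum()
        correct = (y == p).sum()
        total = 0.0
        if n_pred_cr:
            total += ppv_cr * n_pred_cr
        if n_pred_res:
            total += ppv_res * n_pred_res
        assert total == pytest.approx(correct)


# -- Wilcoxon rank-sum -------------------------------------------------------


def test_wilcoxon_exact_worked_example():
    w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
    assert w == 6.0
    assert p == pytest.approx(1 / 20)  # 1 of C(6,3)=20 assignments as extreme


def test_wilcoxon_identical_samples_two_sided():
    _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], alternative="two-sided")
    assert p == 1.0


def test_wilcoxon_extreme_configurations_have_p_one():
    # the most extreme statistic in the favourable direction covers the
    # whole enumeration, so its cumulative probability is 1
    _, p_hi = wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], alternative="less")
    assert p_hi == 1.0


def test_wilcoxon_exact_matches_reference():
    rng = np.random.default_rng(1)
    for _ in range(100):
        nx, ny = rng.integers(3, 7), rng.integers(3, 7)
        x = rng.normal(size=nx)
        y = rng.normal(size=ny) + rng.normal()
        for alt in ("two-sided", "less", "greater"):
            _, p = wilcoxon_rank_sum(x, y, alternative=alt, method="exact")
            expected = mannwhitneyu(x, y, alternative=alt, method="exact").pvalue
            assert p == pytest.approx(expected, abs=1e-12)


def test_wilcoxon_asymptotic_matches_reference_with_ties():
    rng = np.random.default_rng(2)
    for _ in range(100):
        nx, ny = rng.integers(8, 30), rng.integers(8, 30)
        x = rng.integers(0, 8, nx).astype(float)
        y = rng.integers(0, 8, ny).astype(float) + rng.integers(0, 3)
        for alt in ("two-sided", "less", "greater"):
            _, p = wilcoxon_rank_sum(x, y, alternative=alt, method="asymptotic")
            expected = mannwhitneyu(
                x, y, alternative=alt, method="asymptotic", use_continuity=True
            ).pvalue
            assert p == pytest.approx(expected, abs=1e-10)


def test_wilcoxon_empty_sample_rejected():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1, 2])


# -- chi-squared -------------------------------------------------------------


def test_chi_squared_diagonal_table():
    feature = [True] * 10 + [False] * 10
    outcome = ["CR"] * 10 + ["Resistant"] * 10
    stat, p = chi_squared_association(feature, outcome)
    assert stat == pytest.approx(20.0)
    assert p < 1e-4


def test_chi_squared_independent_table():
    feature = [True, True, False, False] * 5
    outcome = ["CR", "Resistant"] * 10
    stat, p = chi_squared_association(feature, outcome)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi_squared_matches_reference_on_random_tables():
    rng = np.random.default_rng(3)
    for _ in range(100):
        table = rng.integers(1, 30, size=(2, 2))
        feature = np.repeat([True, True, False, False], table.ravel())
        outcome = np.repeat(["CR", "Resistant", "CR", "Resistant"], table.ravel())
        stat, p = chi_squared_association(feature, outcome)
        expected = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(expected.statistic, abs=1e-10)
        assert p == pytest.approx(expected.pvalue, abs=1e-12)


def test_chi_squared_zero_margin_rejected():
    with pytest.raises(ValueError):
        chi_squared_association([True, True], ["CR", "Resistant"])


# -- population study --------------------------------------------------------


def test_resistant_insensitive_models_have_lower_resistant_ppv(test_cohort):
    """Models that only carry signal for CR patients predict the Resistant
    class at chance PPV, reproducing the class-accuracy asymmetry."""
    truth = test_cohort.outcomes()
    cr = (truth["rt_label"] == "CR").to_numpy()
    utility = _standardize(test_cohort.truth.utility.to_numpy())
    rng = np.random.default_rng(4)
    sets = []
    for i in range(8):
        conf = np.where(
            cr,
            _logistic(-utility + 0.3 * rng.normal(size=len(cr))),
            _logistic(rng.normal(size=len(cr))),
        )
        sets.append(make_sc1_set(f"t{i}", truth.index, np.clip(conf, 0, 1)))
    study = class_accuracy_study(truth, sets)
    assert study.median_ppv_resistant < study.median_ppv_cr
    assert study.test_status == "ok"


def test_single_team_skips_test(test_cohort, sc1_population):
    truth = test_cohort.outcomes()
    study = class_accuracy_study(truth, sc1_population[:1])
    assert study.test_status == "skipped"
    assert study.median_ppv_cr == pytest.approx(
        study.per_team["ppv_cr"].iloc[0]
    )


def test_all_perfect_teams_flagged_degenerate(test_cohort):
    truth = test_cohort.outcomes()
    conf = np.clip((truth["rt_label"] == "CR").astype(float).to_numpy(), 0.01, 0.99)
    sets = [make_sc1_set(f"t{i}", truth.index, conf) for i in range(3)]
    study = class_accuracy_study(truth, sets)
    assert study.test_status == "degenerate"
    assert study.median_ppv_cr == 1.0 and study.median_ppv_resistant == 1.0
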