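"""Metric primitives against brute-force oracles and worked examples."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amlbench.metrics import (
    MetricUndefinedError,
    CoverageError,
    auroc,
    balanced_accuracy,
    concordance_index,
    pearson_censored,
    random_prediction_null,
    score_submission,
    threshold_confidences,
)
from conftest import make_sc1_set, make_survival_set


# -- independent oracles ----------------------------------------------------


def auroc_bruteforce(labels, conf):
    """Mann-Whitney pair count: concordant + half of tied pairs."""
    labels = np.asarray(labels)
    conf = np.asarray(conf, dtype=float)
    pos = conf[labels == 1]
    neg = conf[labels == 0]
    total = concordant = tied = 0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                tied += 1
    return (concordant + 0.5 * tied) / total


def concordance_bruteforce(t, events, p):
    """Comparable-pair enumeration: earlier time must carry an event."""
    n = len(t)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if t[i] < t[j] and events[i]:
                den += 1
                if p[i] < p[j]:
                    num += 1
                elif p[i] == p[j]:
                    num += 0.5
    return num / den


# -- auroc -------------------------------------------------------------------


def test_auroc_worked_example():
    assert auroc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == pytest.approx(0.75)


def test_auroc_perfect_and_tied():
    assert auroc([1, 1, 0], [0.9, 0.8, 0.1]) == 1.0
    assert auroc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5


def test_auroc_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = rng.integers(4, 31)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        conf = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
        assert auroc(labels, conf) == pytest.approx(
            auroc_bruteforce(labels, conf), abs=1e-12
        )


def test_auroc_matches_sklearn():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = rng.integers(5, 60)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        conf = rng.uniform(size=n)
        assert auroc(labels, conf) == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, conf), abs=1e-12
        )


@settings(deadline=None, derandomize=True)
@given(
    st.lists(st.sampled_from([0, 1]), min_size=4, max_size=40),
    st.integers(0, 2**31 - 1),
)
def test_auroc_complement_identity(labels, seed):
    """auroc(y, c) + auroc(y, 1-c) = 1 when confidences are tie-free."""
    labels = np.array(labels)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    conf = np.random.default_rng(seed).permutation(
        np.linspace(0.01, 0.99, len(labels))
    )
    assert auroc(labels, conf) + auroc(labels, 1 - conf) == pytest.approx(1.0)


def test_auroc_single_class_undefined():
    with pytest.raises(MetricUndefinedError):
        auroc([1, 1, 1], [0.2, 0.4, 0.9])


# -- balanced accuracy & thresholding ----------------------------------------


def test_bac_confusion_matrix_example():
    # TP=3, FN=1 (4 positives), TN=2, FP=2 (4 negatives)
    labels = [1, 1, 1, 1, 0, 0, 0, 0]
    predicted = [1, 1, 1, 0, 0, 0, 1, 1]
    assert balanced_accuracy(labels, predicted) == pytest.approx(0.625)


def test_bac_extremes():
    y = [1, 0, 1, 0]
    assert balanced_accuracy(y, y) == 1.0
    assert balanced_accuracy(y, [0, 1, 0, 1]) == 0.0


def test_threshold_boundary_inclusive():
    np.testing.assert_array_equal(
        threshold_confidences([0.2, 0.5, 0.8], 0.5), [0, 1, 1]
    )
    np.testing.assert_array_equal(threshold_confidences([0.2, 0.9], 0.0), [1, 1])
    np.testing.assert_array_equal(threshold_confidences([0.2, 0.9], 0.91), [0, 0])


# -- concordance index -------------------------------------------------------


def test_concordance_perfect_and_tied():
    assert concordance_index([1, 2, 3], [1, 1, 1], [1, 2, 3]) == 1.0
    assert concordance_index([1, 2, 3], [1, 1, 1], [5, 5, 5]) == 0.5


def test_concordance_censoring_worked_example():
    # (5, 10): comparable, predicted 8 > 4 -> discordant;
    # (5, 15): comparable, 8 < 20 -> concordant;
    # (10 censored, 15): earlier time censored -> not comparable.
    value = concordance_index([5, 10, 15], [1, 0, 1], [8, 4, 20])
    assert value == pytest.approx(0.5)


def test_concordance_matches_bruteforce_with_censoring():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = rng.integers(4, 25)
        t = rng.exponential(50, n).round(1)
        e = rng.integers(0, 2, n)
        p = rng.choice(np.arange(1, 8, dtype=float), size=n)  # prediction ties
        if not ((t[:, None] - t[None, :] < 0) & e[:, None].astype(bool)).any():
            continue
        assert concordance_index(t, e, p) == pytest.approx(
            concordance_bruteforce(t, e, p), abs=1e-12
        )


def test_concordance_matches_lifelines_on_tie_free_data():
    lifelines_utils = pytest.importorskip("lifelines.utils")
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = rng.integers(5, 40)
        t = rng.exponential(50, n)
        e = rng.integers(0, 2, n)
        p = rng.exponential(50, n)
        if not ((t[:, None] - t[None, :] < 0) & e[:, None].astype(bool)).any():
            continue
        assert concordance_index(t, e, p) == pytest.approx(
            lifelines_utils.concordance_index(t, p, e), abs=1e-12
        )


def test_concordance_no_comparable_pairs():
    with pytest.raises(MetricUndefinedError):
        concordance_index([5, 5], [1, 1], [1, 2])  # tied actual times


# -- censored Pearson --------------------------------------------------------


def test_pearson_worked_examples():
    ones = np.ones(3, dtype=bool)
    assert pearson_censored([2, 4, 6], [1, 2, 3], ones) == pytest.approx(1.0)
    assert pearson_censored([2, 4, 6], [-2, -4, -6], ones) == pytest.approx(-1.0)
    assert pearson_censored([1, 2, 3], [1, 3, 2], ones) == pytest.approx(0.5)


def test_pearson_subset_requirements():
    with pytest.raises(MetricUndefinedError):
        pearson_censored([1, 2, 3], [1, 2, 3], [True, True, False])
    with pytest.raises(MetricUndefinedError):
        pearson_censored([1, 1, 1], [1, 2, 3], np.ones(3, bool))


# -- submission scoring ------------------------------------------------------


def test_score_sc1_perfect_predictor(test_cohort):
    truth = test_cohort.outcomes()
    conf = (truth["rt_label"] == "CR").astype(float).to_numpy()
    ps = make_sc1_set("perfect", truth.index, np.clip(conf, 0.01, 0.99))
    report = score_submission("SC1", truth, ps, truth.index)
    assert report.combined == 1.0
    assert report.metric_a_name == "AUROC" and report.metric_b_name == "BAC"


def test_score_sc2_restricted_to_responders(test_cohort):
    truth = test_cohort.outcomes()
    ps = make_survival_set(
        "t", "SC2", truth.index, np.linspace(1, 100, len(truth.index))
    )
    report = score_submission("SC2", truth, ps, truth.index)
    assert report.n_evaluated == int((truth["rt_label"] == "CR").sum())


def test_score_sc2_undefined_without_relapses(test_cohort):
    truth = test_cohort.outcomes().copy()
    truth.loc[truth["rt_label"] == "CR", "rd_event"] = "censored"
    ps = make_survival_set("t", "SC2", truth.index, np.arange(1, len(truth) + 1))
    with pytest.raises(MetricUndefinedError):
        score_submission("SC2", truth, ps, truth.index)


def test_score_row_order_invariance(test_cohort, sc1_population):
    truth = test_cohort.outcomes()
    ids = list(truth.index)
    shuffled = list(np.random.default_rng(5).permutation(ids))
    a = score_submission("SC1", truth, sc1_population[4], ids)
    b = score_submission("SC1", truth, sc1_population[4], shuffled)
    assert a.combined == pytest.approx(b.combined)


def test_score_missing_patient_coverage(test_cohort, sc1_population):
    truth = test_cohort.outcomes()
    ps = sc1_population[0]
    trimmed = make_sc1_set(
        "trimmed", ps.patient_ids[:-1], ps.frame["confidence"].iloc[:-1]
    )
    with pytest.raises(CoverageError):
        score_submission("SC1", truth, trimmed, truth.index)


def test_higher_skill_scores_higher_on_average(test_cohort):
    from amlbench import PredictorConfig, simulate_predictor

    truth = test_cohort.outcomes()
    rng = np.random.default_rng(7)
    diffs = []
    for rep in range(50):
        hi = simulate_predictor(
            test_cohort,
            test_cohort.truth,
            PredictorConfig("hi", skill=0.8, seed=rep),
            "SC1",
        )
        lo = simulate_predictor(
            test_cohort,
            test_cohort.truth,
            PredictorConfig("lo", skill=0.2, seed=1000 + rep),
            "SC1",
        )
        subset = rng.choice(truth.index, size=75, replace=False)
        diffs.append(
            score_submission("SC1", truth, hi, subset).combined
            - score_submission("SC1", truth, lo, subset).combined
        )
    assert np.mean(diffs) > 0


# -- random null -------------------------------------------------------------


def test_random_null_is_seeded(test_cohort):
    truth = test_cohort.outcomes()
    a = random_prediction_null("SC1", truth, truth.index, 20, seed=9)
    b = random_prediction_null("SC1", truth, truth.index, 20, seed=9)
    assert [r.combined for r in a] == [r.combined for r in b]


def test_random_null_rejects_zero_reps(test_cohort):
    with pytest.raises(ValueError):
        random_prediction_null(
            "SC1", test_cohort.outcomes(), test_cohort.patient_ids, 0
        )
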