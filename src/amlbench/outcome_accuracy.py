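"""Per-outcome-class accuracy across the model population.

"Accuracy" here is the positive predictive value (PPV) per outcome class:
among the patients a model calls CR (or Resistant), the fraction that truly
are.  Comparing the PPV distributions of the two classes across all
submitted models shows which outcome is harder to predict; a Wilcoxon
rank-sum test quantifies the separation.  A chi-squared association test
links a binarised feature (e.g. a protein level below 0) to the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .metrics import threshold_confidences
from .synthetic_data import PredictionSet

__all__ = [
    "ClassAccuracyResult",
    "per_class_accuracy",
    "wilcoxon_rank_sum",
    "chi_squared_association",
    "class_accuracy_study",
]

#: Pooled sample size at or below which the Wilcoxon p-value is exact.
EXACT_ENUMERATION_LIMIT = 12


def per_class_accuracy(truth_labels, predicted_labels) -> tuple[float, float]:
    """Positive predictive value for each outcome class.

    Returns ``(ppv_cr, ppv_resistant)``; a class the model never predicts
    has no defined PPV and is returned as NaN.
    """
    y = _to_cr_indicator(truth_labels)
    p = _to_cr_indicator(predicted_labels)
    if y.shape != p.shape:
        raise ValueError("labels must have equal length")

    def ppv(cls: int) -> float:
        predicted_cls = p == cls
        if not predicted_cls.any():
            return math.nan
        return float((y[predicted_cls] == cls).mean())

    return ppv(1), ppv(0)


def _to_cr_indicator(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        bad = set(np.unique(arr)) - {"CR", "Resistant"}
        if bad:
            raise ValueError(f"unknown outcome labels: {sorted(bad)}")
        return (arr == "CR").astype(int)
    return arr.astype(int)


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Wilcoxon rank-sum test: (rank-sum statistic of x, p-value).

    Mid-ranks are assigned to ties.  The p-value is exact (enumeration of
    all ways to assign the pooled ranks to x) when the pooled size is at
    most 12, and otherwise a normal approximation with tie and continuity
    corrections.  ``alternative`` is "two-sided", "less" (x shifted below
    y) or "greater".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:nx].sum())

    if method == "auto":
        method = "exact" if nx + ny <= EXACT_ENUMERATION_LIMIT else "asymptotic"
    if method == "exact":
        p = _exact_rank_sum_p(ranks, nx, w, alternative)
    elif method == "asymptotic":
        p = _asymptotic_rank_sum_p(pooled, ranks, nx, ny, w, alternative)
    else:
        raise ValueError(f"unknown method {method!r}")
    return w, p


def _exact_rank_sum_p(ranks: np.ndarray, nx: int, w: float, alternative: str) -> float:
    """Exact p by enumerating every assignment of pooled ranks to x."""
    n = len(ranks)
    total = math.comb(n, nx)
    n_le = n_ge = 0
    eps = 1e-9
    for subset in combinations(range(n), nx):
        ws = ranks[list(subset)].sum()
        if ws <= w + eps:
            n_le += 1
        if ws >= w - eps:
            n_ge += 1
    p_less = n_le / total
    p_greater = n_ge / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def _asymptotic_rank_sum_p(
    pooled: np.ndarray, ranks: np.ndarray, nx: int, ny: int, w: float, alternative: str
) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = nx + ny
    u1 = w - nx * (nx + 1) / 2.0
    u2 = nx * ny - u1
    mu = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    if alternative == "greater":
        u = u1
    elif alternative == "less":
        u = u2
    else:
        u = max(u1, u2)
    z = (u - mu - 0.5) / sd
    p = float(norm.sf(z))
    if alternative == "two-sided":
        p = min(1.0, 2.0 * p)
    return p


def chi_squared_association(binary_feature, outcome_labels) -> tuple[float, float]:
    """Pearson chi-squared test of a 2x2 feature/outcome table (1 df).

    No continuity correction.  The statistic is
    n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the p-value comes from the
    chi-squared survival function with one degree of freedom.
    """
    f = np.asarray(binary_feature).astype(bool)
    o = _to_cr_indicator(outcome_labels).astype(bool)
    if f.shape != o.shape:
        raise ValueError("inputs must have equal length")
    a = float((f & o).sum())
    b = float((f & ~o).sum())
    c = float((~f & o).sum())
    d = float((~f & ~o).sum())
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("chi-squared test requires all table margins > 0")
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(stat), float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# population study
# ---------------------------------------------------------------------------


@dataclass
class ClassAccuracyResult:
    per_team: pd.DataFrame  # index team_id; columns ppv_cr, ppv_resistant
    median_ppv_cr: float
    median_ppv_resistant: float
    statistic: float | None
    p_value: float | None
    test_status: str  # "ok" | "degenerate" | "skipped"

    def to_dict(self) -> dict:
        return {
            "median_ppv_cr": self.median_ppv_cr,
            "median_ppv_resistant": self.median_ppv_resistant,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "test_status": self.test_status,
        }


def class_accuracy_study(
    truth: pd.DataFrame,
    all_prediction_sets: Sequence[PredictionSet],
    threshold: float = 0.5,
    alternative: str = "two-sided",
) -> ClassAccuracyResult:
    """Per-team class PPVs, population medians, and their rank-sum comparison.

    With a single team the medians are that team's PPVs and the test is
    skipped; when the pooled PPV values are all identical (e.g. every team
    perfect) the test is flagged degenerate.
    """
    if not all_prediction_sets:
        raise ValueError("at least one prediction set is required")
    ids = truth.index
    labels = (truth["rt_label"] == "CR").astype(int).to_numpy()
    rows = {}
    for ps in all_prediction_sets:
        predicted = threshold_confidences(ps.confidences(ids), threshold)
        rows[ps.team_id] = per_class_accuracy(labels, predicted)
    per_team = pd.DataFrame.from_dict(
        rows, orient="index", columns=["ppv_cr", "ppv_resistant"]
    )
    per_team.index.name = "team_id"
    cr_sample = per_team["ppv_cr"].dropna().to_numpy()
    res_sample = per_team["ppv_resistant"].dropna().to_numpy()
    median_cr = float(np.median(cr_sample)) if cr_sample.size else math.nan
    median_res = float(np.median(res_sample)) if res_sample.size else math.nan

    if len(per_team) < 2 or cr_sample.size == 0 or res_sample.size == 0:
        return ClassAccuracyResult(per_team, median_cr, median_res, None, None, "skipped")
    pooled = np.concatenate([cr_sample, res_sample])
    if np.all(pooled == pooled[0]):
        return ClassAccuracyResult(
            per_team, median_cr, median_res, None, None, "degenerate"
        )
    stat, p = wilcoxon_rank_sum(cr_sample, res_sample, alternative=alternative)
    return ClassAccuracyResult(per_team, median_cr, median_res, stat, p, "ok")
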