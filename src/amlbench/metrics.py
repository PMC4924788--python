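"""Evaluation metrics with the challenge's exact censoring rules.

Each sub-challenge is scored with two metrics whose arithmetic mean is the
combined score:

* SC1 (response to therapy): AUROC of the submitted CR confidences, and
  balanced accuracy (mean of true-positive and true-negative rate) after
  thresholding the confidences;
* SC2 (remission duration): Harrell concordance index under right censoring
  over the CR patients, and Pearson correlation restricted to responders who
  subsequently relapsed;
* SC3 (overall survival): concordance index over all patients, and Pearson
  correlation restricted to patients known deceased.

Undefined situations (single-class truth, no comparable pairs, too-small or
degenerate correlation subsets) raise :class:`MetricUndefinedError` so the
caller can skip-and-log rather than silently score a sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthetic_data import PredictionSet, substream

__all__ = [
    "MetricUndefinedError",
    "CoverageError",
    "ScoreReport",
    "auroc",
    "balanced_accuracy",
    "threshold_confidences",
    "concordance_index",
    "pearson_censored",
    "score_submission",
    "random_prediction_null",
    "METRIC_NAMES",
]

#: (metric_a, metric_b) per sub-challenge.
METRIC_NAMES = {
    "SC1": ("AUROC", "BAC"),
    "SC2": ("CI", "PC"),
    "SC3": ("CI", "PC"),
}


class MetricUndefinedError(ValueError):
    """A metric has no defined value on the given input."""


class CoverageError(ValueError):
    """A submission does not cover every patient it is being scored on."""


@dataclass(frozen=True)
class ScoreReport:
    """The two metric values and their average for one scored submission."""

    team_id: str
    subchallenge: str
    metric_a_name: str
    metric_a: float
    metric_b_name: str
    metric_b: float
    n_evaluated: int
    subset_id: str = ""

    @property
    def combined(self) -> float:
        return 0.5 * (self.metric_a + self.metric_b)

    def metric(self, selector: str) -> float:
        if selector == "combined":
            return self.combined
        if selector in ("metric_a", self.metric_a_name):
            return self.metric_a
        if selector in ("metric_b", self.metric_b_name):
            return self.metric_b
        raise KeyError(f"unknown metric selector {selector!r}")

    def to_dict(self) -> dict:
        return {
            "team_id": self.team_id,
            "subchallenge": self.subchallenge,
            self.metric_a_name: self.metric_a,
            self.metric_b_name: self.metric_b,
            "combined": self.combined,
            "n_evaluated": self.n_evaluated,
            "subset_id": self.subset_id,
        }

    def to_tsv_row(self) -> str:
        return "\t".join(
            [
                self.team_id,
                self.subchallenge,
                f"{self.metric_a:.6f}",
                f"{self.metric_b:.6f}",
                f"{self.combined:.6f}",
                str(self.n_evaluated),
                self.subset_id,
            ]
        )


# ---------------------------------------------------------------------------
# primitive metrics
# ---------------------------------------------------------------------------


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        arr = (arr == "CR").astype(int)
    else:
        arr = arr.astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary (0/1 or CR/Resistant)")
    return arr


def auroc(labels, confidences) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) identity.

    Equals (concordant pairs + 0.5 * tied pairs) / (positive-negative
    pairs); ties in confidence receive half credit through mid-ranks.
    """
    y = _as_binary(labels)
    c = np.asarray(confidences, dtype=float)
    if y.shape != c.shape:
        raise ValueError("labels and confidences must have equal length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricUndefinedError("AUROC requires both classes in the truth")
    ranks = rankdata(c)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def balanced_accuracy(labels, predicted) -> float:
    """Mean of true-positive rate and true-negative rate."""
    y = _as_binary(labels)
    p = _as_binary(predicted)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricUndefinedError("BAC requires both classes in the truth")
    tpr = float((p[y == 1] == 1).mean())
    tnr = float((p[y == 0] == 0).mean())
    return 0.5 * (tpr + tnr)


def threshold_confidences(confidences, threshold: float = 0.5) -> np.ndarray:
    """Binarise confidences: positive iff confidence >= threshold."""
    c = np.asarray(confidences, dtype=float)
    if ((c < 0) | (c > 1)).any():
        raise ValueError("confidences must lie in [0, 1]")
    return (c >= threshold).astype(int)


def concordance_index(actual_weeks, event_flags, predicted_weeks) -> float:
    """Harrell concordance index under right censoring.

    A pair is comparable when the smaller actual time carries an event
    (pairs with tied actual times are not comparable).  Concordant pairs
    score 1, prediction ties 0.5.
    """
    t = np.asarray(actual_weeks, dtype=float)
    e = _event_mask(event_flags)
    p = np.asarray(predicted_weeks, dtype=float)
    if not (t.shape == e.shape == p.shape):
        raise ValueError("inputs must have equal length")
    if (t < 0).any():
        raise ValueError("actual weeks must be nonnegative")

    dt = t[:, None] - t[None, :]
    # comparable with i the earlier, event-bearing patient
    comparable = (dt < 0) & e[:, None]
    dp = p[:, None] - p[None, :]
    concordant = comparable & (dp < 0)
    tied = comparable & (dp == 0)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise MetricUndefinedError("no comparable pairs for the concordance index")
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def _event_mask(event_flags) -> np.ndarray:
    arr = np.asarray(event_flags)
    if arr.dtype.kind in "OUS":
        valid = {"relapsed", "deceased", "censored"}
        bad = set(np.unique(arr)) - valid
        if bad:
            raise ValueError(f"unknown event flags: {sorted(bad)}")
        return np.isin(arr, ("relapsed", "deceased"))
    return arr.astype(bool)


def pearson_censored(actual_weeks, predicted_weeks, include_mask) -> float:
    """Sample Pearson correlation over an included patient subset only."""
    t = np.asarray(actual_weeks, dtype=float)
    p = np.asarray(predicted_weeks, dtype=float)
    m = np.asarray(include_mask, dtype=bool)
    if not (t.shape == p.shape == m.shape):
        raise ValueError("inputs must have equal length")
    ti, pi = t[m], p[m]
    if len(ti) < 3:
        raise MetricUndefinedError(
            f"Pearson correlation needs >= 3 included patients, got {len(ti)}"
        )
    if ti.std() == 0 or pi.std() == 0:
        raise MetricUndefinedError("Pearson correlation undefined at zero variance")
    return float(np.corrcoef(ti, pi)[0, 1])


# ---------------------------------------------------------------------------
# submission scoring
# ---------------------------------------------------------------------------


def score_submission(
    subchallenge: str,
    truth: pd.DataFrame,
    prediction_set: PredictionSet,
    patient_subset: Sequence,
    bac_threshold: float = 0.5,
    subset_id: str = "",
) -> ScoreReport:
    """Score one submission on one patient subset with the challenge rules.

    ``truth`` is an outcome table indexed by patient id with columns
    rt_label, rd_weeks, rd_event, os_weeks, os_event.  The censoring rules:
    SC2 restricts the concordance index to CR patients and the Pearson
    correlation to relapsed responders; SC3 restricts the Pearson
    correlation to deceased patients.
    """
    ids = pd.Index(patient_subset)
    if not ids.isin(truth.index).all():
        missing = ids[~ids.isin(truth.index)].tolist()
        raise CoverageError(f"subset patients absent from truth: {missing[:5]}")
    if not prediction_set.covers(ids):
        missing = ids[~ids.isin(prediction_set.patient_ids)].tolist()
        raise CoverageError(
            f"{prediction_set.team_id} is missing predictions for {missing[:5]}"
        )
    if prediction_set.subchallenge != subchallenge:
        raise ValueError(
            f"prediction set is for {prediction_set.subchallenge}, not {subchallenge}"
        )
    sub = truth.loc[ids]
    name_a, name_b = METRIC_NAMES[subchallenge]

    if subchallenge == "SC1":
        labels = (sub["rt_label"] == "CR").astype(int).to_numpy()
        conf = prediction_set.confidences(ids)
        a = auroc(labels, conf)
        b = balanced_accuracy(labels, threshold_confidences(conf, bac_threshold))
        n_eval = len(ids)
    elif subchallenge == "SC2":
        cr_ids = ids[(sub["rt_label"] == "CR").to_numpy()]
        cr = truth.loc[cr_ids]
        weeks = prediction_set.weeks(cr_ids)
        a = concordance_index(
            cr["rd_weeks"].to_numpy(float), cr["rd_event"].to_numpy(), weeks
        )
        relapsed = (cr["rd_event"] == "relapsed").to_numpy()
        b = pearson_censored(cr["rd_weeks"].to_numpy(float), weeks, relapsed)
        n_eval = len(cr_ids)
    else:  # SC3
        weeks = prediction_set.weeks(ids)
        a = concordance_index(
            sub["os_weeks"].to_numpy(float), sub["os_event"].to_numpy(), weeks
        )
        deceased = (sub["os_event"] == "deceased").to_numpy()
        b = pearson_censored(sub["os_weeks"].to_numpy(float), weeks, deceased)
        n_eval = len(ids)

    return ScoreReport(
        team_id=prediction_set.team_id,
        subchallenge=subchallenge,
        metric_a_name=name_a,
        metric_a=a,
        metric_b_name=name_b,
        metric_b=b,
        n_evaluated=n_eval,
        subset_id=subset_id,
    )


def random_prediction_null(
    subchallenge: str,
    truth: pd.DataFrame,
    patient_subset: Sequence,
    n_reps: int,
    seed: int = 0,
    bac_threshold: float = 0.5,
) -> list[ScoreReport]:
    """Score random predictions to characterise the no-skill null.

    SC1 draws uniform confidences; SC2/SC3 permute the observed event/censor
    times among the scored patients (with uniform confidences).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    ids = pd.Index(patient_subset)
    rng = substream(seed, f"null:{subchallenge}")
    sub = truth.loc[ids]
    reports = []
    for rep in range(n_reps):
        if subchallenge == "SC1":
            frame = pd.DataFrame({"confidence": rng.uniform(size=len(ids))}, index=ids)
        else:
            col = "rd_weeks" if subchallenge == "SC2" else "os_weeks"
            observed = sub[col].to_numpy(dtype=float)
            weeks = np.ones(len(ids))
            scored = ~np.isnan(observed)
            weeks[scored] = rng.permutation(np.maximum(observed[scored], 1e-3))
            frame = pd.DataFrame(
                {"confidence": rng.uniform(size=len(ids)), "predicted_weeks": weeks},
                index=ids,
            )
        ps = PredictionSet(f"null_{rep:04d}", subchallenge, frame)
        reports.append(
            score_submission(
                subchallenge, truth, ps, ids, bac_threshold, subset_id=f"null{rep}"
            )
        )
    return reports
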