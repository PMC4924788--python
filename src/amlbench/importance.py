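"""Scramble-based feature importance for trained predictors.

A feature's values are permuted across patients — destroying its
association with outcome while preserving its marginal distribution — the
predictor re-predicts on the scrambled table, and the drop in score
measures the predictor's reliance on that feature.  Proteins can be
scrambled all at once (overall proteomics reliance) or one at a time
(per-protein importance); clinical covariates go through the identical
machinery, categorical columns permuted as labels.

Performance loss per feature is summarised two ways: the fraction of
scrambles that reduced the score below baseline (strictly below — exact
ties do not count), and the percent difference of each scrambled score
from baseline (negative = loss).  Features whose screening fraction
exceeds a cutoff are re-assessed with a much larger number of scrambles.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .metrics import (
    MetricUndefinedError,
    auroc,
    balanced_accuracy,
    threshold_confidences,
)
from .synthetic_data import PredictionSet

__all__ = [
    "ALL_PROTEINS",
    "PredictorHandle",
    "ImportanceResult",
    "scramble_feature",
    "scramble_all",
    "importance_assessment",
    "screen_and_deepen",
    "percent_diff_matrix",
    "importance_summary",
]

logger = logging.getLogger(__name__)

#: Label used when every protein column is scrambled jointly.
ALL_PROTEINS = "ALL_PROTEINS"


class PredictorHandle(Protocol):
    """An evaluable predictor: feature table in, prediction set out.

    Must be deterministic given an identical input table (simulated
    predictors are; externally wrapped models must freeze their own RNG).
    """

    team_id: str

    def predict(self, table: pd.DataFrame) -> PredictionSet: ...


@dataclass
class ImportanceResult:
    feature: str  # a feature name, or ALL_PROTEINS
    baseline_combined: float
    scrambled_scores: np.ndarray
    n_reps: int
    deepened: bool = False

    def __post_init__(self) -> None:
        self.scrambled_scores = np.asarray(self.scrambled_scores, dtype=float)

    @property
    def percent_diffs(self) -> np.ndarray:
        """100 * (scrambled - baseline) / baseline; negative = loss."""
        return 100.0 * (self.scrambled_scores - self.baseline_combined) / (
            self.baseline_combined
        )

    @property
    def fraction_reducing(self) -> float:
        """Fraction of scrambles scoring strictly below baseline."""
        scores = self.scrambled_scores[~np.isnan(self.scrambled_scores)]
        if scores.size == 0:
            return float("nan")
        return float((scores < self.baseline_combined).mean())

    @property
    def performance_loss(self) -> float:
        """Baseline minus the median scrambled score."""
        return self.baseline_combined - float(np.nanmedian(self.scrambled_scores))


# ---------------------------------------------------------------------------
# scrambling primitives
# ---------------------------------------------------------------------------


def scramble_feature(
    table: pd.DataFrame, feature: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Copy of the table with one column permuted across patients.

    The column's multiset of values is preserved exactly; every other
    column is untouched.
    """
    if feature not in table.columns:
        raise KeyError(f"unknown feature {feature!r}")
    out = table.copy()
    out[feature] = rng.permutation(out[feature].to_numpy())
    return out


def scramble_all(
    table: pd.DataFrame, features: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Copy of the table with every listed column independently permuted."""
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"unknown features: {missing}")
    out = table.copy()
    for feature in features:
        out[feature] = rng.permutation(out[feature].to_numpy())
    return out


# ---------------------------------------------------------------------------
# assessment
# ---------------------------------------------------------------------------


def _combined_score(
    prediction: PredictionSet,
    truth: pd.DataFrame,
    bac_threshold: float,
) -> float:
    """Mean of AUROC and BAC of a CR-confidence prediction set."""
    ids = truth.index
    labels = (truth["rt_label"] == "CR").astype(int).to_numpy()
    conf = prediction.confidences(ids)
    a = auroc(labels, conf)
    b = balanced_accuracy(labels, threshold_confidences(conf, bac_threshold))
    return 0.5 * (a + b)


def _feature_rng(seed: int, label: str) -> np.random.Generator:
    """Independent substream per feature, invariant to feature ordering."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key, 0x5C])
    )


def importance_assessment(
    predictor: PredictorHandle,
    table: pd.DataFrame,
    truth: pd.DataFrame,
    feature_or_all: str | Sequence[str],
    n_reps: int = 100,
    seed: int = 0,
    bac_threshold: float = 0.5,
    label: str | None = None,
) -> ImportanceResult:
    """Scramble, re-predict and re-score a predictor ``n_reps`` times.

    ``feature_or_all`` is a single feature name, or a sequence of feature
    names scrambled jointly and independently (reported under the label
    ``ALL_PROTEINS`` unless overridden).  The baseline score is computed
    once on the unscrambled table; a repetition whose score is undefined
    is recorded as NaN and logged.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if isinstance(feature_or_all, str):
        features = [feature_or_all]
        result_label = label or feature_or_all
    else:
        features = list(feature_or_all)
        result_label = label or ALL_PROTEINS
    baseline = _combined_score(predictor.predict(table), truth, bac_threshold)
    rng = _feature_rng(seed, result_label)
    scores = np.full(n_reps, np.nan)
    for rep in range(n_reps):
        scrambled = scramble_all(table, features, rng)
        try:
            scores[rep] = _combined_score(
                predictor.predict(scrambled), truth, bac_threshold
            )
        except MetricUndefinedError as exc:
            logger.warning(
                "%s rep %d: score undefined (%s)", result_label, rep, exc
            )
    return ImportanceResult(
        feature=result_label,
        baseline_combined=baseline,
        scrambled_scores=scores,
        n_reps=n_reps,
    )


def screen_and_deepen(
    predictor: PredictorHandle,
    table: pd.DataFrame,
    truth: pd.DataFrame,
    features: Sequence[str],
    n_screen: int = 100,
    n_deep: int = 10_000,
    cutoff: float = 0.65,
    seed: int = 0,
    bac_threshold: float = 0.5,
) -> dict[str, ImportanceResult]:
    """Screen every feature, then deepen the ones that matter.

    Each feature is scrambled ``n_screen`` times; any feature whose
    fraction of score-reducing scrambles exceeds ``cutoff`` is re-assessed
    with ``n_deep`` scrambles (an independent substream) and flagged
    ``deepened``.  Results are keyed by feature name.
    """
    if not features:
        raise ValueError("features must be non-empty")
    results: dict[str, ImportanceResult] = {}
    for feature in features:
        res = importance_assessment(
            predictor, table, truth, feature, n_screen, seed, bac_threshold
        )
        if res.fraction_reducing > cutoff:
            deep = importance_assessment(
                predictor,
                table,
                truth,
                feature,
                n_deep,
                seed,
                bac_threshold,
                label=f"{feature}:deep",
            )
            res = ImportanceResult(
                feature=feature,
                baseline_combined=deep.baseline_combined,
                scrambled_scores=deep.scrambled_scores,
                n_reps=n_deep,
                deepened=True,
            )
        results[feature] = res
    return results


# ---------------------------------------------------------------------------
# tabular exports
# ---------------------------------------------------------------------------


def percent_diff_matrix(results: dict[str, ImportanceResult]) -> pd.DataFrame:
    """Heat-map style matrix: rows are scramble repetitions, columns features.

    Entries are percent differences from baseline (negative = performance
    loss).  Deepened features are truncated to the shared screening depth.
    """
    n = min(r.n_reps for r in results.values())
    return pd.DataFrame(
        {name: r.percent_diffs[:n] for name, r in results.items()},
        index=pd.RangeIndex(1, n + 1, name="rep"),
    )


def importance_summary(results: dict[str, ImportanceResult]) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "feature": name,
                "baseline": r.baseline_combined,
                "median_scrambled": float(np.nanmedian(r.scrambled_scores)),
                "performance_loss": r.performance_loss,
                "fraction_reducing": r.fraction_reducing,
                "n_reps": r.n_reps,
                "deepened": r.deepened,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
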