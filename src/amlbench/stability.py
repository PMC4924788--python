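"""Rank-stability analysis via subsample re-scoring and Bayes factors.

Final submissions are re-scored on many random subsets of the final test
patients (subsets, not bootstrap resamples).  For a model pair, the paired
score differences across subsamples give win/loss/tie counts; the Bayes
factor is the posterior-to-prior odds ratio that the reference model
outperforms the comparison model, with prior odds 1:

    BF = P(M_ref > M_comp | D) / P(M_comp > M_ref | D) = wins / losses.

Subsamples where the comparison model wins define the score "overlap".
When the reference never loses, the Bayes factor is reported as the
conservative lower bound (n - 1)/1, rendered e.g. ">999" at 1000
subsamples.  Evidence categories follow the conventional thresholds:
BF > 3 positive, > 20 strong, > 150 very strong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import MetricUndefinedError, score_submission
from .synthetic_data import PredictionSet, substream

__all__ = [
    "StabilityConfig",
    "SubsampleScores",
    "StabilityResult",
    "BayesFactor",
    "subsample_scores",
    "pairwise_stability",
    "bayes_factor",
    "classify_evidence",
    "EVIDENCE_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: (threshold, category); strictly-greater comparisons, checked descending.
EVIDENCE_THRESHOLDS = ((150.0, "very strong"), (20.0, "strong"), (3.0, "positive"))


@dataclass(frozen=True)
class StabilityConfig:
    n_subsamples: int = 1000
    subsample_size: int = 60  # ~81% of the 74 final test patients
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be at least 1")
        if self.subsample_size < 1:
            raise ValueError("subsample_size must be at least 1")


@dataclass(frozen=True)
class BayesFactor:
    """A frequency Bayes factor, possibly only known as a lower bound."""

    value: float
    is_lower_bound: bool = False

    def __float__(self) -> float:
        return self.value

    def __str__(self) -> str:
        text = f"{self.value:g}"
        return f">{text}" if self.is_lower_bound else text


@dataclass
class SubsampleScores:
    """Per-metric score matrices (teams x subsamples) on shared subsamples."""

    matrices: dict[str, pd.DataFrame]  # selector -> (teams x subsamples)
    manifests: list[list]  # patient ids per subsample
    failures: list[tuple[int, str, str]] = field(default_factory=list)

    def matrix(self, selector: str = "combined") -> pd.DataFrame:
        return self.matrices[selector]


@dataclass
class StabilityResult:
    reference_rank: int
    comparison_rank: int
    delta_samples: np.ndarray  # M_ref - M_comp per subsample
    wins: int
    losses: int
    ties: int
    bayes_factor: BayesFactor | None
    evidence: str

    @property
    def n_subsamples(self) -> int:
        return self.wins + self.losses + self.ties

    @property
    def overlap(self) -> float:
        """Fraction of subsamples in which the lower-ranked model wins."""
        return self.losses / self.n_subsamples

    def to_dict(self) -> dict:
        return {
            "reference_rank": self.reference_rank,
            "comparison_rank": self.comparison_rank,
            "wins": self.wins,
            "losses": self.losses,
            "ties": self.ties,
            "overlap": self.overlap,
            "bf": str(self.bayes_factor) if self.bayes_factor else "NA",
            "evidence": self.evidence,
        }


def subsample_scores(
    prediction_sets: Sequence[PredictionSet],
    truth: pd.DataFrame,
    config: StabilityConfig,
    bac_threshold: float = 0.5,
) -> SubsampleScores:
    """Re-score every team on the same seeded random subsamples.

    Each subsample is drawn without replacement from the truth's patients.
    A score that is undefined on some subsample (e.g. no relapsed responder
    drawn) is recorded as NaN and logged.  Deterministic given the seed.
    """
    if not prediction_sets:
        raise ValueError("at least one prediction set is required")
    test_ids = truth.index
    if config.subsample_size >= len(test_ids) + 1:
        raise ValueError(
            f"subsample_size {config.subsample_size} exceeds the "
            f"{len(test_ids)} available patients"
        )
    sc = prediction_sets[0].subchallenge
    teams = [ps.team_id for ps in prediction_sets]
    rng = substream(config.seed, "stability")
    manifests = [
        list(rng.choice(test_ids, size=config.subsample_size, replace=False))
        for _ in range(config.n_subsamples)
    ]
    selectors = ("metric_a", "metric_b", "combined")
    arrays = {
        s: np.full((len(teams), config.n_subsamples), np.nan) for s in selectors
    }
    failures: list[tuple[int, str, str]] = []
    for j, subset in enumerate(manifests):
        for i, ps in enumerate(prediction_sets):
            try:
                rep = score_submission(
                    sc, truth, ps, subset, bac_threshold, subset_id=f"sub{j:04d}"
                )
            except MetricUndefinedError as exc:
                logger.warning("subsample %d: %s undefined (%s)", j, ps.team_id, exc)
                failures.append((j, ps.team_id, str(exc)))
                continue
            for s in selectors:
                arrays[s][i, j] = rep.metric(s)
    matrices = {
        s: pd.DataFrame(arrays[s], index=pd.Index(teams, name="team_id"))
        for s in selectors
    }
    return SubsampleScores(matrices=matrices, manifests=manifests, failures=failures)


def pairwise_stability(
    score_matrix: pd.DataFrame, ref_rank: int, comp_rank: int
) -> StabilityResult:
    """Win/loss/tie counts and Bayes factor for one model pair.

    ``score_matrix`` rows must be ordered by final rank (row 1 = rank 1).
    Subsamples where either model's score is missing are dropped from the
    counts.  Ties (zero difference) enter neither the Bayes factor's
    numerator nor denominator.
    """
    for rank in (ref_rank, comp_rank):
        if not 1 <= rank <= len(score_matrix):
            raise ValueError(f"rank {rank} outside the score matrix")
    ref = score_matrix.iloc[ref_rank - 1].to_numpy(dtype=float)
    comp = score_matrix.iloc[comp_rank - 1].to_numpy(dtype=float)
    ok = ~(np.isnan(ref) | np.isnan(comp))
    delta = ref[ok] - comp[ok]
    wins = int((delta > 0).sum())
    losses = int((delta < 0).sum())
    ties = int((delta == 0).sum())
    if wins + losses == 0:
        bf = None
        evidence = "inconclusive"
    else:
        bf = bayes_factor(wins, losses)
        evidence = classify_evidence(bf)
    return StabilityResult(
        reference_rank=ref_rank,
        comparison_rank=comp_rank,
        delta_samples=delta,
        wins=wins,
        losses=losses,
        ties=ties,
        bayes_factor=bf,
        evidence=evidence,
    )


def bayes_factor(wins: int, losses: int) -> BayesFactor:
    """Posterior-to-prior odds ratio with prior odds 1: wins / losses.

    With zero losses the ratio is unbounded; the conservative lower bound
    (wins - 1)/1 is returned and flagged, so 1000 unbeaten subsamples are
    reported as ">999".
    """
    if wins < 0 or losses < 0:
        raise ValueError("counts must be nonnegative")
    if wins + losses == 0:
        raise ValueError("Bayes factor undefined with no strict orderings")
    if losses == 0:
        return BayesFactor(float(wins - 1), is_lower_bound=True)
    return BayesFactor(wins / losses)


def classify_evidence(bf: BayesFactor | float) -> str:
    """Map a Bayes factor to its conventional evidence category.

    Lower bounds are classified by the bound itself (the true value can
    only be larger, so the category is conservative).
    """
    value = float(bf)
    if value < 0:
        raise ValueError("Bayes factor must be nonnegative")
    for threshold, category in EVIDENCE_THRESHOLDS:
        if value > threshold:
            return category
    return "inconclusive"


def stability_table(
    score_matrix: pd.DataFrame, ref_rank: int = 1
) -> pd.DataFrame:
    """StabilityResult rows for the reference rank against every other rank."""
    rows = []
    for comp in range(1, len(score_matrix) + 1):
        if comp == ref_rank:
            continue
        rows.append(pairwise_stability(score_matrix, ref_rank, comp).to_dict())
    return pd.DataFrame(rows)
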