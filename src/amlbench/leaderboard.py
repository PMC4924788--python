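"""Weekly leaderboard simulation and final ranking.

Reproduces the 13-week challenge cadence: weeks 1-11 are scored on a fresh
random 75-of-100 patient subset to discourage over-fitting to the feedback;
weeks 12-13 are scored on a fixed-size subset (default 74) drawn after
removing a configurable exclusion list of patients whose outcomes might have
been externally knowable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import MetricUndefinedError, ScoreReport, score_submission
from .synthetic_data import PredictionSet, substream

__all__ = [
    "LeaderboardConfig",
    "LeaderboardResult",
    "run_leaderboard",
    "best_score_trajectory",
    "trajectory_improvement",
    "final_ranking",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LeaderboardConfig:
    n_weeks: int = 13
    weekly_subset_size: int = 75  # weeks 1 .. n_weeks-2
    final_subset_size: int = 74  # last two weeks, after exclusions
    final_weeks: int = 2
    exclusion_ids: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be at least 1")
        if self.final_weeks < 0 or self.final_weeks > self.n_weeks:
            raise ValueError("final_weeks must lie in [0, n_weeks]")


@dataclass
class LeaderboardResult:
    reports: dict[int, list[ScoreReport]]  # week -> reports
    manifests: dict[int, list]  # week -> patient ids scored that week
    skipped: list[tuple[int, str, str]] = field(default_factory=list)

    def final_reports(self) -> list[ScoreReport]:
        last = max(self.reports)
        return self.reports[last]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for week, reps in sorted(self.reports.items()):
            for r in reps:
                d = r.to_dict()
                d["week"] = week
                d["metric_a"] = r.metric_a
                d["metric_b"] = r.metric_b
                rows.append(
                    {
                        "week": week,
                        "team_id": r.team_id,
                        "metric_a": r.metric_a,
                        "metric_b": r.metric_b,
                        "combined": r.combined,
                        "n_evaluated": r.n_evaluated,
                    }
                )
        return pd.DataFrame(rows)


def run_leaderboard(
    truth: pd.DataFrame,
    prediction_sets_by_week: Mapping[int, Sequence[PredictionSet]]
    | Sequence[PredictionSet],
    config: LeaderboardConfig,
    subchallenge: str | None = None,
    bac_threshold: float = 0.5,
) -> LeaderboardResult:
    """Score every team on every week's seeded random subset.

    ``prediction_sets_by_week`` may be a mapping week -> sets (teams may
    revise submissions) or a flat sequence reused every week.  Submissions
    whose metrics are undefined on a given subset are skipped and logged,
    not failed.  Deterministic given ``config.seed``.
    """
    test_ids = truth.index
    if isinstance(prediction_sets_by_week, Mapping):
        by_week = {int(w): list(v) for w, v in prediction_sets_by_week.items()}
    else:
        sets = list(prediction_sets_by_week)
        by_week = {w: sets for w in range(1, config.n_weeks + 1)}

    n_regular = config.n_weeks - config.final_weeks
    if config.weekly_subset_size > len(test_ids):
        raise ValueError(
            f"weekly subset size {config.weekly_subset_size} exceeds "
            f"test-set size {len(test_ids)}"
        )
    final_pool = test_ids[~test_ids.isin(config.exclusion_ids)]
    if config.final_weeks and config.final_subset_size > len(final_pool):
        raise ValueError(
            f"final subset size {config.final_subset_size} exceeds the "
            f"{len(final_pool)} patients left after exclusions"
        )

    rng = substream(config.seed, "leaderboard")
    result = LeaderboardResult(reports={}, manifests={})
    for week in range(1, config.n_weeks + 1):
        if week <= n_regular:
            subset = rng.choice(test_ids, size=config.weekly_subset_size, replace=False)
        else:
            subset = rng.choice(
                final_pool, size=config.final_subset_size, replace=False
            )
        subset = list(subset)
        result.manifests[week] = subset
        result.reports[week] = []
        for ps in by_week.get(week, []):
            sc = subchallenge or ps.subchallenge
            try:
                report = score_submission(
                    sc, truth, ps, subset, bac_threshold, subset_id=f"week{week:02d}"
                )
            except MetricUndefinedError as exc:
                logger.warning(
                    "week %d: skipping %s (%s)", week, ps.team_id, exc
                )
                result.skipped.append((week, ps.team_id, str(exc)))
                continue
            result.reports[week].append(report)
    return result


def best_score_trajectory(
    weekly_reports: Mapping[int, Sequence[ScoreReport]],
    metric_selector: str = "combined",
) -> pd.Series:
    """Running maximum of the weekly best score.

    If no week's best exceeds the previous running best, the previous value
    is maintained, so the trajectory is non-decreasing by construction.
    """
    if not weekly_reports:
        raise ValueError("at least one week of reports is required")
    weeks = sorted(weekly_reports)
    best = -np.inf
    values = []
    for w in weeks:
        scores = [r.metric(metric_selector) for r in weekly_reports[w]]
        if scores:
            best = max(best, max(scores))
        values.append(best)
    return pd.Series(values, index=pd.Index(weeks, name="week"), name=metric_selector)


def trajectory_improvement(trajectory: pd.Series) -> float:
    """Percent improvement from the first week's best to the overall best."""
    first = float(trajectory.iloc[0])
    best = float(trajectory.max())
    if first == 0:
        raise ZeroDivisionError("first-week best score is zero")
    return 100.0 * (best - first) / first


def final_ranking(final_reports: Sequence[ScoreReport]) -> pd.DataFrame:
    """Rank teams by combined score, ties broken by metric_a then team id."""
    teams = [r.team_id for r in final_reports]
    if len(set(teams)) != len(teams):
        raise ValueError("one final report per team required")
    rows = sorted(
        final_reports, key=lambda r: (-r.combined, -r.metric_a, r.team_id)
    )
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(rows) + 1),
            "team_id": [r.team_id for r in rows],
            "metric_a": [r.metric_a for r in rows],
            "metric_b": [r.metric_b for r in rows],
            "combined": [r.combined for r in rows],
        }
    )
    return frame.set_index("rank")
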