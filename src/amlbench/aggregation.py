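"""Wisdom-of-crowds aggregation of ranked submissions.

The ensemble prediction for rank k is the per-patient arithmetic mean of the
raw submitted values (confidences; and predicted weeks for the survival
sub-challenges) over the top-k ranked models.  Scoring the aggregate across
k yields the aggregation curve: how ensemble performance moves as
progressively weaker models are folded in.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import score_submission
from .synthetic_data import PredictionSet

__all__ = ["aggregate_predictions", "aggregation_curve"]


def aggregate_predictions(
    prediction_sets: Sequence[PredictionSet], k: int
) -> PredictionSet:
    """Arithmetic mean of the top-k prediction sets (ordered by rank)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if not prediction_sets:
        raise ValueError("at least one prediction set is required")
    top = list(prediction_sets[:k])
    sc = top[0].subchallenge
    ids = top[0].patient_ids
    for ps in top[1:]:
        if ps.subchallenge != sc:
            raise ValueError("all sets must target the same sub-challenge")
        if len(ps.patient_ids) != len(ids) or not ps.covers(ids):
            raise ValueError(
                f"patient coverage mismatch between {top[0].team_id} and {ps.team_id}"
            )
    conf = np.mean([ps.confidences(ids) for ps in top], axis=0)
    data = {"confidence": conf}
    if sc in ("SC2", "SC3"):
        data["predicted_weeks"] = np.mean([ps.weeks(ids) for ps in top], axis=0)
    frame = pd.DataFrame(data, index=ids)
    return PredictionSet(f"aggregate_top{len(top)}", sc, frame)


def aggregation_curve(
    ranked_sets: Sequence[PredictionSet],
    truth: pd.DataFrame,
    subset: Sequence,
    bac_threshold: float = 0.5,
) -> pd.DataFrame:
    """Combined score of the top-k ensemble for every k, vs. individuals.

    Row k gives the score of the mean prediction over ranks 1..k (the
    minimum included rank is k) next to the rank-k model's own score.
    """
    if not ranked_sets:
        raise ValueError("at least one prediction set is required")
    sc = ranked_sets[0].subchallenge
    rows = []
    for k in range(1, len(ranked_sets) + 1):
        agg = aggregate_predictions(ranked_sets, k)
        agg_report = score_submission(sc, truth, agg, subset, bac_threshold)
        ind_report = score_submission(sc, truth, ranked_sets[k - 1], subset, bac_threshold)
        rows.append(
            {
                "min_rank": k,
                "team_id": ranked_sets[k - 1].team_id,
                "aggregate_combined": agg_report.combined,
                "individual_combined": ind_report.combined,
            }
        )
    return pd.DataFrame(rows).set_index("min_rank")
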