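"""Full-dataset metrics, responder classification, and selection reports.

Models refit on the full dataset are scored by squared error, one minus the
pooled Pearson correlation, and R-squared (defined as the squared Pearson
correlation between observed and predicted outcomes).  Classification
accuracy compares observed and predicted responder status at fixed
change-in-viral-load thresholds.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crossval import ONE_MINUS_R, SQE, rank_learners, risk

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (-0.5, -0.6)


def r_squared(y: Sequence[float], pred: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and predicted outcomes.

    Constant predictions give 0 by convention.
    """
    y = np.asarray(y, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if y.shape != pred.shape or y.size < 2:
        raise ValueError("need equal-length vectors with at least two entries")
    if np.ptp(y) == 0 or np.ptp(pred) == 0:
        logger.warning("constant vector in r_squared; returning 0 by convention")
        return 0.0
    r = float(np.corrcoef(y, pred)[0, 1])
    return r * r


def classify_response(values: Sequence[float], threshold: float) -> np.ndarray:
    """Responder flags: a change at or below the (negative) threshold responds."""
    values = np.asarray(values, dtype=float)
    return values <= threshold


def accuracy(
    y_obs: Sequence[float], y_pred: Sequence[float], threshold: float
) -> float:
    """Fraction of patients whose observed and predicted responder status agree."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("observed and predicted vectors must have equal length")
    if y_obs.size == 0:
        raise ValueError("empty input")
    return float(
        np.mean(classify_response(y_obs, threshold) == classify_response(y_pred, threshold))
    )


def full_model_report(
    y: Sequence[float], predictions: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Per-model squared error, pooled 1 - R, and R-squared, each with ranks.

    Returns one row per model with columns ``sqe``, ``one_minus_r``, ``r2``
    and the corresponding ``*_rank`` columns (rank 1 = best; R-squared is
    ranked descending).
    """
    y = np.asarray(y, dtype=float)
    names = list(predictions)
    if not names:
        raise ValueError("no models supplied")
    rows = {}
    for name in names:
        pred = np.asarray(predictions[name], dtype=float)
        rows[name] = {
            "sqe": risk(SQE, y, pred),
            "one_minus_r": risk(ONE_MINUS_R, y, pred),
            "r2": r_squared(y, pred),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "model"
    for col in ("sqe", "one_minus_r"):
        df[f"{col}_rank"] = pd.Series(rank_learners(df[col].to_dict()))
    df["r2_rank"] = pd.Series(rank_learners((-df["r2"]).to_dict()))
    return df.reset_index()


def accuracy_report(
    y: Sequence[float],
    predictions: Mapping[str, Sequence[float]],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Long-format accuracy table: one row per (model, threshold)."""
    rows = []
    for name, pred in predictions.items():
        for t in thresholds:
            rows.append(
                {"model": name, "threshold": t, "accuracy": accuracy(y, pred, t)}
            )
    return pd.DataFrame(rows)


def selected_mutations_report(models: Mapping[str, object]) -> dict[str, list[str]]:
    """Per-model sorted list of mutation labels the fitted model actually uses."""
    return {
        name: sorted(model.selected_features) for name, model in models.items()
    }
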