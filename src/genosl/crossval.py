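"""k-fold construction, loss functions, cross-validated risk, and ranking.

Two losses are supported: squared error (``SQE``) and one minus the Pearson
correlation between observed and predicted outcomes (``ONE_MINUS_R``).  The
cross-validated risk of a learner is the average of the k per-validation-fold
risks; the out-of-fold predictions form one column of the level-one matrix
on which Super Learner weights are later fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

SQE = "sqe"
ONE_MINUS_R = "one_minus_r"
LOSSES = (SQE, ONE_MINUS_R)

#: risks equal after rounding to this many decimals are treated as ties
RANK_TIE_DECIMALS = 10


class FoldParameterError(ValueError):
    """Raised for invalid fold counts."""


@dataclass(frozen=True)
class FoldAssignment:
    """A random partition of ``n`` patients into ``k`` near-equal folds."""

    k: int
    fold_index: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.fold_index)

    def validation_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def training_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Uniformly random partition of ``n`` patients into ``k`` folds.

    Fold sizes differ by at most one; reproducible for fixed ``(n, k, seed)``.
    """
    if k < 2 or k > n:
        raise FoldParameterError(f"fold count k={k} must satisfy 2 <= k <= n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_index = np.empty(n, dtype=np.int64)
    fold_index[order] = np.arange(n) % k
    return FoldAssignment(k=k, fold_index=fold_index, seed=seed)


def _pearson_r(y: np.ndarray, pred: np.ndarray) -> float:
    """Pearson correlation; 0 by convention (with a warning) for constant input."""
    if np.ptp(y) == 0 or np.ptp(pred) == 0:
        logger.warning("constant vector in correlation; R set to 0 by convention")
        return 0.0
    return float(np.corrcoef(y, pred)[0, 1])


def risk(loss: str, y: Sequence[float], pred: Sequence[float]) -> float:
    """Empirical risk of ``pred`` against ``y`` under ``loss``.

    ``SQE`` is the mean squared difference; ``ONE_MINUS_R`` is one minus the
    Pearson correlation (in [0, 2]; constant inputs give 1 by convention).
    """
    y = np.asarray(y, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if y.shape != pred.shape or y.ndim != 1:
        raise ValueError("y and pred must be equal-length vectors")
    if y.size == 0:
        raise ValueError("empty vectors")
    if not (np.isfinite(y).all() and np.isfinite(pred).all()):
        raise ValueError("non-finite values in risk computation")
    if loss == SQE:
        return float(np.mean((y - pred) ** 2))
    if loss == ONE_MINUS_R:
        if y.size < 2:
            raise ValueError("ONE_MINUS_R requires at least two observations")
        return 1.0 - _pearson_r(y, pred)
    raise ValueError(f"unknown loss {loss!r}")


@dataclass
class CVResult:
    """Per-fold risks, their mean, and the out-of-fold prediction column."""

    fold_risks: np.ndarray
    mean_risk: float
    level_one: np.ndarray


FitFunction = Callable[["object", np.ndarray], "object"]


def _resolve_fit(learner) -> Callable:
    """Accept a learner name (resolved via the learners module) or a callable
    ``fit(dataset, indices) -> model with .predict``."""
    if callable(learner):
        return learner
    from . import learners as _learners

    def fit(dataset, indices):
        return _learners.fit_learner(learner, _subset(dataset, indices))

    return fit


def _subset(dataset, indices: np.ndarray):
    from .genotype import Dataset, GenotypeMatrix

    g = dataset.genotype
    return Dataset(
        genotype=GenotypeMatrix(
            values=g.values[indices],
            patient_ids=[g.patient_ids[i] for i in indices],
            mutation_labels=list(g.mutation_labels),
        ),
        outcome=dataset.outcome[indices],
    )


def level_one_column(learner, dataset, folds: FoldAssignment) -> np.ndarray:
    """Out-of-fold predictions for one learner: entry i comes from the model
    trained on the folds excluding patient i's fold."""
    fit = _resolve_fit(learner)
    column = np.empty(dataset.n, dtype=float)
    for fold in range(folds.k):
        train_idx = folds.training_indices(fold)
        val_idx = folds.validation_indices(fold)
        try:
            model = fit(dataset, train_idx)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(
                f"learner {learner!r} failed to fit on training split of fold {fold}"
            ) from exc
        column[val_idx] = model.predict(dataset.X[val_idx])
    return column


def fold_risks_from_column(
    column: np.ndarray, y: np.ndarray, folds: FoldAssignment, loss: str
) -> np.ndarray:
    """Score a level-one column per validation fold under ``loss``."""
    return np.array(
        [
            risk(loss, y[folds.validation_indices(f)], column[folds.validation_indices(f)])
            for f in range(folds.k)
        ]
    )


def pooled_risk_from_column(column: np.ndarray, y: np.ndarray, loss: str) -> float:
    """Single pooled risk over all out-of-fold predictions (sensitivity variant)."""
    return risk(loss, y, column)


def cross_validated_risk(learner, dataset, folds: FoldAssignment, loss: str) -> CVResult:
    """Fit on each fold's complement, score on the fold, average the k risks."""
    column = level_one_column(learner, dataset, folds)
    fold_risks = fold_risks_from_column(column, dataset.y, folds, loss)
    return CVResult(
        fold_risks=fold_risks,
        mean_risk=float(fold_risks.mean()),
        level_one=column,
    )


def rank_learners(mean_risks: Mapping[str, float]) -> dict[str, float]:
    """Ascending ranks (1 = smallest risk); exact ties receive the mean rank.

    Risks are rounded to ``RANK_TIE_DECIMALS`` decimals before comparison so
    that genuinely equal values tie despite floating-point noise.
    """
    names = list(mean_risks)
    if not names:
        raise ValueError("at least one learner required")
    values = np.array([mean_risks[n] for n in names], dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("risks must be finite")
    ranks = rankdata(np.round(values, RANK_TIE_DECIMALS), method="average")
    return {n: float(r) for n, r in zip(names, ranks)}


@dataclass
class CVRiskTable:
    """Per-learner, per-fold cross-validated risks with mean risk and rank."""

    learner_names: list[str]
    fold_risks: dict[str, np.ndarray]
    mean_risks: dict[str, float]
    ranks: dict[str, float] = field(default_factory=dict)
    k: int = 0
    loss: str = SQE

    def __post_init__(self) -> None:
        if not self.ranks:
            self.ranks = rank_learners(self.mean_risks)
        for name in self.learner_names:
            fr = np.asarray(self.fold_risks[name], dtype=float)
            if not np.isclose(fr.mean(), self.mean_risks[name], atol=1e-10):
                raise ValueError(
                    f"mean risk for {name} is not the mean of its fold risks"
                )

    @classmethod
    def from_fold_risks(
        cls, fold_risks: Mapping[str, np.ndarray], k: int, loss: str
    ) -> "CVRiskTable":
        names = list(fold_risks)
        means = {n: float(np.mean(fold_risks[n])) for n in names}
        return cls(
            learner_names=names,
            fold_risks={n: np.asarray(fold_risks[n], dtype=float) for n in names},
            mean_risks=means,
            k=k,
            loss=loss,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.learner_names:
            rows.append(
                {
                    "learner": name,
                    "rank": self.ranks[name],
                    "mean_risk": self.mean_risks[name],
                    **{
                        f"fold_{i}": r
                        for i, r in enumerate(self.fold_risks[name])
                    },
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
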