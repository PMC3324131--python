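"""Discrete and weighted Super Learner construction from out-of-fold predictions.

The discrete Super Learner selects the candidate with the smallest mean
cross-validated risk.  The weighted Super Learner fits non-negative weights
summing to one over the candidates' level-one (out-of-fold) predictions,
minimizing the chosen loss.  Squared error gives a convex quadratic program
on the simplex; the correlation loss is non-convex and is attacked by
multi-start local optimization, with every simplex vertex always evaluated so
the fitted combination can never do worse than the best single candidate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from . import crossval, learners
from .crossval import (
    CVRiskTable,
    FoldAssignment,
    ONE_MINUS_R,
    SQE,
    make_folds,
    risk,
)
from .genotype import Dataset

logger = logging.getLogger(__name__)

SL5 = "SL5"
SL6 = "SL6"
ROSTERS: dict[str, tuple[str, ...]] = {
    SL5: (learners.DSA, learners.LM1, learners.LM2, learners.RF, learners.CART),
    SL6: (
        learners.DSA,
        learners.LM1,
        learners.LM2,
        learners.RF,
        learners.CART,
        learners.LOGICREG,
    ),
}

WEIGHT_SPARSITY_TOL = 1e-8
_N_STARTS = 20


@dataclass
class SLWeights:
    """Non-negative weights summing to one over the candidate learners."""

    weights: dict[str, float]
    loss: str
    risk: float

    def __post_init__(self) -> None:
        self.weights = {k: float(v) for k, v in self.weights.items()}
        self.risk = float(self.risk)
        w = np.array(list(self.weights.values()))
        if (w < -1e-12).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.weights[n] for n in names])

    def to_json(self, path, **extra) -> None:
        payload = {
            "weights": self.weights,
            "loss": self.loss,
            "risk": self.risk,
            **extra,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def discrete_super_learner(table: CVRiskTable) -> str:
    """Name of the learner with minimum mean cross-validated risk.

    Exact ties go to the learner earliest in the fixed roster order
    (:data:`genosl.learners.ROSTER_ORDER`).
    """
    if not table.learner_names:
        raise ValueError("empty risk table")

    def order_key(name: str) -> int:
        try:
            return learners.ROSTER_ORDER.index(name)
        except ValueError:
            return len(learners.ROSTER_ORDER)

    rounded = {
        n: round(table.mean_risks[n], crossval.RANK_TIE_DECIMALS)
        for n in table.learner_names
    }
    best_risk = min(rounded.values())
    tied = [n for n in table.learner_names if rounded[n] == best_risk]
    return min(tied, key=order_key)


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.flatnonzero(u * np.arange(1, len(v) + 1) > css - 1)[-1]
    theta = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - theta, 0.0)


def fit_sl_weights(
    Z: np.ndarray, y: np.ndarray, loss: str, seed: int = 0
) -> SLWeights:
    """Weights on the simplex minimizing ``risk(loss, y, Z @ w)``.

    All simplex vertices are evaluated along with the optimizer's solutions
    and the best is returned, so the achieved risk never exceeds any single
    column's risk.  Weights below ``WEIGHT_SPARSITY_TOL`` are zeroed and the
    rest renormalized when this does not worsen the risk.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != len(y):
        raise ValueError("Z must be n x L with rows matching y")
    n, L = Z.shape
    names = [f"col{j}" for j in range(L)]

    def obj(w: np.ndarray) -> float:
        return risk(loss, y, Z @ w)

    if np.ptp(Z, axis=0).max(initial=0) == 0 and loss == ONE_MINUS_R:
        logger.warning("all-constant level-one matrix; uniform weights returned")
        w = np.full(L, 1.0 / L)
        return SLWeights(dict(zip(names, w)), loss, obj(w))

    candidates: list[np.ndarray] = [np.eye(L)[j] for j in range(L)]
    rng = np.random.default_rng(seed)
    starts = [np.full(L, 1.0 / L)]
    starts += [np.eye(L)[j] * 0.9 + 0.1 / L for j in range(L)]
    while len(starts) < _N_STARTS:
        starts.append(rng.dirichlet(np.ones(L)))

    constraints = {"type": "eq", "fun": lambda w: w.sum() - 1.0}
    bounds = [(0.0, 1.0)] * L
    for w0 in starts if loss == ONE_MINUS_R else starts[:2]:
        res = minimize(
            obj,
            w0,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if res.success or np.isfinite(res.fun):
            w = _project_simplex(np.asarray(res.x))
            candidates.append(w)

    best_w = min(candidates, key=obj)
    best_risk = obj(best_w)

    sparse = best_w.copy()
    sparse[sparse < WEIGHT_SPARSITY_TOL] = 0.0
    total = sparse.sum()
    if total > 0:
        sparse = sparse / total
        if obj(sparse) <= best_risk + 1e-12:
            best_w, best_risk = sparse, obj(sparse)

    return SLWeights(dict(zip(names, best_w)), loss, float(best_risk))


@dataclass
class SuperLearnerModel:
    """Weighted combination of full-data candidate fits."""

    roster: str
    candidate_names: tuple[str, ...]
    weights: SLWeights
    candidates: dict[str, learners.FittedLearner]
    level_one: np.ndarray = field(repr=False, default=None)
    folds: FoldAssignment | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        w = self.weights.as_array(self.candidate_names)
        Z_new = np.column_stack(
            [self.candidates[n].predict(X) for n in self.candidate_names]
        )
        return Z_new @ w

    @property
    def selected_features(self) -> frozenset[str]:
        out: set[str] = set()
        w = self.weights.weights
        for name in self.candidate_names:
            if w[name] > 0:
                out |= self.candidates[name].selected_features
        return frozenset(out)


def _named_weights(raw: SLWeights, names: Sequence[str]) -> SLWeights:
    values = list(raw.weights.values())
    return SLWeights(dict(zip(names, values)), raw.loss, raw.risk)


def build_super_learner(
    dataset: Dataset,
    roster: str,
    k: int,
    loss: str,
    seed: int,
    learner_params: Mapping[str, Mapping] | None = None,
    folds: FoldAssignment | None = None,
    level_one: Mapping[str, np.ndarray] | None = None,
) -> SuperLearnerModel:
    """Level-one matrix via cross-validation, simplex weights, full refits.

    ``folds`` and precomputed ``level_one`` columns may be supplied so that a
    pipeline can share one fold assignment across learners and losses.
    """
    if roster not in ROSTERS:
        raise ValueError(f"unknown roster {roster!r}; expected one of {list(ROSTERS)}")
    names = ROSTERS[roster]
    learner_params = learner_params or {}
    if folds is None:
        folds = make_folds(dataset.n, k, seed)

    def fit_full(name: str) -> learners.FittedLearner:
        return learners.fit_learner(
            name,
            dataset,
            seed=learners.derive_seed(seed, name),
            **learner_params.get(name, {}),
        )

    columns = {}
    for name in names:
        if level_one is not None and name in level_one:
            columns[name] = np.asarray(level_one[name], dtype=float)
        else:
            def fit_subset(ds, idx, _name=name):
                return learners.fit_learner(
                    _name,
                    crossval._subset(ds, idx),
                    seed=learners.derive_seed(seed, _name),
                    **learner_params.get(_name, {}),
                )

            columns[name] = crossval.level_one_column(fit_subset, dataset, folds)

    Z = np.column_stack([columns[n] for n in names])
    raw = fit_sl_weights(Z, dataset.y, loss, seed=seed)
    weights = _named_weights(raw, names)
    candidates = {name: fit_full(name) for name in names}
    return SuperLearnerModel(
        roster=roster,
        candidate_names=names,
        weights=weights,
        candidates=candidates,
        level_one=Z,
        folds=folds,
    )


def sl_level_one_risk(
    weights: SLWeights,
    Z: np.ndarray,
    y: np.ndarray,
    loss: str,
    names: Sequence[str] | None = None,
) -> float:
    """Risk of the weighted level-one predictions (the default SL table entry)."""
    names = list(weights.weights) if names is None else list(names)
    w = weights.as_array(names)
    return risk(loss, y, np.asarray(Z, dtype=float) @ w)


def honest_sl_cv_risk(
    dataset: Dataset,
    roster: str,
    k: int,
    loss: str,
    seed: int,
    learner_params: Mapping[str, Mapping] | None = None,
) -> float:
    """Nested-CV risk of the whole Super Learner (outer CV around fitting).

    More expensive and pessimistic than the level-one risk; available for
    sensitivity analysis.
    """
    folds = make_folds(dataset.n, k, seed)
    fold_risks = []
    for f in range(folds.k):
        tr = folds.training_indices(f)
        va = folds.validation_indices(f)
        sub = crossval._subset(dataset, tr)
        inner_k = min(k, max(2, sub.n // 2))
        model = build_super_learner(
            sub, roster, inner_k, loss, seed=seed + 1 + f, learner_params=learner_params
        )
        pred = model.predict(dataset.X[va])
        fold_risks.append(risk(loss, dataset.y[va], pred))
    return float(np.mean(fold_risks))
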