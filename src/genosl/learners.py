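"""The six candidate learners behind one fit/predict/selected-features contract.

Learners: main-terms least squares (``lm1``), least squares with all two-way
interactions (``lm2``), a cost-complexity-pruned regression tree (``cart``),
a random forest (``rf``), a deletion/substitution/addition search over
polynomial-basis linear models (``dsa``), and single-tree logic regression
fitted by simulated annealing (``logicreg``).

Least-squares fits use a minimum-norm solution so that rank-deficient designs
(e.g. all two-way interactions of near-collinear binary columns with n < p)
are handled deterministically.
"""

from __future__ import annotations

import abc
import hashlib
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from .crossval import make_folds
from .genotype import Dataset

logger = logging.getLogger(__name__)

LM1 = "lm1"
LM2 = "lm2"
CART = "cart"
RF = "rf"
DSA = "dsa"
LOGICREG = "logicreg"

LEARNER_NAMES = (LM1, LM2, CART, RF, DSA, LOGICREG)

#: fixed order used for deterministic tie-breaking in the discrete Super Learner
ROSTER_ORDER = (LM1, LM2, RF, DSA, CART, LOGICREG)

DEFAULT_CP = 0.01
DEFAULT_N_TREES = 1000
DEFAULT_MAXORDERINT = 2
DEFAULT_MAXSUMOFPOW = 2
DEFAULT_INNER_FOLDS = 5
DEFAULT_MAX_LEAVES = 8
DEFAULT_ANNEAL_ITER = 10_000
MIN_SAMPLES_LEAF = 5


def default_m_try(p: int) -> int:
    """Random-forest default: number of covariates divided by 3 (at least 1)."""
    return max(1, p // 3)


def default_maxsize(p: int) -> int:
    """D/S/A default maximum model size: two times the number of covariates."""
    return 2 * p


def derive_seed(master_seed: int, name: str) -> int:
    """Stable per-learner seed: master seed combined with a name hash."""
    digest = hashlib.blake2s(name.encode(), digest_size=4).digest()
    ss = np.random.SeedSequence([int(master_seed), int.from_bytes(digest, "big")])
    return int(ss.generate_state(1)[0])


class LearnerParameterError(ValueError):
    """Raised for invalid learner hyperparameters."""


@dataclass(frozen=True)
class LearnerSpec:
    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.name not in LEARNER_NAMES:
            raise LearnerParameterError(f"unknown learner {self.name!r}")


class FittedLearner(abc.ABC):
    """A fitted model: predicts on any matrix with the training column set."""

    spec: LearnerSpec
    selected_features: frozenset[str]

    @abc.abstractmethod
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict outcomes for rows of ``X`` (columns as in training)."""


# ---------------------------------------------------------------------------
# linear models


def _interaction_design(X: np.ndarray) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Columns: p main terms then p(p-1)/2 pairwise products, after intercept."""
    n, p = X.shape
    terms: list[tuple[int, ...]] = [(j,) for j in range(p)]
    terms += [(i, j) for i, j in itertools.combinations(range(p), 2)]
    cols = [X[:, t[0]] if len(t) == 1 else X[:, t[0]] * X[:, t[1]] for t in terms]
    return np.column_stack([np.ones(n)] + cols), terms


class _FittedLinear(FittedLearner):
    def __init__(self, spec, coef, terms, labels):
        self.spec = spec
        self.coef = coef  # intercept first
        self.terms = terms  # per non-intercept column: tuple of feature indices
        self._labels = labels
        used: set[str] = set()
        for c, t in zip(coef[1:], terms):
            if c != 0.0:
                used.update(labels[j] for j in t)
        self.selected_features = frozenset(used)

    def _design(self, X: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(X))]
        for t in self.terms:
            col = X[:, t[0]].astype(float)
            for j in t[1:]:
                col = col * X[:, j]
            cols.append(col)
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._design(np.asarray(X, dtype=float)) @ self.coef


def _min_norm_lstsq(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank < D.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d of %d columns); minimum-norm solution",
            rank,
            D.shape[1],
        )
    return coef


def fit_lm_main(dataset: Dataset, seed: int | None = None) -> FittedLearner:
    """Ordinary least squares on intercept plus all main terms (``lm1``)."""
    if dataset.n < 2:
        raise LearnerParameterError("need at least two observations")
    X, y = dataset.X, dataset.y
    D = np.column_stack([np.ones(dataset.n), X])
    if np.ptp(X, axis=0).max(initial=0) == 0:
        logger.warning("all-constant design; intercept-only fit")
    coef = _min_norm_lstsq(D, y)
    terms = [(j,) for j in range(dataset.p)]
    return _FittedLinear(LearnerSpec(LM1), coef, terms, dataset.mutation_labels)


def fit_lm_interact(dataset: Dataset, seed: int | None = None) -> FittedLearner:
    """Least squares on main terms plus all two-way interactions (``lm2``)."""
    if dataset.n < 2:
        raise LearnerParameterError("need at least two observations")
    D, terms = _interaction_design(dataset.X)
    coef = _min_norm_lstsq(D, dataset.y)
    return _FittedLinear(LearnerSpec(LM2), coef, terms, dataset.mutation_labels)


# ---------------------------------------------------------------------------
# trees


class _FittedSKTree(FittedLearner):
    def __init__(self, spec, model, labels):
        self.spec = spec
        self.model = model
        feats: set[str] = set()
        estimators = getattr(model, "estimators_", [model])
        for est in estimators:
            used = est.tree_.feature
            feats.update(labels[j] for j in np.unique(used[used >= 0]))
        self.selected_features = frozenset(feats)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))


def fit_cart(
    dataset: Dataset, cp: float = DEFAULT_CP, seed: int | None = None
) -> FittedLearner:
    """Regression tree pruned by the cost-complexity rule.

    A subtree is kept only if it reduces the training error by at least ``cp``
    times the root error per added leaf; leaves keep at least
    ``MIN_SAMPLES_LEAF`` observations and predict the leaf mean.
    """
    if dataset.n < 2:
        raise LearnerParameterError("need at least two observations")
    y = dataset.y
    # cp scales the root relative error; sklearn's ccp_alpha is absolute per-sample
    ccp_alpha = cp * float(np.var(y))
    model = DecisionTreeRegressor(
        min_samples_leaf=MIN_SAMPLES_LEAF,
        ccp_alpha=ccp_alpha,
        random_state=0 if seed is None else seed,
    )
    model.fit(dataset.X, y)
    spec = LearnerSpec(CART, {"cp": cp}, seed)
    return _FittedSKTree(spec, model, dataset.mutation_labels)


def fit_random_forest(
    dataset: Dataset,
    n_trees: int = DEFAULT_N_TREES,
    m_try: int | None = None,
    seed: int | None = None,
    bootstrap: bool = True,
) -> FittedLearner:
    """Bootstrap-aggregated unpruned regression trees (``rf``).

    ``m_try`` variables are sampled at each node; default is p // 3.
    """
    p = dataset.p
    if m_try is None:
        m_try = default_m_try(p)
    if not 1 <= m_try <= p:
        raise LearnerParameterError(f"m_try={m_try} must be in [1, {p}]")
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=m_try,
        min_samples_leaf=MIN_SAMPLES_LEAF,
        bootstrap=bootstrap,
        random_state=0 if seed is None else seed,
        n_jobs=1,
    )
    model.fit(dataset.X, dataset.y)
    spec = LearnerSpec(RF, {"n_trees": n_trees, "m_try": m_try}, seed)
    return _FittedSKTree(spec, model, dataset.mutation_labels)


# ---------------------------------------------------------------------------
# deletion / substitution / addition search


@dataclass(frozen=True)
class PolynomialTerm:
    """A product of covariates with integer powers.

    On binary covariates any positive power collapses to 1, so terms are
    canonicalized to squarefree products (this is logged once per fit by the
    search, not silently ignored).
    """

    powers: tuple[tuple[int, int], ...]  # sorted (index, power) pairs

    @classmethod
    def from_indices(cls, indices: Iterable[int]) -> "PolynomialTerm":
        return cls(tuple((int(i), 1) for i in sorted(set(indices))))

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.powers)

    @property
    def order(self) -> int:
        return len(self.powers)

    @property
    def sum_of_powers(self) -> int:
        return sum(p for _, p in self.powers)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        col = np.ones(len(X))
        for i, p in self.powers:
            col = col * X[:, i] ** p
        return col


def _ols_rss(D: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    return float(resid @ resid), coef


class _TermModelCache:
    """RSS evaluations for term sets, with column and result caching."""

    def __init__(self, X: np.ndarray, y: np.ndarray, candidates: Sequence[tuple[int, ...]]):
        self.y = y
        self.n = len(y)
        self.cols = {
            t: np.prod(X[:, list(t)], axis=1) if len(t) > 1 else X[:, t[0]].astype(float)
            for t in candidates
        }
        self._rss: dict[tuple, float] = {}

    def rss(self, terms: tuple[tuple[int, ...], ...]) -> float:
        key = tuple(sorted(terms))
        if key not in self._rss:
            D = np.column_stack(
                [np.ones(self.n)] + [self.cols[t] for t in key]
            )
            self._rss[key], _ = _ols_rss(D, self.y)
        return self._rss[key]

    def fit(self, terms: tuple[tuple[int, ...], ...]) -> np.ndarray:
        D = np.column_stack([np.ones(self.n)] + [self.cols[t] for t in terms])
        _, coef = _ols_rss(D, self.y)
        return coef


def _dsa_candidates(p: int, maxorderint: int, maxsumofpow: int) -> list[tuple[int, ...]]:
    max_order = min(maxorderint, maxsumofpow)
    cands: list[tuple[int, ...]] = []
    for size in range(1, max_order + 1):
        cands.extend(itertools.combinations(range(p), size))
    return cands


def _dsa_search(
    X: np.ndarray,
    y: np.ndarray,
    maxsize: int,
    candidates: Sequence[tuple[int, ...]],
) -> dict[int, tuple[tuple[tuple[int, ...], ...], float]]:
    """Best term set of each size 0..maxsize found by D/S/A moves.

    From the current set, all single-term deletions, substitutions, and
    additions are proposed; the move minimizing training RSS that improves the
    recorded best model of the destination size is accepted.
    """
    cache = _TermModelCache(X, y, candidates)
    eps = 1e-12
    current: tuple[tuple[int, ...], ...] = ()
    best: dict[int, tuple[tuple[tuple[int, ...], ...], float]] = {
        0: ((), cache.rss(()))
    }
    cand_set = set(candidates)
    for _ in range(100 * (maxsize + 1)):
        s = len(current)
        in_current = set(current)
        # deletion
        if s >= 1:
            props = [tuple(t for t in current if t != d) for d in current]
            rsss = [cache.rss(p_) for p_ in props]
            i = int(np.argmin(rsss))
            if s - 1 not in best or rsss[i] < best[s - 1][1] - eps:
                best[s - 1] = (props[i], rsss[i])
                current = props[i]
                continue
        # substitution
        if s >= 1:
            best_sub, best_sub_rss = None, math.inf
            for d in current:
                base = tuple(t for t in current if t != d)
                for a in cand_set - in_current:
                    r = cache.rss(base + (a,))
                    if r < best_sub_rss:
                        best_sub, best_sub_rss = base + (a,), r
            if best_sub is not None and best_sub_rss < best[s][1] - eps:
                best[s] = (best_sub, best_sub_rss)
                current = best_sub
                continue
        # addition
        if s < maxsize:
            adds = [current + (a,) for a in cand_set - in_current]
            if adds:
                rsss = [cache.rss(p_) for p_ in adds]
                i = int(np.argmin(rsss))
                if s + 1 not in best or rsss[i] < best[s + 1][1] - eps:
                    best[s + 1] = (adds[i], rsss[i])
                    current = adds[i]
                    continue
        break
    return best


def _one_se_size(cv_mean: dict[int, float], cv_se: dict[int, float]) -> int:
    """Smallest size whose CV risk is within one SE of the minimum."""
    s_min = min(cv_mean, key=lambda s: (cv_mean[s], s))
    threshold = cv_mean[s_min] + cv_se[s_min]
    return min(s for s in cv_mean if cv_mean[s] <= threshold)


def _nearest_size(best: dict[int, tuple], size: int) -> int:
    avail = [s for s in best if s <= size]
    return max(avail) if avail else min(best)


class _FittedDSA(FittedLearner):
    def __init__(self, spec, terms, coef, labels):
        self.spec = spec
        self.terms = [PolynomialTerm.from_indices(t) for t in terms]
        self._raw_terms = terms
        self.coef = coef
        self._labels = labels
        used: set[str] = set()
        for t in terms:
            used.update(labels[j] for j in t)
        self.selected_features = frozenset(used)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = [np.ones(len(X))]
        for t in self._raw_terms:
            cols.append(np.prod(X[:, list(t)], axis=1))
        return np.column_stack(cols) @ self.coef


def fit_dsa(
    dataset: Dataset,
    maxsize: int | None = None,
    maxorderint: int = DEFAULT_MAXORDERINT,
    maxsumofpow: int = DEFAULT_MAXSUMOFPOW,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    seed: int | None = None,
) -> FittedLearner:
    """Deletion/substitution/addition search over polynomial-basis models.

    Records the best model of each size up to ``maxsize`` (default two times
    the number of covariates) and picks the final size by internal
    cross-validation (smallest size within one standard error of the minimum
    CV risk).
    """
    if maxsize is None:
        maxsize = default_maxsize(dataset.p)
    if maxsize < 0:
        raise LearnerParameterError("maxsize must be >= 0")
    logger.info(
        "DSA on binary covariates: powers canonicalized to 1, so maxsumofpow=%d "
        "bounds interaction order together with maxorderint=%d",
        maxsumofpow,
        maxorderint,
    )
    seed = 0 if seed is None else seed
    X, y = dataset.X, dataset.y
    candidates = _dsa_candidates(dataset.p, maxorderint, maxsumofpow)
    maxsize = min(maxsize, len(candidates))
    best_full = _dsa_search(X, y, maxsize, candidates)

    chosen = max(best_full)
    if maxsize > 0 and inner_folds >= 2 and dataset.n >= 2 * inner_folds:
        folds = make_folds(dataset.n, inner_folds, seed)
        sizes = range(maxsize + 1)
        fold_mse = {s: [] for s in sizes}
        for f in range(folds.k):
            tr, va = folds.training_indices(f), folds.validation_indices(f)
            best_tr = _dsa_search(X[tr], y[tr], maxsize, candidates)
            cache = _TermModelCache(X[tr], y[tr], candidates)
            for s in sizes:
                terms = best_tr[_nearest_size(best_tr, s)][0]
                coef = cache.fit(terms)
                cols = [np.ones(len(va))] + [
                    np.prod(X[np.ix_(va, list(t))], axis=1) for t in terms
                ]
                pred = np.column_stack(cols) @ coef
                fold_mse[s].append(float(np.mean((y[va] - pred) ** 2)))
        cv_mean = {s: float(np.mean(fold_mse[s])) for s in sizes}
        cv_se = {
            s: float(np.std(fold_mse[s], ddof=1) / math.sqrt(folds.k)) for s in sizes
        }
        chosen = _one_se_size(cv_mean, cv_se)

    terms = best_full[_nearest_size(best_full, chosen)][0]
    cache = _TermModelCache(X, y, candidates)
    coef = cache.fit(terms)
    spec = LearnerSpec(
        DSA,
        {
            "maxsize": maxsize,
            "maxorderint": maxorderint,
            "maxsumofpow": maxsumofpow,
            "inner_folds": inner_folds,
        },
        seed,
    )
    return _FittedDSA(spec, terms, coef, dataset.mutation_labels)


# ---------------------------------------------------------------------------
# logic regression


class BooleanTree:
    """AND/OR tree over binary covariates with optionally negated leaves.

    Nodes are nested tuples: ``("leaf", var, negated)`` or
    ``(op, left, right)`` with ``op`` in ``{"and", "or"}``.
    """

    def __init__(self, root: tuple):
        self.root = root

    @classmethod
    def leaf(cls, var: int, negated: bool = False) -> "BooleanTree":
        return cls(("leaf", int(var), bool(negated)))

    @classmethod
    def combine(cls, op: str, left: "BooleanTree", right: "BooleanTree") -> "BooleanTree":
        if op not in ("and", "or"):
            raise ValueError(f"unknown operator {op!r}")
        return cls((op, left.root, right.root))

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Evaluate to a {0,1} vector on the rows of a binary matrix."""
        X = np.asarray(X)
        return _eval_node(self.root, X).astype(float)

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in _iter_leaves(self.root))

    @property
    def variables(self) -> frozenset[int]:
        return frozenset(v for v, _ in _iter_leaves(self.root))

    def __repr__(self) -> str:
        return f"BooleanTree({_node_str(self.root)})"

    def __eq__(self, other) -> bool:
        return isinstance(other, BooleanTree) and self.root == other.root

    def __hash__(self) -> int:
        return hash(self.root)


def _eval_node(node: tuple, X: np.ndarray) -> np.ndarray:
    kind = node[0]
    if kind == "leaf":
        col = X[:, node[1]].astype(bool)
        return ~col if node[2] else col
    left = _eval_node(node[1], X)
    right = _eval_node(node[2], X)
    return left & right if kind == "and" else left | right


def _iter_leaves(node: tuple):
    if node[0] == "leaf":
        yield node[1], node[2]
    else:
        yield from _iter_leaves(node[1])
        yield from _iter_leaves(node[2])


def _node_str(node: tuple) -> str:
    if node[0] == "leaf":
        return ("!x" if node[2] else "x") + str(node[1])
    sep = " & " if node[0] == "and" else " | "
    return "(" + _node_str(node[1]) + sep + _node_str(node[2]) + ")"


def _node_paths(node: tuple, path=()):  # all paths, leaves and internal
    yield path, node
    if node[0] != "leaf":
        yield from _node_paths(node[1], path + (1,))
        yield from _node_paths(node[2], path + (2,))


def _replace(node: tuple, path: tuple, new: tuple) -> tuple:
    if not path:
        return new
    head, rest = path[0], path[1:]
    if head == 1:
        return (node[0], _replace(node[1], rest, new), node[2])
    return (node[0], node[1], _replace(node[2], rest, new))


def _count_leaves(node: tuple) -> int:
    return sum(1 for _ in _iter_leaves(node))


def _random_leaf(rng: np.random.Generator, p: int) -> tuple:
    return ("leaf", int(rng.integers(p)), bool(rng.integers(2)))


def _complement(node: tuple) -> tuple:
    """De Morgan complement: same indicator negated, as an AND/OR tree."""
    if node[0] == "leaf":
        return ("leaf", node[1], not node[2])
    op = "or" if node[0] == "and" else "and"
    return (op, _complement(node[1]), _complement(node[2]))


def _propose_move(node: tuple, rng: np.random.Generator, p: int, max_leaves: int) -> tuple:
    """One random move: alternate leaf, alternate operator, grow, prune, split."""
    paths = list(_node_paths(node))
    leaves = [(pa, nd) for pa, nd in paths if nd[0] == "leaf"]
    internal = [(pa, nd) for pa, nd in paths if nd[0] != "leaf"]
    n_leaves = len(leaves)
    moves = ["alternate_leaf"]
    if internal:
        moves += ["alternate_operator", "prune"]
    if n_leaves < max_leaves:
        moves += ["grow", "split"]
    move = moves[int(rng.integers(len(moves)))]
    if move == "alternate_leaf":
        path, _ = leaves[int(rng.integers(n_leaves))]
        return _replace(node, path, _random_leaf(rng, p))
    if move == "alternate_operator":
        path, nd = internal[int(rng.integers(len(internal)))]
        flipped = ("or" if nd[0] == "and" else "and", nd[1], nd[2])
        return _replace(node, path, flipped)
    if move == "prune":
        path, nd = internal[int(rng.integers(len(internal)))]
        keep = nd[1] if rng.integers(2) == 0 else nd[2]
        return _replace(node, path, keep)
    if move == "grow":  # join a new leaf at the root
        op = "and" if rng.integers(2) == 0 else "or"
        return (op, node, _random_leaf(rng, p))
    # split: replace a random leaf with (op, leaf, new leaf)
    path, nd = leaves[int(rng.integers(n_leaves))]
    op = "and" if rng.integers(2) == 0 else "or"
    return _replace(node, path, (op, nd, _random_leaf(rng, p)))


def _simple_fit(L: np.ndarray, y: np.ndarray, syy: float, ybar: float) -> tuple[float, float, float]:
    """Closed-form least squares of y on a binary vector: (rss, b0, b1)."""
    n = len(y)
    nL = float(L.sum())
    sxx = nL - nL * nL / n
    if sxx <= 0:
        return syy, ybar, 0.0
    sxy = float(L @ y) - nL * ybar
    b1 = sxy / sxx
    rss = syy - sxy * sxy / sxx
    mean_L = nL / n
    b0 = ybar - b1 * mean_L
    return rss, b0, b1


def _anneal(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    max_leaves: int,
    n_iter: int,
) -> dict[int, tuple[float, tuple]]:
    """Simulated annealing over Boolean trees; returns the best state (lowest
    RSS of y ~ b0 + b1*tree) seen for each leaf count."""
    n, p = X.shape
    ybar = float(y.mean())
    syy = float(((y - ybar) ** 2).sum())

    def objective(node: tuple) -> float:
        L = _eval_node(node, X)
        rss, _, _ = _simple_fit(L, y, syy, ybar)
        return rss

    state = _random_leaf(rng, p)
    state_obj = objective(state)
    best_by_size: dict[int, tuple[float, tuple]] = {1: (state_obj, state)}

    def record(node: tuple, obj: float) -> None:
        size = _count_leaves(node)
        if size not in best_by_size or obj < best_by_size[size][0]:
            best_by_size[size] = (obj, node)

    # pilot: set T0 so roughly half of uphill moves would be accepted
    uphill = []
    probe = state
    probe_obj = state_obj
    for _ in range(100):
        cand = _propose_move(probe, rng, p, max_leaves)
        cand_obj = objective(cand)
        record(cand, cand_obj)
        if cand_obj > probe_obj:
            uphill.append(cand_obj - probe_obj)
        probe, probe_obj = cand, cand_obj
    t0 = (float(np.median(uphill)) / math.log(2.0)) if uphill else max(syy, 1.0) / 100
    t0 = max(t0, 1e-12)
    t_end = t0 * 1e-7
    cool = (t_end / t0) ** (1.0 / max(n_iter, 1))

    temp = t0
    for _ in range(n_iter):
        cand = _propose_move(state, rng, p, max_leaves)
        cand_obj = objective(cand)
        record(cand, cand_obj)
        delta = cand_obj - state_obj
        if delta <= 0 or rng.random() < math.exp(-delta / temp):
            state, state_obj = cand, cand_obj
        temp *= cool
    return best_by_size


class _FittedLogicReg(FittedLearner):
    def __init__(self, spec, tree: BooleanTree, b0: float, b1: float, labels):
        self.spec = spec
        self.tree = tree
        self.b0 = b0
        self.b1 = b1
        if b1 != 0.0:
            self.selected_features = frozenset(labels[v] for v in tree.variables)
        else:
            self.selected_features = frozenset()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.b0 + self.b1 * self.tree.evaluate(np.asarray(X))


def fit_fixed_boolean(dataset: Dataset, tree: BooleanTree) -> FittedLearner:
    """Least-squares fit of y on a given Boolean tree (no search)."""
    y = dataset.y
    ybar = float(y.mean())
    syy = float(((y - ybar) ** 2).sum())
    L = tree.evaluate(dataset.X)
    _, b0, b1 = _simple_fit(L, y, syy, ybar)
    return _FittedLogicReg(LearnerSpec(LOGICREG), tree, b0, b1, dataset.mutation_labels)


def fit_logicreg(
    dataset: Dataset,
    max_leaves: int = DEFAULT_MAX_LEAVES,
    n_iter: int = DEFAULT_ANNEAL_ITER,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    seed: int | None = None,
) -> FittedLearner:
    """Single-tree logic regression: y ~ b0 + b1 * L(X) with L an AND/OR tree.

    The tree is found by simulated annealing (geometric cooling, best-so-far
    kept per leaf count); the leaf count is chosen by internal cross-validation
    with a one-standard-error rule.
    """
    if max_leaves < 1:
        raise LearnerParameterError("max_leaves must be >= 1")
    seed = 0 if seed is None else seed
    rng = np.random.default_rng(seed)
    X, y = dataset.X, dataset.y

    best_full = _anneal(X, y, rng, max_leaves, n_iter)

    chosen = min(best_full, key=lambda s: best_full[s][0])
    if inner_folds >= 2 and dataset.n >= 2 * inner_folds and max_leaves > 1:
        folds = make_folds(dataset.n, inner_folds, seed)
        sizes = sorted(best_full)
        fold_mse = {s: [] for s in sizes}
        for f in range(folds.k):
            tr, va = folds.training_indices(f), folds.validation_indices(f)
            ytr = y[tr]
            ybar = float(ytr.mean())
            syy = float(((ytr - ybar) ** 2).sum())
            best_tr = _anneal(X[tr], ytr, rng, max_leaves, n_iter)
            for s in sizes:
                avail = [t for t in best_tr if t <= s]
                s_use = max(avail) if avail else min(best_tr)
                node = best_tr[s_use][1]
                _, b0, b1 = _simple_fit(_eval_node(node, X[tr]), ytr, syy, ybar)
                pred = b0 + b1 * _eval_node(node, X[va])
                fold_mse[s].append(float(np.mean((y[va] - pred) ** 2)))
        cv_mean = {s: float(np.mean(fold_mse[s])) for s in sizes}
        cv_se = {
            s: float(np.std(fold_mse[s], ddof=1) / math.sqrt(folds.k)) for s in sizes
        }
        chosen = _one_se_size(cv_mean, cv_se)

    avail = [t for t in best_full if t <= chosen]
    node = best_full[max(avail) if avail else min(best_full)][1]
    ybar = float(y.mean())
    syy = float(((y - ybar) ** 2).sum())
    _, b0, b1 = _simple_fit(_eval_node(node, X), y, syy, ybar)
    if b1 < 0:
        # canonical form: non-negative slope; the complement tree with flipped
        # coefficients gives identical predictions
        node = _complement(node)
        b0, b1 = b0 + b1, -b1
    spec = LearnerSpec(
        LOGICREG,
        {"max_leaves": max_leaves, "n_iter": n_iter, "inner_folds": inner_folds},
        seed,
    )
    return _FittedLogicReg(spec, BooleanTree(node), b0, b1, dataset.mutation_labels)


# ---------------------------------------------------------------------------
# dispatch

_FITTERS = {
    LM1: fit_lm_main,
    LM2: fit_lm_interact,
    CART: fit_cart,
    RF: fit_random_forest,
    DSA: fit_dsa,
    LOGICREG: fit_logicreg,
}

_STOCHASTIC = frozenset({RF, DSA, LOGICREG})


def fit_learner(
    name: str, dataset: Dataset, seed: int | None = None, **hyperparameters
) -> FittedLearner:
    """Fit a learner by name with the stated defaults for its hyperparameters."""
    if name not in _FITTERS:
        raise LearnerParameterError(f"unknown learner {name!r}")
    return _FITTERS[name](dataset, seed=seed, **hyperparameters)
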