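"""Synthetic cohorts with the statistical structure the analysis assumes.

Provides a default cohort generator emulating a small add-on trial arm
(n = 102 patients, ten binary resistance-mutation covariates with fixed
prevalences, a continuous change-in-viral-load outcome), plus planted-truth
generators (Boolean rule, polynomial terms) used by learner-recovery tests.

Default effect sizes, intercept and noise level are packaged constants chosen
once by calibration simulation so the marginal outcome median is near -0.56
log10 copies/mL with an interquartile range near (-1.2, -0.14); they are not
estimates of any real mutation effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .genotype import Dataset, GenotypeMatrix
from .learners import BooleanTree, PolynomialTerm

DEFAULT_N = 102

DEFAULT_MUTATION_LABELS = (
    "M41L",
    "D67N",
    "T69D",
    "K70R",
    "L74V",
    "V118I",
    "M184V/I",
    "L210W",
    "T215Y/F",
    "K219Q/E",
)

DEFAULT_PREVALENCES = (0.48, 0.343, 0.088, 0.265, 0.088, 0.186, 0.922, 0.275, 0.539, 0.245)

# calibration constants (frozen; see module docstring)
DEFAULT_INTERCEPT = -1.85
DEFAULT_EFFECTS = (0.5, 0.3, 0.2, 0.3, 0.2, 0.2, 0.4, 0.3, 0.5, 0.3)
DEFAULT_NOISE_SD = 0.63


class SyntheticConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass
class SyntheticConfig:
    """Configuration for the cohort generator.

    ``correlation`` (optional) is a latent Gaussian-copula correlation matrix
    inducing mutation co-occurrence while preserving the marginal
    prevalences.  ``censor_floor`` (optional) clamps outcomes below the floor,
    emulating assay-limit censoring in outcome space.
    """

    n: int = DEFAULT_N
    prevalences: tuple[float, ...] = DEFAULT_PREVALENCES
    mutation_labels: tuple[str, ...] | None = DEFAULT_MUTATION_LABELS
    intercept: float = DEFAULT_INTERCEPT
    effects: tuple[float, ...] = DEFAULT_EFFECTS
    interactions: tuple[tuple[int, int, float], ...] = ()
    noise_sd: float = DEFAULT_NOISE_SD
    correlation: Sequence[Sequence[float]] | None = None
    censor_floor: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SyntheticConfigError("n must be >= 1")
        prev = np.asarray(self.prevalences, dtype=float)
        if not ((prev > 0) & (prev < 1)).all():
            raise SyntheticConfigError("prevalences must lie strictly in (0, 1)")
        if self.noise_sd < 0:
            raise SyntheticConfigError("noise_sd must be >= 0")
        if len(self.effects) != len(self.prevalences):
            raise SyntheticConfigError("effects length must match prevalences")
        if self.mutation_labels is not None and len(self.mutation_labels) != len(
            self.prevalences
        ):
            raise SyntheticConfigError("mutation_labels length must match prevalences")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            p = len(self.prevalences)
            if R.shape != (p, p) or not np.allclose(R, R.T):
                raise SyntheticConfigError("correlation must be a symmetric p x p matrix")
            eigvals = np.linalg.eigvalsh(R)
            if eigvals.min() < -1e-10:
                raise SyntheticConfigError("correlation matrix must be positive semi-definite")

    @property
    def p(self) -> int:
        return len(self.prevalences)

    def labels(self) -> list[str]:
        if self.mutation_labels is not None:
            return list(self.mutation_labels)
        return [f"v{j + 1}" for j in range(self.p)]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        payload = json.loads(Path(path).read_text())
        for key in ("prevalences", "effects", "mutation_labels"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        if payload.get("interactions"):
            payload["interactions"] = tuple(
                (int(i), int(j), float(c)) for i, j, c in payload["interactions"]
            )
        else:
            payload["interactions"] = ()
        return cls(**payload)


def default_config(seed: int = 0) -> SyntheticConfig:
    """The packaged default cohort configuration (n = 102, ten mutations)."""
    return SyntheticConfig(seed=seed)


def generate_cohort(config: SyntheticConfig) -> Dataset:
    """Draw a cohort from the configured model; reproducible from the seed.

    Mutations are marginally Bernoulli(prevalence); if a correlation matrix is
    given, co-occurrence is induced by thresholding a latent multivariate
    normal (Gaussian copula).  The outcome is intercept + main effects +
    interactions + Gaussian noise, optionally floored at ``censor_floor``.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p
    prev = np.asarray(config.prevalences, dtype=float)
    if config.correlation is None:
        X = (rng.random((n, p)) < prev).astype(np.int8)
    else:
        R = np.asarray(config.correlation, dtype=float)
        # small jitter keeps Cholesky feasible for PSD-but-singular inputs
        Lc = np.linalg.cholesky(R + 1e-10 * np.eye(p))
        Z = rng.standard_normal((n, p)) @ Lc.T
        X = (Z < norm.ppf(prev)).astype(np.int8)

    y = np.full(n, config.intercept, dtype=float)
    y += X.astype(float) @ np.asarray(config.effects, dtype=float)
    for i, j, coef in config.interactions:
        y += coef * X[:, i] * X[:, j]
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=n)
    if config.censor_floor is not None:
        y = np.maximum(y, config.censor_floor)

    genotype = GenotypeMatrix(
        values=X,
        patient_ids=[f"P{i + 1:03d}" for i in range(n)],
        mutation_labels=config.labels(),
    )
    return Dataset(genotype=genotype, outcome=y)


def _planted_genotype(n: int, p: int, rng: np.random.Generator) -> GenotypeMatrix:
    X = (rng.random((n, p)) < 0.5).astype(np.int8)
    return GenotypeMatrix(
        values=X,
        patient_ids=[f"S{i + 1:04d}" for i in range(n)],
        mutation_labels=[f"v{j + 1}" for j in range(p)],
    )


def generate_planted_boolean(
    n: int,
    rule: BooleanTree,
    effect: float,
    noise_sd: float,
    seed: int,
    p: int | None = None,
) -> Dataset:
    """i.i.d. Bernoulli(0.5) covariates; y = effect * rule(x) + Gaussian noise."""
    max_var = max(rule.variables) if rule.variables else 0
    if p is None:
        p = max(10, max_var + 1)
    if p <= max_var:
        raise SyntheticConfigError(f"rule uses variable {max_var} but p={p}")
    rng = np.random.default_rng(seed)
    genotype = _planted_genotype(n, p, rng)
    y = effect * rule.evaluate(genotype.values)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return Dataset(genotype=genotype, outcome=y)


def generate_planted_polynomial(
    n: int,
    terms: Sequence[tuple[PolynomialTerm, float]],
    noise_sd: float,
    seed: int,
    p: int | None = None,
) -> Dataset:
    """i.i.d. Bernoulli(0.5) covariates; y = sum of coefficient * term + noise."""
    max_var = max((max(t.indices) for t, _ in terms), default=0)
    if p is None:
        p = max(10, max_var + 1)
    if p <= max_var:
        raise SyntheticConfigError(f"terms use variable {max_var} but p={p}")
    rng = np.random.default_rng(seed)
    genotype = _planted_genotype(n, p, rng)
    X = genotype.values.astype(float)
    y = np.zeros(n)
    for term, coef in terms:
        y += coef * term.evaluate(X)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return Dataset(genotype=genotype, outcome=y)
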