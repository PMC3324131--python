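"""End-to-end orchestration: cross-validated risk tables for every fold
scheme, loss and roster, Super Learner weights, full-dataset reports, and
deterministic seeding, written to a run directory.

One fold assignment is computed per fold count and shared by every learner
and loss, so that rankings compare learners rather than fold noise.  Seeds
fan out from the master seed by stable name hashes, so adding a learner does
not perturb the others' randomness.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, crossval, evaluate, learners, superlearner
from .crossval import LOSSES, ONE_MINUS_R, SQE, CVRiskTable, rank_learners
from .genotype import Dataset, read_dataset
from .superlearner import ROSTERS, SL5, SL6, SLWeights
from .synthetic_data import SyntheticConfig, default_config, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_KS = (10, 4, 3, 2)
SL_ROW = "super_learner"


class PipelineError(RuntimeError):
    """Raised when an analysis stage fails; message names the stage."""


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    dataset_path: str | None = None
    synthetic: SyntheticConfig | None = None
    ks: tuple[int, ...] = DEFAULT_KS
    losses: tuple[str, ...] = (SQE, ONE_MINUS_R)
    rosters: tuple[str, ...] = (SL5, SL6)
    thresholds: tuple[float, ...] = evaluate.DEFAULT_THRESHOLDS
    seed: int = 0
    honest_sl: bool = False
    learner_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for loss in self.losses:
            if loss not in LOSSES:
                raise ValueError(f"unknown loss {loss!r}")
        for roster in self.rosters:
            if roster not in ROSTERS:
                raise ValueError(f"unknown roster {roster!r}")
        for t in self.thresholds:
            if t >= 0:
                raise ValueError("thresholds must be negative (reductions)")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        payload = json.loads(Path(path).read_text())
        if payload.get("synthetic") is not None:
            payload["synthetic"] = SyntheticConfig(**payload["synthetic"])
        for key in ("ks", "losses", "rosters", "thresholds"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class AnalysisResult:
    """All outputs of one analysis run."""

    cv_tables: dict[tuple[str, str, int], CVRiskTable]
    summary_tables: dict[tuple[str, str], pd.DataFrame]
    weights: dict[tuple[str, str, int], SLWeights]
    discrete_selections: dict[str, str]
    full_model_report: pd.DataFrame
    accuracy_report: pd.DataFrame
    selected_mutations: dict[str, list[str]]
    meta: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        created = not out.exists()
        try:
            (out / "tables").mkdir(parents=True, exist_ok=True)
            (out / "weights").mkdir(exist_ok=True)
            (out / "figures_data").mkdir(exist_ok=True)
            for (loss, roster), df in self.summary_tables.items():
                df.to_csv(out / "tables" / f"cvrisk_{loss}_{roster}.csv", index=False)
            for (loss, roster, k), table in self.cv_tables.items():
                table.to_csv(out / "tables" / f"cvrisk_{loss}_{roster}_k{k}.csv")
            for (loss, roster, k), w in self.weights.items():
                w.to_json(
                    out / "weights" / f"weights_{loss}_{roster}_k{k}.json",
                    roster=roster,
                    k=k,
                )
            self.full_model_report.to_csv(
                out / "tables" / "full_model_report.csv", index=False
            )
            self.accuracy_report.to_csv(
                out / "figures_data" / "accuracy.csv", index=False
            )
            with open(out / "figures_data" / "selected_mutations.json", "w") as fh:
                json.dump(self.selected_mutations, fh, indent=2)
            with open(out / "meta.json", "w") as fh:
                json.dump(self.meta, fh, indent=2)
        except Exception:
            if created and out.exists():
                shutil.rmtree(out)
            raise


def _load_dataset(config: AnalysisConfig) -> Dataset:
    if config.dataset_path is not None:
        return read_dataset(config.dataset_path)
    synth = config.synthetic if config.synthetic is not None else default_config(config.seed)
    return generate_cohort(synth)


def run_full_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Run the whole analysis; deterministic given dataset bytes and seed."""
    t_start = time.time()
    try:
        dataset = _load_dataset(config)
    except Exception as exc:
        raise PipelineError(f"dataset loading failed: {exc}") from exc

    for k in config.ks:
        if not 2 <= k <= dataset.n:
            raise PipelineError(
                f"fold construction failed: k={k} invalid for n={dataset.n}"
            )

    master = config.seed
    all_learners = ROSTERS[SL6]

    # one fold assignment per k, shared by every learner and loss
    folds = {
        k: crossval.make_folds(dataset.n, k, learners.derive_seed(master, f"folds_k{k}"))
        for k in config.ks
    }

    def fit_for(name: str, ds: Dataset):
        return learners.fit_learner(
            name,
            ds,
            seed=learners.derive_seed(master, name),
            **config.learner_params.get(name, {}),
        )

    logger.info("computing level-one predictions for %d learners", len(all_learners))
    columns: dict[tuple[str, int], np.ndarray] = {}
    for name in all_learners:
        for k in config.ks:
            t0 = time.time()
            try:
                columns[(name, k)] = crossval.level_one_column(
                    lambda ds, idx, _n=name: fit_for(_n, crossval._subset(ds, idx)),
                    dataset,
                    folds[k],
                )
            except Exception as exc:
                raise PipelineError(
                    f"cross-validation failed for learner {name} at k={k}: {exc}"
                ) from exc
            logger.debug("level-one %s k=%d: %.2fs", name, k, time.time() - t0)

    logger.info("fitting full-data models")
    try:
        full_models: dict[str, learners.FittedLearner] = {
            name: fit_for(name, dataset) for name in all_learners
        }
    except Exception as exc:
        raise PipelineError(f"full-data fitting failed: {exc}") from exc

    cv_tables: dict[tuple[str, str, int], CVRiskTable] = {}
    summary: dict[tuple[str, str], pd.DataFrame] = {}
    weights: dict[tuple[str, str, int], SLWeights] = {}
    discrete: dict[str, str] = {}

    for loss in config.losses:
        for roster in config.rosters:
            names = ROSTERS[roster]
            per_k_rank: dict[str, dict[int, float]] = {n: {} for n in [*names, SL_ROW]}
            per_k_mean: dict[str, dict[int, float]] = {n: {} for n in [*names, SL_ROW]}
            for k in config.ks:
                fold_risks = {
                    n: crossval.fold_risks_from_column(
                        columns[(n, k)], dataset.y, folds[k], loss
                    )
                    for n in names
                }
                Z = np.column_stack([columns[(n, k)] for n in names])
                try:
                    raw = superlearner.fit_sl_weights(
                        Z, dataset.y, loss, seed=learners.derive_seed(master, f"sl_{k}")
                    )
                except Exception as exc:
                    raise PipelineError(
                        f"Super Learner weight fitting failed ({loss}, {roster}, k={k}): {exc}"
                    ) from exc
                w = SLWeights(
                    dict(zip(names, raw.weights.values())), raw.loss, raw.risk
                )
                weights[(loss, roster, k)] = w
                sl_column = Z @ w.as_array(names)
                if config.honest_sl:
                    sl_mean = superlearner.honest_sl_cv_risk(
                        dataset,
                        roster,
                        k,
                        loss,
                        seed=learners.derive_seed(master, f"honest_{k}"),
                        learner_params=config.learner_params,
                    )
                    sl_fold = np.full(k, sl_mean)
                else:
                    sl_fold = crossval.fold_risks_from_column(
                        sl_column, dataset.y, folds[k], loss
                    )
                table = CVRiskTable.from_fold_risks(
                    {**fold_risks, SL_ROW: sl_fold}, k=k, loss=loss
                )
                cv_tables[(loss, roster, k)] = table
                base_table = CVRiskTable.from_fold_risks(fold_risks, k=k, loss=loss)
                discrete[f"{loss}_{roster}_k{k}"] = superlearner.discrete_super_learner(
                    base_table
                )
                for n in table.learner_names:
                    per_k_rank[n][k] = table.ranks[n]
                    per_k_mean[n][k] = table.mean_risks[n]

            rows = []
            for n in [*names, SL_ROW]:
                row: dict[str, object] = {"learner": n}
                for k in config.ks:
                    row[f"rank_k{k}"] = per_k_rank[n][k]
                    row[f"mean_k{k}"] = per_k_mean[n][k]
                row["mean_rank"] = float(
                    np.mean([per_k_rank[n][k] for k in config.ks])
                )
                rows.append(row)
            summary[(loss, roster)] = pd.DataFrame(rows)

    # full-dataset models: the six learners plus one SL per roster (weights
    # from the first configured loss and fold count)
    sl_loss, sl_k = config.losses[0], config.ks[0]
    predictions: dict[str, np.ndarray] = {
        name: full_models[name].predict(dataset.X) for name in all_learners
    }
    sl_models: dict[str, superlearner.SuperLearnerModel] = {}
    for roster in config.rosters:
        names = ROSTERS[roster]
        model = superlearner.SuperLearnerModel(
            roster=roster,
            candidate_names=names,
            weights=weights[(sl_loss, roster, sl_k)],
            candidates={n: full_models[n] for n in names},
            level_one=np.column_stack([columns[(n, sl_k)] for n in names]),
            folds=folds[sl_k],
        )
        sl_models[roster] = model
        predictions[roster] = model.predict(dataset.X)

    full_report = evaluate.full_model_report(dataset.y, predictions)
    acc_report = evaluate.accuracy_report(dataset.y, predictions, config.thresholds)
    selected = evaluate.selected_mutations_report({**full_models, **sl_models})

    meta = {
        "package_version": __version__,
        "seed": master,
        "n": dataset.n,
        "p": dataset.p,
        "ks": list(config.ks),
        "losses": list(config.losses),
        "rosters": list(config.rosters),
        "thresholds": list(config.thresholds),
        "honest_sl": config.honest_sl,
        "fold_sharing": "one fold assignment per k, shared across learners and losses",
        "sl_full_model_weights": {"loss": sl_loss, "k": sl_k},
        "runtime_seconds": round(time.time() - t_start, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if config.synthetic is not None:
        meta["synthetic"] = asdict(config.synthetic)
    elif config.dataset_path is None:
        meta["synthetic"] = asdict(default_config(config.seed))

    return AnalysisResult(
        cv_tables=cv_tables,
        summary_tables=summary,
        weights=weights,
        discrete_selections=discrete,
        full_model_report=full_report,
        accuracy_report=acc_report,
        selected_mutations=selected,
        meta=meta,
    )
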