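"""Gradient-boosted regression on interaction features, plus the repeated-seed
cross-validation protocol.

The regression target is pK = -log10 of the inhibition or dissociation
constant. Published hyperparameter sets are exposed per feature family via
:func:`default_config`; they assume corpus-scale training (20k-30k boosting
stages), so the config object makes the stage count explicit and reduced
configurations used in tests and demos are visibly scaled down.

Determinism contract: (data, config, seed) fully determine the fitted model,
and (data, base seed) fully determine every cross-validation partition.
"""
from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import GradientBoostingRegressor

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GBTConfig:
    """Hyperparameters of a gradient-boosted tree regressor."""

    n_stages: int
    max_depth: int
    learning_rate: float
    subsample_fraction: float
    max_features_rule: str = "sqrt"   # "sqrt" or "all"
    min_samples_split: int = 2
    loss: str = "least_squares"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.max_features_rule not in ("sqrt", "all"):
            raise ValueError("max_features_rule must be 'sqrt' or 'all'")
        if self.loss != "least_squares":
            raise ValueError("only least-squares loss is supported")

    def to_estimator(self) -> GradientBoostingRegressor:
        return GradientBoostingRegressor(
            n_estimators=self.n_stages,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample_fraction,
            max_features="sqrt" if self.max_features_rule == "sqrt" else None,
            min_samples_split=self.min_samples_split,
            loss="squared_error",
            random_state=self.seed,
        )


#: Published best hyperparameters per feature family.
_DEFAULT_CONFIGS = {
    "multishell": dict(n_stages=20_000, max_depth=10, learning_rate=0.005,
                       subsample_fraction=0.6, min_samples_split=3),
    "weighted": dict(n_stages=30_000, max_depth=10, learning_rate=0.005,
                     subsample_fraction=0.6, min_samples_split=2),
    "ecif_baseline": dict(n_stages=20_000, max_depth=8, learning_rate=0.005,
                          subsample_fraction=0.7, min_samples_split=2),
}


def default_config(method: str, seed: int = 0) -> GBTConfig:
    """The published best GBT hyperparameters for a feature family."""
    if method not in _DEFAULT_CONFIGS:
        raise ValueError(f"unknown method {method!r}; expected one of "
                         f"{sorted(_DEFAULT_CONFIGS)}")
    return GBTConfig(seed=seed, **_DEFAULT_CONFIGS[method])


@dataclass
class TrainedModel:
    """A fitted ensemble plus the exact feature-name order it expects."""

    config: GBTConfig
    feature_names: list[str]
    estimator: GradientBoostingRegressor
    metadata: dict = field(default_factory=dict)


def _dataset_hash(features: pd.DataFrame, pk: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(",".join(map(str, features.columns)).encode())
    h.update(np.ascontiguousarray(features.to_numpy(dtype=float)).tobytes())
    h.update(np.ascontiguousarray(pk).tobytes())
    return h.hexdigest()[:16]


def _validate(features: pd.DataFrame, pk) -> np.ndarray:
    pk = np.asarray(pk, dtype=float)
    if len(features) != len(pk):
        raise ValueError(f"features ({len(features)} rows) and pK "
                         f"({len(pk)} values) are misaligned")
    if features.isna().to_numpy().any() or np.isnan(pk).any():
        raise ValueError("features/pK contain nulls; filter before training")
    return pk


def train(features: pd.DataFrame, pk, config: GBTConfig) -> TrainedModel:
    """Fit a least-squares gradient-boosted ensemble on a feature table."""
    pk = _validate(features, pk)
    estimator = config.to_estimator()
    estimator.fit(features.to_numpy(dtype=float), pk)
    return TrainedModel(
        config=config,
        feature_names=list(features.columns),
        estimator=estimator,
        metadata={"n_samples": len(pk),
                  "dataset_hash": _dataset_hash(features, pk),
                  "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")},
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Predict pK for each row; feature names are authoritative, not order."""
    missing = [n for n in model.feature_names if n not in features.columns]
    if missing:
        raise KeyError(f"feature column missing: {missing[0]!r} "
                       f"({len(missing)} missing in total)")
    aligned = features[model.feature_names]
    return model.estimator.predict(aligned.to_numpy(dtype=float))


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump({"format_version": _FORMAT_VERSION,
                 "config": model.config,
                 "feature_names": model.feature_names,
                 "estimator": model.estimator,
                 "metadata": model.metadata}, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model file version in {path}")
    return TrainedModel(config=payload["config"],
                        feature_names=payload["feature_names"],
                        estimator=payload["estimator"],
                        metadata=payload["metadata"])


# ---------------------------------------------------------------- cross-validation

def _fold_indices(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Shuffled indices split into contiguous blocks (no stratification)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(order, n_folds)]


def cross_validate(features: pd.DataFrame, pk, config: GBTConfig,
                   n_folds: int = 10, n_trials: int = 10,
                   base_seed: int = 0) -> pd.DataFrame:
    """Repeated-seed k-fold cross-validation.

    Each trial uses a fresh fold partition seeded with ``base_seed + trial``;
    the per-trial mean (see :func:`trial_means`) is the quantity used to
    compare conditions.

    Returns a tidy table with one row per (trial, fold): columns ``trial``,
    ``fold``, ``pearson_r``, ``rmse``, ``n_test``.
    """
    pk = _validate(features, pk)
    n = len(pk)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds n_rows={n}")
    x = features.to_numpy(dtype=float)
    records = []
    for trial in range(n_trials):
        folds = _fold_indices(n, n_folds, base_seed + trial)
        for fold_id, test_idx in enumerate(folds):
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            estimator = config.to_estimator()
            estimator.fit(x[train_mask], pk[train_mask])
            pred = estimator.predict(x[test_idx])
            truth = pk[test_idx]
            r = pearsonr(pred, truth).statistic if np.std(pred) > 0 else np.nan
            rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
            records.append({"trial": trial, "fold": fold_id,
                            "pearson_r": r, "rmse": rmse, "n_test": len(test_idx)})
    return pd.DataFrame.from_records(records)


def trial_means(cv_table: pd.DataFrame) -> pd.DataFrame:
    """Mean Pearson's R and RMSE per trial (the comparison unit)."""
    return cv_table.groupby("trial")[["pearson_r", "rmse"]].mean()


def two_stage_grid_search(features: pd.DataFrame, pk, base_config: GBTConfig,
                          stage1_grid: dict[str, list] | None = None,
                          stage2_grid: dict[str, list] | None = None,
                          n_folds: int = 10, n_trials: int = 10,
                          base_seed: int = 0) -> tuple[GBTConfig, pd.DataFrame]:
    """Two-stage GBT hyperparameter search by repeated-seed CV.

    Stage one scans stage count / learning rate / tree depth with the other
    fields fixed at ``base_config``; stage two fixes the stage-one optimum and
    scans min-samples-split / max-features / subsample. Mean CV Pearson's R
    over trials selects the winner at each stage.
    """
    stage1_grid = stage1_grid or {}
    stage2_grid = stage2_grid or {}
    allowed1 = {"n_stages", "learning_rate", "max_depth"}
    allowed2 = {"min_samples_split", "max_features_rule", "subsample_fraction"}
    if set(stage1_grid) - allowed1:
        raise ValueError(f"stage-1 grid fields must be within {allowed1}")
    if set(stage2_grid) - allowed2:
        raise ValueError(f"stage-2 grid fields must be within {allowed2}")

    records = []

    def scan(grid: dict[str, list], config: GBTConfig, stage: int) -> GBTConfig:
        best, best_r = config, -np.inf
        keys = sorted(grid)
        for combo in product(*(grid[k] for k in keys)) if keys else [()]:
            candidate = replace(config, **dict(zip(keys, combo)))
            cv = cross_validate(features, pk, candidate, n_folds=n_folds,
                                n_trials=n_trials, base_seed=base_seed)
            mean_r = float(trial_means(cv)["pearson_r"].mean())
            records.append({"stage": stage, **dict(zip(keys, combo)),
                            "mean_pearson_r": mean_r,
                            "mean_rmse": float(trial_means(cv)["rmse"].mean())})
            if mean_r > best_r:
                best, best_r = candidate, mean_r
        return best

    best1 = scan(stage1_grid, base_config, stage=1)
    best2 = scan(stage2_grid, best1, stage=2)
    return best2, pd.DataFrame.from_records(records)
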