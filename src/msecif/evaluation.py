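"""Scoring-power metrics, screening enrichment, statistical model comparison
and feature-importance analyses.

Conventions: higher predicted pK means a better (more active) compound, so
screening rankings are descending in score; the enrichment-factor top set has
size ceil(fraction * n) with ties broken by stable input order; bootstrap
comparisons resample complexes (rows), not residuals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr, ttest_ind
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .model_training import GBTConfig, TrainedModel, cross_validate


@dataclass(frozen=True)
class ScoringResult:
    """Scoring power on a set of complexes: Pearson's R and RMSE in pK units."""

    pearson_r: float
    rmse: float
    n: int


@dataclass(frozen=True)
class ScreeningResult:
    """Early-enrichment summary of a virtual-screening ranking."""

    ef_fraction: float
    ef_value: float
    n_compounds: int
    n_actives: int


def scoring_power(predicted, experimental) -> ScoringResult:
    """Pearson correlation and root-mean-square error between predictions and
    experimental affinities.

    Raises if either vector has zero variance (R undefined).
    """
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape:
        raise ValueError("prediction/experiment lengths differ")
    n = len(predicted)
    if n < 3:
        raise ValueError("at least 3 points are needed for a defined R")
    if np.isnan(predicted).any() or np.isnan(experimental).any():
        raise ValueError("inputs contain nulls")
    if np.std(predicted) == 0 or np.std(experimental) == 0:
        raise ValueError("zero variance input: Pearson's R is undefined")
    r = float(pearsonr(predicted, experimental).statistic)
    rmse = float(np.sqrt(np.mean((predicted - experimental) ** 2)))
    return ScoringResult(pearson_r=r, rmse=rmse, n=n)


def enrichment_factor(scores, active_labels,
                      fraction: float = 0.01) -> ScreeningResult:
    """Enrichment factor at a top fraction of a descending score ranking.

    EF = (actives in the top ceil(fraction*n) / top-set size) divided by the
    overall active rate. Ties in score keep stable input order.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(active_labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels lengths differ")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(scores)
    n_actives = int(labels.sum())
    if n_actives == 0:
        raise ValueError("no actives in the label vector")
    n_top = math.ceil(fraction * n)
    order = np.argsort(-scores, kind="stable")
    hits = int(labels[order[:n_top]].sum())
    ef = (hits / n_top) / (n_actives / n)
    return ScreeningResult(ef_fraction=fraction, ef_value=float(ef),
                           n_compounds=n, n_actives=n_actives)


def aggregate_templates(ef_values) -> tuple[float, float]:
    """Mean and sample SD of per-template EFs; a single template has SD 0."""
    ef_values = np.asarray(ef_values, dtype=float)
    if ef_values.size == 0:
        raise ValueError("at least one template is required")
    sd = float(np.std(ef_values, ddof=1)) if ef_values.size > 1 else 0.0
    return float(np.mean(ef_values)), sd


# ----------------------------------------------------------- statistical comparison

def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (B, n) matrices."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a * b).sum(axis=1) / denom


def cliffs_delta(sample_a, sample_b) -> float:
    """Cliff's delta effect size: P(a > b) - P(a < b) over all cross pairs."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    u = mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(2.0 * u / (len(a) * len(b)) - 1.0)


def bootstrap_compare(preds_a, preds_b, experimental,
                      n_boot: int = 10_000, seed: int = 0) -> dict:
    """Compare two prediction vectors on one test set by bootstrap.

    Rows (complexes) are resampled with replacement ``n_boot`` times; each
    replicate yields Pearson's R and RMSE for both models, and the two
    replicate distributions are compared per metric with a two-sided
    Mann-Whitney U-test plus Cliff's delta.

    Returns a dict with keys ``p_pearson_r``, ``p_rmse``, ``delta_pearson_r``,
    ``delta_rmse`` and the replicate arrays.
    """
    a = np.asarray(preds_a, dtype=float)
    b = np.asarray(preds_b, dtype=float)
    y = np.asarray(experimental, dtype=float)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("prediction/experiment vectors are misaligned")
    n = len(y)
    if n < 5:
        raise ValueError("too few complexes for bootstrap resampling")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ya = a[idx]
    yb = b[idx]
    yy = y[idx]
    r_a = _row_pearson(ya, yy)
    r_b = _row_pearson(yb, yy)
    rmse_a = np.sqrt(((ya - yy) ** 2).mean(axis=1))
    rmse_b = np.sqrt(((yb - yy) ** 2).mean(axis=1))
    if np.array_equal(a, b):
        p_r = p_rmse = 1.0
        d_r = d_rmse = 0.0
    else:
        p_r = float(mannwhitneyu(r_a, r_b, alternative="two-sided").pvalue)
        p_rmse = float(mannwhitneyu(rmse_a, rmse_b, alternative="two-sided").pvalue)
        d_r = cliffs_delta(r_a, r_b)
        d_rmse = cliffs_delta(rmse_a, rmse_b)
    return {"p_pearson_r": p_r, "p_rmse": p_rmse,
            "delta_pearson_r": d_r, "delta_rmse": d_rmse,
            "replicates": {"pearson_r_a": r_a, "pearson_r_b": r_b,
                           "rmse_a": rmse_a, "rmse_b": rmse_b}}


def seed_ensemble_compare(metrics_a, metrics_b, alpha: float = 0.05,
                          n_comparisons: int = 1) -> dict:
    """Compare two per-seed metric samples (e.g. per-seed CV Pearson's R).

    Independent two-sample t-test with Bonferroni correction (p multiplied by
    ``n_comparisons``, capped at 1) and pooled-SD Cohen's d.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    stat = ttest_ind(a, b)
    p_corrected = min(1.0, float(stat.pvalue) * n_comparisons)
    pooled_sd = np.sqrt(((len(a) - 1) * np.var(a, ddof=1)
                         + (len(b) - 1) * np.var(b, ddof=1))
                        / (len(a) + len(b) - 2))
    d = float((np.mean(a) - np.mean(b)) / pooled_sd) if pooled_sd > 0 else 0.0
    return {"t_statistic": float(stat.statistic),
            "p_raw": float(stat.pvalue),
            "p_corrected": p_corrected,
            "significant": p_corrected < alpha,
            "cohens_d": d}


# ------------------------------------------------------------- feature importance

def permutation_importance(model: TrainedModel, features: pd.DataFrame, pk,
                           n_repeats: int = 30, seed: int = 0) -> pd.DataFrame:
    """Permutation feature importance of a trained model.

    For each feature, the mean drop in the model's score over ``n_repeats``
    independent column shuffles. Returns a DataFrame indexed by feature name
    with columns ``importance_mean`` and ``importance_sd``, in model feature
    order.
    """
    missing = [n for n in model.feature_names if n not in features.columns]
    if missing:
        raise KeyError(f"feature column missing: {missing[0]!r}")
    aligned = features[model.feature_names]
    result = _sk_permutation_importance(
        model.estimator, aligned.to_numpy(dtype=float),
        np.asarray(pk, dtype=float), n_repeats=n_repeats, random_state=seed)
    return pd.DataFrame({"importance_mean": result.importances_mean,
                         "importance_sd": result.importances_std},
                        index=pd.Index(model.feature_names, name="feature"))


def per_shell_ablation(features: pd.DataFrame, pk, scheme, config: GBTConfig,
                       bands: list[tuple[float, ...]] | None = None,
                       n_folds: int = 10, n_trials: int = 10,
                       base_seed: int = 0) -> pd.DataFrame:
    """Cross-validate models trained on single distance bands of a
    multi-shelled feature table (no ligand descriptors).

    ``bands`` is a list of tuples of shell upper bounds; by default each shell
    forms its own band. Columns are selected by their trailing ``-<bound>``
    tag. Returns one row per band with mean CV Pearson's R and RMSE.
    """
    from .featurization import format_bound

    if bands is None:
        bands = [(b,) for b in scheme.bounds]
    records = []
    for band in bands:
        if not band:
            raise ValueError("empty shell band")
        suffixes = tuple(f"-{format_bound(b)}" for b in band)
        cols = [c for c in features.columns if c.endswith(suffixes)]
        if not cols:
            raise ValueError(f"no feature columns for shell band {band}")
        cv = cross_validate(features[cols], pk, config,
                            n_folds=n_folds, n_trials=n_trials,
                            base_seed=base_seed)
        records.append({"band": "/".join(format_bound(b) for b in band),
                        "n_features": len(cols),
                        "mean_pearson_r": float(cv["pearson_r"].mean()),
                        "mean_rmse": float(cv["rmse"].mean())})
    return pd.DataFrame.from_records(records).set_index("band")
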