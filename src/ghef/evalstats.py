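"""Evaluation statistics, cross-validation, rank tests and local attribution.

Five evaluation statistics are reported throughout the package:

    RMSE  = sqrt( (1/n) Σ (y_i − ŷ_i)² )
    R²    = 1 − Σ(y_i − ŷ_i)² / Σ(y_i − ȳ)²
    MAPE  = (100/n) Σ |(y_i − ŷ_i)/y_i|            [percent]
    PI    = (1/n) Σ 1{ y_i ∈ [L_i, U_i] }           [coverage proportion]
    FGE   = (1/n) Σ |y_i − ŷ_i| / |y_i|

MAPE and FGE are proportional by construction (MAPE = 100·FGE); both
refuse zero-valued observations outright, because relative errors with
near-zero denominators explode silently otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import scipy.stats

from ghef.dataio import Dataset, FEATURE_COLUMNS, SolubilityRecord


def _as_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return y, yhat


def rmse(y, yhat) -> float:
    y, yhat = _as_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y, yhat) -> float:
    y, yhat = _as_pair(y, yhat)
    if y.size < 2:
        raise ValueError("r_squared requires n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r_squared undefined for constant observations")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def _check_nonzero(y: np.ndarray) -> None:
    if np.any(y == 0):
        raise ValueError("relative error undefined: observed vector contains zeros")


def mape(y, yhat) -> float:
    """Mean absolute percentage error (percent)."""
    y, yhat = _as_pair(y, yhat)
    _check_nonzero(y)
    return 100.0 * float(np.mean(np.abs((y - yhat) / y)))


def fge(y, yhat) -> float:
    """Fractional error: mean |y − ŷ|/|y|; equals MAPE/100 identically."""
    y, yhat = _as_pair(y, yhat)
    _check_nonzero(y)
    return float(np.mean(np.abs(y - yhat) / np.abs(y)))


def pi_coverage(y, lower, upper) -> float:
    """Fraction of observations inside their closed prediction interval."""
    y = np.asarray(y, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if not (y.shape == lower.shape == upper.shape):
        raise ValueError("length mismatch between observations and bounds")
    if np.any(lower > upper):
        raise ValueError("crossed interval bounds (lower > upper)")
    return float(np.mean((y >= lower) & (y <= upper)))


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    r_squared: float
    mape: float
    fge: float
    n: int
    pi_coverage: float | None = None

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(asdict(self), indent=indent)


def metrics_report(y, yhat, lower=None, upper=None) -> MetricsReport:
    y_arr = np.asarray(y, dtype=float)
    coverage = None if lower is None else pi_coverage(y, lower, upper)
    return MetricsReport(
        rmse=rmse(y, yhat),
        r_squared=r_squared(y, yhat),
        mape=mape(y, yhat),
        fge=fge(y, yhat),
        n=int(y_arr.size),
        pi_coverage=coverage,
    )


# ---------------------------------------------------------------------------
# k-fold cross-validation


@dataclass(frozen=True)
class FoldAssignment:
    labels: np.ndarray  # fold label per record index
    k: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)


def kfold_indices(n: int, k: int, seed: int) -> FoldAssignment:
    """Random permutation chunked into k folds whose sizes differ by ≤ 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split n={n} records into k={k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    start = 0
    for fold, size in enumerate(sizes):
        labels[perm[start : start + size]] = fold
        start += size
    return FoldAssignment(labels=labels, k=k)


def cross_validate(config, dataset: Dataset, k: int = 5, seed: int = 0) -> dict:
    """Train/evaluate a learner configuration across k folds.

    Returns per-fold reports plus the mean and population std of RMSE and
    R² across folds.  Out-of-fold predictions are returned in record order
    so downstream fusion can be fit without information leakage.
    """
    from ghef.learners import predict_learner, train_learner

    if not dataset.has_targets:
        raise ValueError("cross-validation requires solubility targets")
    folds = kfold_indices(len(dataset), k, seed)
    y = dataset.targets()
    reports = []
    oof = np.empty(len(dataset))
    for fold in range(k):
        val_idx = folds.fold_indices(fold)
        tr_idx = np.flatnonzero(folds.labels != fold)
        model = train_learner(config, dataset.subset(tr_idx))
        yhat = predict_learner(model, dataset.subset(val_idx))
        oof[val_idx] = yhat
        y_val = y[val_idx]
        reports.append(
            MetricsReport(
                rmse=rmse(y_val, yhat),
                r_squared=r_squared(y_val, yhat) if y_val.size >= 2 and np.ptp(y_val) > 0 else float("nan"),
                mape=mape(y_val, yhat),
                fge=fge(y_val, yhat),
                n=int(y_val.size),
            )
        )
    fold_rmse = np.array([r.rmse for r in reports])
    fold_r2 = np.array([r.r_squared for r in reports])
    valid_r2 = fold_r2[~np.isnan(fold_r2)]  # singleton folds carry no R²
    return {
        "folds": reports,
        "assignment": folds,
        "oof_predictions": oof,
        "mean_rmse": float(fold_rmse.mean()),
        "std_rmse": float(fold_rmse.std()),
        "mean_r_squared": float(valid_r2.mean()) if valid_r2.size else float("nan"),
        "std_r_squared": float(valid_r2.std()) if valid_r2.size else float("nan"),
    }


# ---------------------------------------------------------------------------
# Kruskal–Wallis rank test


@dataclass(frozen=True)
class KWResult:
    h_statistic: float
    p_value: float
    group_count: int
    tie_corrected: bool

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(asdict(self), indent=indent)


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> KWResult:
    """Rank-based H test of whether distributions differ across groups.

    Tie-corrected H with a chi-square reference on (g − 1) degrees of
    freedom.  All-identical values yield H = 0 (p = 1) by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    ties = np.unique(values).size < values.size
    if np.unique(values).size == 1:
        return KWResult(h_statistic=0.0, p_value=1.0, group_count=int(labels.size), tie_corrected=True)
    h, p = scipy.stats.kruskal(*samples)
    return KWResult(h_statistic=float(h), p_value=float(p), group_count=int(labels.size), tie_corrected=ties)


def feature_significance(dataset: Dataset) -> dict[str, KWResult]:
    """Kruskal–Wallis screen of solubility grouped by each feature's levels."""
    if not dataset.has_targets:
        raise ValueError("feature screening requires solubility targets")
    y = dataset.targets()
    X = dataset.feature_matrix()
    return {
        feature: kruskal_wallis(y, X[:, j])
        for j, feature in enumerate(FEATURE_COLUMNS)
    }


# ---------------------------------------------------------------------------
# Local surrogate attribution (LIME-style)


@dataclass(frozen=True)
class AttributionConfig:
    n_samples: int = 2000
    kernel_width: float = 0.75 * np.sqrt(len(FEATURE_COLUMNS))  # standardized scale
    ridge: float = 1e-8


@dataclass(frozen=True)
class AttributionVector:
    """Per-feature local contribution scores in target units.

    Each score is the weighted-least-squares coefficient of the local
    linear surrogate on *standardized* features, i.e. the predicted
    response change per one background standard deviation of the feature.
    """

    scores: dict[str, float]
    kernel_width: float
    surrogate_r_squared: float
    zero_variance_features: tuple[str, ...] = ()


def local_attribution(
    predict: Callable[[np.ndarray], np.ndarray],
    record: SolubilityRecord,
    background: Dataset,
    config: AttributionConfig | None = None,
    seed: int = 0,
) -> AttributionVector:
    """Explain one prediction by a locally weighted linear surrogate.

    Perturbations are drawn per-feature from Gaussians centered at the
    record with the background's per-feature standard deviation; samples
    are weighted by an exponential kernel on standardized distance and a
    linear surrogate is fit by weighted least squares.  Features with zero
    background variance are flagged and get attribution 0.
    """
    config = config or AttributionConfig()
    rng = np.random.default_rng(seed)
    x0 = np.asarray(record.features, dtype=float)
    stds = background.feature_matrix().std(axis=0, ddof=0)
    active = stds > 0
    zero_var = tuple(f for f, a in zip(FEATURE_COLUMNS, active) if not a)

    samples = np.tile(x0, (config.n_samples, 1))
    noise = rng.normal(size=(config.n_samples, active.sum()))
    samples[:, active] += noise * stds[active]
    z = np.zeros_like(samples)
    z[:, active] = (samples[:, active] - x0[active]) / stds[active]

    preds = np.asarray(predict(samples), dtype=float)
    d2 = np.sum(z**2, axis=1)
    w = np.exp(-d2 / (2.0 * config.kernel_width**2))

    design = np.column_stack([np.ones(config.n_samples), z[:, active]])
    sw = np.sqrt(w)
    gram = (design * sw[:, None]).T @ (design * sw[:, None])
    gram += config.ridge * np.eye(gram.shape[0])
    beta = np.linalg.solve(gram, (design * sw[:, None]).T @ (preds * sw))

    fitted = design @ beta
    ss_tot = float(np.sum(w * (preds - np.average(preds, weights=w)) ** 2))
    ss_res = float(np.sum(w * (preds - fitted) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    scores = dict.fromkeys(FEATURE_COLUMNS, 0.0)
    for coef, feature in zip(beta[1:], (f for f, a in zip(FEATURE_COLUMNS, active) if a)):
        scores[feature] = float(coef)
    return AttributionVector(
        scores=scores,
        kernel_width=config.kernel_width,
        surrogate_r_squared=r2,
        zero_variance_features=zero_var,
    )
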