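"""Percentile-bootstrap 95% prediction intervals.

The training set is resampled with replacement B times; the model is
refit on each pseudo-training set (hyperparameters frozen by default) and
predicts every target record, yielding an empirical distribution of B
predictions per record.  The interval bounds are the (1−level)/2 and
1−(1−level)/2 empirical quantiles of that distribution (linear
interpolation between order statistics); the point prediction is the
replicate mean.  Coverage — the fraction of observed values inside their
interval — is the calibration diagnostic.

Replicate RNG streams derive per-replicate from the master seed, so
raising B extends the replicate set without changing earlier replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from ghef.dataio import Dataset
from ghef.evalstats import pi_coverage


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    level: float = 0.95
    seed: int = 0
    refit_hyperparameters: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")


class ModelSpec(Protocol):
    """Anything that can be refit from scratch on a dataset."""

    def fit(self, train: Dataset) -> "FittedModel": ...


class FittedModel(Protocol):
    def predict(self, records: Dataset) -> np.ndarray: ...


@dataclass(frozen=True)
class LearnerSpec:
    """Refit recipe for a single base learner with frozen hyperparameters."""

    config: object  # LearnerConfig

    def fit(self, train: Dataset):
        from ghef.learners import train_learner

        return train_learner(self.config, train)


@dataclass(frozen=True)
class WeightedEnsembleSpec:
    """Refit recipe for the weighted ensemble with frozen weights.

    Each replicate refits every member on the resampled data; the simplex
    weights (fitted once on the original training set) stay frozen, which
    mirrors freezing hyperparameters across replicates.
    """

    configs: tuple
    weights: object  # WeightVector

    def fit(self, train: Dataset):
        from ghef.learners import train_learner

        members = tuple(train_learner(c, train) for c in self.configs)
        return _WeightedEnsemblePredictor(members, self.weights)


@dataclass(frozen=True)
class DstEnsembleSpec:
    """Refit recipe for the Dempster-Shafer ensemble.

    Members are refit on each resampled set; the reliabilities, bandwidths
    and frame (all fitted once on the original training data) stay frozen.
    """

    configs: tuple
    reliabilities: object  # Reliability
    bandwidths: tuple[float, ...]
    frame: object  # Frame

    def fit(self, train: Dataset):
        from ghef.learners import train_learner

        members = tuple(train_learner(c, train) for c in self.configs)
        return _DstEnsemblePredictor(members, self.reliabilities, self.bandwidths, self.frame)


@dataclass(frozen=True)
class _DstEnsemblePredictor:
    members: tuple
    reliabilities: object
    bandwidths: tuple[float, ...]
    frame: object

    def predict(self, records: Dataset) -> np.ndarray:
        from ghef.ensemble_fusion import dst_predict

        P = np.column_stack([m.predict(records) for m in self.members])
        fused = dst_predict(P, self.reliabilities, self.bandwidths, self.frame)
        return np.array([f.estimate for f in fused])


@dataclass(frozen=True)
class _WeightedEnsemblePredictor:
    members: tuple
    weights: object

    def predict(self, records: Dataset) -> np.ndarray:
        from ghef.ensemble_fusion import weighted_predict

        P = np.column_stack([m.predict(records) for m in self.members])
        return weighted_predict(self.weights, P)


@dataclass(frozen=True)
class IntervalTable:
    """Per-record point prediction and [L, U] percentile bounds."""

    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    replicates: int
    level: float

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("interval bounds crossed (lower > upper)")

    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    def to_frame(self, records: Dataset | None = None) -> pd.DataFrame:
        frame = pd.DataFrame({"prediction": self.point, "lower": self.lower, "upper": self.upper})
        if records is not None:
            frame = pd.concat([records.to_frame().drop(columns=["solubility"]), frame], axis=1)
        return frame


def bootstrap_resample(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Sample n records with replacement from an n-record dataset."""
    n = len(dataset)
    return dataset.subset(rng.integers(0, n, size=n).tolist())


def bootstrap_pi(
    model_spec: ModelSpec,
    train: Dataset,
    targets: Dataset,
    config: BootstrapConfig,
) -> IntervalTable:
    """Percentile-bootstrap prediction intervals for the target records."""
    if not train.has_targets:
        raise ValueError("bootstrap training data must carry solubility values")
    preds = np.empty((config.replicates, len(targets)))
    for b in range(config.replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), b]))
        resampled = bootstrap_resample(train, rng)
        model = model_spec.fit(resampled)
        preds[b] = model.predict(targets)
    alpha = (1.0 - config.level) / 2.0
    lower = np.quantile(preds, alpha, axis=0, method="linear")
    upper = np.quantile(preds, 1.0 - alpha, axis=0, method="linear")
    return IntervalTable(
        point=preds.mean(axis=0),
        lower=lower,
        upper=upper,
        replicates=config.replicates,
        level=config.level,
    )


@dataclass(frozen=True)
class CalibrationReport:
    coverage: float
    mean_width: float
    n: int


def calibration_report(intervals: IntervalTable, y_true) -> CalibrationReport:
    """Empirical coverage and mean interval width against observed truths."""
    y = np.asarray(y_true, dtype=float)
    coverage = pi_coverage(y, intervals.lower, intervals.upper)
    return CalibrationReport(coverage=coverage, mean_width=float(intervals.widths().mean()), n=int(y.size))


def extrapolation_flags(train: Dataset, targets: Dataset) -> np.ndarray:
    """Flag target records outside the training feature hull (per-axis box).

    Intervals for flagged records extrapolate beyond the sampled domain and
    should be read with caution.
    """
    X_train = train.feature_matrix()
    X_t = targets.feature_matrix()
    lo, hi = X_train.min(axis=0), X_train.max(axis=0)
    return np.any((X_t < lo) | (X_t > hi), axis=1)
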