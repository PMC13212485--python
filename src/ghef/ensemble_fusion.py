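"""Fusion of base-learner predictions: weighted averaging and Dempster-Shafer.

Two fusion strategies combine the base learners' outputs:

* **Weighted averaging** — a convex combination ŷ = Σ_m w_m ŷ_m with the
  simplex weights fitted by EEFO against RMSE on a fitting set.  The unit
  vectors are seeded into the optimizer's initial population, so the fused
  fitting-set RMSE can never exceed the best single member's.

* **Dempster-Shafer evidence combination** — the solubility axis is
  discretized into a frame of K bins plus the ignorance set Θ.  Each model
  contributes a mass function: a reliability-discounted Gaussian (centered
  at its prediction, bandwidth = its validation RMSE) spread over the bins,
  with the remaining 1 − r on Θ.  Masses are folded with Dempster's
  conflict-renormalized rule, and a point value is extracted by the
  pignistic transform.  Belief and plausibility bracket the evidential
  support for any solubility interval; their gap is the ignorance interval.

Focal elements are restricted to singleton bins plus Θ, a family closed
under Dempster's rule, which keeps combination exact and O(K²)-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from ghef.eefo import EEFOConfig, optimize


class TotalConflictError(ValueError):
    """Dempster combination attempted between totally conflicting masses."""


# ---------------------------------------------------------------------------
# Weighted averaging


@dataclass(frozen=True)
class WeightVector:
    """Non-negative per-model weights summing to one."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def _normalize_simplex(raw: np.ndarray) -> np.ndarray:
    raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    if total <= 0:
        return np.full(raw.size, 1.0 / raw.size)
    return raw / total


def fit_weights(prediction_matrix, y, eefo: EEFOConfig | None = None) -> WeightVector:
    """Fit simplex weights minimizing fused RMSE on the fitting set.

    EEFO searches [0,1]^M and repairs each position onto the simplex by
    normalization.  The M unit vectors (plus the uniform point) are seeded
    into the initial population, so the fitted fused RMSE is bounded above
    by every single member's RMSE on this set.
    """
    P = np.asarray(prediction_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    if P.ndim != 2:
        raise ValueError("prediction_matrix must be n × M")
    n, m = P.shape
    if m < 2:
        raise ValueError("need at least 2 models to fuse")
    if n == 0 or y.shape != (n,):
        raise ValueError(f"targets must have length {n}")
    if n < m:
        raise ValueError(f"need at least as many records ({n}) as models ({m})")
    if eefo is None:
        eefo = EEFOConfig(bounds=((0.0, 1.0),) * m, seed=0)
    elif len(eefo.bounds) != m:
        raise ValueError(f"eefo.bounds must be {m}-dimensional")

    def objective(position: np.ndarray) -> float:
        w = _normalize_simplex(position)
        return float(np.sqrt(np.mean((P @ w - y) ** 2)))

    seeds = np.vstack([np.eye(m), np.full((1, m), 1.0 / m)])
    result = optimize(objective, eefo, seed_positions=seeds)
    return WeightVector(tuple(float(w) for w in _normalize_simplex(result.best_position)))


def weighted_predict(weights: WeightVector, predictions) -> np.ndarray:
    """Fuse per-record member predictions: ŷ = Σ_m w_m ŷ_m."""
    P = np.atleast_2d(np.asarray(predictions, dtype=float))
    w = weights.as_array()
    if P.shape[-1] != w.size:
        raise ValueError(f"prediction rows have {P.shape[-1]} models, weights have {w.size}")
    return P @ w


# ---------------------------------------------------------------------------
# Dempster-Shafer frame and mass functions


@dataclass(frozen=True)
class Frame:
    """Discretization of the solubility axis: K bins given by K+1 edges."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 3:
            raise ValueError("a frame needs at least 2 bins (3 edges)")
        if np.any(np.diff(e) <= 0):
            raise ValueError("frame edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    @classmethod
    def from_targets(cls, y, n_bins: int = 20, padding: float = 0.05) -> "Frame":
        """K equal bins spanning [min(y) − pad·range, max(y) + pad·range]."""
        y = np.asarray(y, dtype=float)
        lo, hi = float(y.min()), float(y.max())
        span = hi - lo
        if span <= 0:
            span = max(abs(hi), 1.0)  # degenerate targets: symmetric unit-ish frame
        lo -= padding * span
        hi += padding * span
        return cls(tuple(np.linspace(lo, hi, n_bins + 1)))


@dataclass(frozen=True)
class MassFunction:
    """Mass over singleton bins plus the ignorance set Θ; sums to one."""

    frame: Frame
    singleton_masses: tuple[float, ...]
    ignorance_mass: float
    truncated: bool = False  # evidence extended past the frame and was clipped
    conflict: float = 0.0  # K of the combination that produced this mass

    def __post_init__(self) -> None:
        m = np.asarray(self.singleton_masses, dtype=float)
        if m.size != self.frame.n_bins:
            raise ValueError("one singleton mass per frame bin required")
        if np.any(m < -1e-15) or self.ignorance_mass < -1e-15:
            raise ValueError("masses must be non-negative")
        total = m.sum() + self.ignorance_mass
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"masses must sum to 1, got {total!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.singleton_masses, dtype=float)


def vacuous_mass(frame: Frame) -> MassFunction:
    """Total ignorance: all mass on Θ."""
    return MassFunction(frame=frame, singleton_masses=(0.0,) * frame.n_bins, ignorance_mass=1.0)


# ---------------------------------------------------------------------------
# Reliability discounting


@dataclass(frozen=True)
class Reliability:
    """Per-learner trust r ∈ [0, 0.999], derived from validation RMSE."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        for r in self.values:
            if not 0 <= r < 1:
                raise ValueError(f"reliability must lie in [0, 1), got {r}")


_RELIABILITY_CAP = 0.999


def reliability_from_rmse(validation_rmse, y_scale: float) -> Reliability:
    """r_m = 1 / (1 + rmse_m / σ_y), capped at 0.999 to preserve ignorance.

    Dimensionless and monotone: a learner whose validation RMSE equals the
    target spread gets r = 0.5; a perfect learner is capped so its mass
    function always keeps a sliver of ignorance.
    """
    if y_scale <= 0:
        raise ValueError("y_scale must be > 0")
    rmse_arr = np.atleast_1d(np.asarray(validation_rmse, dtype=float))
    if np.any(rmse_arr < 0):
        raise ValueError("validation RMSE must be >= 0")
    r = 1.0 / (1.0 + rmse_arr / y_scale)
    return Reliability(tuple(np.minimum(r, _RELIABILITY_CAP)))


# ---------------------------------------------------------------------------
# Mass construction, combination, queries


def build_mass_function(prediction: float, bandwidth: float, reliability: float, frame: Frame) -> MassFunction:
    """Reliability-discounted discretized Gaussian evidence for one model.

    Singleton masses are r times the Gaussian(prediction, bandwidth²) bin
    probabilities renormalized over the frame; m(Θ) = 1 − r.  Evidence
    extending beyond the frame by more than 4 bandwidths is flagged as
    truncated (renormalization still makes the mass proper).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if not 0 <= reliability < 1:
        raise ValueError("reliability must lie in [0, 1)")
    edges = np.asarray(frame.edges, dtype=float)
    cdf = scipy.stats.norm.cdf(edges, loc=prediction, scale=bandwidth)
    bin_probs = np.diff(cdf)
    total = bin_probs.sum()
    truncated = (prediction - 4 * bandwidth < edges[0]) or (prediction + 4 * bandwidth > edges[-1])
    if total <= 0:
        # prediction so far outside the frame that float cdf underflows:
        # put the evidence on the nearest edge bin
        bin_probs = np.zeros(frame.n_bins)
        bin_probs[0 if prediction < edges[0] else -1] = 1.0
        total = 1.0
        truncated = True
    singles = reliability * bin_probs / total
    return MassFunction(
        frame=frame,
        singleton_masses=tuple(float(s) for s in singles),
        ignorance_mass=1.0 - float(singles.sum()),
        truncated=truncated,
    )


def dempster_combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's conflict-renormalized conjunctive combination.

    For the singleton+Θ family the rule closes on itself:

        K        = Σ_{i≠j} m1(b_i) m2(b_j)
        m(b_k)   = [m1(b_k) m2(b_k) + m1(b_k) m2(Θ) + m1(Θ) m2(b_k)] / (1−K)
        m(Θ)     = m1(Θ) m2(Θ) / (1−K)

    Raises :class:`TotalConflictError` when K ≈ 1.
    """
    if m1.frame != m2.frame:
        raise ValueError("mass functions must share the same frame")
    a, b = m1.as_array(), m2.as_array()
    agree = float(a @ b)
    conflict = float(a.sum() * b.sum()) - agree
    if conflict >= 1.0 - 1e-12:
        raise TotalConflictError(f"total conflict between sources (K = {conflict})")
    norm = 1.0 - conflict
    singles = (a * b + a * m2.ignorance_mass + b * m1.ignorance_mass) / norm
    theta = m1.ignorance_mass * m2.ignorance_mass / norm
    # nudge away float drift so the invariant Σm = 1 holds to 1e-12
    total = singles.sum() + theta
    singles /= total
    theta /= total
    return MassFunction(
        frame=m1.frame,
        singleton_masses=tuple(singles),
        ignorance_mass=float(theta),
        truncated=m1.truncated or m2.truncated,
        conflict=conflict,
    )


def bel_pl(mass: MassFunction, interval: tuple[float, float]) -> tuple[float, float]:
    """Belief and plausibility of the hypothesis y ∈ [a, b].

    Belief sums masses of bins fully inside the interval; plausibility sums
    masses of bins intersecting it, plus m(Θ) whenever the interval touches
    the frame at all.  Always Bel ≤ Pl.
    """
    a, b = interval
    if a > b:
        raise ValueError("interval must satisfy a <= b")
    edges = np.asarray(mass.frame.edges)
    lo, hi = edges[:-1], edges[1:]
    inside = (lo >= a) & (hi <= b)
    intersects = (lo <= b) & (hi >= a)
    m = mass.as_array()
    bel = float(m[inside].sum())
    if a <= edges[0] and b >= edges[-1]:  # Θ itself lies inside the interval
        bel += mass.ignorance_mass
    pl = float(m[intersects].sum())
    if intersects.any():
        pl += mass.ignorance_mass
    return min(bel, 1.0), min(pl, 1.0)


def pignistic_predict(mass: MassFunction) -> float:
    """Point estimate by the pignistic transform.

    Ignorance is split uniformly over the bins — BetP(b_k) = m(b_k) + m(Θ)/K
    — and the estimate is the BetP-weighted mean of bin centers.
    """
    k = mass.frame.n_bins
    betp = mass.as_array() + mass.ignorance_mass / k
    return float(betp @ mass.frame.centers)


# ---------------------------------------------------------------------------
# DST ensemble prediction


@dataclass(frozen=True)
class FusedPrediction:
    """Fused point estimate with its combined mass for Bel/Pl queries."""

    estimate: float
    conflict: float
    mass: MassFunction

    def bel_pl(self, interval: tuple[float, float]) -> tuple[float, float]:
        return bel_pl(self.mass, interval)


def dst_predict(
    predictions,
    reliabilities: Reliability,
    bandwidths: Sequence[float],
    frame: Frame,
) -> list[FusedPrediction]:
    """Fuse per-record member predictions by Dempster's rule.

    ``predictions`` is n × M (one column per model).  Each model's evidence
    for a record is its discounted discretized Gaussian; masses are folded
    left-to-right and the point value extracted pignistically.  The
    reported conflict is the total conflict accumulated across the folds,
    1 − Π(1 − K_step).
    """
    P = np.atleast_2d(np.asarray(predictions, dtype=float))
    n, m = P.shape
    if m < 2:
        raise ValueError("need at least 2 models to fuse")
    if len(reliabilities.values) != m or len(bandwidths) != m:
        raise ValueError("reliabilities and bandwidths must have one entry per model")
    fused: list[FusedPrediction] = []
    for i in range(n):
        combined = vacuous_mass(frame)
        kept = 1.0
        for j in range(m):
            evidence = build_mass_function(float(P[i, j]), float(bandwidths[j]), reliabilities.values[j], frame)
            try:
                combined = dempster_combine(combined, evidence)
            except TotalConflictError as err:
                raise TotalConflictError(f"record {i}: {err}") from None
            kept *= 1.0 - combined.conflict
        fused.append(
            FusedPrediction(estimate=pignistic_predict(combined), conflict=1.0 - kept, mass=combined)
        )
    return fused
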