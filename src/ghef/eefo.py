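"""Electric Eel Foraging Optimization for bound-constrained minimization.

EEFO is a population metaheuristic modeled on the social foraging of
electric eels.  Each iteration every eel draws an energy factor

    E = 4 · u · (1 − t / T_max),     u ~ U(0, 1)

which schedules the regime: E > 1 triggers an exploratory *interacting*
move toward (or beyond) a random peer, while E ≤ 1 picks one of three
exploitation behaviors — *resting* (a local perturbation whose radius
shrinks linearly with t), *hunting* (a pull toward the population best)
or *migrating* (a drift along the best-minus-peer direction) — with equal
probability.  A candidate replaces its eel only if strictly better
(greedy selection; ties keep the incumbent), so the best-fitness
trajectory is monotone non-increasing by construction.

The package uses this optimizer for two jobs: tuning base-learner
hyperparameters against cross-validated RMSE and fitting ensemble
fusion weights on the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

Objective = Callable[[np.ndarray], float]

# local-perturbation radius as a fraction of the box extent at t = 0
_RESTING_SCALE = 0.1


@dataclass(frozen=True)
class EEFOConfig:
    bounds: tuple[tuple[float, float], ...]
    population_size: int = 30
    max_iterations: int = 200
    patience: int = 20
    improvement_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1 or self.patience < 1:
            raise ValueError("max_iterations and patience must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound [{lo}, {hi}]")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    @property
    def lows(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def highs(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


@dataclass
class EEFOState:
    """Mutable population snapshot during a run."""

    positions: np.ndarray  # population × dim
    fitnesses: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    iteration: int
    config: EEFOConfig


@dataclass(frozen=True)
class EEFOResult:
    best_position: np.ndarray
    best_fitness: float
    trajectory: np.ndarray  # per-iteration best fitness, non-increasing
    iterations_run: int
    converged_early: bool


def energy_factor(t: int, config: EEFOConfig, draw: float) -> float:
    """E = 4·draw·(1 − t/T_max); E > 1 means exploration, E ≤ 1 exploitation."""
    return 4.0 * draw * (1.0 - t / config.max_iterations)


def _resting_radius(t: int, config: EEFOConfig) -> np.ndarray:
    return _RESTING_SCALE * (1.0 - t / config.max_iterations) * (config.highs - config.lows)


def propose_candidate(state: EEFOState, i: int, E: float, rng: np.random.Generator) -> np.ndarray:
    """One movement proposal for eel ``i``, clipped into the box bounds."""
    cfg = state.config
    x = state.positions[i]
    lows, highs = cfg.lows, cfg.highs
    radius = _resting_radius(state.iteration, cfg)
    if E > 1.0:
        # interacting: leap toward/beyond a partner — a random peer or a
        # fresh random point, half-and-half, keeping exploration global
        if rng.random() < 0.5:
            j = rng.integers(cfg.population_size - 1)
            partner = state.positions[j if j < i else j + 1]
        else:
            partner = rng.uniform(lows, highs)
        v = partner + rng.normal() * (partner - x)
    else:
        move = rng.integers(3)
        if move == 0:  # resting: local search in a shrinking ball
            v = x + rng.uniform(-1.0, 1.0, cfg.dim) * radius
        elif move == 1:  # hunting: pull toward the prey (population best)
            v = state.best_position + rng.random() * (state.best_position - x)
            v = v + rng.uniform(-1.0, 1.0, cfg.dim) * radius
        else:  # migrating: drift along the best-minus-peer direction
            j = rng.integers(cfg.population_size - 1)
            peer = state.positions[j if j < i else j + 1]
            v = x + rng.random() * (state.best_position - peer)
    return np.clip(v, lows, highs)


def _safe_fitness(objective: Objective, x: np.ndarray) -> float:
    value = float(objective(x))
    return value if np.isfinite(value) else np.inf


def greedy_select(x: np.ndarray, v: np.ndarray, objective: Objective) -> np.ndarray:
    """Keep the incumbent unless the candidate is strictly better."""
    return x if _safe_fitness(objective, x) <= _safe_fitness(objective, v) else v


def optimize(
    objective: Objective,
    config: EEFOConfig,
    seed_positions: Sequence[Sequence[float]] | None = None,
) -> EEFOResult:
    """Minimize ``objective`` over the box in ``config.bounds``.

    ``seed_positions`` are injected into the initial population (replacing
    its first rows), which turns "never worse than this known candidate"
    guarantees into theorems — the tuner seeds the space midpoint, the
    weight fitter seeds the unit vectors.  Stops early once the best
    fitness fails to improve by more than ``improvement_tol`` for
    ``patience`` consecutive iterations.  Fully deterministic given
    (objective, config, seed).
    """
    rng = np.random.default_rng(config.seed)
    lows, highs = config.lows, config.highs
    positions = rng.uniform(lows, highs, size=(config.population_size, config.dim))
    if seed_positions is not None:
        seeds = np.clip(np.asarray(seed_positions, dtype=float), lows, highs)
        if seeds.ndim != 2 or seeds.shape[1] != config.dim:
            raise ValueError("seed_positions must be a sequence of dim-length vectors")
        k = min(len(seeds), config.population_size)
        positions[:k] = seeds[:k]
    fitnesses = np.array([_safe_fitness(objective, p) for p in positions])
    best_i = int(np.argmin(fitnesses))
    state = EEFOState(
        positions=positions,
        fitnesses=fitnesses,
        best_position=positions[best_i].copy(),
        best_fitness=float(fitnesses[best_i]),
        iteration=0,
        config=config,
    )
    trajectory: list[float] = []
    stall = 0
    converged_early = False
    for t in range(config.max_iterations):
        state.iteration = t
        previous_best = state.best_fitness
        for i in range(config.population_size):
            E = energy_factor(t, config, rng.random())
            v = propose_candidate(state, i, E, rng)
            fv = _safe_fitness(objective, v)
            if fv < state.fitnesses[i]:  # greedy selection, ties keep incumbent
                state.positions[i] = v
                state.fitnesses[i] = fv
                if fv < state.best_fitness:
                    state.best_fitness = fv
                    state.best_position = v.copy()
        trajectory.append(state.best_fitness)
        if previous_best - state.best_fitness > config.improvement_tol:
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                converged_early = True
                break
    return EEFOResult(
        best_position=state.best_position,
        best_fitness=state.best_fitness,
        trajectory=np.array(trajectory),
        iterations_run=len(trajectory),
        converged_early=converged_early,
    )


# ---------------------------------------------------------------------------
# Hyperparameter tuning


def tune_learner(
    kind,
    train,
    k: int = 5,
    eefo: EEFOConfig | None = None,
    seed: int = 0,
    full_output: bool = False,
):
    """Tune a base learner's hyperparameters by EEFO against k-fold CV RMSE.

    The objective decodes a position in [0,1]^3 onto the learner's default
    space and scores it by mean validation RMSE over folds that are fixed
    once per tuning run.  The space midpoint is seeded into the initial
    population, so the tuned configuration is never worse (on those folds)
    than the midpoint configuration.  Returns the best configuration refit
    on all of ``train``.
    """
    from ghef.learners import LearnerKind, decode_position, default_space, train_learner, predict_learner
    from ghef.evalstats import kfold_indices, rmse

    kind = LearnerKind(kind)
    space = default_space(kind)
    if eefo is None:
        eefo = EEFOConfig(bounds=((0.0, 1.0),) * 3, seed=seed)
    elif len(eefo.bounds) != 3:
        raise ValueError("eefo.bounds must be 3-dimensional for hyperparameter tuning")
    folds = kfold_indices(len(train), k, seed)
    fold_data = []
    y_all = train.targets()
    for fold in range(k):
        val_idx = np.flatnonzero(folds.labels == fold)
        tr_idx = np.flatnonzero(folds.labels != fold)
        fold_data.append((train.subset(tr_idx), train.subset(val_idx), y_all[val_idx]))

    def objective(position: np.ndarray) -> float:
        config = decode_position(space, position, kind, seed=seed)
        errors = []
        for tr, val, y_val in fold_data:
            model = train_learner(config, tr)
            errors.append(rmse(y_val, predict_learner(model, val)))
        return float(np.mean(errors))

    result = optimize(objective, eefo, seed_positions=[[0.5, 0.5, 0.5]])
    best_config = decode_position(space, result.best_position, kind, seed=seed)
    model = train_learner(best_config, train)
    if full_output:
        return best_config, model, result
    return best_config, model
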