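"""Synthetic solubility datasets with the structure of the experimental design.

The generator emulates the published study design: four lipophilic drugs
measured on factorial temperature-pressure grids inside the supercritical
CO2 region (308-338 K, 12-30 MPa; Sirolimus on a narrower 19-point
design), with per-compound solubility ranges used as calibration anchors.
The noiseless surface is a Chrastil-style log-linear model

    ln y = a · ln(rho(T, P)) + b / T + c

where ``rho`` is a smooth analytic density proxy (monotone increasing in
pressure, decreasing in temperature).  Measurement error is multiplicative
lognormal so solubilities spanning two orders of magnitude stay positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ghef.dataio import Dataset, SolubilityRecord

# CO2 critical point, used only to place the proxy's logistic rise.
_T_CRIT_K = 304.1
_P_CRIT_MPA = 7.38


@dataclass(frozen=True)
class CompoundSpec:
    """Design grid and solubility anchors for one compound."""

    name: str
    molecular_weight: float
    melting_point: float
    temperature_levels: tuple[float, ...]
    pressure_levels: tuple[float, ...]
    target_min: float
    target_max: float
    # explicit (T, P) design cells; None means the full factorial grid
    cells: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        for levels, label in ((self.temperature_levels, "temperature"), (self.pressure_levels, "pressure")):
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise ValueError(f"{label} levels must be strictly increasing")
        if not 0 < self.target_min < self.target_max:
            raise ValueError("require 0 < target_min < target_max")

    def design_cells(self) -> tuple[tuple[float, float], ...]:
        if self.cells is not None:
            return self.cells
        return tuple((t, p) for t in self.temperature_levels for p in self.pressure_levels)


@dataclass(frozen=True)
class SurfaceCoefficients:
    """(a, b, c) of the log-linear surface for one compound; a > 0."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class GeneratorConfig:
    compounds: tuple[CompoundSpec, ...]
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def density_proxy(temperature: float, pressure: float) -> float:
    """Dimensionless CO2 density surrogate.

    A logistic rise in pressure centered near the critical pressure,
    scaled by the inverse reduced temperature: strictly increasing in P,
    strictly decreasing in T, positive everywhere.  It stands in for a
    real equation of state — only sign and monotonicity matter here.
    """
    temperature = float(temperature)
    pressure = float(pressure)
    if temperature <= 0 or pressure <= 0:
        raise ValueError("temperature and pressure must be > 0")
    rise = 1.0 / (1.0 + math.exp(-(pressure - _P_CRIT_MPA) / 5.0))
    return (_T_CRIT_K / temperature) * rise


def calibrate_surface(spec: CompoundSpec) -> SurfaceCoefficients:
    """Solve (a, b, c) so the noiseless surface hits the compound's anchors.

    The min-solubility anchor sits at (min T, min P) and the max anchor at
    (max T, max P).  The density exponent ``a`` is fixed first from the
    pressure-range log-ratio at the anchor temperature (so the pressure
    span alone accounts for the solubility span); ``b`` and ``c`` then
    follow from the two anchor equations as an exact 2×2 linear solve.
    """
    cells = spec.design_cells()
    if len(cells) < 2:
        raise ValueError(f"{spec.name}: degenerate design (need >= 2 grid points)")
    t_lo, t_hi = min(spec.temperature_levels), max(spec.temperature_levels)
    p_lo, p_hi = min(spec.pressure_levels), max(spec.pressure_levels)
    log_ratio = math.log(spec.target_max / spec.target_min)
    proxy_ratio = math.log(density_proxy(t_lo, p_hi) / density_proxy(t_lo, p_lo))
    a = max(log_ratio / proxy_ratio, 0.0)
    # anchor system:  ln y_min = a ln rho(t_lo, p_lo) + b/t_lo + c
    #                 ln y_max = a ln rho(t_hi, p_hi) + b/t_hi + c
    lhs = np.array([[1.0 / t_lo, 1.0], [1.0 / t_hi, 1.0]])
    rhs = np.array(
        [
            math.log(spec.target_min) - a * math.log(density_proxy(t_lo, p_lo)),
            math.log(spec.target_max) - a * math.log(density_proxy(t_hi, p_hi)),
        ]
    )
    b, c = np.linalg.solve(lhs, rhs)
    return SurfaceCoefficients(a=a, b=float(b), c=float(c))


def true_solubility_surface(
    coeffs: SurfaceCoefficients, temperature: float, pressure: float
) -> float:
    """Noiseless solubility (g/L × 10) at one (T, P) state point."""
    log_y = coeffs.a * math.log(density_proxy(temperature, pressure)) + coeffs.b / temperature + coeffs.c
    return math.exp(log_y)


# ---------------------------------------------------------------------------
# Default study design

# Sirolimus: the published design summary implies a 19-point non-factorial
# layout over {313,318,323,328} K × {12.5,...,25} MPa whose exact cells are
# not printed; this fixed subset (full 24-cell grid minus five corners-adjacent
# cells) is the package's documented stand-in.
_SIROLIMUS_T = (313.0, 318.0, 323.0, 328.0)
_SIROLIMUS_P = (12.5, 15.0, 17.5, 20.0, 22.5, 25.0)
_SIROLIMUS_DROPPED = {(313.0, 22.5), (318.0, 12.5), (323.0, 25.0), (328.0, 12.5), (318.0, 25.0)}
_SIROLIMUS_CELLS = tuple(
    (t, p) for t in _SIROLIMUS_T for p in _SIROLIMUS_P if (t, p) not in _SIROLIMUS_DROPPED
)

_MAIN_T = (308.0, 318.0, 328.0, 338.0)
_MAIN_P = (12.0, 15.0, 18.0, 21.0, 24.0, 27.0, 30.0)

DEFAULT_COMPOUNDS: tuple[CompoundSpec, ...] = (
    CompoundSpec("Tacrolimus", 804.03, 128.0, _MAIN_T, _MAIN_P, 0.029, 0.235),
    CompoundSpec("Rifampin", 822.95, 185.0, _MAIN_T, _MAIN_P, 0.109, 2.983),
    CompoundSpec("Teriflunomide", 270.21, 230.0, _MAIN_T, _MAIN_P, 0.127, 3.212),
    CompoundSpec(
        "Sirolimus", 914.172, 183.0, _SIROLIMUS_T, _SIROLIMUS_P, 0.2122, 0.4567, cells=_SIROLIMUS_CELLS
    ),
)


def default_generator_config(noise_cv: float = 0.05, seed: int = 0) -> GeneratorConfig:
    """The standard 103-record fixture design (3 × 28 factorial + 19 cells)."""
    return GeneratorConfig(compounds=DEFAULT_COMPOUNDS, noise_cv=noise_cv, seed=seed)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate one record per design cell with lognormal multiplicative noise.

    solubility = surface(T, P) · exp(eps), eps ~ N(0, sigma²),
    sigma = ln(1 + noise_cv); noiseless when noise_cv = 0.  Each compound
    draws from its own RNG stream derived from (seed, compound index), so
    appending compounds never perturbs earlier ones.
    """
    records: list[SolubilityRecord] = []
    sigma = math.log1p(config.noise_cv)
    for idx, spec in enumerate(config.compounds):
        coeffs = calibrate_surface(spec)
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), idx]))
        for t, p in spec.design_cells():
            y = true_solubility_surface(coeffs, t, p)
            if sigma > 0:
                y *= math.exp(rng.normal(0.0, sigma))
            records.append(
                SolubilityRecord(
                    temperature=t,
                    pressure=p,
                    molecular_weight=spec.molecular_weight,
                    melting_point=spec.melting_point,
                    solubility=y,
                    compound=spec.name,
                )
            )
    return Dataset(tuple(records), provenance=f"synthetic(seed={config.seed}, noise_cv={config.noise_cv})")
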