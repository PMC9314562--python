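"""Synthetic inputs with the statistical structure the assessment assumes.

The real study inputs — a national energy-transition scenario's mileage
trajectories, a travel-survey age distribution of walking/cycling, and
official demographic projections — are external datasets.  This module
generates stand-ins with the same structure so the full pipeline runs and is
tested offline:

* demography from a Gompertz–Makeham hazard with a secular improvement
  factor, evolved forward from a smooth base-year pyramid under constant
  births;
* national weekly per-capita mileage trajectories that pass exactly through
  a set of anchor years (monotone piecewise-cubic between anchors);
* smooth age distributions of mileage — hump-shaped for cycling, flatter
  for walking;
* a value-of-statistical-life-year (VSLY) series growing geometrically.

All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .engine import residual_life_expectancy

__all__ = [
    "PyramidShape",
    "DemographyParams",
    "MileageAnchors",
    "AgeShape",
    "gen_demography",
    "gen_mileage",
    "gen_age_distribution",
    "gen_vsly",
    "DEFAULT_ANCHORS",
    "DEFAULT_CYCLE_SHAPE",
    "DEFAULT_WALK_SHAPE",
]


@dataclass(frozen=True)
class PyramidShape:
    """Smooth base-year population-by-age curve.

    The pyramid is the stationary population implied by base-year mortality
    (constant births), modulated by a Gaussian bulge (a cohort surplus around
    ``bulge_age``) and a small seeded lognormal jitter so that distinct seeds
    give distinct, equally plausible pyramids.
    """

    bulge_age: float = 45.0
    bulge_width: float = 22.0
    bulge_amplitude: float = 0.25
    jitter_sd: float = 0.01


@dataclass(frozen=True)
class DemographyParams:
    base_year: int = 2021
    horizon_year: int = 2050
    a_max: int = 110
    makeham_c: float = 2.0e-4       # background hazard, year^-1
    gompertz_b: float = 2.7e-5      # hazard scale at age 0, year^-1
    gompertz_theta: float = 0.095   # hazard slope, age^-1
    annual_improvement: float = 0.01
    pyramid_shape: PyramidShape = field(default_factory=PyramidShape)
    total_population: float = 65.0e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon_year <= self.base_year:
            raise ValueError("horizon_year must exceed base_year")
        if self.a_max < 100:
            raise ValueError("a_max must be at least 100")
        if self.makeham_c < 0 or self.gompertz_b <= 0 or self.gompertz_theta <= 0:
            raise ValueError("hazard parameters must be positive (makeham_c >= 0)")
        if not 0.0 <= self.annual_improvement < 1.0:
            raise ValueError("annual_improvement must lie in [0, 1)")
        if self.total_population <= 0:
            raise ValueError("total_population must be positive")


def _hazard_matrix(p: DemographyParams) -> np.ndarray:
    """m[a, y] for ages 0..a_max and years base..horizon."""
    ages = np.arange(p.a_max + 1)
    years = np.arange(p.base_year, p.horizon_year + 1)
    m_age = p.makeham_c + p.gompertz_b * np.exp(p.gompertz_theta * ages)
    decline = (1.0 - p.annual_improvement) ** (years - p.base_year)
    return m_age[:, None] * decline[None, :]


def gen_demography(params: DemographyParams) -> pd.DataFrame:
    """Generate a (year, age) demography table.

    Returns columns ``year, age, population, mortality_q, residual_le``.
    Mortality is generated as a hazard and converted to an annual probability
    via ``q = 1 - exp(-m)``, which keeps q in (0, 1) by construction; the
    population evolves by ageing and survival from the base pyramid with a
    constant annual birth cohort; residual life expectancy is computed from
    the same probabilities via the period life table.
    """
    p = params
    m = _hazard_matrix(p)
    q = 1.0 - np.exp(-m)
    if np.any(q >= 1.0):
        raise ValueError("mortality parameters too aggressive: q >= 1 reached")

    ages = np.arange(p.a_max + 1)
    years = np.arange(p.base_year, p.horizon_year + 1)
    n_ages, n_years = len(ages), len(years)

    # base pyramid: stationary survival x bulge x jitter, scaled to the total
    survival = np.concatenate([[1.0], np.cumprod(1.0 - q[:-1, 0])])
    shape = p.pyramid_shape
    bulge = 1.0 + shape.bulge_amplitude * np.exp(
        -0.5 * ((ages - shape.bulge_age) / shape.bulge_width) ** 2
    )
    rng = np.random.default_rng(p.seed)
    jitter = np.exp(rng.normal(0.0, shape.jitter_sd, size=n_ages)) if shape.jitter_sd > 0 else 1.0
    weights = survival * bulge * jitter
    pop = np.empty((n_ages, n_years))
    pop[:, 0] = p.total_population * weights / weights.sum()

    births = pop[0, 0]  # constant annual birth cohort
    for j in range(1, n_years):
        pop[1:, j] = pop[:-1, j - 1] * (1.0 - q[:-1, j - 1])
        pop[0, j] = births

    le = np.column_stack([residual_life_expectancy(q[:, j]) for j in range(n_years)])

    yy, aa = np.meshgrid(years, ages, indexing="ij")
    return pd.DataFrame({
        "year": yy.ravel(),
        "age": aa.ravel(),
        "population": pop.T.ravel(),
        "mortality_q": q.T.ravel(),
        "residual_le": le.T.ravel(),
    })


@dataclass(frozen=True)
class MileageAnchors:
    """Anchor points (year, value) for each national trajectory."""

    walk: tuple[tuple[int, float], ...]
    cycle: tuple[tuple[int, float], ...]
    ebike_share: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        for name, pts in (("walk", self.walk), ("cycle", self.cycle),
                          ("ebike_share", self.ebike_share)):
            yrs = [y for y, _ in pts]
            if len(set(yrs)) != len(yrs):
                raise ValueError(f"duplicate anchor years in {name}")
            if yrs != sorted(yrs):
                raise ValueError(f"anchor years must be increasing in {name}")
            if any(v < 0 for _, v in pts):
                raise ValueError(f"negative anchor value in {name}")
        if any(not 0.0 <= v <= 1.0 for _, v in self.ebike_share):
            raise ValueError("ebike_share anchors must lie in [0, 1]")


#: Modal-shift scenario anchors: cycling rises from 2.4 km/inh/week (2021) to
#: 17.1 (2040), peaks at 17.5 (2045) and returns to 17.1 (2050); walking grows
#: +11% over the horizon; the e-bike share of cycled km rises from 3.3% to 70%
#: by 2040 and stays constant thereafter.
DEFAULT_ANCHORS = MileageAnchors(
    walk=((2021, 6.0), (2050, 6.66)),
    cycle=((2021, 2.4), (2040, 17.1), (2045, 17.5), (2050, 17.1)),
    ebike_share=((2021, 0.033), (2040, 0.70), (2050, 0.70)),
)


def _interp_series(pts, years: np.ndarray, interpolation: str) -> np.ndarray:
    x = np.array([y for y, _ in pts], dtype=float)
    v = np.array([val for _, val in pts], dtype=float)
    if years.min() > x.min() or years.max() < x.max():
        raise ValueError("anchor years fall outside the [base_year, horizon_year] range")
    if len(x) == 1:
        return np.full(len(years), v[0])
    if interpolation == "linear":
        return np.interp(years, x, v)
    if interpolation == "pchip":
        # monotone cubic between anchors, constant beyond the outermost ones
        f = PchipInterpolator(x, v, extrapolate=False)
        out = f(np.clip(years, x.min(), x.max()))
        return np.asarray(out, dtype=float)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def gen_mileage(
    anchors: MileageAnchors,
    base_year: int,
    horizon_year: int,
    interpolation: str = "pchip",
) -> pd.DataFrame:
    """Per-year national trajectory passing exactly through every anchor.

    Returns columns ``year, walk_km_pc, cycle_km_pc, ebike_share`` (weekly km
    per inhabitant; share of cycled km by e-bike).  With monotone
    interpolation, values between anchors stay bounded by the neighbouring
    anchor values (no overshoot of the scenario's inverse-U shapes).
    """
    years = np.arange(base_year, horizon_year + 1)
    return pd.DataFrame({
        "year": years,
        "walk_km_pc": _interp_series(anchors.walk, years, interpolation),
        "cycle_km_pc": _interp_series(anchors.cycle, years, interpolation),
        "ebike_share": np.clip(_interp_series(anchors.ebike_share, years, interpolation), 0.0, 1.0),
    })


@dataclass(frozen=True)
class AgeShape:
    """Smooth age-distribution shape: a Gaussian hump on a uniform floor."""

    peak_age: float
    spread: float
    floor: float
    peak_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.spread <= 0 or self.peak_age < 0:
            raise ValueError("peak_age and spread must be positive")
        if self.floor < 0 or self.peak_weight < 0:
            raise ValueError("floor and peak_weight must be non-negative")


DEFAULT_CYCLE_SHAPE = AgeShape(peak_age=25.0, spread=16.0, floor=0.35)
DEFAULT_WALK_SHAPE = AgeShape(peak_age=45.0, spread=35.0, floor=0.80)


def gen_age_distribution(mode: str, shape: AgeShape, a_max: int = 110) -> pd.DataFrame:
    """Normalized shares d(a) of national mileage by 1-year age for one mode.

    Cycling-like shapes are unimodal with the mode at ``peak_age``; a pure
    floor (``peak_weight = 0``) yields the uniform distribution.
    """
    ages = np.arange(a_max + 1)
    w = shape.floor + shape.peak_weight * np.exp(-0.5 * ((ages - shape.peak_age) / shape.spread) ** 2)
    total = w.sum()
    if total <= 0:
        raise ValueError("age-distribution weights are all zero; cannot normalize")
    return pd.DataFrame({"mode": mode, "age": ages, "share": w / total})


def gen_vsly(
    base_value: float,
    base_year: int,
    growth_rate: float,
    start_year: int,
    horizon_year: int,
) -> pd.DataFrame:
    """VSLY series: ``vsly(y) = base_value * (1 + growth_rate)**(y - base_year)``."""
    if base_value <= 0:
        raise ValueError("base_value must be positive")
    years = np.arange(start_year, horizon_year + 1)
    return pd.DataFrame({
        "year": years,
        "vsly_eur": base_value * (1.0 + growth_rate) ** (years - base_year),
    })
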