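"""Core health-impact arithmetic: period life tables, deaths and YLL averted.

The attribution follows the HEAT-style comparative-risk logic: an age- and
year-specific relative risk ``rr`` from active-travel exposure is applied to
projected baseline mortality, so that at each (year, age)

    deaths_prevented = population * q * (1 - rr)

with ``q`` the annual probability of death.  Years of life lost (YLL) weight
each prevented death by residual life expectancy at that age.  Life
expectancy gains compare period life tables built from ``q`` scaled by the
combined relative risk of each scenario.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "build_life_table",
    "residual_life_expectancy",
    "deaths_prevented",
    "yll_prevented",
    "scenario_delta",
    "life_expectancy_gain",
]

IMPACT_KEYS = ["year", "age", "mode"]


def build_life_table(q_by_age, a_fraction: float = 0.5) -> pd.DataFrame:
    """Build a period life table from annual death probabilities.

    Parameters
    ----------
    q_by_age
        Annual death probabilities for integer ages ``0..closure_age``.  The
        final entry is the closure age and is treated as ``q = 1`` (everyone
        alive there dies within the interval).
    a_fraction
        Average fraction of the year lived by those dying in the interval
        (Chiang's a; 0.5 assumes deaths at mid-interval).

    Returns
    -------
    DataFrame with columns ``age, q, l, L, e`` where ``l`` are survivors from
    a unit radix, ``L`` person-years lived in the interval and ``e`` residual
    life expectancy.
    """
    q = np.asarray(q_by_age, dtype=float).copy()
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q_by_age must be a non-empty 1-D array")
    if np.any(~np.isfinite(q)) or np.any(q < 0) or np.any(q > 1):
        raise ValueError("death probabilities must lie in [0, 1]")
    if not 0.0 <= a_fraction <= 1.0:
        raise ValueError("a_fraction must lie in [0, 1]")
    q[-1] = 1.0

    n = q.size
    l = np.empty(n + 1)
    l[0] = 1.0
    np.cumprod(1.0 - q, out=l[1:])
    L = l[1:] + a_fraction * (l[:-1] - l[1:])
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l[:-1] > 0, T / l[:-1], 0.0)
    return pd.DataFrame({"age": np.arange(n), "q": q, "l": l[:-1], "L": L, "e": e})


def residual_life_expectancy(q_by_age, a_fraction: float = 0.5) -> np.ndarray:
    """Residual life expectancy e(a) for every age, from :func:`build_life_table`."""
    return build_life_table(q_by_age, a_fraction)["e"].to_numpy()


def deaths_prevented(
    demo: pd.DataFrame,
    rr: pd.DataFrame,
    age_window: tuple[int, int] = (20, 84),
) -> pd.DataFrame:
    """Deaths averted per (year, age, mode).

    ``demo`` carries ``year, age, population, mortality_q``; ``rr`` carries
    ``year, age, mode, rr`` (mode ``"all"`` rows hold the combined relative
    risk).  Ages outside the closed ``age_window`` contribute zero regardless
    of exposure.
    """
    merged = rr.merge(demo[["year", "age", "population", "mortality_q"]],
                      on=["year", "age"], how="left", validate="many_to_one")
    if merged["population"].isna().any():
        missing = merged.loc[merged["population"].isna(), ["year", "age"]].drop_duplicates()
        raise ValueError(f"demography missing for keys:\n{missing.head()}")
    lo, hi = age_window
    in_window = (merged["age"] >= lo) & (merged["age"] <= hi)
    prevented = merged["population"] * merged["mortality_q"] * (1.0 - merged["rr"])
    out = merged[IMPACT_KEYS].copy()
    out["deaths_prevented"] = np.where(in_window, prevented, 0.0)
    return out


def yll_prevented(impact: pd.DataFrame, demo: pd.DataFrame) -> pd.DataFrame:
    """Attach YLL averted: deaths averted times residual life expectancy."""
    if "residual_le" not in demo.columns:
        raise ValueError("demography table lacks a residual_le column")
    out = impact.merge(demo[["year", "age", "residual_le"]],
                       on=["year", "age"], how="left", validate="many_to_one")
    if out["residual_le"].isna().any():
        missing = out.loc[out["residual_le"].isna(), ["year", "age"]].drop_duplicates()
        raise ValueError(f"residual_le missing for keys:\n{missing.head()}")
    out["yll_prevented"] = out["deaths_prevented"] * out["residual_le"]
    return out.drop(columns="residual_le")


def scenario_delta(scenario_impact: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-key difference (modal-shift scenario minus frozen reference).

    Negative values are meaningful (e.g. classical-bike mileage falling below
    its base-year level late in the horizon) and are reported, not clipped.
    """
    measures = [c for c in ("deaths_prevented", "yll_prevented") if c in scenario_impact.columns]
    merged = scenario_impact.merge(reference, on=IMPACT_KEYS,
                                   suffixes=("_nw", "_ref"),
                                   how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", IMPACT_KEYS]
        raise ValueError(f"scenario impact tables have mismatched keys:\n{bad.head()}")
    out = merged[IMPACT_KEYS].copy()
    for m in measures:
        out[m] = merged[f"{m}_nw"] - merged[f"{m}_ref"]
    return out


def _rr_all_vector(rr: pd.DataFrame, year: int, ages: np.ndarray) -> np.ndarray:
    sub = rr[(rr["year"] == year) & (rr["mode"] == "all")]
    vec = pd.Series(1.0, index=ages, dtype=float)
    vec.update(sub.set_index("age")["rr"])
    return vec.to_numpy()


def life_expectancy_gain(
    demo: pd.DataFrame,
    rr_scenario: pd.DataFrame,
    rr_reference: pd.DataFrame,
    year: int,
    a_fraction: float = 0.5,
) -> float:
    """Gain in period life expectancy at birth for one calendar year, in months.

    Each scenario's life table uses ``q'(a) = min(q(a) * rr_all(a), 1)``;
    ages without an rr entry keep their baseline mortality.
    """
    sub = demo[demo["year"] == year].sort_values("age")
    if sub.empty:
        raise ValueError(f"year {year} not present in demography table")
    ages = sub["age"].to_numpy()
    q = sub["mortality_q"].to_numpy()
    e0 = []
    for rr in (rr_scenario, rr_reference):
        q_adj = np.clip(q * _rr_all_vector(rr, year, ages), 0.0, 1.0)
        e0.append(build_life_table(q_adj, a_fraction)["e"].iloc[0])
    return 12.0 * (e0[0] - e0[1])
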