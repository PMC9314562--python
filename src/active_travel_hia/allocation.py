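"""Allocate national mileage across ages and split cycling by bike type.

National weekly per-capita trajectories are distributed over 1-year ages by a
reference age distribution of mileage (per-capita mileage at age a is the
age's share of national kilometres divided by its population), then cycled
kilometres are attributed between classical bikes and e-bikes with an
age-increasing logistic share s(a) = expit(alpha + beta*a), solved each
calendar year so that

  (i)  the kilometre-weighted national e-bike share equals the scenario's
       share for that year, and
  (ii) the mean age of e-bike kilometres exceeds the mean age of classical
       kilometres by a fixed target gap (default 6.7 years).

The reference (business-as-usual) counterfactual freezes the base year's
national values while reusing the same age distribution and split machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "build_reference_scenario",
    "allocate_mileage",
    "split_ebike",
    "mean_age_of_mileage",
    "SplitSolution",
    "SolverError",
]


class SolverError(RuntimeError):
    """E-bike split solver failed to converge; message carries diagnostics."""


@dataclass(frozen=True)
class SplitSolution:
    """Per-year logistic split diagnostics."""

    year: int
    alpha: float
    beta: float
    achieved_share: float
    achieved_age_gap: float  # NaN when the gap is undefined (degenerate share)


def build_reference_scenario(traj: pd.DataFrame, base_year: int) -> pd.DataFrame:
    """Freeze every year of a trajectory at its base-year values."""
    row = traj.loc[traj["year"] == base_year]
    if row.empty:
        raise ValueError(f"base year {base_year} not present in trajectory")
    out = traj[["year"]].copy()
    for col in traj.columns:
        if col != "year":
            out[col] = float(row[col].iloc[0])
    return out


def allocate_mileage(
    traj: pd.DataFrame,
    value_col: str,
    dist: pd.DataFrame,
    demo: pd.DataFrame,
    out_mode: str,
) -> pd.DataFrame:
    """Distribute a national per-capita trajectory over ages.

    National weekly kilometres in year y are ``traj[value_col] * total
    population(y)``; age a receives fraction d(a) of them, so per-capita
    mileage at age a is ``national * d(a) / population(a, y)``.  The
    population-weighted mean over ages recovers the national value exactly.
    """
    share_sum = dist["share"].sum()
    if abs(share_sum - 1.0) > 1e-9:
        raise ValueError(f"age distribution not normalized (sum {share_sum:.3e})")
    pop = demo.pivot(index="age", columns="year", values="population")
    years = traj["year"].to_numpy()
    missing = set(years) - set(pop.columns)
    if missing:
        raise ValueError(f"demography lacks years {sorted(missing)}")
    d = dist.set_index("age")["share"].reindex(pop.index)
    if d.isna().any():
        raise ValueError("age distribution does not cover all demography ages")

    frames = []
    for year, km_pc in zip(years, traj[value_col].to_numpy()):
        n = pop[year].to_numpy()
        national_km = km_pc * n.sum()
        zero_pop = (n <= 0) & (d.to_numpy() > 0)
        if zero_pop.any():
            bad = pop.index[zero_pop].tolist()
            raise ValueError(
                f"zero population at ages {bad} in {year} but the age "
                f"distribution assigns them mileage"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            km_age = np.where(n > 0, national_km * d.to_numpy() / n, 0.0)
        frames.append(pd.DataFrame({
            "year": year, "age": pop.index, "mode": out_mode, "km_pc": km_age,
        }))
    return pd.concat(frames, ignore_index=True)


def mean_age_of_mileage(km_by_age: pd.DataFrame, demo: pd.DataFrame) -> float:
    """Kilometre-weighted mean age: sum(a * km(a) * N(a)) / sum(km(a) * N(a))."""
    merged = km_by_age.merge(demo[["year", "age", "population"]],
                             on=["year", "age"], how="left", validate="many_to_one")
    w = merged["km_pc"] * merged["population"]
    total = w.sum()
    if total <= 0:
        raise ValueError("total mileage is zero; mean age undefined")
    return float((merged["age"] * w).sum() / total)


def _weighted_share(s: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(s * w) / np.sum(w))


def _age_gap(s: np.ndarray, ages: np.ndarray, w: np.ndarray) -> float:
    we, wc = s * w, (1.0 - s) * w
    if we.sum() <= 0 or wc.sum() <= 0:
        return float("nan")
    return float((ages * we).sum() / we.sum() - (ages * wc).sum() / wc.sum())


def _solve_alpha(beta: float, ages: np.ndarray, w: np.ndarray, target: float,
                 tol: float = 1e-13) -> float:
    """Share constraint is strictly increasing in alpha; bracket and bisect."""
    def f(alpha: float) -> float:
        return _weighted_share(expit(alpha + beta * ages), w) - target

    lo, hi = -1.0, 1.0
    for _ in range(80):
        if f(lo) <= 0:
            break
        lo *= 2.0
    for _ in range(80):
        if f(hi) >= 0:
            break
        hi *= 2.0
    if f(lo) > 0 or f(hi) < 0:
        raise SolverError(f"cannot bracket alpha for share target {target}")
    return brentq(f, lo, hi, xtol=tol)


def _solve_split(ages: np.ndarray, w: np.ndarray, share_target: float,
                 gap_target: float, gap_tol: float = 1e-3,
                 beta_max: float = 50.0) -> tuple[float, float]:
    """Solve (alpha, beta) for the joint share + mean-age-gap constraints."""
    if gap_target == 0.0:
        return float(logit(share_target)), 0.0

    def gap_residual(beta: float) -> float:
        alpha = _solve_alpha(beta, ages, w, share_target)
        return _age_gap(expit(alpha + beta * ages), ages, w) - gap_target

    sign = 1.0 if gap_target > 0 else -1.0
    hi = 0.125 * sign
    r0 = gap_residual(0.0)  # = -gap_target
    while abs(hi) <= beta_max:
        if gap_residual(hi) * r0 <= 0:
            break
        hi *= 2.0
    else:
        raise SolverError(
            f"age gap {gap_target} unreachable: residual at beta={beta_max * sign} "
            f"is {gap_residual(beta_max * sign):.3f}"
        )
    beta = brentq(gap_residual, 0.0, hi, xtol=1e-9, maxiter=200)
    if abs(gap_residual(beta)) > gap_tol:
        raise SolverError(f"gap residual {gap_residual(beta):.2e} above tolerance {gap_tol}")
    return _solve_alpha(beta, ages, w, share_target), beta


def split_ebike(
    cycle: pd.DataFrame,
    share_by_year: pd.Series,
    age_gap_target: float,
    demo: pd.DataFrame,
    enforce_gap_each_year: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split total cycling mileage into classical-bike and e-bike rows.

    Parameters
    ----------
    cycle
        Per-(year, age) total cycling mileage (``km_pc`` column, any mode label).
    share_by_year
        Target national e-bike share of cycled kilometres, indexed by year.
    age_gap_target
        Target difference (years) between the mean age of e-bike and of
        classical-bike kilometres; enforced every year when feasible.
    demo
        Demography table supplying populations (kilometre weights are
        ``km_pc * population``).

    Returns
    -------
    (diagnostics, mileage) — per-year :class:`SplitSolution` rows, and an
    age-mileage frame with modes ``bike_classical`` and ``bike_e`` whose sum
    reproduces the input exactly.

    Degenerate years (share target 0 or 1, or no cycling at all) fall back to
    a constant share with an undefined (NaN) age gap and a logged warning.

    With ``enforce_gap_each_year=False`` the age slope beta is calibrated once
    — in the year with the largest cycling volume — and held fixed; other
    years solve only the share constraint, letting the achieved gap drift.
    """
    merged = cycle.merge(demo[["year", "age", "population"]],
                         on=["year", "age"], how="left", validate="many_to_one")

    fixed_beta: float | None = None
    if not enforce_gap_each_year:
        weight = (merged["km_pc"] * merged["population"]).groupby(merged["year"]).sum()
        calib_year = int(weight.idxmax())
        grp = merged[merged["year"] == calib_year]
        _, fixed_beta = _solve_split(grp["age"].to_numpy(dtype=float),
                                     (grp["km_pc"] * grp["population"]).to_numpy(),
                                     float(share_by_year.loc[calib_year]), age_gap_target)

    diags, frames = [], []
    for year, grp in merged.groupby("year", sort=True):
        target = float(share_by_year.loc[year])
        if not 0.0 <= target <= 1.0:
            raise ValueError(f"e-bike share target {target} outside [0, 1] in {year}")
        ages = grp["age"].to_numpy(dtype=float)
        w = (grp["km_pc"] * grp["population"]).to_numpy()
        degenerate = target in (0.0, 1.0) or w.sum() <= 0
        if degenerate:
            logger.warning(
                "year %s: e-bike split degenerate (share target %.3f, total km "
                "weight %.3g); using constant share", year, target, w.sum())
            s = np.full(len(ages), target)
            alpha, beta = float("nan"), float("nan")
        elif fixed_beta is not None:
            beta = fixed_beta
            alpha = _solve_alpha(beta, ages, w, target)
            s = expit(alpha + beta * ages)
        else:
            alpha, beta = _solve_split(ages, w, target, age_gap_target)
            s = expit(alpha + beta * ages)
        km = grp["km_pc"].to_numpy()
        km_e = s * km
        diags.append(SplitSolution(
            year=int(year), alpha=alpha, beta=beta,
            achieved_share=_weighted_share(s, w) if w.sum() > 0 else target,
            achieved_age_gap=_age_gap(s, ages, w) if not degenerate else float("nan"),
        ))
        frames.append(pd.DataFrame({
            "year": int(year),
            "age": grp["age"].to_numpy(),
            "mode": "bike_classical",
            "km_pc": km - km_e,
        }))
        frames.append(pd.DataFrame({
            "year": int(year),
            "age": grp["age"].to_numpy(),
            "mode": "bike_e",
            "km_pc": km_e,
        }))
    diag_df = pd.DataFrame([d.__dict__ for d in diags])
    return diag_df, pd.concat(frames, ignore_index=True)
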