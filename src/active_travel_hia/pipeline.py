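"""End-to-end orchestration: inputs -> exposure -> relative risks -> impacts.

``run_analysis`` executes one full assessment at one dose-response bound:
the modal-shift scenario and its frozen-base-year reference are allocated
over ages, cycling is split by bike type, exposures are converted to capped
linear relative risks, and deaths/YLL averted, their scenario deltas, the
per-year life-expectancy gain and monetized benefits are assembled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import allocation, dose_response, engine
from .config import RunConfig
from .io import InputBundle

logger = logging.getLogger(__name__)

__all__ = ["ScenarioResult", "PipelineResult", "run_analysis", "build_specs"]

ACTIVE_MODES = ["walk", "bike_classical", "bike_e"]


def build_specs(cfg: RunConfig) -> dict[str, dose_response.DoseResponseSpec]:
    """DRF specs keyed by mode family, with the config's MET ratio applied."""
    return {
        "cycling": replace(cfg.drf_cycling, met_ratio=cfg.met_ratio),
        "walking": cfg.drf_walking,
    }


@dataclass
class ScenarioResult:
    name: str
    impact: pd.DataFrame        # year, age, mode (incl. "all"), deaths_prevented, yll_prevented
    rr: pd.DataFrame            # year, age, mode (incl. "all"), rr
    split_diagnostics: pd.DataFrame
    exposure: pd.DataFrame


@dataclass
class PipelineResult:
    annual: pd.DataFrame            # year, deaths_prevented, yll_prevented, benefits_eur, le_gain_months
    per_mode_annual: pd.DataFrame   # year, mode, deaths_prevented, yll_prevented
    per_age_delta: pd.DataFrame     # year, age, mode, deaths_prevented, yll_prevented
    scenarios: dict[str, ScenarioResult]
    cumulative: dict[str, float]
    mode_contributions: pd.DataFrame  # mode, deaths_pct, yll_pct
    bound: str
    config: RunConfig


def _scenario_run(name: str, traj: pd.DataFrame, inputs: InputBundle,
                  cfg: RunConfig, bound: str) -> ScenarioResult:
    demo = inputs.demography
    dist = inputs.age_distribution
    walk = allocation.allocate_mileage(
        traj, "walk_km_pc", dist[dist["mode"] == "walk"], demo, out_mode="walk")
    cycle = allocation.allocate_mileage(
        traj, "cycle_km_pc", dist[dist["mode"] == "cycle"], demo, out_mode="bike_total")
    diag, bike = allocation.split_ebike(
        cycle, traj.set_index("year")["ebike_share"], cfg.age_gap_target, demo,
        enforce_gap_each_year=cfg.enforce_gap_each_year)
    mileage = pd.concat([walk, bike], ignore_index=True)

    specs = build_specs(cfg)
    exposure = dose_response.exposure_table(mileage, cfg.speeds, specs)
    rr = dose_response.rr_surface(exposure, specs, bound, cfg.age_window)

    capped_minutes = _capped_person_minutes(exposure, specs, demo)
    if capped_minutes > 0:
        logger.info("%s/%s: %.3g person-minutes/week above the DRF cap threshold",
                    name, bound, capped_minutes)

    impact = engine.deaths_prevented(demo, rr, cfg.age_window)
    le_source = demo if cfg.yll_residual_le == "common" else _scenario_le(demo, rr, cfg)
    impact = engine.yll_prevented(impact, le_source)
    return ScenarioResult(name, impact, rr, diag, exposure)


def _capped_person_minutes(exposure: pd.DataFrame, specs, demo: pd.DataFrame) -> float:
    merged = exposure.merge(demo[["year", "age", "population"]], on=["year", "age"])
    excess = 0.0
    for mode, grp in merged.groupby("mode"):
        spec = specs[dose_response.MODE_FAMILY[mode]]
        threshold = spec.reference_exposure * spec.cap / spec.reduction_central
        over = np.clip(grp["eff_minutes"] - threshold, 0.0, None)
        excess += float((over * grp["population"]).sum())
    return excess


def _scenario_le(demo: pd.DataFrame, rr: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Residual life expectancy recomputed under the scenario's combined rr."""
    rr_all = rr[rr["mode"] == "all"].set_index(["year", "age"])["rr"]
    out = []
    for year, grp in demo.sort_values("age").groupby("year"):
        factor = rr_all.reindex([(year, a) for a in grp["age"]], fill_value=1.0).to_numpy()
        q_adj = np.clip(grp["mortality_q"].to_numpy() * factor, 0.0, 1.0)
        out.append(pd.DataFrame({
            "year": year, "age": grp["age"].to_numpy(),
            "residual_le": engine.residual_life_expectancy(q_adj, cfg.a_fraction),
        }))
    return pd.concat(out, ignore_index=True)


def run_analysis(inputs: InputBundle, cfg: RunConfig, bound: str = "central") -> PipelineResult:
    """Run the full assessment at one dose-response bound."""
    traj = inputs.mileage[(inputs.mileage["year"] >= cfg.base_year)
                          & (inputs.mileage["year"] <= cfg.end_year)].reset_index(drop=True)
    reference_traj = allocation.build_reference_scenario(traj, cfg.base_year)

    shift = _scenario_run("scenario", traj, inputs, cfg, bound)
    reference = _scenario_run("reference", reference_traj, inputs, cfg, bound)
    delta = engine.scenario_delta(shift.impact, reference.impact)

    all_rows = delta[delta["mode"] == "all"]
    annual = (all_rows.groupby("year", as_index=False)
              [["deaths_prevented", "yll_prevented"]].sum())
    per_mode = (delta[delta["mode"].isin(ACTIVE_MODES)]
                .groupby(["year", "mode"], as_index=False)
                [["deaths_prevented", "yll_prevented"]].sum())

    from .economics import monetize  # deferred: economics re-runs this pipeline
    benefits, cumulative_benefits = monetize(
        annual.set_index("year")["yll_prevented"], inputs.vsly)
    annual = annual.merge(benefits, on="year", validate="one_to_one")
    annual["le_gain_months"] = [
        engine.life_expectancy_gain(inputs.demography, shift.rr, reference.rr,
                                    year, cfg.a_fraction)
        for year in annual["year"]
    ]

    mode_tot = per_mode.groupby("mode")[["deaths_prevented", "yll_prevented"]].sum()
    denom = mode_tot.sum()
    contributions = pd.DataFrame({
        "mode": mode_tot.index,
        "deaths_pct": 100.0 * mode_tot["deaths_prevented"] / denom["deaths_prevented"]
        if denom["deaths_prevented"] != 0 else 0.0,
        "yll_pct": 100.0 * mode_tot["yll_prevented"] / denom["yll_prevented"]
        if denom["yll_prevented"] != 0 else 0.0,
    }).reset_index(drop=True)

    diagnostics = pd.concat([
        shift.split_diagnostics.assign(scenario="scenario"),
        reference.split_diagnostics.assign(scenario="reference"),
    ], ignore_index=True)
    for sc in (shift, reference):
        sc.split_diagnostics = diagnostics[diagnostics["scenario"] == sc.name]

    return PipelineResult(
        annual=annual,
        per_mode_annual=per_mode,
        per_age_delta=delta,
        scenarios={"scenario": shift, "reference": reference},
        cumulative={
            "deaths_prevented": float(annual["deaths_prevented"].sum()),
            "yll_prevented": float(annual["yll_prevented"].sum()),
            "benefits_eur": cumulative_benefits,
        },
        mode_contributions=contributions,
        bound=bound,
        config=cfg,
    )
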