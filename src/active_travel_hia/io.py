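"""CSV schemas, validated readers/writers and the input bundle.

Normative input schemas (tidy long formats, integer years and 1-year ages):

* ``demography.csv``       — year, age, population, mortality_q, residual_le
* ``mileage.csv``          — year, walk_km_pc, cycle_km_pc, ebike_share
* ``age_distribution.csv`` — mode, age, share
* ``vsly.csv``             — year, vsly_eur

Every written file carries ``#``-prefixed header lines with the generating
seed and a parameter hash; readers skip them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .synthetic import gen_age_distribution, gen_demography, gen_mileage, gen_vsly

__all__ = ["InputBundle", "SCHEMAS", "generate_inputs", "read_input_csv",
           "write_input_csv", "write_inputs", "read_inputs"]

SCHEMAS: dict[str, list[str]] = {
    "demography": ["year", "age", "population", "mortality_q", "residual_le"],
    "mileage": ["year", "walk_km_pc", "cycle_km_pc", "ebike_share"],
    "age_distribution": ["mode", "age", "share"],
    "vsly": ["year", "vsly_eur"],
}

_BOUNDS = {  # column -> (min, max) closed bounds checked on read
    "mortality_q": (0.0, 1.0),
    "ebike_share": (0.0, 1.0),
    "share": (0.0, 1.0),
    "population": (0.0, None),
    "residual_le": (0.0, None),
    "walk_km_pc": (0.0, None),
    "cycle_km_pc": (0.0, None),
    "vsly_eur": (0.0, None),
}


@dataclass
class InputBundle:
    """The four validated input tables the pipeline consumes."""

    demography: pd.DataFrame
    mileage: pd.DataFrame
    age_distribution: pd.DataFrame
    vsly: pd.DataFrame


def _validate(df: pd.DataFrame, name: str) -> pd.DataFrame:
    cols = SCHEMAS[name]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    df = df[cols]
    for col in cols:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise ValueError(f"{name}: missing value at row {row}, column {col!r}")
        lo_hi = _BOUNDS.get(col)
        if lo_hi:
            lo, hi = lo_hi
            bad = (df[col] < lo) if hi is None else ~df[col].between(lo, hi)
            if bad.any():
                row = int(df.index[bad][0])
                raise ValueError(
                    f"{name}: value {df[col].iloc[row]!r} out of range at row "
                    f"{row}, column {col!r}")
    for col in ("year", "age"):
        if col in cols:
            df = df.astype({col: int})
    return df


def generate_inputs(cfg: RunConfig) -> InputBundle:
    """Build the four input tables from the synthetic generators."""
    s = cfg.synth
    # the demography generator needs a 2+ year horizon; over-generate one year
    # for degenerate single-year runs and trim below
    demo_horizon = max(cfg.end_year, cfg.base_year + 1)
    demo_params = s.demography
    if (demo_params.base_year, demo_params.horizon_year, demo_params.seed) != (
            cfg.base_year, demo_horizon, s.seed):
        from dataclasses import replace
        demo_params = replace(demo_params, base_year=cfg.base_year,
                              horizon_year=demo_horizon, seed=s.seed)
    demo = gen_demography(demo_params)
    demo = demo[demo["year"] <= cfg.end_year].reset_index(drop=True)
    mileage = gen_mileage(s.anchors, cfg.base_year, cfg.end_year, s.interpolation)
    dist = pd.concat([
        gen_age_distribution("walk", s.walk_shape, demo_params.a_max),
        gen_age_distribution("cycle", s.cycle_shape, demo_params.a_max),
    ], ignore_index=True)
    vsly = gen_vsly(s.vsly_base_value, s.vsly_base_year, s.vsly_growth_rate,
                    cfg.base_year, cfg.end_year)
    return InputBundle(demo, mileage, dist, vsly)


def write_input_csv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_input_csv(path, name: str) -> pd.DataFrame:
    return _validate(pd.read_csv(path, comment="#", float_precision="round_trip"), name)


def write_inputs(bundle: InputBundle, out_dir, meta: dict | None = None) -> dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {}
    for name, df in (("demography", bundle.demography), ("mileage", bundle.mileage),
                     ("age_distribution", bundle.age_distribution), ("vsly", bundle.vsly)):
        paths[name] = out_dir / f"{name}.csv"
        write_input_csv(paths[name], _validate(df, name), meta)
    return paths


def read_inputs(in_dir) -> InputBundle:
    in_dir = Path(in_dir)
    return InputBundle(*(read_input_csv(in_dir / f"{name}.csv", name)
                         for name in ("demography", "mileage", "age_distribution", "vsly")))
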