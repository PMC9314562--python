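"""Run configuration: defaults, YAML (de)serialization, sensitivity overrides.

Every default equals the main-analysis value of the assessment: horizon
2021-2050, speeds 4.8/14.9/18.1 km/h, the meta-analytic dose-response
specs with caps 0.45/0.30, e-bike MET ratio 0.90, effect-age window 20-84,
mean-age gap target 6.7 years, Chiang a = 0.5, closure age 110.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Any

import yaml

from .dose_response import CYCLING_DRF, DEFAULT_SPEEDS, WALKING_DRF, DoseResponseSpec
from .synthetic import (
    DEFAULT_ANCHORS,
    DEFAULT_CYCLE_SHAPE,
    DEFAULT_WALK_SHAPE,
    AgeShape,
    DemographyParams,
    MileageAnchors,
    PyramidShape,
)

__all__ = ["SynthConfig", "RunConfig", "apply_overrides", "OVERRIDE_KEYS"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic input generators."""

    demography: DemographyParams = field(default_factory=DemographyParams)
    anchors: MileageAnchors = DEFAULT_ANCHORS
    cycle_shape: AgeShape = DEFAULT_CYCLE_SHAPE
    walk_shape: AgeShape = DEFAULT_WALK_SHAPE
    interpolation: str = "pchip"
    vsly_base_value: float = 139_000.0
    vsly_base_year: int = 2020
    vsly_growth_rate: float = 0.012
    seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    base_year: int = 2021
    end_year: int = 2050
    report_year: int = 2045
    speeds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPEEDS))
    drf_cycling: DoseResponseSpec = CYCLING_DRF
    drf_walking: DoseResponseSpec = WALKING_DRF
    met_ratio: float = 0.90
    age_window: tuple[int, int] = (20, 84)
    age_gap_target: float = 6.7
    enforce_gap_each_year: bool = True
    mode_combination: str = "multiplicative"
    a_fraction: float = 0.5
    yll_residual_le: str = "common"  # or "scenario"
    input_dir: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self) -> None:
        if self.end_year < self.base_year:
            raise ValueError("end_year must not precede base_year")
        if self.mode_combination != "multiplicative":
            raise ValueError("only multiplicative mode combination is implemented")
        if self.yll_residual_le not in ("common", "scenario"):
            raise ValueError("yll_residual_le must be 'common' or 'scenario'")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["age_window"] = list(self.age_window)
        for key in ("walk", "cycle", "ebike_share"):
            d["synth"]["anchors"][key] = [list(p) for p in d["synth"]["anchors"][key]]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        synth = dict(d.pop("synth", {}))
        if "demography" in synth:
            demo = dict(synth["demography"])
            if "pyramid_shape" in demo:
                demo["pyramid_shape"] = PyramidShape(**demo["pyramid_shape"])
            synth["demography"] = DemographyParams(**demo)
        if "anchors" in synth:
            synth["anchors"] = MileageAnchors(**{
                k: tuple((int(y), float(v)) for y, v in pts)
                for k, pts in synth["anchors"].items()
            })
        for key in ("cycle_shape", "walk_shape"):
            if key in synth:
                synth[key] = AgeShape(**synth[key])
        d["synth"] = SynthConfig(**synth)
        for key in ("drf_cycling", "drf_walking"):
            if key in d and isinstance(d[key], dict):
                d[key] = DoseResponseSpec(**d[key])
        if "age_window" in d:
            d["age_window"] = tuple(d["age_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def param_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def _override_age_gap(cfg: RunConfig, v) -> RunConfig:
    return replace(cfg, age_gap_target=float(v))


def _override_met_ratio(cfg: RunConfig, v) -> RunConfig:
    return replace(cfg, met_ratio=float(v))


def _override_age_window_high(cfg: RunConfig, v) -> RunConfig:
    return replace(cfg, age_window=(cfg.age_window[0], int(v)))


def _override_cycling_drf(cfg: RunConfig, v) -> RunConfig:
    spec = replace(cfg.drf_cycling, reduction_central=float(v["central"]),
                   reduction_low=float(v["low"]), reduction_high=float(v["high"]))
    return replace(cfg, drf_cycling=spec)


def _override_cycling_cap(cfg: RunConfig, v) -> RunConfig:
    return replace(cfg, drf_cycling=replace(cfg.drf_cycling, cap=float(v)))


def _override_walking_cap(cfg: RunConfig, v) -> RunConfig:
    return replace(cfg, drf_walking=replace(cfg.drf_walking, cap=float(v)))


OVERRIDE_KEYS = {
    "age_gap_target": _override_age_gap,
    "met_ratio": _override_met_ratio,
    "age_window_high": _override_age_window_high,
    "cycling_drf": _override_cycling_drf,
    "cycling_cap": _override_cycling_cap,
    "walking_cap": _override_walking_cap,
}


def apply_overrides(cfg: RunConfig, overrides: dict[str, Any]) -> RunConfig:
    """Apply a sensitivity variant's config deltas; unknown keys are rejected."""
    for key, value in overrides.items():
        if key not in OVERRIDE_KEYS:
            raise KeyError(f"unknown override key {key!r}; known: {sorted(OVERRIDE_KEYS)}")
        cfg = OVERRIDE_KEYS[key](cfg, value)
    return cfg
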