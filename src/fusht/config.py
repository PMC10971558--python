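"""Run configuration: YAML parsing, defaults, validation, unit handling.

Configuration files use display units (mm, MPa, min, °C); everything is
converted to strict SI (m, Pa, s) when domain objects are built, which
keeps the mm/MHz/Np unit traps of the material table out of the solvers.
Unknown keys are rejected and validation errors name the offending key.

An empty (or absent) file yields the full default treatment scene: the
350 kHz / 44 mm / 31.5 mm bowl driven to a 1 MPa focal pressure, the
0.8 mm-skin / 6 mm-tumor layered phantom with the standard material table,
a 0.4 mm grid, 10 min equilibration, 20 min treatment under the
42 / 41.5 °C relay, and the published four-arm cohort parameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import yaml

from .acoustics import TransducerSpec
from .bioheat import BHTEConfig
from .control import HysteresisController
from .grids import SimulationGrid
from .materials import DEFAULT_MEDIA, LayeredPhantom, Medium

__all__ = ["ConfigError", "RunConfig", "load_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


DEFAULTS: dict[str, Any] = {
    "transducer": {
        "frequency_hz": 350e3,
        "aperture_mm": 44.0,
        "focal_length_mm": 31.5,
        "focal_pressure_mpa": 1.0,
    },
    "phantom": {
        "standoff_mm": None,  # None -> focal_length - skin - tumor_radius
        "skin_mm": 0.8,
        "tumor_diameter_mm": 6.0,
    },
    "materials": {
        name: {
            "density": m.density,
            "sound_speed": m.sound_speed,
            "attenuation": m.attenuation,
            "conductivity": m.conductivity,
            "specific_heat": m.specific_heat,
            "perfusion": m.perfusion,
        }
        for name, m in DEFAULT_MEDIA.items()
    },
    "grid": {
        "spacing_mm": 0.4,
        "extent_mm": [40.0, 50.0],  # lateral, axial
    },
    "bhte": {
        "dt_s": None,
        "arterial_c": 37.0,
        "blood_specific_heat": 3700.0,
        "tissue_initial_c": 37.0,
        "water_initial_c": 23.0,
        "equilibration_min": 10.0,
        "treatment_min": 20.0,
        "boundary": "dirichlet_z",
    },
    "controller": {
        "upper_c": 42.0,
        "lower_c": 41.5,
    },
    "dose": {
        "r_above": 0.5,
        "r_below": 0.25,
        "snapshot_stride": 10,
    },
    "rt": {
        "dose_gy": 2.0,
        "base_rate_gy_min": 4.1,
        "output_factor": 0.79,
        "depth_mm": 3.0,
    },
    "analysis": {
        "day": 7,
        "alpha": 0.05,
        "bonferroni_m": 3,
        "comparisons": [
            ["FUS-HT+RT2Gy", "control"],
            ["FUS-HT+RT2Gy", "RT2Gy"],
            ["FUS-HT+RT2Gy", "FUS-HT"],
        ],
    },
    "synth": {
        "preset": "paper-day7",
        "aspect_lo": 1.0,
        "aspect_hi": 1.6,
    },
}


def _merge(user: Any, default: Any, path: str) -> Any:
    if isinstance(default, dict):
        if user is None:
            return copy.deepcopy(default)
        if not isinstance(user, dict):
            raise ConfigError(f"{path or 'config'}: expected a mapping")
        out = {}
        for key in user:
            if key not in default:
                raise ConfigError(f"unknown key {path + '.' if path else ''}{key}")
        for key, dval in default.items():
            sub = f"{path}.{key}" if path else key
            out[key] = _merge(user.get(key, None), dval, sub) if key in user \
                else copy.deepcopy(dval)
        return out
    return copy.deepcopy(user)


def _require_positive(cfg: dict, *keys: str) -> None:
    for dotted in keys:
        node: Any = cfg
        for part in dotted.split("."):
            node = node[part]
        if node is None or not node > 0:
            raise ConfigError(f"{dotted} must be positive (got {node!r})")


@dataclass(frozen=True)
class RunConfig:
    """Validated merged configuration plus provenance."""

    raw: dict[str, Any]
    source_path: str | None = None

    # -- builders (display units -> SI domain objects) -------------------
    def transducer(self) -> TransducerSpec:
        t = self.raw["transducer"]
        return TransducerSpec(
            frequency=float(t["frequency_hz"]),
            aperture_diameter=float(t["aperture_mm"]) * 1e-3,
            radius_of_curvature=float(t["focal_length_mm"]) * 1e-3,
        )

    @property
    def focal_pressure(self) -> float:
        return float(self.raw["transducer"]["focal_pressure_mpa"]) * 1e6

    def grid(self) -> SimulationGrid:
        g = self.raw["grid"]
        lat, ax = (float(v) * 1e-3 for v in g["extent_mm"])
        return SimulationGrid.from_extent(float(g["spacing_mm"]) * 1e-3, lat, ax)

    def media(self) -> dict[str, Medium]:
        return {
            name: Medium(name=name, **{k: float(v) for k, v in props.items()})
            for name, props in self.raw["materials"].items()
        }

    def phantom(self) -> LayeredPhantom:
        p = self.raw["phantom"]
        t = self.raw["transducer"]
        focal = float(t["focal_length_mm"]) * 1e-3
        skin = float(p["skin_mm"]) * 1e-3
        tumor = float(p["tumor_diameter_mm"]) * 1e-3
        standoff = p["standoff_mm"]
        ph = LayeredPhantom.default_for_focus(
            focal_length=focal,
            skin_thickness=skin,
            tumor_diameter=tumor,
            water_standoff=None if standoff is None else float(standoff) * 1e-3,
        )
        return replace(ph, media=self.media())

    def bhte(self) -> BHTEConfig:
        b = self.raw["bhte"]
        return BHTEConfig(
            dt=None if b["dt_s"] is None else float(b["dt_s"]),
            arterial_temperature=float(b["arterial_c"]),
            blood_specific_heat=float(b["blood_specific_heat"]),
            tissue_initial=float(b["tissue_initial_c"]),
            water_initial=float(b["water_initial_c"]),
            equilibration_duration=float(b["equilibration_min"]) * 60.0,
            boundary=str(b["boundary"]),
        )

    @property
    def treatment_duration(self) -> float:
        return float(self.raw["bhte"]["treatment_min"]) * 60.0

    def controller(self) -> HysteresisController:
        c = self.raw["controller"]
        return HysteresisController(upper=float(c["upper_c"]),
                                    lower=float(c["lower_c"]))


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load, merge with defaults, and validate a YAML configuration.

    ``overrides`` (a nested partial dict) is applied on top of the file,
    which is itself applied on top of the defaults; pass ``path=None`` for
    a pure-default configuration.
    """
    user: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        user = loaded

    merged = _merge(user, DEFAULTS, "")
    if overrides:
        merged = _merge(overrides, merged, "")

    _validate(merged)
    return RunConfig(raw=merged, source_path=None if path is None else str(path))


def _validate(cfg: dict[str, Any]) -> None:
    _require_positive(
        cfg,
        "transducer.frequency_hz", "transducer.aperture_mm",
        "transducer.focal_length_mm",
        "phantom.skin_mm",
        "grid.spacing_mm",
        "rt.dose_gy", "rt.base_rate_gy_min", "rt.output_factor",
        "dose.r_above", "dose.r_below",
        "analysis.alpha",
    )
    t = cfg["transducer"]
    if t["aperture_mm"] >= 2 * t["focal_length_mm"]:
        raise ConfigError(
            "transducer.aperture_mm must be smaller than twice the focal length"
        )
    if t["focal_pressure_mpa"] < 0:
        raise ConfigError("transducer.focal_pressure_mpa must be non-negative")
    if cfg["phantom"]["tumor_diameter_mm"] < 0:
        raise ConfigError("phantom.tumor_diameter_mm must be non-negative")
    c = cfg["controller"]
    if not c["lower_c"] < c["upper_c"]:
        raise ConfigError("controller.lower_c must be below controller.upper_c")
    if not 0 < cfg["rt"]["output_factor"] <= 1:
        raise ConfigError("rt.output_factor must lie in (0, 1]")
    b = cfg["bhte"]
    if b["equilibration_min"] < 0:
        raise ConfigError("bhte.equilibration_min must be non-negative")
    if b["treatment_min"] <= 0:
        raise ConfigError("bhte.treatment_min must be positive")
    if b["boundary"] not in ("dirichlet_z", "insulated"):
        raise ConfigError("bhte.boundary must be 'dirichlet_z' or 'insulated'")
    ext = cfg["grid"]["extent_mm"]
    if not (isinstance(ext, (list, tuple)) and len(ext) == 2
            and all(v > 0 for v in ext)):
        raise ConfigError("grid.extent_mm must be [lateral_mm, axial_mm] > 0")
    for name, props in cfg["materials"].items():
        for key, val in props.items():
            if val < 0:
                raise ConfigError(f"materials.{name}.{key} must be non-negative")
    s = cfg["synth"]
    if not 1.0 <= s["aspect_lo"] <= s["aspect_hi"]:
        raise ConfigError("synth.aspect_lo/aspect_hi must satisfy 1 <= lo <= hi")
    if cfg["dose"]["snapshot_stride"] < 1:
        raise ConfigError("dose.snapshot_stride must be at least 1")
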