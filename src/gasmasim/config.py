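"""Run configuration: YAML loading, validation, defaults, hashing.

A run is fully specified by a config file plus a master seed.  Every numeric
default is the corresponding phantom/instrument value (229 capillaries,
0.25 mm bore, mu_a = 0.50 1/cm, 37 degC chamber, ...); an empty file is a
valid, complete configuration.  Unknown keys are rejected with their dotted
path so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .environment import DriftModel, Environment
from .forward import GasLineModel, OpticalProperties
from .geometry import BeamFootprint, CapillaryArray

__all__ = ["ConfigError", "RunConfig", "load_config", "dump_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Raised for unparseable, unknown, or invalid configuration input."""


DEFAULTS: dict[str, Any] = {
    "geometry": {
        "n_capillaries": 229,
        "inner_radius_m": 0.25e-3,
        "outer_radius_m": 0.625e-3,
        "capillary_length_m": 125e-3,
        "n_columns_along_beam": 20,
        "n_rows": 12,
    },
    "beam": {
        "width_m": 0.01,
        "depth_m": 0.014,
        "array_path_length_m": 0.025,
        "sampled_capillary_length_m": 0.01,
    },
    "environment": {
        "temperature_c": 37.0,
        "rh_percent": 92.0,
        "pressure_hpa": 1013.25,
    },
    "drift": {
        "temperature_range_c": [36.0, 39.0],
        "rh_range_percent": [90.0, 94.0],
    },
    "lines": {
        "o2": {
            "effective_absorptivity": 1.0,
            "halfwidth": 1.0,
            "modulation_index": 2.2,
            "wms_gain": 1000.0,
        },
        "h2o": {
            "effective_absorptivity": 4.0,
            "halfwidth": 1.0,
            "modulation_index": 2.2,
            "wms_gain": 1000.0,
        },
    },
    "optics": {"mu_a_per_cm": 0.50, "mu_s_prime_per_cm": 5.4, "g": 0.6},
    "simulation": {
        "noise_sd": 0.03,
        "o2_fraction": 0.209,
        "include_interstitial": True,
        "path_enhancement": 1.0,
        "qc_multiplier": 1.0,
    },
    "design": {
        "replicates_per_config": 10,
        "step": 20,
        "n_steps": 10,
        "set1_drift_enabled": True,
        "set2_drift_enabled": False,
    },
    # Reference constants quoted for context (both appear in the source
    # material with mutually inconsistent magnitudes; neither enters any
    # computation by default, so both are exposed rather than reconciled).
    "alveoli": {"unit_volume_m3": 1.41e-8, "diameter_m": 0.3e-3},
    "output": {"out_dir": "results"},
    "master_seed": 0,
}

_BOOL_KEYS = {
    "include_interstitial",
    "set1_drift_enabled",
    "set2_drift_enabled",
}
_INT_KEYS = {
    "n_capillaries",
    "n_columns_along_beam",
    "n_rows",
    "replicates_per_config",
    "step",
    "n_steps",
    "master_seed",
}
_STR_KEYS = {"out_dir"}


def _merge(defaults: Mapping[str, Any], user: Mapping[str, Any], path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in user.items():
        here = f"{path}{key}"
        if key not in out:
            raise ConfigError(f"{here}: unknown key")
        if isinstance(out[key], Mapping):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge(out[key], value, path=f"{here}.")
        else:
            out[key] = _coerce(key, value, here)
    return out


def _coerce(key: str, value: Any, path: str) -> Any:
    if key in _BOOL_KEYS:
        if not isinstance(value, bool):
            raise ConfigError(f"{path}: expected a boolean, got {value!r}")
        return value
    if key in _STR_KEYS:
        if not isinstance(value, str):
            raise ConfigError(f"{path}: expected a string, got {value!r}")
        return value
    if key in _INT_KEYS:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{path}: expected an integer, got {value!r}")
        return value
    if isinstance(value, (list, tuple)):
        try:
            return [float(v) for v in value]
        except (TypeError, ValueError):
            raise ConfigError(f"{path}: expected a list of numbers, got {value!r}")
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{path}: expected a number, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration with domain objects already constructed."""

    raw: dict[str, Any]
    array: CapillaryArray
    beam: BeamFootprint
    environment: Environment
    drift: DriftModel
    line_o2: GasLineModel
    line_h2o: GasLineModel
    optics: OpticalProperties
    noise_sd: float
    o2_fraction: float
    include_interstitial: bool
    path_enhancement: float
    qc_multiplier: float
    replicates_per_config: int
    step: int
    n_steps: int
    set1_drift_enabled: bool
    set2_drift_enabled: bool
    out_dir: str
    master_seed: int

    def config_hash(self) -> str:
        """Stable short hash of the full (merged) configuration."""
        canon = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:12]


def _build(merged: dict[str, Any]) -> RunConfig:
    geo, beam, env = merged["geometry"], merged["beam"], merged["environment"]
    sim, des = merged["simulation"], merged["design"]

    def ctx(section: str, fn):
        try:
            return fn()
        except ValueError as exc:
            raise ConfigError(f"{section}: {exc}") from exc

    array = ctx(
        "geometry",
        lambda: CapillaryArray(
            n_capillaries=geo["n_capillaries"],
            inner_radius=geo["inner_radius_m"],
            outer_radius=geo["outer_radius_m"],
            capillary_length=geo["capillary_length_m"],
            n_columns_along_beam=geo["n_columns_along_beam"],
            n_rows=geo["n_rows"],
        ),
    )
    footprint = ctx(
        "beam",
        lambda: BeamFootprint(
            width=beam["width_m"],
            depth=beam["depth_m"],
            array_path_length=beam["array_path_length_m"],
            sampled_capillary_length=beam["sampled_capillary_length_m"],
        ),
    )
    environment = ctx(
        "environment",
        lambda: Environment(
            temperature=env["temperature_c"],
            relative_humidity=env["rh_percent"],
            pressure=env["pressure_hpa"],
        ),
    )
    drift = ctx(
        "drift",
        lambda: DriftModel(
            temperature_range=tuple(merged["drift"]["temperature_range_c"]),
            rh_range=tuple(merged["drift"]["rh_range_percent"]),
            enabled=True,
        ),
    )

    def line(gas: str, block: dict[str, Any]) -> GasLineModel:
        return GasLineModel(
            gas=gas,
            effective_absorptivity=block["effective_absorptivity"],
            halfwidth=block["halfwidth"],
            modulation_index=block["modulation_index"],
            wms_gain=block["wms_gain"],
        )

    line_o2 = ctx("lines.o2", lambda: line("O2", merged["lines"]["o2"]))
    line_h2o = ctx("lines.h2o", lambda: line("H2O", merged["lines"]["h2o"]))
    optics = ctx(
        "optics",
        lambda: OpticalProperties(
            mu_a=merged["optics"]["mu_a_per_cm"],
            mu_s_prime=merged["optics"]["mu_s_prime_per_cm"],
            g=merged["optics"]["g"],
        ),
    )
    if sim["noise_sd"] < 0:
        raise ConfigError("simulation.noise_sd: must be non-negative")
    if not 0.0 <= sim["o2_fraction"] <= 1.0:
        raise ConfigError("simulation.o2_fraction: must lie in [0, 1]")
    if des["replicates_per_config"] < 1:
        raise ConfigError("design.replicates_per_config: must be >= 1")
    if des["step"] * des["n_steps"] > array.n_capillaries:
        raise ConfigError("design: step * n_steps exceeds the number of capillaries")
    return RunConfig(
        raw=merged,
        array=array,
        beam=footprint,
        environment=environment,
        drift=drift,
        line_o2=line_o2,
        line_h2o=line_h2o,
        optics=optics,
        noise_sd=sim["noise_sd"],
        o2_fraction=sim["o2_fraction"],
        include_interstitial=sim["include_interstitial"],
        path_enhancement=sim["path_enhancement"],
        qc_multiplier=sim["qc_multiplier"],
        replicates_per_config=des["replicates_per_config"],
        step=des["step"],
        n_steps=des["n_steps"],
        set1_drift_enabled=des["set1_drift_enabled"],
        set2_drift_enabled=des["set2_drift_enabled"],
        out_dir=merged["output"]["out_dir"],
        master_seed=merged["master_seed"],
    )


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` yields the all-defaults run.

    ``overrides`` (a nested mapping) is applied on top of the file, with the
    same unknown-key and bound checks.
    """
    user: dict[str, Any] = {}
    if path is not None:
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping at top level")
        user = dict(loaded)
    merged = _merge(DEFAULTS, user)
    if overrides:
        merged = _merge(merged, overrides)
    return _build(merged)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully merged configuration back out as YAML (round-trips)."""
    Path(path).write_text(yaml.safe_dump(config.raw, sort_keys=True))
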