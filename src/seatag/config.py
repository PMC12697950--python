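"""Structured YAML configuration covering every module of the toolkit.

One file, one section per module (``chain``, ``environment``, ``geometry``,
``mission``, ``synth``, ``calibration``).  Dataclass defaults *are* the
deployed configuration (−205 dB re FS/μPa, 16-bit, 96 kSPS, 3 channels,
the 3/5 m and 6.4/6.2/6.0 V thresholds); a config file overrides fields.
Unknown sections or keys are errors — fail-fast beats silently ignoring a
typo in the field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .aoa import ArrayGeometry, default_l_array
from .chain import AcousticEnvironment, AudioChainSpec
from .mission import MissionConfig
from .synth import ClickModel, DiveProfileSpec

__all__ = ["Config", "ConfigError", "CalibrationRefs", "load_config"]


class ConfigError(ValueError):
    """Unknown key/section or inconsistent configuration."""


@dataclass(frozen=True)
class CalibrationRefs:
    """Reference inputs used by the ``calibrate`` report: the acoustic band
    of interest, the far-field calibration setup, and the reference maximum
    pressure converted to depth."""

    max_signal_freq_hz: float = 40_000.0
    far_field_separation_m: float = 1.0
    far_field_n_wavelengths: int = 5
    reference_pressure_bar: float = 97.5
    detection_source_spl_db: float = 190.0
    detection_floor_spl_db: float = 120.0
    detection_absorption_db_per_km: float = 1.0


@dataclass
class Config:
    chain: AudioChainSpec = field(default_factory=AudioChainSpec)
    environment: AcousticEnvironment = field(default_factory=AcousticEnvironment)
    geometry: ArrayGeometry = field(default_factory=default_l_array)
    mission: MissionConfig = field(default_factory=MissionConfig)
    click_model: ClickModel = field(default_factory=ClickModel)
    dive_spec: DiveProfileSpec = field(default_factory=DiveProfileSpec)
    calibration: CalibrationRefs = field(default_factory=CalibrationRefs)


_SECTION_TYPES = {
    "chain": AudioChainSpec,
    "environment": AcousticEnvironment,
    "mission": MissionConfig,
    "click_model": ClickModel,
    "dive_spec": DiveProfileSpec,
    "calibration": CalibrationRefs,
}


def _build(cls, section: str, values: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{section}] configuration: {exc}") from exc


def _build_geometry(values: dict) -> ArrayGeometry:
    known = {"positions_m", "arm_m", "sound_speed_m_s", "sample_rate_sps"}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown keys in [geometry]: {sorted(unknown)}")
    c = values.get("sound_speed_m_s", 1491.2)
    fs = values.get("sample_rate_sps", 96_000.0)
    if "positions_m" in values:
        if "arm_m" in values:
            raise ConfigError("[geometry] positions_m and arm_m are mutually exclusive")
        return ArrayGeometry(np.asarray(values["positions_m"], dtype=float), c, fs)
    return default_l_array(values.get("arm_m", 0.125), c, fs)


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config on top of the deployed defaults; ``None`` returns
    the defaults unchanged."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    unknown = set(raw) - (set(_SECTION_TYPES) | {"geometry"})
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            setattr(cfg, section, _build(cls, section, raw[section] or {}))
    if "geometry" in raw:
        cfg.geometry = _build_geometry(raw["geometry"] or {})
    return cfg
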