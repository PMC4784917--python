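"""Structured run configuration: parsing, validation, SI conversion.

Config files are YAML (JSON is a YAML subset and accepted) with three
sections in laboratory-friendly units::

    particles:
      mean_core_radius_nm: 20
      mean_hydro_radius_nm: 50
      size_cv: 0.10            # optional, s_r / m_r for both radii
      Ms_kA_per_m: 250
    environment:
      viscosity_mPa_s: 1.0
      temperature_K: 293       # optional
      density_kg_m3: 1000      # optional
    field:
      amplitude_mT: 5
      frequency_Hz: 1000

Unknown keys are rejected (typos must not silently become defaults); all
quantities are converted to SI on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constants import ROOM_TEMPERATURE
from .parameters import DriveField, Environment, ParticleSpec

__all__ = ["RunConfig", "load_config", "dump_config"]

_SCHEMA = {
    "particles": {
        "required": {"mean_core_radius_nm", "mean_hydro_radius_nm", "Ms_kA_per_m"},
        "optional": {"size_cv"},
    },
    "environment": {
        "required": {"viscosity_mPa_s"},
        "optional": {"temperature_K", "density_kg_m3"},
    },
    "field": {
        "required": {"amplitude_mT", "frequency_Hz"},
        "optional": set(),
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Validated SI configuration: particle spec, environment, drive field.

    ``lab_units`` keeps the (defaults-filled) laboratory-unit mapping the
    configuration was loaded from, so dump -> load round-trips exactly.
    """

    particles: ParticleSpec
    environment: Environment
    field: DriveField
    lab_units: dict | None = field(default=None, compare=False, repr=False)

    def to_dict(self) -> dict:
        """Round-trippable laboratory-unit dictionary."""
        if self.lab_units is not None:
            return self.lab_units
        p, e, f = self.particles, self.environment, self.field
        return {
            "particles": {
                "mean_core_radius_nm": p.mean_core_radius * 1e9,
                "mean_hydro_radius_nm": p.mean_hydro_radius * 1e9,
                "size_cv": p.std_core_radius / p.mean_core_radius,
                "Ms_kA_per_m": p.saturation_magnetization / 1e3,
            },
            "environment": {
                "viscosity_mPa_s": e.viscosity * 1e3,
                "temperature_K": e.temperature,
                "density_kg_m3": e.density,
            },
            "field": {
                "amplitude_mT": f.amplitude * 1e3,
                "frequency_Hz": f.frequency,
            },
        }


def _validate_sections(raw: dict) -> list[str]:
    problems = []
    if not isinstance(raw, dict):
        return [f"top level must be a mapping with sections {sorted(_SCHEMA)}"]
    for section in _SCHEMA:
        if section not in raw:
            problems.append(f"missing section {section!r} "
                            f"(required keys: {sorted(_SCHEMA[section]['required'])})")
    for section in set(raw) - set(_SCHEMA):
        problems.append(f"unknown section {section!r}")
    for section, spec in _SCHEMA.items():
        block = raw.get(section)
        if block is None:
            continue
        if not isinstance(block, dict):
            problems.append(f"section {section!r} must be a mapping")
            continue
        for key in spec["required"] - set(block):
            problems.append(f"missing key {section}.{key}")
        for key in set(block) - spec["required"] - spec["optional"]:
            problems.append(f"unknown key {section}.{key}")
        for key, value in block.items():
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                problems.append(f"{section}.{key} must be a number, got {value!r}")
    return problems


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON configuration, converting to SI."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    problems = _validate_sections(raw if raw is not None else {})
    if problems:
        raise ValueError(
            "invalid configuration %s:\n  %s" % (path, "\n  ".join(problems))
        )
    p = raw["particles"]
    e = raw["environment"]
    f = raw["field"]
    cv = float(p.get("size_cv", ParticleSpec.DEFAULT_CV))
    if cv < 0:
        raise ValueError("particles.size_cv must be non-negative")
    mean_core = float(p["mean_core_radius_nm"]) * 1e-9
    mean_hydro = float(p["mean_hydro_radius_nm"]) * 1e-9
    lab_units = {
        "particles": {
            "mean_core_radius_nm": float(p["mean_core_radius_nm"]),
            "mean_hydro_radius_nm": float(p["mean_hydro_radius_nm"]),
            "size_cv": cv,
            "Ms_kA_per_m": float(p["Ms_kA_per_m"]),
        },
        "environment": {
            "viscosity_mPa_s": float(e["viscosity_mPa_s"]),
            "temperature_K": float(e.get("temperature_K", ROOM_TEMPERATURE)),
            "density_kg_m3": float(e.get("density_kg_m3", 1.0e3)),
        },
        "field": {
            "amplitude_mT": float(f["amplitude_mT"]),
            "frequency_Hz": float(f["frequency_Hz"]),
        },
    }
    return RunConfig(
        lab_units=lab_units,
        particles=ParticleSpec(
            mean_core_radius=mean_core,
            mean_hydro_radius=mean_hydro,
            std_core_radius=cv * mean_core,
            std_hydro_radius=cv * mean_hydro,
            saturation_magnetization=float(p["Ms_kA_per_m"]) * 1e3,
        ),
        environment=Environment(
            viscosity=float(e["viscosity_mPa_s"]) * 1e-3,
            temperature=float(e.get("temperature_K", ROOM_TEMPERATURE)),
            density=float(e.get("density_kg_m3", 1.0e3)),
        ),
        field=DriveField(
            amplitude=float(f["amplitude_mT"]) * 1e-3,
            frequency=float(f["frequency_Hz"]),
        ),
    )


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (load -> dump -> load is identity)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
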