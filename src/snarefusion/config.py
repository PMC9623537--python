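"""YAML run configuration: defaults, validation, and assembly of the
domain objects used by the command-line interface."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .assays import AssaySpec
from .encounter import EncounterParams
from .pore import PoreGeometry
from .units import InvalidParameterError, Medium, VesicleGeometry
from .zippering import ZipperingParams

__all__ = ["RunConfig", "ConfigError", "load_config", "validate_config", "default_config_dict"]

logger = logging.getLogger("snarefusion")

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Configuration file failed validation; message lists every problem."""


@dataclass(frozen=True)
class AssayConditions:
    """Assay-level settings that are not part of AssaySpec proper."""

    lipid_concentration_mm: float = 1.0
    t_fraction: float = 0.9
    snares_per_contact: float = 10.0
    prefactor_time_s: float = 1e-8
    # rounded per-collision dwell used in the published contact-time chain;
    # the mean-square-displacement estimate (d²/6D ≈ 1.9 μs) is computed
    # separately by encounter.contact_dwell_time and not silently reconciled
    dwell_per_collision_s: float = 1e-5


@dataclass(frozen=True)
class RunConfig:
    medium: Medium = field(default_factory=Medium)
    vesicle_geometry: VesicleGeometry = field(default_factory=VesicleGeometry)
    encounter: EncounterParams = field(default_factory=EncounterParams)
    zippering: ZipperingParams = field(default_factory=ZipperingParams)
    pore: PoreGeometry = field(default_factory=PoreGeometry)
    assay: AssaySpec = field(default_factory=AssaySpec)
    conditions: AssayConditions = field(default_factory=AssayConditions)
    output_dir: Path = Path("snarefusion_out")
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise InvalidParameterError("seed must be a non-negative integer")


_SECTIONS: dict[str, type] = {
    "medium": Medium,
    "vesicle_geometry": VesicleGeometry,
    "encounter": EncounterParams,
    "zippering": ZipperingParams,
    "pore": PoreGeometry,
    "assay": AssaySpec,
    "conditions": AssayConditions,
}
_TOP_LEVEL_SCALARS = {"schema_version", "output_dir", "seed", "verbose"}


def default_config_dict() -> dict[str, Any]:
    """The full default configuration as a plain dictionary."""
    out: dict[str, Any] = {"schema_version": CONFIG_SCHEMA_VERSION}
    for name, cls in _SECTIONS.items():
        out[name] = dataclasses.asdict(cls())
    out.update(output_dir="snarefusion_out", seed=0, verbose=False)
    return out


def _build_section(name: str, cls: type, data: dict[str, Any], errors: list[str]):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        errors.append(f"{name}: unknown keys {sorted(unknown)}")
        data = {k: v for k, v in data.items() if k in allowed}
    try:
        return cls(**data)
    except (InvalidParameterError, TypeError) as exc:
        errors.append(f"{name}: {exc}")
        return cls()


def validate_config(data: dict[str, Any] | None) -> RunConfig:
    """Validate a parsed configuration mapping into a RunConfig.

    Unknown keys are rejected; a missing section falls back to defaults
    with a logged warning; every validation failure is collected and
    reported in a single ConfigError.
    """
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    errors: list[str] = []
    unknown_top = set(data) - set(_SECTIONS) - _TOP_LEVEL_SCALARS
    if unknown_top:
        errors.append(f"unknown top-level keys {sorted(unknown_top)}")
    sections: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name not in data:
            logger.warning("config: missing section %r, defaults injected", name)
            sections[name] = cls()
            continue
        raw = data[name]
        if not isinstance(raw, dict):
            errors.append(f"{name}: must be a mapping")
            sections[name] = cls()
            continue
        sections[name] = _build_section(name, cls, raw, errors)
    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(
        medium=sections["medium"],
        vesicle_geometry=sections["vesicle_geometry"],
        encounter=sections["encounter"],
        zippering=sections["zippering"],
        pore=sections["pore"],
        assay=sections["assay"],
        conditions=sections["conditions"],
        output_dir=Path(data.get("output_dir", "snarefusion_out")),
        seed=int(data.get("seed", 0)),
        verbose=bool(data.get("verbose", False)),
    )


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config file; None gives pure defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"YAML parse error: {exc}") from exc
    return validate_config(data)
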