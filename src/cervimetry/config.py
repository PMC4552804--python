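"""Run configuration: YAML loading, validation and defaults.

A single YAML file drives the full pipeline; unknown keys are rejected and
every violation is reported with its path into the config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .elasto import DEFAULT_RHO, DEFAULT_QC_THRESHOLD
from .shgtex import DEFAULT_FT_THRESHOLD, DEFAULT_ROI_UM
from .synth import (SWEDesign, TrajectoryModel, FibreParams,
                    CONTROL_TRAJECTORY, TREATED_TRAJECTORY,
                    ALIGNED_FIBRES, DISORDERED_FIBRES)


class ConfigError(ValueError):
    """Raised with the full list of config violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of a full synthetic-study run."""

    seed: int = 0
    out_dir: str = "results"
    rho: float = DEFAULT_RHO
    qc_threshold: float = DEFAULT_QC_THRESHOLD
    ft_threshold: float = DEFAULT_FT_THRESHOLD
    roi_um: float = DEFAULT_ROI_UM
    n_qc_violations: int = 2
    n_fibre_images_per_group: int = 10
    design: SWEDesign = field(default_factory=SWEDesign)
    control_model: TrajectoryModel = field(default_factory=lambda: CONTROL_TRAJECTORY)
    treated_model: TrajectoryModel = field(default_factory=lambda: TREATED_TRAJECTORY)
    aligned_fibres: FibreParams = field(default_factory=lambda: ALIGNED_FIBRES)
    disordered_fibres: FibreParams = field(default_factory=lambda: DISORDERED_FIBRES)


_NESTED = {
    "design": SWEDesign,
    "control_model": TrajectoryModel,
    "treated_model": TrajectoryModel,
    "aligned_fibres": FibreParams,
    "disordered_fibres": FibreParams,
}


def _build_dataclass(cls, mapping: dict, path: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    for key in mapping:
        if key not in known:
            errors.append(f"{path}.{key}: unknown key")
    kwargs = {k: v for k, v in mapping.items() if k in known}
    if cls is SWEDesign and "hours" in kwargs:
        kwargs["hours"] = tuple(kwargs["hours"])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"{path}: {exc}")
        return None


def validate_config(raw: dict | None) -> RunConfig:
    """Normalise a raw config mapping into a :class:`RunConfig`.

    Unknown keys are rejected, defaults filled in, value ranges checked;
    all violations are collected into one :class:`ConfigError`.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"config.{key}: unknown key")
    kwargs = {}
    for name, cls in _NESTED.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                errors.append(f"config.{name}: expected a mapping")
            else:
                built = _build_dataclass(cls, raw[name], f"config.{name}", errors)
                if built is not None:
                    kwargs[name] = built
    for name in known - set(_NESTED):
        if name in raw:
            kwargs[name] = raw[name]
    for frac_key in ("qc_threshold", "ft_threshold"):
        if frac_key in kwargs and not (0.0 < float(kwargs[frac_key]) < 1.0):
            errors.append(f"config.{frac_key}: must be in (0, 1)")
    if "rho" in kwargs and float(kwargs["rho"]) <= 0:
        errors.append("config.rho: must be positive")
    if errors:
        raise ConfigError(errors)
    return RunConfig(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (None -> all defaults)."""
    if path is None:
        return validate_config({})
    raw = yaml.safe_load(Path(path).read_text())
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError(["config: top level must be a mapping"])
    return validate_config(raw)
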