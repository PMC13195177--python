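"""Run configuration: YAML schema, validation, defaults, round-tripping.

A single seed in the config governs phantom generation; the optimizer is
deterministic, so an entire run is reproducible from the config alone.
Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .controller import ControllerConfig, OrganClass
from .optimizer import OptimizerConfig
from .phantom import PhantomConfig


class ConfigError(ValueError):
    """Raised for schema violations in a run configuration."""


@dataclass(frozen=True)
class ArcConfig:
    start: float | None = None   # None -> laterality default (left 180-288, right 180-72)
    stop: float | None = None
    n_angles: int = 28
    beamlets_per_angle: int = 24
    margin_mm: float = 10.0
    source_distance_mm: float = 1000.0


@dataclass(frozen=True)
class KernelConfig:
    attenuation_per_mm: float = 0.005
    lateral_sigma_mm: float = 3.0
    halo_amplitude: float = 0.012
    halo_sigma_mm: float = 80.0


@dataclass(frozen=True)
class GridConfig:
    shape: tuple[int, int] = (128, 128)
    spacing_mm: float = 2.5
    slice_thickness_mm: float = 3.0


@dataclass(frozen=True)
class ClassConfig:
    target_ofv: float
    intercept: float = 0.8
    phase2_fraction: float = 0.5
    slope: float | None = None   # None -> derived as (1 - intercept) / target_ofv

    def resolved_slope(self) -> float:
        if self.slope is not None:
            return self.slope
        return (1.0 - self.intercept) / self.target_ofv


@dataclass(frozen=True)
class LoopConfig:
    max_outer_loops: int = 12
    saturation_tolerance: float = 0.025
    coverage_trigger_pct: float = 95.0
    repair_loops: int = 2
    max_eud_floor: float = 0.1
    ptv_weight: float = 3000.0
    oar_weight: float = 10.0


@dataclass(frozen=True)
class InnerConfig:
    inner_iterations: int = 40
    tolerance: float = 1e-9
    backend: str = "lbfgs"


@dataclass(frozen=True)
class RunConfig:
    """Complete description of one automated planning run."""

    laterality: str = "left"
    seed: int = 7
    prescription_gy: float = 50.0
    grid: GridConfig = GridConfig()
    arc: ArcConfig = ArcConfig()
    kernel: KernelConfig = KernelConfig()
    optimizer: InnerConfig = InnerConfig()
    controller: LoopConfig = LoopConfig()
    # Empirically calibrated defaults: class 1 = contralateral structures
    # (gentle updates, slope 0.44), class 2 = ipsilateral lung and heart
    # (aggressive, slope 0.089); both intercept 0.8.
    class1: ClassConfig = ClassConfig(target_ofv=0.45, phase2_fraction=0.5, slope=0.44)
    class2: ClassConfig = ClassConfig(target_ofv=2.25, phase2_fraction=0.2, slope=0.089)

    def __post_init__(self):
        if self.laterality not in ("left", "right"):
            raise ConfigError(f"laterality must be left|right, got {self.laterality!r}")
        if self.prescription_gy <= 0:
            raise ConfigError("prescription must be positive")
        if self.controller.ptv_weight <= 0 or self.controller.oar_weight <= 0:
            raise ConfigError("objective weights must be positive")

    # -- builders -----------------------------------------------------------

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(grid_shape=tuple(self.grid.shape),
                             spacing_mm=self.grid.spacing_mm,
                             slice_thickness_mm=self.grid.slice_thickness_mm)

    def organ_classes(self) -> tuple[OrganClass, OrganClass]:
        c1, c2 = self.class1, self.class2
        return (
            OrganClass("class1", ("lung_contra", "breast_contra"),
                       c1.resolved_slope(), c1.intercept, c1.target_ofv,
                       c1.phase2_fraction),
            OrganClass("class2", ("lung_ipsi", "heart"),
                       c2.resolved_slope(), c2.intercept, c2.target_ofv,
                       c2.phase2_fraction),
        )

    def controller_config(self) -> ControllerConfig:
        lc = self.controller
        return ControllerConfig(
            prescription=self.prescription_gy,
            max_outer_loops=lc.max_outer_loops,
            saturation_tolerance=lc.saturation_tolerance,
            coverage_trigger_pct=lc.coverage_trigger_pct,
            repair_loops=lc.repair_loops,
            max_eud_floor=lc.max_eud_floor,
            ptv_weight=lc.ptv_weight,
            oar_weight=lc.oar_weight,
            classes=self.organ_classes(),
            optimizer=OptimizerConfig(
                inner_iterations=self.optimizer.inner_iterations,
                tolerance=self.optimizer.tolerance,
                backend=self.optimizer.backend),
        )


_SECTIONS = {"grid": GridConfig, "arc": ArcConfig, "kernel": KernelConfig,
             "optimizer": InnerConfig, "controller": LoopConfig,
             "class1": ClassConfig, "class2": ClassConfig}


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys under {path!r}: {sorted(unknown)}")
    if cls is GridConfig and "shape" in data:
        data = dict(data, shape=tuple(data["shape"]))
    try:
        return cls(**data)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid section {path!r}: {err}") from err


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], dict(value), key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def config_to_dict(config: RunConfig) -> dict:
    data = asdict(config)
    data["grid"]["shape"] = list(data["grid"]["shape"])
    return data


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration, filling defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data if data is not None else {})


def dump_config(config: RunConfig, path: str | Path | None = None) -> str:
    """Serialize canonically (sorted keys) so round-trips are bit-identical."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
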