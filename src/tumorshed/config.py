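"""Model configuration: defaults, YAML/JSON loading, and test fixtures.

All literature-derived defaults live here in one serializable record.
Field names carry units (``sigma_um``, ``r_half_mm``) so that a config
file cannot silently change unit conventions.  Unknown keys are rejected
on load; every dataclass invariant is re-validated during construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import DensityParams, SpatialConfig, VascularizationParams
from .growth import MotilityParams
from .oxygen_rates import OxygenProfile, RateAnchors
from .shedding import ProteinParams

__all__ = [
    "ConfigError",
    "SimulationParams",
    "ModelConfig",
    "load_config",
    "save_config",
    "make_fixture_config",
    "FIXTURE_SCENARIOS",
]


class ConfigError(ValueError):
    """Raised for malformed or invariant-violating configuration input."""


@dataclass(frozen=True)
class SimulationParams:
    """Time grid and initial condition of the growth run."""

    dt_days: float = 1.0
    t_end_days: int = 4380  # 12 years on the daily grid
    p0_cells: float = 1.0
    capacity_enabled: bool = True  # False: unlimited compartments (closed-form checks)

    def __post_init__(self) -> None:
        if self.dt_days <= 0:
            raise ConfigError("dt_days must be > 0")
        if self.t_end_days < 0:
            raise ConfigError("t_end_days must be >= 0")
        if self.p0_cells <= 0:
            raise ConfigError("p0_cells must be > 0")


@dataclass(frozen=True)
class ModelConfig:
    """Fully resolved parameter set for one tumor/protein simulation."""

    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    vascular: VascularizationParams = field(default_factory=VascularizationParams)
    density: DensityParams = field(default_factory=DensityParams)
    oxygen: OxygenProfile = field(default_factory=OxygenProfile)
    anchors: RateAnchors = field(default_factory=RateAnchors)
    motility: MotilityParams = field(default_factory=MotilityParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    proteins: tuple[ProteinParams, ...] = field(
        default_factory=lambda: (
            ProteinParams(name="ec_reference", ec=1, phi=4.5e-4, psi=0.0,
                          t_half_days=6.4, u_h=456.0),
            ProteinParams(name="nonec_reference", ec=0, phi=0.0, psi=4.5e-4,
                          t_half_days=6.4, u_h=456.0),
        )
    )

    def to_dict(self) -> dict:
        d = {
            "spatial": dataclasses.asdict(self.spatial),
            "vascular": dataclasses.asdict(self.vascular),
            "density": dataclasses.asdict(self.density),
            "oxygen": dataclasses.asdict(self.oxygen),
            "anchors": dataclasses.asdict(self.anchors),
            "motility": dataclasses.asdict(self.motility),
            "simulation": dataclasses.asdict(self.simulation),
            "proteins": [dataclasses.asdict(p) for p in self.proteins],
        }
        return d


_SECTION_TYPES = {
    "spatial": SpatialConfig,
    "vascular": VascularizationParams,
    "density": DensityParams,
    "oxygen": OxygenProfile,
    "anchors": RateAnchors,
    "motility": MotilityParams,
    "simulation": SimulationParams,
}


def _build_section(name: str, cls, payload: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{name}'; "
            f"valid keys: {sorted(known)}"
        )
    try:
        return cls(**payload)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


def config_from_dict(data: dict) -> ModelConfig:
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - set(_SECTION_TYPES) - {"proteins"}
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build_section(name, cls, data[name] or {})
    if "proteins" in data:
        entries = data["proteins"] or []
        kwargs["proteins"] = tuple(
            _build_section(f"proteins[{i}]", ProteinParams, entry)
            for i, entry in enumerate(entries)
        )
    return ModelConfig(**kwargs)


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a YAML or JSON config file; with no path, return the defaults."""
    if path is None:
        return ModelConfig()
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        return ModelConfig()
    return config_from_dict(data)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def _single_compartment_malthusian() -> ModelConfig:
    # One uncapped compartment with no deaths and no motility: the growth
    # step reduces to P_{t+1} = (1 + kb) * P_t, checkable in closed form.
    anchors = RateAnchors(kb_low=5e-3, kb_high=5e-3, kd_low=0.0, kd_high=0.0)
    return ModelConfig(
        spatial=SpatialConfig(sigma_um=10.0, mvd_um=60.0, epsilon_um=10.0),
        anchors=anchors,
        motility=MotilityParams(p_in=0.0, p_out=0.0, p_out_boost=0.0),
        simulation=SimulationParams(t_end_days=200, capacity_enabled=False),
    )


def _xenograft() -> ModelConfig:
    base = ModelConfig()
    proteins = tuple(
        dataclasses.replace(p, u_h=0.0, q0=0.0) for p in base.proteins
    )
    return dataclasses.replace(
        base,
        proteins=proteins,
        simulation=SimulationParams(t_end_days=365),
    )


def _protein_corner_scan() -> ModelConfig:
    # Non-EC proteins at the corner values of the published three-way scan
    # (see experiments.DEFAULT_SCAN_*), alongside the EC reference.
    base = ModelConfig()
    corners = tuple(
        ProteinParams(name=f"nonec_psi{psi:g}_th{th:g}", ec=0, phi=0.0,
                      psi=psi, t_half_days=th, u_h=456.0)
        for psi in (1.423e-2, 4.5e2)
        for th in (0.64, 640.0)
    )
    return dataclasses.replace(base, proteins=(base.proteins[0],) + corners)


FIXTURE_SCENARIOS = {
    "defaults": ModelConfig,
    "single_compartment_malthusian": _single_compartment_malthusian,
    "xenograft": _xenograft,
    "protein_corner_scan": _protein_corner_scan,
}


def make_fixture_config(scenario: str) -> ModelConfig:
    """Small, fast configurations used throughout the test suite."""
    try:
        factory = FIXTURE_SCENARIOS[scenario]
    except KeyError:
        raise ConfigError(
            f"unknown scenario '{scenario}'; choose from {sorted(FIXTURE_SCENARIOS)}"
        ) from None
    return factory()
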