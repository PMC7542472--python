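"""Cylindrical discretization of the perivascular microenvironment.

The tumor tissue surrounding a vessel is modeled as a cylinder of radius
``R`` whose core (radius ``delta``, half the mean vessel diameter) is the
vessel itself.  The viable tissue annulus — the necrotic cuff of width
``epsilon`` beyond which oxygen cannot sustain cells — is partitioned into
``n`` concentric shells of single-cell thickness ``sigma``.  Each shell is
one compartment; its volume grows with the vascular height ``h_t``, which
increases linearly in time as the tumor recruits vasculature, and its
carrying capacity is the shell volume times cell density times packing
fraction.

All radial inputs are accepted in micrometres (the scale on which the
parameters are measured); internal volume arithmetic is done in millimetres
so that capacities are consistent with cell densities given per mm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "SpatialConfig",
    "VascularizationParams",
    "DensityParams",
    "map_radius_to_compartment",
    "compartment_midpoints",
    "shell_subvolumes",
    "vascular_height",
    "carrying_capacities",
]

UM_PER_MM = 1000.0


class GeometryError(ValueError):
    """Raised for radii outside the modeled annulus or invalid geometry."""


@dataclass(frozen=True)
class SpatialConfig:
    """Radial geometry of the perivascular cylinder.

    Parameters
    ----------
    sigma_um:
        Partition width (compartment thickness), ~ one cell diameter.
    mvd_um:
        Mean vessel diameter ``d``; the vascular core radius is ``d/2``.
    epsilon_um:
        Necrotic cuff: radial extent of viable tissue beyond the vessel
        wall.  Must be an integer multiple of ``sigma_um``.
    """

    sigma_um: float = 10.0
    mvd_um: float = 60.0
    epsilon_um: float = 100.0

    def __post_init__(self) -> None:
        for name in ("sigma_um", "mvd_um", "epsilon_um"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0, got {getattr(self, name)}")
        ratio = self.epsilon_um / self.sigma_um
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
            raise GeometryError(
                "epsilon_um must be an integer multiple of sigma_um "
                f"(epsilon={self.epsilon_um}, sigma={self.sigma_um})"
            )

    @property
    def delta_um(self) -> float:
        """Vascular core radius, half the mean vessel diameter."""
        return self.mvd_um / 2.0

    @property
    def n(self) -> int:
        """Number of concentric compartments."""
        return int(round(self.epsilon_um / self.sigma_um))

    @property
    def outer_radius_um(self) -> float:
        """Outer radius of the cylinder: core plus cuff."""
        return self.n * self.sigma_um + self.delta_um

    # mm views used by the volume arithmetic
    @property
    def sigma_mm(self) -> float:
        return self.sigma_um / UM_PER_MM

    @property
    def delta_mm(self) -> float:
        return self.delta_um / UM_PER_MM


@dataclass(frozen=True)
class VascularizationParams:
    """Linear vascular recruitment: the cylinder height grows as k_v * t.

    ``unit_length_mm`` fixes the physical length of one unit of height
    (default 1 mm, which makes volumes in mm^3 consistent with cell
    densities per mm^3).
    """

    k_v: float = 0.101
    unit_length_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.k_v < 0:
            raise GeometryError(f"k_v must be >= 0, got {self.k_v}")
        if self.unit_length_mm <= 0:
            raise GeometryError(f"unit_length_mm must be > 0, got {self.unit_length_mm}")


@dataclass(frozen=True)
class DensityParams:
    """Cellularity of solid tumor tissue."""

    rho_cells_per_mm3: float = 1e6
    p: float = 0.2  # fraction of tissue volume occupied by tumor cells

    def __post_init__(self) -> None:
        if self.rho_cells_per_mm3 <= 0:
            raise GeometryError(
                f"rho_cells_per_mm3 must be > 0, got {self.rho_cells_per_mm3}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise GeometryError(f"p must be in [0, 1], got {self.p}")


def map_radius_to_compartment(r_um: float, cfg: SpatialConfig) -> int:
    """Map a radial distance from the vessel wall to its compartment index.

    Distance ``r`` is measured outward from the vessel wall, so the viable
    annulus spans ``0 < r <= epsilon``.  Compartment ``i`` collects radii in
    ``((i-1)*sigma, i*sigma]``, i.e. the index is ``ceil(r / sigma)``.
    """
    if r_um <= 0 or r_um > cfg.epsilon_um:
        raise GeometryError(
            f"radius {r_um} um lies outside the tissue annulus (0, {cfg.epsilon_um}]"
        )
    return math.ceil(r_um / cfg.sigma_um)


def compartment_midpoints(cfg: SpatialConfig) -> np.ndarray:
    """Radial midpoints s_i = ((2i - 1)/2) * sigma, in micrometres.

    Rates and shedding weights are evaluated at these midpoints.
    """
    i = np.arange(1, cfg.n + 1, dtype=float)
    return (2.0 * i - 1.0) / 2.0 * cfg.sigma_um


def shell_subvolumes(cfg: SpatialConfig, h_mm: float) -> np.ndarray:
    """Volumes (mm^3) of the n concentric shells at vascular height ``h``.

    The innermost subvolume includes the vascular core, so that the total
    is exactly the full cylinder volume pi * (n*sigma + delta)^2 * h:

        v_1 = pi * (sigma + delta)^2 * h
        v_i = pi * [(2i - 1) * sigma^2 + 2 * sigma * delta] * h,  i >= 2

    The closed form for i >= 2 also satisfies the ratio recurrence
    v_i = [((2i-1)sigma + 2delta) / ((2i-3)sigma + 2delta)] * v_{i-1}.
    """
    if h_mm < 0:
        raise GeometryError(f"height must be >= 0, got {h_mm}")
    s, d = cfg.sigma_mm, cfg.delta_mm
    i = np.arange(1, cfg.n + 1, dtype=float)
    v = math.pi * ((2.0 * i - 1.0) * s * s + 2.0 * s * d) * h_mm
    v[0] = math.pi * (s + d) ** 2 * h_mm  # innermost shell includes the core
    return v


def vascular_height(t_days: float, vp: VascularizationParams) -> float:
    """Vascular height h_t = k_v * t, in mm. Nondecreasing in t."""
    if t_days < 0:
        raise GeometryError(f"time must be >= 0, got {t_days}")
    return vp.k_v * t_days * vp.unit_length_mm


def carrying_capacities(v_mm3: np.ndarray, dp: DensityParams) -> np.ndarray:
    """Cell capacity of each shell: K_i = v_i * rho * p (real-valued)."""
    v = np.asarray(v_mm3, dtype=float)
    if np.any(v < 0):
        raise GeometryError("volumes must be >= 0")
    return v * dp.rho_cells_per_mm3 * dp.p
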