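"""Oxygen gradient and per-compartment kinetic rates.

Oxygen decays exponentially with radial distance from the vessel wall with
a characteristic half-distance ``r_half`` (near-anoxia at the ~100 um edge
of the necrotic cuff).  Birth and death rates measured in vitro at two
oxygen tensions (hypoxic 1% and normoxic 20% culture) anchor straight lines
that are evaluated — extrapolating linearly outside the measured range,
then clamping at zero — at the oxygen level of each compartment midpoint.
Death decreases with oxygen, birth increases, so the net growth rate
kg = kb - kd falls monotonically with distance from the vessel: inner
compartments proliferate, outer ones necrose.

Shedding weights w_i = 1/sqrt(s_i) (midpoint in um) approximate the
one-dimensional diffusive attenuation of protein transported from a
compartment back to the vasculature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import SpatialConfig, compartment_midpoints, UM_PER_MM

__all__ = [
    "OxygenProfile",
    "RateAnchors",
    "CompartmentRates",
    "oxygen_at",
    "interpolate_rates",
    "shedding_weights",
    "compartment_rate_table",
]


@dataclass(frozen=True)
class OxygenProfile:
    """Exponential-decay oxygen profile C(r) = c0 * 0.5**(r / r_half)."""

    c0_pct: float = 16.0
    r_half_mm: float = 0.018

    def __post_init__(self) -> None:
        if self.c0_pct <= 0:
            raise ValueError(f"c0_pct must be > 0, got {self.c0_pct}")
        if self.r_half_mm <= 0:
            raise ValueError(f"r_half_mm must be > 0, got {self.r_half_mm}")


@dataclass(frozen=True)
class RateAnchors:
    """Birth/death rates (day^-1) measured at two culture oxygen levels.

    ``*_low`` values were measured at ``c_low_pct`` oxygen (hypoxic
    condition), ``*_high`` at ``c_high_pct`` (normoxic).  Note death is
    highest in the hypoxic condition: kd_low > kd_high.
    """

    c_low_pct: float = 1.0
    c_high_pct: float = 20.0
    kb_low: float = 7.8e-4
    kb_high: float = 8.2e-3
    kd_low: float = 1.6e-3
    kd_high: float = 0.0

    def __post_init__(self) -> None:
        if not self.c_low_pct < self.c_high_pct:
            raise ValueError("c_low_pct must be < c_high_pct")
        for name in ("kb_low", "kb_high", "kd_low", "kd_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CompartmentRates:
    """Per-compartment kinetic rates and shedding weights."""

    kb: np.ndarray  # birth rates, day^-1
    kd: np.ndarray  # death rates, day^-1
    kg: np.ndarray  # net growth rates kb - kd, day^-1
    w: np.ndarray   # dimensionless diffusion weights, strictly decreasing

    @property
    def n(self) -> int:
        return len(self.kb)


def oxygen_at(r_mm: float | np.ndarray, ox: OxygenProfile) -> float | np.ndarray:
    """Oxygen concentration (%) at radial distance r (mm) from the vessel wall."""
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance must be >= 0")
    out = ox.c0_pct * 0.5 ** (r / ox.r_half_mm)
    return float(out) if np.isscalar(r_mm) else out


def interpolate_rates(
    c_pct: float | np.ndarray, anchors: RateAnchors
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(birth, death, net) rates at oxygen level(s) ``c_pct``.

    Each rate is the straight line through its two measured anchor points,
    extrapolated linearly outside the measured oxygen span and clamped
    below at zero (negative per-capita birth or death rates are
    meaningless in the difference equations).  The net rate is the
    difference of the clamped components.
    """
    c = np.asarray(c_pct, dtype=float)
    dc = anchors.c_high_pct - anchors.c_low_pct
    mb = (anchors.kb_high - anchors.kb_low) / dc
    md = (anchors.kd_high - anchors.kd_low) / dc
    kb = np.maximum(anchors.kb_low + mb * (c - anchors.c_low_pct), 0.0)
    kd = np.maximum(anchors.kd_low + md * (c - anchors.c_low_pct), 0.0)
    return kb, kd, kb - kd


def shedding_weights(midpoints_um: np.ndarray) -> np.ndarray:
    """Diffusive attenuation weights w_i = 1 / sqrt(s_i), s_i in um."""
    s = np.asarray(midpoints_um, dtype=float)
    if np.any(s <= 0):
        raise ValueError("compartment midpoints must be > 0")
    return 1.0 / np.sqrt(s)


def compartment_rate_table(
    cfg: SpatialConfig, ox: OxygenProfile, anchors: RateAnchors
) -> CompartmentRates:
    """Evaluate oxygen and rates at every compartment midpoint."""
    s_um = compartment_midpoints(cfg)
    c = oxygen_at(s_um / UM_PER_MM, ox)
    kb, kd, kg = interpolate_rates(c, anchors)
    return CompartmentRates(kb=kb, kd=kd, kg=kg, w=shedding_weights(s_um))


def rate_table_frame(
    cfg: SpatialConfig, ox: OxygenProfile, anchors: RateAnchors
) -> pd.DataFrame:
    """Tabular view of the rate profile for export or inspection."""
    s_um = compartment_midpoints(cfg)
    rates = compartment_rate_table(cfg, ox, anchors)
    return pd.DataFrame(
        {
            "compartment": np.arange(1, cfg.n + 1),
            "s_um": s_um,
            "C_pct": oxygen_at(s_um / UM_PER_MM, ox),
            "kB": rates.kb,
            "kD": rates.kd,
            "kG": rates.kg,
            "w": rates.w,
        }
    )
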