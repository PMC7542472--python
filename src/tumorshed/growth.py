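"""Per-compartment tumor population dynamics on a daily grid.

Each compartment carries a real-valued proliferative population advanced by
a forward-Euler step of the Malthusian model with its local net growth
rate.  A day's update is, in fixed order:

1. capacities are refreshed from the vascular height at the new day;
2. births ``kb * dt * P`` and deaths ``kd * dt * P`` are applied;
3. an inner-to-outer overflow sweep displaces cells in excess of a
   compartment's carrying capacity one compartment outward (the outermost
   compartment is uncapped and retains its excess);
4. deterministic motility fractions exchange cells between neighbors,
   with inward movement favored (toward oxygen) and outward movement
   boosted when a compartment dwarfs its outer neighbor tenfold or that
   neighbor is empty (so the growth front can advance).

Dead cells are cleared instantly: they occupy no capacity and are tracked
only as instantaneous and cumulative death counts.  Every exchange
(overflow, motility) is internally conservative, so per step
``sum(P_new) - sum(P_old) == sum(births) - sum(deaths)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    DensityParams,
    SpatialConfig,
    VascularizationParams,
    carrying_capacities,
    shell_subvolumes,
    vascular_height,
)
from .oxygen_rates import CompartmentRates

__all__ = [
    "MotilityParams",
    "GrowthState",
    "GrowthTrajectory",
    "SimulationError",
    "compute_overflow",
    "apply_motility",
    "step_growth",
    "simulate_growth",
    "necrotic_fraction",
]


class SimulationError(RuntimeError):
    """Raised when populations become non-finite."""


@dataclass(frozen=True)
class MotilityParams:
    """Deterministic daily exchange fractions between adjacent compartments.

    ``p_in`` of each compartment moves one compartment inward (toward the
    better-oxygenated vessel side); ``p_out`` moves outward, boosted to
    ``p_out_boost`` when the donor is at least ``fold_threshold`` times the
    outer neighbor's population, or the neighbor is empty.
    """

    p_in: float = 0.10
    p_out: float = 0.05
    p_out_boost: float = 0.10
    fold_threshold: float = 10.0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "p_out_boost"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_in + max(self.p_out, self.p_out_boost) > 1.0:
            raise ValueError("p_in + max(p_out, p_out_boost) must be <= 1")
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be > 0")


@dataclass(frozen=True)
class GrowthState:
    """Snapshot of the compartment system at one day."""

    t: int
    P: np.ndarray        # proliferative populations (cells)
    B_inst: np.ndarray   # births this step
    D_inst: np.ndarray   # deaths this step
    D_cum: np.ndarray    # cumulative deaths
    K: np.ndarray        # carrying capacities (cells)
    h_mm: float          # vascular height

    @property
    def n(self) -> int:
        return len(self.P)


@dataclass
class GrowthTrajectory:
    """Columnar record of a growth run: arrays indexed [day, compartment]."""

    t: np.ndarray        # day indices, 0..t_end
    P: np.ndarray
    B_inst: np.ndarray
    D_inst: np.ndarray
    D_cum: np.ndarray
    K: np.ndarray
    h_mm: np.ndarray

    @property
    def n(self) -> int:
        return self.P.shape[1]

    @property
    def total_P(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def total_D_cum(self) -> np.ndarray:
        return self.D_cum.sum(axis=1)

    @property
    def total_D_inst(self) -> np.ndarray:
        return self.D_inst.sum(axis=1)

    def state_at(self, t: int) -> GrowthState:
        return GrowthState(
            t=int(self.t[t]), P=self.P[t], B_inst=self.B_inst[t],
            D_inst=self.D_inst[t], D_cum=self.D_cum[t], K=self.K[t],
            h_mm=float(self.h_mm[t]),
        )

    def by_compartment_frame(self) -> pd.DataFrame:
        """Long format: one row per (day, compartment)."""
        T, n = self.P.shape
        days = np.repeat(self.t, n)
        comp = np.tile(np.arange(1, n + 1), T)
        return pd.DataFrame(
            {
                "t_day": days,
                "comp": comp,
                "P": self.P.ravel(),
                "D_inst": self.D_inst.ravel(),
                "D_cum": self.D_cum.ravel(),
                "K": self.K.ravel(),
                "h_mm": np.repeat(self.h_mm, n),
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_day": self.t,
                "P_total": self.total_P,
                "D_total_inst": self.total_D_inst,
                "D_cum_total": self.total_D_cum,
                "necrotic_fraction": necrotic_fraction(self),
            }
        )


def compute_overflow(P: float, K: float) -> float:
    """Cells in excess of capacity (strict inequality: P == K overflows nothing)."""
    return P - K if P > K else 0.0


def apply_motility(P: np.ndarray, mp: MotilityParams) -> np.ndarray:
    """One day of deterministic inter-compartment movement.

    All fluxes are computed from the pre-move populations and applied
    simultaneously; the total population is conserved exactly.
    """
    P = np.asarray(P, dtype=float)
    n = len(P)
    if n == 1:
        return P.copy()
    inward = np.zeros(n)
    outward = np.zeros(n)
    inward[1:] = mp.p_in * P[1:]
    for i in range(n - 1):
        boosted = (P[i + 1] > 0 and P[i] >= mp.fold_threshold * P[i + 1]) or (
            P[i + 1] == 0 and P[i] > 0
        )
        outward[i] = (mp.p_out_boost if boosted else mp.p_out) * P[i]
    new = P - inward - outward
    new[:-1] += inward[1:]
    new[1:] += outward[:-1]
    return new


def _capacities_at(
    t: float,
    cfg: SpatialConfig,
    vp: VascularizationParams,
    dp: DensityParams,
    capacity_enabled: bool,
) -> tuple[np.ndarray, float]:
    h = vascular_height(t, vp)
    if capacity_enabled:
        K = carrying_capacities(shell_subvolumes(cfg, h), dp)
    else:
        K = np.full(cfg.n, np.inf)
    return K, h


def step_growth(
    state: GrowthState,
    rates: CompartmentRates,
    cfg: SpatialConfig,
    vp: VascularizationParams,
    dp: DensityParams,
    mp: MotilityParams,
    dt: float = 1.0,
    capacity_enabled: bool = True,
) -> GrowthState:
    """Advance the compartment system by one day (t -> t + dt)."""
    K, h = _capacities_at(state.t + dt, cfg, vp, dp, capacity_enabled)

    B = rates.kb * dt * state.P
    D = rates.kd * dt * state.P
    P = state.P + B - D

    # inner-to-outer overflow sweep; compartment n is uncapped
    for i in range(len(P) - 1):
        O = compute_overflow(P[i], K[i])
        P[i] -= O
        P[i + 1] += O

    P = apply_motility(P, mp)

    if not np.all(np.isfinite(P)):
        raise SimulationError(f"non-finite population at day {state.t + dt}")
    return GrowthState(
        t=state.t + 1, P=P, B_inst=B, D_inst=D,
        D_cum=state.D_cum + D, K=K, h_mm=h,
    )


def simulate_growth(
    cfg: SpatialConfig,
    vp: VascularizationParams,
    dp: DensityParams,
    rates: CompartmentRates,
    mp: MotilityParams,
    t_end: int,
    p0: float = 1.0,
    dt: float = 1.0,
    capacity_enabled: bool = True,
) -> GrowthTrajectory:
    """Run the daily difference equations from a seed of ``p0`` cells.

    The seed is placed in the innermost compartment at t=0, when the
    vascular height (hence every capacity) is still zero; capacities first
    bind during the step to t=1, so the seed is never overflowed away.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if p0 <= 0:
        raise ValueError("p0 must be > 0")
    n = cfg.n
    if rates.n != n:
        raise ValueError(f"rate table has {rates.n} compartments, geometry has {n}")

    T = int(t_end) + 1
    traj = GrowthTrajectory(
        t=np.arange(T),
        P=np.zeros((T, n)),
        B_inst=np.zeros((T, n)),
        D_inst=np.zeros((T, n)),
        D_cum=np.zeros((T, n)),
        K=np.zeros((T, n)),
        h_mm=np.zeros(T),
    )
    K0, h0 = _capacities_at(0.0, cfg, vp, dp, capacity_enabled)
    state = GrowthState(
        t=0, P=np.zeros(n), B_inst=np.zeros(n), D_inst=np.zeros(n),
        D_cum=np.zeros(n), K=K0, h_mm=h0,
    )
    state.P[0] = p0
    traj.P[0] = state.P
    traj.K[0] = K0
    traj.h_mm[0] = h0

    for t in range(1, T):
        state = step_growth(state, rates, cfg, vp, dp, mp, dt, capacity_enabled)
        traj.P[t] = state.P
        traj.B_inst[t] = state.B_inst
        traj.D_inst[t] = state.D_inst
        traj.D_cum[t] = state.D_cum
        traj.K[t] = state.K
        traj.h_mm[t] = state.h_mm
    return traj


def necrotic_fraction(traj: GrowthTrajectory) -> np.ndarray:
    """Cumulative deaths over all cells accounted for, per day, in [0, 1]."""
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    dead = traj.total_D_cum
    total = dead + traj.total_P
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, dead / np.where(total > 0, total, 1.0), 0.0)
    return frac
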