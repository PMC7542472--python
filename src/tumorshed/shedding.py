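"""Protein outflux from tumor compartments and one-compartment plasma kinetics.

A protein species is either extracellular (EC=1: actively shed by viable
cells at a per-cell rate Phi) or non-extracellular (EC=0: released at Psi
units per dying cell, so its source is necrosis).  The compartmental
outflux is attenuated by the distance weight w_i, and all outfluxes feed a
single plasma compartment with constant healthy-tissue influx u_H and
first-order elimination k_E = ln(2)/t_half:

    q_{t+1} = sum_i(u_{i,t}) * dt + u_H * dt + (1 - k_E * dt) * q_t

Shedding never feeds back on growth, so many proteins can be evaluated
against one cached growth trajectory.  Half-lives short enough that
k_E * dt >= 1 (where the daily Euler step would oscillate or go negative)
are handled by uniform sub-stepping of the plasma recurrence only — the
populations stay on the daily grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthState, GrowthTrajectory
from .oxygen_rates import CompartmentRates

__all__ = [
    "StabilityError",
    "ProteinParams",
    "SheddingTrajectory",
    "elimination_rate",
    "plasma_substeps",
    "compartment_outflux",
    "step_plasma",
    "simulate_shedding",
]


class StabilityError(ValueError):
    """Euler step too large for the protein's elimination rate."""


def elimination_rate(t_half_days: float, dt: float | None = None) -> float:
    """First-order plasma elimination rate k_E = ln(2) / t_half (day^-1).

    When ``dt`` is given, raises :class:`StabilityError` if ``k_E * dt >= 1``
    — the undamped daily recurrence would oscillate; callers wanting such
    short half-lives must sub-step (see :func:`plasma_substeps`).
    """
    if t_half_days <= 0:
        raise ValueError(f"t_half_days must be > 0, got {t_half_days}")
    k_e = math.log(2.0) / t_half_days
    if dt is not None and k_e * dt >= 1.0:
        raise StabilityError(
            f"k_E * dt = {k_e * dt:.3g} >= 1: daily Euler step unstable for "
            f"t_half = {t_half_days} days; sub-step the plasma recurrence"
        )
    return k_e


def plasma_substeps(k_e: float, dt: float = 1.0) -> int:
    """Substep count for a stable plasma update.

    1 while ``k_E * dt < 1``; otherwise the smallest m with
    ``k_E * dt / m <= 0.5``.
    """
    if k_e * dt < 1.0:
        return 1
    return max(1, math.ceil(k_e * dt / 0.5))


@dataclass(frozen=True)
class ProteinParams:
    """Shedding-relevant description of one protein species.

    ``phi`` is the per-viable-cell shedding rate (U/cell/day, drives the
    EC route); ``psi`` the per-dying-cell release (U/cell, drives the
    non-EC route); ``u_h`` the constant influx from healthy tissue (zero
    in xenograft settings where the tracked human protein is
    non-endogenous to the host).  ``q0`` defaults to the healthy steady
    state u_h / k_E so that tumor-free runs are flat.
    """

    name: str = "protein"
    ec: int = 1
    phi: float = 4.5e-4
    psi: float = 4.5e-4
    t_half_days: float = 6.4
    u_h: float = 456.0
    q0: float | None = None

    def __post_init__(self) -> None:
        if self.ec not in (0, 1):
            raise ValueError(f"ec must be 0 or 1, got {self.ec}")
        for name in ("phi", "psi", "u_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t_half_days <= 0:
            raise ValueError("t_half_days must be > 0")
        if self.q0 is not None and self.q0 < 0:
            raise ValueError("q0 must be >= 0")

    @property
    def k_e(self) -> float:
        return elimination_rate(self.t_half_days)

    def resolve_q0(self) -> float:
        """Initial plasma mass: the healthy steady state unless overridden."""
        if self.q0 is not None:
            return self.q0
        return self.u_h / self.k_e


@dataclass
class SheddingTrajectory:
    """Per-day compartmental outflux and plasma mass for one protein."""

    t: np.ndarray      # day indices
    u: np.ndarray      # outflux per compartment, U/day, shape (T, n)
    q: np.ndarray      # plasma mass, U, shape (T,)
    protein: ProteinParams

    @property
    def u_total(self) -> np.ndarray:
        return self.u.sum(axis=1)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_day": self.t, "q": self.q, "u_total": self.u_total})
        for i in range(self.u.shape[1]):
            df[f"u_{i + 1}"] = self.u[:, i]
        return df


def compartment_outflux(
    state: GrowthState,
    rates: CompartmentRates,
    pp: ProteinParams,
    dt: float = 1.0,
) -> np.ndarray:
    """Per-compartment protein outflux (U/day) for one day's state."""
    if len(state.P) != rates.n:
        raise ValueError("state and rate table disagree on compartment count")
    if pp.ec == 1:
        return rates.w * pp.phi * state.P
    return rates.w * pp.psi * (state.D_inst / dt)


def step_plasma(
    q: float,
    u_total: float,
    pp: ProteinParams,
    dt: float = 1.0,
    substeps: int | None = None,
) -> float:
    """One day of the plasma mass recurrence, sub-stepped if requested."""
    k_e = pp.k_e
    m = plasma_substeps(k_e, dt) if substeps is None else substeps
    h = dt / m
    for _ in range(m):
        q = (u_total + pp.u_h) * h + (1.0 - k_e * h) * q
    return q


def simulate_shedding(
    traj: GrowthTrajectory,
    rates: CompartmentRates,
    pp: ProteinParams,
    dt: float = 1.0,
) -> SheddingTrajectory:
    """Integrate plasma mass over a finished growth trajectory.

    The outflux at day t is computed from the day-t populations (EC) or
    deaths (non-EC) and drives the plasma update from q_t to q_{t+1}; the
    growth system never sees the plasma, so the two are run in series.
    """
    if traj.n != rates.n:
        raise ValueError("trajectory and rate table disagree on compartment count")
    T = len(traj.t)
    u = np.empty((T, traj.n))
    if pp.ec == 1:
        u[:] = rates.w[None, :] * pp.phi * traj.P
    else:
        u[:] = rates.w[None, :] * pp.psi * (traj.D_inst / dt)

    q = np.empty(T)
    q[0] = pp.resolve_q0()
    m = plasma_substeps(pp.k_e, dt)
    for t in range(T - 1):
        q[t + 1] = step_plasma(q[t], u[t].sum(), pp, dt, substeps=m)
    return SheddingTrajectory(t=traj.t.copy(), u=u, q=q, protein=pp)
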