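"""Computational experiments on the coupled growth/shedding model.

These are the analyses a user runs on top of the simulator: a validity
grid scan over the vascularization rate and peak oxygen level with a
run-selection rule, one-at-a-time sensitivity sweeps, per-compartment
contribution decompositions, and combinatorial protein-parameter scans
summarized as dynamic-range envelopes.  Everything is deterministic:
repeating a scan with the same configuration yields identical tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig
from .geometry import VascularizationParams
from .growth import GrowthTrajectory, simulate_growth, necrotic_fraction
from .oxygen_rates import OxygenProfile, compartment_rate_table
from .shedding import ProteinParams, SheddingTrajectory, simulate_shedding

__all__ = [
    "ValidityCriteria",
    "ScanResult",
    "run_growth",
    "run_shedding",
    "grid_scan_growth",
    "select_valid_run",
    "sensitivity_sweep",
    "per_compartment_decomposition",
    "protein_scan_envelopes",
    "growth_inflection_day",
    "DEFAULT_SCAN_UH",
    "DEFAULT_SCAN_THALF",
    "DEFAULT_SCAN_PSI",
    "SWEEP_PARAMS",
]

# corner grids of the published three-parameter protein scan
DEFAULT_SCAN_UH = (4.56e0, 4.56e2, 4.56e4)
DEFAULT_SCAN_THALF = (0.64, 20.24, 640.0)
DEFAULT_SCAN_PSI = (1.423e-2, 2.531e0, 4.5e2)


@dataclass(frozen=True)
class ValidityCriteria:
    """What counts as a biologically plausible simulated tumor.

    A run is valid when the final total population reaches
    ``min_final_population`` and (optionally) every compartment holds more
    than ``populated_threshold`` cells at the end of the run.
    """

    min_final_population: float = 1e7
    require_all_compartments: bool = True
    t_end_days: int = 4380
    populated_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.min_final_population <= 0:
            raise ValueError("min_final_population must be > 0")


@dataclass
class ScanResult:
    """Outcome of a (k_v, c0) grid scan.

    ``table`` has one row per grid cell with the final population, the
    populated-compartment count, the validity flag and a failure reason;
    ``selected`` is the chosen (k_v, c0) pair or None when no cell is valid.
    """

    table: pd.DataFrame
    criteria: ValidityCriteria
    selected: tuple[float, float] | None = None


def run_growth(cfg: ModelConfig, t_end: int | None = None) -> GrowthTrajectory:
    """Simulate growth under a full model configuration."""
    rates = compartment_rate_table(cfg.spatial, cfg.oxygen, cfg.anchors)
    sim = cfg.simulation
    return simulate_growth(
        cfg.spatial, cfg.vascular, cfg.density, rates, cfg.motility,
        t_end=sim.t_end_days if t_end is None else t_end,
        p0=sim.p0_cells, dt=sim.dt_days,
        capacity_enabled=sim.capacity_enabled,
    )


def run_shedding(
    cfg: ModelConfig, traj: GrowthTrajectory
) -> dict[str, SheddingTrajectory]:
    """Evaluate every configured protein against one growth trajectory."""
    rates = compartment_rate_table(cfg.spatial, cfg.oxygen, cfg.anchors)
    return {
        p.name: simulate_shedding(traj, rates, p, dt=cfg.simulation.dt_days)
        for p in cfg.proteins
    }


def grid_scan_growth(
    kv_values,
    c0_values,
    criteria: ValidityCriteria,
    base: ModelConfig,
) -> ScanResult:
    """Run one growth simulation per (k_v, c0) pair and flag valid tumors.

    A simulation failure (including degenerate parameters such as k_v = 0,
    which pins every capacity at zero) marks the cell invalid with the
    reason recorded; it never aborts the scan.
    """
    rows = []
    for kv in kv_values:
        for c0 in c0_values:
            row = {
                "k_v": float(kv), "c0": float(c0),
                "final_population": np.nan, "populated_compartments": 0,
                "valid": False, "reason": "",
            }
            try:
                cfg = dataclasses.replace(
                    base,
                    vascular=dataclasses.replace(base.vascular, k_v=float(kv)),
                    oxygen=dataclasses.replace(base.oxygen, c0_pct=float(c0)),
                )
                traj = run_growth(cfg, t_end=criteria.t_end_days)
            except Exception as exc:  # noqa: BLE001 — scan cells fail soft
                row["reason"] = f"simulation failed: {exc}"
                rows.append(row)
                continue
            final_P = traj.P[-1]
            total = float(final_P.sum())
            populated = int((final_P > criteria.populated_threshold).sum())
            row["final_population"] = total
            row["populated_compartments"] = populated
            ok_pop = total >= criteria.min_final_population
            ok_comp = (not criteria.require_all_compartments) or populated == traj.n
            row["valid"] = bool(ok_pop and ok_comp)
            if not ok_pop:
                row["reason"] = "final population below cutoff"
            elif not ok_comp:
                row["reason"] = "not all compartments populated"
            rows.append(row)
    result = ScanResult(table=pd.DataFrame(rows), criteria=criteria)
    result.selected = select_valid_run(result)
    return result


def select_valid_run(scan: ScanResult) -> tuple[float, float] | None:
    """Pick the valid pair with the smallest final population.

    The smallest valid tumor is the most necrotic one that still clears
    the criteria.  Ties break on smaller k_v, then smaller c0.  Returns
    None when no grid cell is valid ("no valid tumor").
    """
    valid = scan.table[scan.table["valid"]]
    if valid.empty:
        return None
    ordered = valid.sort_values(
        ["final_population", "k_v", "c0"], kind="mergesort"
    )
    top = ordered.iloc[0]
    return (float(top["k_v"]), float(top["c0"]))


# name -> how to apply the value to a ModelConfig
SWEEP_PARAMS = ("k_v", "c0", "phi_or_psi", "t_half", "u_h")


def _apply_sweep_value(cfg: ModelConfig, name: str, value: float) -> ModelConfig:
    if name == "k_v":
        return dataclasses.replace(
            cfg, vascular=dataclasses.replace(cfg.vascular, k_v=value)
        )
    if name == "c0":
        return dataclasses.replace(
            cfg, oxygen=dataclasses.replace(cfg.oxygen, c0_pct=value)
        )
    if name == "phi_or_psi":
        proteins = tuple(
            dataclasses.replace(p, phi=value) if p.ec == 1
            else dataclasses.replace(p, psi=value)
            for p in cfg.proteins
        )
        return dataclasses.replace(cfg, proteins=proteins)
    if name == "t_half":
        proteins = tuple(
            dataclasses.replace(p, t_half_days=value) for p in cfg.proteins
        )
        return dataclasses.replace(cfg, proteins=proteins)
    if name == "u_h":
        proteins = tuple(
            dataclasses.replace(p, u_h=value) for p in cfg.proteins
        )
        return dataclasses.replace(cfg, proteins=proteins)
    raise ValueError(f"unknown sweep parameter '{name}'; valid: {SWEEP_PARAMS}")


@dataclass
class SweepEntry:
    """One member of a one-at-a-time sensitivity family."""

    param: str
    value: float
    growth: GrowthTrajectory
    shedding: dict[str, SheddingTrajectory] | None = None


def sensitivity_sweep(
    param_name: str,
    values,
    base: ModelConfig,
    mode: str = "growth",
) -> list[SweepEntry]:
    """One-at-a-time sweep: vary one parameter, pin everything else.

    ``mode='growth'`` returns only growth trajectories; ``mode='shedding'``
    also evaluates every configured protein.  Growth-side parameters
    (k_v, c0) rerun the growth model per value; protein-side parameters
    reuse a single cached growth trajectory, since shedding never feeds
    back on growth.
    """
    if param_name not in SWEEP_PARAMS:
        raise ValueError(
            f"unknown sweep parameter '{param_name}'; valid: {SWEEP_PARAMS}"
        )
    if mode not in ("growth", "shedding"):
        raise ValueError("mode must be 'growth' or 'shedding'")
    growth_side = param_name in ("k_v", "c0")
    cached = None if growth_side else run_growth(base)
    out = []
    for value in values:
        cfg = _apply_sweep_value(base, param_name, float(value))
        traj = run_growth(cfg) if growth_side else cached
        shed = run_shedding(cfg, traj) if mode == "shedding" else None
        out.append(SweepEntry(param=param_name, value=float(value),
                              growth=traj, shedding=shed))
    return out


def per_compartment_decomposition(
    traj: GrowthTrajectory,
    shed: SheddingTrajectory | None = None,
) -> pd.DataFrame:
    """Per-day share of each compartment in P, instantaneous deaths and outflux.

    Long format: one row per (day, compartment) with absolute values and
    shares; shares of a quantity sum to 1 at every day where its total is
    positive, and the absolute columns sum to the totals exactly.
    """
    T, n = traj.P.shape
    frame = traj.by_compartment_frame()[["t_day", "comp", "P", "D_inst"]]

    def shares(x: np.ndarray) -> np.ndarray:
        tot = x.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, x / np.where(tot > 0, tot, 1.0), 0.0)

    frame["P_share"] = shares(traj.P).ravel()
    frame["D_share"] = shares(traj.D_inst).ravel()
    if shed is not None:
        if shed.u.shape != traj.P.shape:
            raise ValueError("shedding trajectory is not aligned with growth")
        frame["u"] = shed.u.ravel()
        frame["u_share"] = shares(shed.u).ravel()
    return frame


@dataclass
class EnvelopeResult:
    """Dynamic-range envelope of a protein scan at one healthy-influx level."""

    u_h: float
    t: np.ndarray
    q_min: np.ndarray
    q_max: np.ndarray
    corner_min: tuple[float, float]  # (psi, t_half) attaining the lower bound
    corner_max: tuple[float, float]
    crossover_day: int | None  # first day q_max exceeds the EC reference
    grid: dict[tuple[float, float], np.ndarray]  # all scanned trajectories


def protein_scan_envelopes(
    traj: GrowthTrajectory,
    rates,
    psi_values=DEFAULT_SCAN_PSI,
    uh_values=DEFAULT_SCAN_UH,
    thalf_values=DEFAULT_SCAN_THALF,
    ec_reference: ProteinParams | None = None,
    dt: float = 1.0,
) -> list[EnvelopeResult]:
    """Scan non-EC protein parameters and summarize min/max plasma envelopes.

    For every healthy influx u_h, all (psi, t_half) combinations are
    simulated; the pointwise min and max trajectories bound the dynamic
    range.  Because plasma mass is monotone in both psi and t_half, the
    bounds coincide with the corner trajectories.  When an EC reference
    protein is given, the first day its trajectory is exceeded by the
    envelope's upper bound is reported (None if never).
    """
    results = []
    for u_h in uh_values:
        grid: dict[tuple[float, float], np.ndarray] = {}
        for psi in psi_values:
            for th in thalf_values:
                pp = ProteinParams(
                    name=f"scan_psi{psi:g}_th{th:g}", ec=0, phi=0.0,
                    psi=float(psi), t_half_days=float(th), u_h=float(u_h),
                )
                grid[(float(psi), float(th))] = simulate_shedding(
                    traj, rates, pp, dt=dt
                ).q
        keys = list(grid.keys())
        stack = np.stack([grid[k] for k in keys])
        q_min = stack.min(axis=0)
        q_max = stack.max(axis=0)
        # identify the corners achieving the bounds at the final day
        corner_min = keys[int(np.argmin(stack[:, -1]))]
        corner_max = keys[int(np.argmax(stack[:, -1]))]

        crossover = None
        if ec_reference is not None:
            q_ec = simulate_shedding(traj, rates, ec_reference, dt=dt).q
            above = np.nonzero(q_max > q_ec)[0]
            crossover = int(above[0]) if above.size else None
        results.append(
            EnvelopeResult(
                u_h=float(u_h), t=traj.t.copy(), q_min=q_min, q_max=q_max,
                corner_min=corner_min, corner_max=corner_max,
                crossover_day=crossover, grid=grid,
            )
        )
    return results


def growth_inflection_day(
    traj: GrowthTrajectory,
    window: int = 30,
    initial_phase_days: int = 730,
) -> int:
    """Day the run leaves its early exponential phase.

    The trailing ``window``-day log-growth rate of the total population is
    compared against the initial exponential rate, taken as the maximum
    trailing rate within the first ``initial_phase_days`` (robust to the
    seeding transient).  Returns the first day after that maximum at which
    the trailing rate falls below half the initial rate.
    """
    total = traj.total_P
    if len(total) <= window:
        raise ValueError("trajectory shorter than the trailing window")
    if np.any(total <= 0):
        raise ValueError("total population must stay positive")
    logp = np.log(total)
    rate = np.full(len(total), np.nan)
    rate[window:] = (logp[window:] - logp[:-window]) / window
    early = slice(window, min(initial_phase_days, len(total)))
    g0_idx = window + int(np.nanargmax(rate[early]))
    g0 = rate[g0_idx]
    below = np.nonzero(rate[g0_idx:] < 0.5 * g0)[0]
    if below.size == 0:
        raise ValueError("no exponential-to-capacity-limited transition found")
    return int(g0_idx + below[0])
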