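"""Deterministic output writing: trajectory CSVs and a run manifest."""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .config import ModelConfig
from .growth import GrowthTrajectory
from .shedding import SheddingTrajectory

__all__ = ["write_outputs", "read_protein_table"]


def write_outputs(
    out_dir: str | Path,
    config: ModelConfig,
    growth: GrowthTrajectory | None = None,
    sheddings: dict[str, SheddingTrajectory] | None = None,
    extra_tables: dict[str, "pd.DataFrame"] | None = None,
) -> list[Path]:
    """Write trajectories, scan tables and a reproduction manifest.

    File naming is deterministic and the CSV content is a pure function of
    the configuration, so re-running with the same manifest reproduces
    every file byte for byte.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    written: list[Path] = []

    def _write_csv(name: str, frame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    if growth is not None:
        _write_csv("growth_summary.csv", growth.summary_frame())
        _write_csv("growth_by_compartment.csv", growth.by_compartment_frame())
    for name, shed in (sheddings or {}).items():
        _write_csv(f"shedding_{name}.csv", shed.frame())
    for name, frame in (extra_tables or {}).items():
        _write_csv(f"{name}.csv", frame)

    manifest = {
        "tool": "tumorshed",
        "version": __version__,
        "config": config.to_dict(),
        "files": sorted(p.name for p in written),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return written


def read_protein_table(path: str | Path):
    """Read protein parameter sets from a CSV/TSV table.

    Expected columns: name, ec, phi, psi, t_half_days, u_h and optionally
    q0 (blank q0 means the healthy-steady-state default).
    """
    import pandas as pd

    from .shedding import ProteinParams

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"name", "ec", "phi", "psi", "t_half_days", "u_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"protein table {path} is missing columns {sorted(missing)}")
    proteins = []
    for _, row in df.iterrows():
        q0 = row.get("q0")
        proteins.append(
            ProteinParams(
                name=str(row["name"]), ec=int(row["ec"]), phi=float(row["phi"]),
                psi=float(row["psi"]), t_half_days=float(row["t_half_days"]),
                u_h=float(row["u_h"]),
                q0=None if q0 is None or pd.isna(q0) else float(q0),
            )
        )
    return proteins
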