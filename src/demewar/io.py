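"""Result serialization: tidy TSV tables, trajectories, and manifests.

Output files are reproducible byte-for-byte from (config, seed): tables
are written with a fixed float format and column order.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import write_manifest
from .engine import Trajectory
from .model import ModelParams

__all__ = ["write_table", "write_trajectory", "write_summary"]

_FLOAT_FMT = "%.10g"


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    write_table(traj.to_frame(), path)


def write_summary(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    params: ModelParams,
    **manifest_extra,
) -> list[Path]:
    """Write each named table as ``<name>.tsv`` plus ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = out / f"{name}.tsv"
        write_table(table, p)
        written.append(p)
    mpath = out / "manifest.json"
    write_manifest(params, mpath, **manifest_extra)
    written.append(mpath)
    return written
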