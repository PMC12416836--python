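"""Persistence: lineage TSV, trajectory store (HDF5), CSV/Newick writers.

The lineage table round-trips losslessly through TSV.  Trajectories go into
one HDF5 file keyed ``rep<r>/g<generation>_i<index>`` with the time grid and
state matrix per cell plus the species list as a file attribute; a plain-text
export of single trajectories exists for debugging.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .errors import InputError
from .model import ModelSpecs, Trajectory
from .population import CellRecord, LineageTable

__all__ = [
    "lineage_to_frame",
    "write_lineage_tsv",
    "read_lineage_tsv",
    "write_trajectory_store",
    "read_trajectory_store",
    "export_trajectory_tsv",
]

_COLUMNS = [
    "replicate",
    "generation",
    "index",
    "parent_generation",
    "parent_index",
    "birth_h",
    "end_h",
    "fate",
    "division_h",
]


def lineage_to_frame(lineage: LineageTable) -> pd.DataFrame:
    rows = []
    for r in lineage.records:
        rows.append(
            {
                "replicate": lineage.replicate,
                "generation": r.generation,
                "index": r.index,
                "parent_generation": r.parent[0] if r.parent else -1,
                "parent_index": r.parent[1] if r.parent else -1,
                "birth_h": r.birth_time,
                "end_h": r.end_time,
                "fate": r.fate,
                "division_h": r.division_time if r.division_time is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_lineage_tsv(lineages: list[LineageTable] | LineageTable, path: str | Path) -> None:
    if isinstance(lineages, LineageTable):
        lineages = [lineages]
    frame = pd.concat([lineage_to_frame(l) for l in lineages], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False)


def read_lineage_tsv(
    path: str | Path, duration_h: float, dose: float = 0.0, drug: str | None = None
) -> list[LineageTable]:
    """Read back one LineageTable per replicate present in the file."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"lineage TSV lacks columns: {missing}")
    out = []
    for rep, grp in frame.groupby("replicate"):
        records = [
            CellRecord(
                generation=int(row.generation),
                index=int(row.index),
                parent=None
                if row.parent_generation < 0
                else (int(row.parent_generation), int(row.parent_index)),
                birth_time=float(row.birth_h),
                end_time=float(row.end_h),
                fate=str(row.fate),
                division_time=None if pd.isna(row.division_h) else float(row.division_h),
            )
            for row in grp.itertuples(index=False)
        ]
        out.append(
            LineageTable(records, replicate=int(rep), dose=dose, drug=drug, duration=duration_h)
        )
    return out


def write_trajectory_store(
    trajectories: Mapping[int, Mapping[tuple[int, int], Trajectory]],
    path: str | Path,
) -> None:
    """Persist {replicate: {(gen, idx): Trajectory}} to one HDF5 file."""
    with h5py.File(path, "w") as f:
        species_written = False
        for rep, cells in trajectories.items():
            grp = f.create_group(f"rep{rep}")
            for (gen, idx), traj in cells.items():
                g = grp.create_group(f"g{gen}_i{idx}")
                g.create_dataset("times", data=traj.times, compression="gzip")
                g.create_dataset("states", data=traj.states, compression="gzip")
                if not species_written:
                    f.attrs["species"] = list(traj.specs.species_all)
                    f.attrs["cc_marker"] = traj.specs.cc_marker
                    f.attrs["death_marker"] = traj.specs.death_marker or ""
                    f.attrs["progress_markers"] = list(traj.specs.progress_markers)
                    species_written = True


def read_trajectory_store(path: str | Path) -> dict[int, dict[tuple[int, int], Trajectory]]:
    out: dict[int, dict[tuple[int, int], Trajectory]] = {}
    with h5py.File(path, "r") as f:
        specs = ModelSpecs(
            species_all=tuple(str(s) for s in f.attrs["species"]),
            cc_marker=str(f.attrs["cc_marker"]),
            death_marker=str(f.attrs["death_marker"]) or None,
            progress_markers=tuple(str(s) for s in f.attrs["progress_markers"]),
        )
        for rep_key in f:
            rep = int(rep_key.removeprefix("rep"))
            out[rep] = {}
            for cell_key in f[rep_key]:
                gen, idx = cell_key.removeprefix("g").split("_i")
                g = f[rep_key][cell_key]
                out[rep][(int(gen), int(idx))] = Trajectory(
                    np.asarray(g["times"]), np.asarray(g["states"]), specs
                )
    return out


def export_trajectory_tsv(traj: Trajectory, path: str | Path) -> None:
    frame = pd.DataFrame(traj.states, columns=list(traj.specs.species_all))
    frame.insert(0, "time_h", traj.times)
    frame.to_csv(path, sep="\t", index=False)
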