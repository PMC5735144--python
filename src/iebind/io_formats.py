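"""In-memory model and text I/O for topologies, trajectories and energy series.

The pipeline works on a stripped solute (protein + ligand, no water) and
needs only the information required for nonbonded post-processing: partial
charges, Lennard-Jones parameters and a protein/ligand group label per atom.
The topology is therefore a plain delimited-text table rather than a force
field file.  Trajectories are interchanged as multi-model PDB (via biotite)
or, at full float precision, as a long-format XYZ table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError

GROUP_PROTEIN = "protein"
GROUP_LIGAND = "ligand"

TOPOLOGY_COLUMNS = [
    "atom_id",
    "atom_name",
    "element",
    "residue_index",
    "residue_name",
    "group",
    "charge",
    "lj_sigma",
    "lj_epsilon",
    "mass",
]

_TOPOLOGY_NUMERIC = ["atom_id", "residue_index", "charge", "lj_sigma", "lj_epsilon", "mass"]


@dataclass(frozen=True)
class Topology:
    """Static per-atom record: identity, grouping, charge and LJ parameters.

    Atom ids are consecutive from 0 and order all coordinate arrays.
    Charges are in elementary charge units; ``lj_sigma`` in Angstrom,
    ``lj_epsilon`` in kcal/mol (sigma/epsilon convention with
    Lorentz-Berthelot combining downstream), masses in amu.
    """

    atom_id: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    group: np.ndarray
    charge: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        n = len(self.atom_id)
        for col in TOPOLOGY_COLUMNS:
            if len(getattr(self, col)) != n:
                raise ValidationError(f"column '{col}' has length != {n}")
        if n == 0:
            raise EmptyInputError("topology has no atoms")
        if not np.array_equal(self.atom_id, np.arange(n)):
            raise ValidationError("atom_id must be consecutive integers from 0")
        bad = set(np.unique(self.group)) - {GROUP_PROTEIN, GROUP_LIGAND}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if np.any(self.lj_epsilon < 0):
            raise ValidationError("lj_epsilon must be >= 0")
        if np.any(self.lj_sigma <= 0):
            raise ValidationError("lj_sigma must be > 0")
        if np.any(self.mass <= 0):
            raise ValidationError("mass must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    @property
    def protein_index(self) -> np.ndarray:
        return np.flatnonzero(self.group == GROUP_PROTEIN)

    @property
    def ligand_index(self) -> np.ndarray:
        return np.flatnonzero(self.group == GROUP_LIGAND)

    def require_both_groups(self) -> None:
        if len(self.protein_index) == 0 or len(self.ligand_index) == 0:
            raise ValidationError(
                "binding analyses need at least one protein and one ligand atom"
            )

    def subset(self, index: np.ndarray) -> "Topology":
        """Topology restricted to ``index`` with atom ids renumbered from 0."""
        index = np.asarray(index)
        kw = {col: np.asarray(getattr(self, col))[index] for col in TOPOLOGY_COLUMNS}
        kw["atom_id"] = np.arange(len(index))
        return Topology(**kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Topology":
        missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"topology table is missing column(s): {missing}")
        kw = {}
        for col in TOPOLOGY_COLUMNS:
            raw = df[col]
            if col in _TOPOLOGY_NUMERIC:
                vals = pd.to_numeric(raw, errors="coerce")
                bad = vals.isna() & raw.notna()
                if bad.any() or raw.isna().any():
                    line = int(np.flatnonzero(bad | raw.isna())[0]) + 2  # +header
                    raise FormatError(
                        f"non-numeric or missing value in column '{col}' at line {line}"
                    )
                dtype = int if col in ("atom_id", "residue_index") else float
                kw[col] = vals.to_numpy().astype(dtype)
            else:
                kw[col] = raw.astype(str).str.strip().to_numpy()
        return cls(**kw)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({col: getattr(self, col) for col in TOPOLOGY_COLUMNS})


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames of Cartesian coordinates (Angstrom) with times in ps."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray  # (n_frames,), strictly increasing

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        times = np.asarray(self.frame_times, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "frame_times", times)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError("coordinates must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] == 0:
            raise EmptyInputError("trajectory has zero frames")
        if len(times) != coords.shape[0]:
            raise ValidationError("frame_times length must equal n_frames")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates contain non-finite values")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class EnergySeries:
    """Per-frame protein-ligand interaction energies in kcal/mol."""

    frame_times: np.ndarray
    e_ele: np.ndarray
    e_vdw: np.ndarray
    e_total: np.ndarray

    def __post_init__(self):
        arrs = {}
        for name in ("frame_times", "e_ele", "e_vdw", "e_total"):
            arrs[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrs[name])
        n = len(arrs["frame_times"])
        if n == 0:
            raise EmptyInputError("energy series must have length >= 1")
        if any(len(a) != n for a in arrs.values()):
            raise ValidationError("all energy-series arrays must have equal length")
        for name in ("e_ele", "e_vdw", "e_total"):
            if not np.all(np.isfinite(arrs[name])):
                raise ValidationError(f"non-finite value in '{name}'")
        if n > 1 and np.any(np.diff(arrs["frame_times"]) <= 0):
            raise ValidationError("frame times must be strictly increasing")

    @classmethod
    def from_components(cls, frame_times, e_ele, e_vdw) -> "EnergySeries":
        e_ele = np.asarray(e_ele, dtype=float)
        e_vdw = np.asarray(e_vdw, dtype=float)
        return cls(frame_times=np.asarray(frame_times, dtype=float),
                   e_ele=e_ele, e_vdw=e_vdw, e_total=e_ele + e_vdw)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)


# ---------------------------------------------------------------------------
# Topology I/O


def read_topology(path) -> Topology:
    """Read a tab- or comma-separated topology table (header-driven)."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty topology file: {path}") from exc
    return Topology.from_dataframe(df)


def write_topology(topology: Topology, path) -> None:
    topology.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Trajectory I/O


def _pdb_to_trajectory(path, topology: Topology) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    stack = PDBFile.read(str(path)).get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[0] == 0:
        raise EmptyInputError(f"no MODEL frames found in {path}")
    if coords.shape[1] != topology.n_atoms:
        raise FormatError(
            f"frame 0 of {path} has {coords.shape[1]} atoms, "
            f"topology has {topology.n_atoms}"
        )
    return Trajectory(coordinates=coords, frame_times=np.arange(coords.shape[0], dtype=float))


def _xyz_table_to_trajectory(path, topology: Topology) -> Trajectory:
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("frame", "atom_id", "x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"XYZ table is missing column '{col}'")
    frames = np.unique(df["frame"].to_numpy())
    n_frames = len(frames)
    coords = np.empty((n_frames, topology.n_atoms, 3))
    times = np.arange(n_frames, dtype=float)
    for k, f in enumerate(np.sort(frames)):
        block = df[df["frame"] == f].sort_values("atom_id")
        if len(block) != topology.n_atoms:
            raise FormatError(
                f"frame {int(f)} has {len(block)} atoms, topology has {topology.n_atoms}"
            )
        coords[k] = block[["x", "y", "z"]].to_numpy(dtype=float)
        if "time_ps" in df.columns:
            times[k] = float(block["time_ps"].iloc[0])
    return Trajectory(coordinates=coords, frame_times=times)


def read_trajectory(path, topology: Topology) -> Trajectory:
    """Read a multi-model PDB (by ``.pdb`` suffix) or a long-format XYZ table.

    PDB carries no time axis, so frame times default to 0, 1, 2, ... ps;
    the XYZ table may carry an explicit ``time_ps`` column.
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        return _pdb_to_trajectory(path, topology)
    return _xyz_table_to_trajectory(path, topology)


def write_trajectory(trajectory: Trajectory, topology: Topology, path) -> None:
    """Write multi-model PDB (3-decimal coords) or full-precision XYZ table."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        stack = struc.AtomArrayStack(trajectory.n_frames, topology.n_atoms)
        stack.coord = trajectory.coordinates
        stack.chain_id[:] = "A"
        stack.res_id = topology.residue_index.astype(int) + 1
        stack.res_name = np.array([s[:3].upper() for s in topology.residue_name])
        stack.atom_name = np.array([s[:4] for s in topology.atom_name])
        stack.element = np.array([s.upper() for s in topology.element])
        stack.hetero = topology.group == GROUP_LIGAND
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    else:
        rows = []
        for f in range(trajectory.n_frames):
            for a in range(topology.n_atoms):
                x, y, z = trajectory.coordinates[f, a]
                rows.append((f, trajectory.frame_times[f], a, x, y, z))
        pd.DataFrame(rows, columns=["frame", "time_ps", "atom_id", "x", "y", "z"]).to_csv(
            path, index=False, float_format="%.9f"
        )


# ---------------------------------------------------------------------------
# Energy-series I/O


def read_energy_series(path) -> EnergySeries:
    """Read CSV with header ``time_ps,e_ele,e_vdw[,e_total]``.

    ``e_total`` is filled as ``e_ele + e_vdw`` when absent.  Non-monotonic
    times and NaN energies are rejected with the offending line number.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("time_ps", "e_ele", "e_vdw"):
        if col not in df.columns:
            raise FormatError(f"energy series is missing column '{col}'")
    for col in [c for c in ("e_ele", "e_vdw", "e_total") if c in df.columns]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna())[0]) + 2
            raise FormatError(f"NaN or non-numeric '{col}' at line {line}")
    times = df["time_ps"].to_numpy(dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValidationError("energy series times are not strictly increasing")
    if "e_total" in df.columns:
        return EnergySeries(
            frame_times=times,
            e_ele=df["e_ele"].to_numpy(dtype=float),
            e_vdw=df["e_vdw"].to_numpy(dtype=float),
            e_total=df["e_total"].to_numpy(dtype=float),
        )
    return EnergySeries.from_components(times, df["e_ele"], df["e_vdw"])


def write_energy_series(series: EnergySeries, path) -> None:
    pd.DataFrame(
        {
            "time_ps": series.frame_times,
            "e_ele": series.e_ele,
            "e_vdw": series.e_vdw,
            "e_total": series.e_total,
        }
    ).to_csv(path, index=False, float_format="%.9f")


def load_config(path) -> dict:
    """Load a JSON key-value config (temperature, cutoffs, gamma/beta, ...)."""
    import json

    with open(path) as fh:
        return json.load(fh)
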