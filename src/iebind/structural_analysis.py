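"""Trajectory stability analyses: RMSD, B-factors, hydrogen-bond statistics.

Superposition uses the closed-form optimal rotation (Kabsch, via SVD with a
reflection guard), so RMSD and B-factors are invariant under arbitrary
rigid motion of every frame.  Hydrogen bonds use heavy-atom donor-acceptor
distance and the donor-hydrogen-acceptor angle with the vertex at the
hydrogen; the default criteria are distance <= 3.5 A and angle >= 120 deg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .io_formats import GROUP_PROTEIN, Topology, Trajectory

B_FACTOR_CONSTANT = 8.0 * np.pi**2 / 3.0  # converts <|dr|^2> (A^2) to B (A^2)

BACKBONE_NAMES = ("N", "CA", "C")


@dataclass(frozen=True)
class HBondDefinition:
    """Donor heavy atom, its hydrogen, and the acceptor heavy atom."""

    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    label: str = ""

    def __post_init__(self):
        ids = (self.donor_atom, self.hydrogen_atom, self.acceptor_atom)
        if len(set(ids)) != 3:
            raise ValidationError(f"hydrogen bond atoms must be distinct: {ids}")


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.5  # Angstrom, donor-acceptor heavy atoms
    min_dha_angle: float = 120.0  # degrees, vertex at the hydrogen

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValidationError("max_da_distance must be > 0")
        if not (0.0 <= self.min_dha_angle <= 180.0):
            raise ValidationError("min_dha_angle must be in [0, 180]")


@dataclass(frozen=True)
class HBondStats:
    table: pd.DataFrame  # per bond: label, mean_distance, mean_angle, occupancy
    formed: np.ndarray  # (n_bonds, n_frames) boolean


# ---------------------------------------------------------------------------
# Rigid-body superposition


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValidationError("mobile/reference shapes differ")
    if mobile.shape[0] < 3:
        raise ValidationError("superposition needs at least 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (mobile - mc) @ rot.T + rc


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def _selection_index(topology: Topology, atom_selection: str) -> np.ndarray:
    if atom_selection == "all":
        return np.arange(topology.n_atoms)
    if atom_selection == "backbone_nca_c":
        mask = np.isin(topology.atom_name, BACKBONE_NAMES) & (
            topology.group == GROUP_PROTEIN
        )
        return np.flatnonzero(mask)
    if atom_selection == "c_alpha":
        mask = (topology.atom_name == "CA") & (topology.group == GROUP_PROTEIN)
        return np.flatnonzero(mask)
    raise ValidationError(f"unknown atom selection: {atom_selection!r}")


def rmsd_backbone(
    trajectory: Trajectory,
    topology: Topology,
    reference: np.ndarray,
    atom_selection: str = "backbone_nca_c",
) -> np.ndarray:
    """Per-frame RMSD (A) of the selection after optimal superposition."""
    idx = _selection_index(topology, atom_selection)
    if len(idx) < 3:
        raise ValidationError(
            f"selection '{atom_selection}' has {len(idx)} atoms; need >= 3 for a rigid fit"
        )
    ref = np.asarray(reference, dtype=float)[idx]
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        fitted = kabsch_superpose(trajectory.coordinates[f][idx], ref)
        out[f] = _rmsd(fitted, ref)
    return out


def b_factor(
    trajectory: Trajectory, topology: Topology, atom_selection: str = "c_alpha"
) -> np.ndarray:
    """Isotropic B-factor (A^2) per selected atom, (8 pi^2 / 3) <|r - <r>|^2>.

    Frames are superposed onto the mean structure, iterated twice so the
    reference is self-consistent, before the fluctuation is measured.
    """
    if trajectory.n_frames < 2:
        raise ValidationError("B-factor needs at least 2 frames")
    idx = _selection_index(topology, atom_selection)
    if len(idx) < 3:
        raise ValidationError(f"selection '{atom_selection}' has < 3 atoms")
    frames = trajectory.coordinates[:, idx, :].copy()
    mean = frames.mean(axis=0)
    for _ in range(2):
        frames = np.array([kabsch_superpose(f, mean) for f in frames])
        mean = frames.mean(axis=0)
    msf = np.mean(np.sum((frames - mean) ** 2, axis=-1), axis=0)
    return B_FACTOR_CONSTANT * msf


# ---------------------------------------------------------------------------
# Hydrogen bonds


def _angle_deg(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle at ``vertex`` between directions to a and b, in degrees."""
    v1 = a - vertex
    v2 = b - vertex
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise GeometryError("coincident atoms in hydrogen-bond angle")
    cos = np.sum(v1 * v2, axis=-1) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def hbond_geometry(
    coords: np.ndarray, bond: HBondDefinition, angle_vertex: str = "hydrogen"
) -> tuple[np.ndarray, np.ndarray]:
    """(distance, angle) traces for one bond over frames.

    Distance is donor-to-acceptor heavy atom; the angle vertex is the
    hydrogen (D-H...A convention, default) or the donor.
    """
    d = coords[:, bond.donor_atom]
    h = coords[:, bond.hydrogen_atom]
    a = coords[:, bond.acceptor_atom]
    dist = np.linalg.norm(d - a, axis=-1)
    if angle_vertex == "hydrogen":
        ang = _angle_deg(h, d, a)
    elif angle_vertex == "donor":
        ang = _angle_deg(d, h, a)
    else:
        raise ValidationError(f"unknown angle vertex: {angle_vertex!r}")
    return dist, ang


def hbond_stats(
    trajectory: Trajectory,
    topology: Topology,
    bonds: Sequence[HBondDefinition],
    criteria: HBondCriteria = HBondCriteria(),
    angle_vertex: str = "hydrogen",
    mean_over: str = "all",
) -> HBondStats:
    """Occupancy and mean geometry per defined hydrogen bond.

    A bond is formed in a frame iff distance <= max_da_distance AND
    angle >= min_dha_angle.  Means are over all frames by default;
    ``mean_over="formed"`` restricts them to frames where the bond is formed.
    """
    if mean_over not in ("all", "formed"):
        raise ValidationError(f"unknown mean_over: {mean_over!r}")
    coords = trajectory.coordinates
    rows = []
    formed_all = np.zeros((len(bonds), trajectory.n_frames), dtype=bool)
    for k, bond in enumerate(bonds):
        for atom in (bond.donor_atom, bond.hydrogen_atom, bond.acceptor_atom):
            if not (0 <= atom < topology.n_atoms):
                raise ValidationError(f"bond {bond.label!r}: atom id {atom} out of range")
        dist, ang = hbond_geometry(coords, bond, angle_vertex)
        formed = (dist <= criteria.max_da_distance) & (ang >= criteria.min_dha_angle)
        formed_all[k] = formed
        sel = formed if (mean_over == "formed" and formed.any()) else slice(None)
        rows.append(
            (
                bond.label or f"bond{k}",
                float(np.mean(dist[sel])),
                float(np.mean(ang[sel])),
                float(formed.mean()),
            )
        )
    table = pd.DataFrame(rows, columns=["label", "mean_distance", "mean_angle", "occupancy"])
    return HBondStats(table=table, formed=formed_all)


def detect_native_hbonds(
    topology: Topology,
    native_frame: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
    dh_cutoff: float = 1.2,
    angle_vertex: str = "hydrogen",
) -> list[HBondDefinition]:
    """Intra-protein donor-H-acceptor triples satisfying criteria in the native frame.

    Donors are protein N/O heavy atoms with a hydrogen within ``dh_cutoff`` A;
    acceptors are protein N/O heavy atoms other than the donor.
    """
    native = np.asarray(native_frame, dtype=float)
    prot = topology.protein_index
    elements = np.char.upper(topology.element[prot].astype(str))
    heavy = prot[np.isin(elements, ("N", "O"))]
    hydro = prot[elements == "H"]
    bonds = []
    for d in heavy:
        for h in hydro:
            if np.linalg.norm(native[d] - native[h]) > dh_cutoff:
                continue
            for a in heavy:
                if a == d:
                    continue
                cand = HBondDefinition(int(d), int(h), int(a))
                dist, ang = hbond_geometry(native[None], cand, angle_vertex)
                if dist[0] <= criteria.max_da_distance and ang[0] >= criteria.min_dha_angle:
                    bonds.append(cand)
    return bonds


def native_hbond_fraction(
    trajectory: Trajectory,
    topology: Topology,
    native_frame: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
    angle_vertex: str = "hydrogen",
) -> np.ndarray:
    """Fraction of native intra-protein hydrogen bonds present in each frame."""
    native_set = detect_native_hbonds(topology, native_frame, criteria,
                                      angle_vertex=angle_vertex)
    if not native_set:
        raise GeometryError("no intra-protein hydrogen bonds in the native frame")
    stats = hbond_stats(trajectory, topology, native_set, criteria, angle_vertex)
    return stats.formed.mean(axis=0)
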