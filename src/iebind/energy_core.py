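"""Nonbonded protein-ligand interaction energies and per-residue decomposition.

Only inter-group (protein x ligand) pairs are summed: the two groups share
no bonds, so no intramolecular terms or 1-4 exclusions arise.  Electrostatics
use Coulomb's law with k = 332.0637 kcal*A/(mol*e^2); van der Waals uses
12-6 Lennard-Jones in the sigma/epsilon convention with Lorentz-Berthelot
combining.  All pairs are included by default (no cutoff, no periodicity),
matching post-processing of a stripped solute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .io_formats import EnergySeries, Topology, Trajectory

COULOMB_CONSTANT = 332.0637  # kcal*A/(mol*e^2)


@dataclass(frozen=True)
class NonbondedParams:
    coulomb_constant: float = COULOMB_CONSTANT
    combining_rule: str = "lorentz_berthelot"
    cutoff: Optional[float] = None  # Angstrom; None = all pairs

    def __post_init__(self):
        if self.coulomb_constant <= 0:
            raise ValidationError("coulomb_constant must be > 0")
        if self.combining_rule != "lorentz_berthelot":
            raise ValidationError(f"unsupported combining rule: {self.combining_rule}")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValidationError("cutoff must be > 0 if set")


@dataclass(frozen=True)
class ResidueSpectrum:
    """Frame-averaged residue-ligand interaction spectrum (kcal/mol)."""

    table: pd.DataFrame  # columns residue_index, residue_name, e_ele, e_vdw, e_total

    @property
    def total(self) -> float:
        return float(self.table["e_total"].sum())


def _pair_energies(topology: Topology, frame: np.ndarray, params: NonbondedParams):
    """Per-pair (protein x ligand) electrostatic and LJ energy matrices."""
    P = topology.protein_index
    L = topology.ligand_index
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (topology.n_atoms, 3):
        raise ValidationError(
            f"frame shape {frame.shape} does not match topology ({topology.n_atoms} atoms)"
        )
    diff = frame[P][:, None, :] - frame[L][None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    if np.any(r == 0.0):
        i, j = np.argwhere(r == 0.0)[0]
        raise GeometryError(
            f"coincident protein/ligand atoms: atom {P[i]} and atom {L[j]}"
        )
    e_ele = params.coulomb_constant * np.outer(
        topology.charge[P], topology.charge[L]
    ) / r
    sig = 0.5 * (topology.lj_sigma[P][:, None] + topology.lj_sigma[L][None, :])
    eps = np.sqrt(np.outer(topology.lj_epsilon[P], topology.lj_epsilon[L]))
    sr6 = (sig / r) ** 6
    e_vdw = 4.0 * eps * (sr6 * sr6 - sr6)
    if params.cutoff is not None:
        mask = r <= params.cutoff
        e_ele = e_ele * mask
        e_vdw = e_vdw * mask
    return e_ele, e_vdw


def intergroup_energy(
    topology: Topology, frame: np.ndarray, params: NonbondedParams = NonbondedParams()
) -> tuple[float, float]:
    """Total protein-ligand (e_ele, e_vdw) for one frame, kcal/mol."""
    topology.require_both_groups()
    e_ele, e_vdw = _pair_energies(topology, frame, params)
    return float(e_ele.sum()), float(e_vdw.sum())


def energy_series(
    topology: Topology, trajectory: Trajectory, params: NonbondedParams = NonbondedParams()
) -> EnergySeries:
    """Per-frame interaction energies along a trajectory."""
    topology.require_both_groups()
    e_ele = np.empty(trajectory.n_frames)
    e_vdw = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        try:
            e_ele[f], e_vdw[f] = intergroup_energy(topology, trajectory.coordinates[f], params)
        except GeometryError as exc:
            raise GeometryError(f"frame {f}: {exc}") from exc
    return EnergySeries.from_components(trajectory.frame_times, e_ele, e_vdw)


def residue_decomposition(
    topology: Topology, trajectory: Trajectory, params: NonbondedParams = NonbondedParams()
) -> ResidueSpectrum:
    """Frame-averaged interaction energy of each protein residue with the ligand.

    The per-residue totals sum to the mean inter-group total (conservation).
    """
    topology.require_both_groups()
    P = topology.protein_index
    res_of_pair = topology.residue_index[P]
    residues = np.unique(res_of_pair)
    acc_ele = np.zeros(len(residues))
    acc_vdw = np.zeros(len(residues))
    pos = {r: k for k, r in enumerate(residues)}
    row = np.array([pos[r] for r in res_of_pair])
    for f in range(trajectory.n_frames):
        e_ele, e_vdw = _pair_energies(topology, trajectory.coordinates[f], params)
        np.add.at(acc_ele, row, e_ele.sum(axis=1))
        np.add.at(acc_vdw, row, e_vdw.sum(axis=1))
    acc_ele /= trajectory.n_frames
    acc_vdw /= trajectory.n_frames
    names = []
    for r in residues:
        sel = topology.residue_index == r
        names.append(str(topology.residue_name[sel][0]))
    table = pd.DataFrame(
        {
            "residue_index": residues,
            "residue_name": names,
            "e_ele": acc_ele,
            "e_vdw": acc_vdw,
            "e_total": acc_ele + acc_vdw,
        }
    )
    return ResidueSpectrum(table=table)
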