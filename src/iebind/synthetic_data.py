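"""Seeded synthetic inputs with the statistical structure each analysis assumes.

Three generators replace MD output at desk scale:

* Gaussian (optionally AR(1)-correlated) interaction-energy series with
  chosen mean and fluctuation sigma — the interaction-entropy estimator has
  the exact population value sigma^2 / (2 kT) on this input.
* Toy complexes: a small polar "protein" (donor N, hydrogen, acceptor O per
  residue) plus a 3-atom ligand, with designed hydrogen bonds that form and
  break on an explicit per-frame schedule, optional per-atom Gaussian jitter
  and optional per-frame rigid motion.  Formed geometry (2.8 A, 165 deg)
  and broken geometry (5.0 A or 90 deg) sit comfortably inside/outside the
  3.5 A / 120 deg criteria.
* Component tables: snapshot-group free-energy components drawn around fixed
  means with known SDs, for exercising group statistics.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import EnergySeries, Topology, Trajectory
from .structural_analysis import HBondDefinition

Interval = tuple[tuple[int, int], bool]

_RESIDUE_SPACING = 20.0  # A between designed sites: no cross-talk
_DH_LENGTH = 1.0  # A, donor-hydrogen
_FORMED_DISTANCE, _FORMED_ANGLE = 2.8, 165.0
_BROKEN_DISTANCE, _BROKEN_ANGLE = 5.0, 90.0


@dataclass(frozen=True)
class GaussianEnergySpec:
    mean: float  # kcal/mol
    sigma: float  # kcal/mol, >= 0
    n_frames: int
    dt: float = 0.01  # ps; dense production-window stride
    seed: int = 0
    rho: float = 0.0  # AR(1) lag-1 autocorrelation; 0 = i.i.d.

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if not (-1.0 < self.rho < 1.0):
            raise ValidationError("rho must be in (-1, 1)")


def generate_gaussian_series(spec: GaussianEnergySpec) -> EnergySeries:
    """Energy series with N(mean, sigma^2) marginals; e_ele = e_total, e_vdw = 0.

    With ``rho`` nonzero, samples follow a stationary AR(1) process with the
    same marginal variance, for probing IE convergence under correlation.
    """
    rng = np.random.default_rng(spec.seed)
    eps = rng.standard_normal(spec.n_frames)
    if spec.rho == 0.0:
        x = spec.mean + spec.sigma * eps
    else:
        x = np.empty(spec.n_frames)
        x[0] = spec.mean + spec.sigma * eps[0]
        scale = spec.sigma * np.sqrt(1.0 - spec.rho**2)
        for i in range(1, spec.n_frames):
            x[i] = spec.mean + spec.rho * (x[i - 1] - spec.mean) + scale * eps[i]
    times = spec.dt * np.arange(spec.n_frames)
    return EnergySeries(frame_times=times, e_ele=x, e_vdw=np.zeros_like(x), e_total=x)


@dataclass(frozen=True)
class ToyComplexSpec:
    n_protein_residues: int
    hbond_schedule: Sequence[Sequence[Interval]]  # per designed bond
    n_frames: int
    jitter_sigma: float = 0.0  # A, per coordinate
    rigid_motion: Optional[Sequence[tuple]] = None  # per frame: (axis, angle_deg, translation)
    intra_protein: bool = False  # designed bonds within the protein instead of to the ligand
    break_mode: str = "distance"  # "distance" (5.0 A) or "angle" (90 deg)
    seed: int = 0

    def __post_init__(self):
        if self.n_protein_residues < 1:
            raise ValidationError("n_protein_residues must be >= 1")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be >= 0")
        if self.break_mode not in ("distance", "angle"):
            raise ValidationError(f"unknown break_mode: {self.break_mode}")
        n_bonds = len(self.hbond_schedule)
        if n_bonds > self.n_protein_residues:
            raise ValidationError(
                f"schedule defines {n_bonds} bonds but only "
                f"{self.n_protein_residues} donor residues exist"
            )
        if not self.intra_protein and n_bonds > 3:
            raise ValidationError("at most 3 protein-ligand bonds (3 ligand acceptors)")
        for k, sched in enumerate(self.hbond_schedule):
            ivals = sorted(iv for iv, _ in sched)
            covered = 0
            for start, end in ivals:
                if start != covered or end <= start:
                    raise ValidationError(
                        f"bond {k}: intervals must tile [0, n_frames) without overlap"
                    )
                covered = end
            if covered != self.n_frames:
                raise ValidationError(f"bond {k}: schedule does not cover all frames")
        if self.rigid_motion is not None and len(self.rigid_motion) != self.n_frames:
            raise ValidationError("rigid_motion must give one entry per frame")


def _formed_at(sched: Sequence[Interval], frame: int) -> bool:
    for (start, end), formed in sched:
        if start <= frame < end:
            return bool(formed)
    raise ValidationError(f"frame {frame} not covered by schedule")


def _hydrogen_position(donor: np.ndarray, da_axis_origin: np.ndarray,
                       d: float, theta_deg: float) -> np.ndarray:
    """Place H at 1.0 A from the donor so the D-H-A angle equals theta."""
    theta = np.radians(theta_deg)
    # triangle D-H-A: |DH| = 1, |DA| = d, angle at H = theta
    sin_a = _DH_LENGTH * np.sin(theta) / d
    angle_d = np.pi - theta - np.arcsin(sin_a)  # angle at the donor vertex
    return donor + _DH_LENGTH * np.array([np.cos(angle_d), np.sin(angle_d), 0.0])


def _rotation_matrix(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _toy_topology(spec: ToyComplexSpec) -> Topology:
    names, elements, res_idx, res_name, group = [], [], [], [], []
    charge, sigma, eps, mass = [], [], [], []
    for j in range(spec.n_protein_residues):
        for nm, el, q, s, e, m in (
            ("N", "N", -0.4, 3.25, 0.17, 14.007),
            ("H", "H", 0.4, 1.07, 0.0157, 1.008),
            ("O", "O", -0.5, 3.00, 0.21, 15.999),
        ):
            names.append(nm)
            elements.append(el)
            res_idx.append(j)
            res_name.append("RES")
            group.append("protein")
            charge.append(q)
            sigma.append(s)
            eps.append(e)
            mass.append(m)
    for nm, el, q, s, e, m in (
        ("O1", "O", -0.3, 3.00, 0.21, 15.999),
        ("N1", "N", -0.2, 3.25, 0.17, 14.007),
        ("O2", "O", -0.3, 3.00, 0.21, 15.999),
    ):
        names.append(nm)
        elements.append(el)
        res_idx.append(spec.n_protein_residues)
        res_name.append("LIG")
        group.append("ligand")
        charge.append(q)
        sigma.append(s)
        eps.append(e)
        mass.append(m)
    n = len(names)
    return Topology(
        atom_id=np.arange(n),
        atom_name=np.array(names),
        element=np.array(elements),
        residue_index=np.array(res_idx),
        residue_name=np.array(res_name),
        group=np.array(group),
        charge=np.array(charge),
        lj_sigma=np.array(sigma),
        lj_epsilon=np.array(eps),
        mass=np.array(mass),
    )


def generate_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[Topology, Trajectory, list[HBondDefinition]]:
    """Toy complex with scheduled hydrogen bonds; returns the designed bonds.

    Each designed bond ``j`` donates from residue ``j``'s N-H; the acceptor
    is ligand atom ``j`` (default) or residue ``j``'s own O atom when
    ``intra_protein`` is set.  Designed sites are spaced 20 A apart so bonds
    are geometrically independent.
    """
    topology = _toy_topology(spec)
    rng = np.random.default_rng(spec.seed)
    n_bonds = len(spec.hbond_schedule)
    n_res = spec.n_protein_residues
    lig0 = 3 * n_res  # first ligand atom id
    coords = np.empty((spec.n_frames, topology.n_atoms, 3))

    bonds = []
    for j in range(n_bonds):
        donor, hydrogen = 3 * j, 3 * j + 1
        acceptor = (3 * j + 2) if spec.intra_protein else (lig0 + j)
        bonds.append(
            HBondDefinition(donor, hydrogen, acceptor, label=f"designed{j}")
        )

    for f in range(spec.n_frames):
        frame = np.empty((topology.n_atoms, 3))
        for j in range(n_res):
            base = np.array([_RESIDUE_SPACING * j, 0.0, 0.0])
            frame[3 * j] = base  # donor N
            frame[3 * j + 1] = base + np.array([_DH_LENGTH, 0.0, 0.0])
            frame[3 * j + 2] = base + np.array([0.0, 3.0, 0.0])  # inert acceptor O
        for k in range(3):  # ligand parked far from every designed site
            frame[lig0 + k] = np.array([-40.0, 3.0 * k, 0.0])
        for j, bond in enumerate(bonds):
            base = frame[bond.donor_atom].copy()
            if _formed_at(spec.hbond_schedule[j], f):
                d, theta = _FORMED_DISTANCE, _FORMED_ANGLE
            elif spec.break_mode == "distance":
                d, theta = _BROKEN_DISTANCE, _FORMED_ANGLE
            else:
                d, theta = _FORMED_DISTANCE, _BROKEN_ANGLE
            frame[bond.acceptor_atom] = base + np.array([d, 0.0, 0.0])
            frame[bond.hydrogen_atom] = _hydrogen_position(base, base, d, theta)
        if spec.jitter_sigma > 0:
            frame = frame + rng.normal(0.0, spec.jitter_sigma, frame.shape)
        if spec.rigid_motion is not None:
            axis, angle_deg, translation = spec.rigid_motion[f]
            frame = frame @ _rotation_matrix(axis, angle_deg).T + np.asarray(translation, float)
        coords[f] = frame

    trajectory = Trajectory(coordinates=coords, frame_times=np.arange(spec.n_frames, dtype=float))
    return topology, trajectory, bonds


DEFAULT_COMPONENT_MEANS = {
    "e_ele": -51.83,
    "e_vdw": -13.95,
    "e_internal": -11.28,
    "g_pb": 54.35,
    "g_np": 0.92,
    "minus_t_delta_s": 11.17,
}
DEFAULT_COMPONENT_SDS = {
    "e_ele": 4.22,
    "e_vdw": 2.85,
    "e_internal": 3.88,
    "g_pb": 2.97,
    "g_np": 0.10,
    "minus_t_delta_s": 1.69,
}


def generate_component_table(
    seed: int,
    n_groups: int,
    means: Optional[dict] = None,
    sds: Optional[dict] = None,
) -> pd.DataFrame:
    """Snapshot-group free-energy components drawn around fixed means.

    One row per group; columns are the five raw components (entropy term
    kept nonnegative by clipping at zero, as the exponential-average
    estimator guarantees).
    """
    if n_groups < 2:
        raise ValidationError("n_groups must be >= 2")
    means = {**DEFAULT_COMPONENT_MEANS, **(means or {})}
    sds = {**DEFAULT_COMPONENT_SDS, **(sds or {})}
    rng = np.random.default_rng(seed)
    data = {}
    for key in DEFAULT_COMPONENT_MEANS:
        vals = rng.normal(means[key], sds[key], n_groups)
        if key == "minus_t_delta_s":
            vals = np.maximum(vals, 0.0)
        data[key] = vals
    return pd.DataFrame(data)
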