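"""Shrake-Rupley SASA and the linear nonpolar solvation term.

dG_np = gamma * dSASA + beta with the standard constants
gamma = 0.00542 kcal/(mol*A^2) and beta = 0.92 kcal/mol.  dSASA is the
buried surface on binding, SASA(complex) - SASA(protein) - SASA(ligand),
averaged over frames.  Sphere points come from a deterministic Fibonacci
spiral, so results are exactly reproducible at a given point count.

The polar solvation term dG_pb is NOT computed here: it requires a
Poisson-Boltzmann solver and enters the pipeline as externally supplied
per-frame values (see the aggregator module).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import Topology, Trajectory

DEFAULT_ELEMENT_RADII = {
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "H": 1.2,
    "S": 1.8,
    "P": 1.8,
}


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4  # Angstrom
    n_sphere_points: int = 960
    radii_source: str = "element_table"  # or "topology_sigma"
    element_radii: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_RADII)
    )

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValidationError("probe_radius must be >= 0")
        if self.n_sphere_points < 32:
            raise ValidationError("n_sphere_points must be >= 32")
        if self.radii_source not in ("element_table", "topology_sigma"):
            raise ValidationError(f"unknown radii_source: {self.radii_source}")


@dataclass(frozen=True)
class NonpolarParams:
    gamma: float = 0.00542  # kcal/(mol*A^2)
    beta_np: float = 0.92  # kcal/mol


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit vectors on the sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def atom_radii(topology: Topology, params: SasaParams) -> np.ndarray:
    """Per-atom van der Waals radii from the element table or LJ sigma.

    ``topology_sigma`` uses the LJ minimum distance: r = 2^(1/6) * sigma / 2.
    """
    if params.radii_source == "topology_sigma":
        return 2.0 ** (1.0 / 6.0) * topology.lj_sigma / 2.0
    radii = np.empty(topology.n_atoms)
    for k, el in enumerate(topology.element):
        key = str(el).upper()
        if key not in {e.upper(): e for e in params.element_radii}:
            raise LookupError(f"no van der Waals radius for element '{el}'")
        lookup = {e.upper(): v for e, v in params.element_radii.items()}
        radii[k] = lookup[key]
    return radii


def _sasa_coords(coords: np.ndarray, radii: np.ndarray, params: SasaParams) -> np.ndarray:
    """Per-atom SASA (A^2) by Shrake-Rupley on explicit coords + radii."""
    n = len(coords)
    R = radii + params.probe_radius
    unit = fibonacci_sphere(params.n_sphere_points)
    per_atom = np.zeros(n)
    # neighbor prefilter: only spheres that can overlap matter
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        nbr = np.flatnonzero((d[i] < R[i] + R) & (np.arange(n) != i))
        pts = coords[i] + R[i] * unit
        if len(nbr):
            dist2 = np.sum((pts[:, None, :] - coords[nbr][None, :, :]) ** 2, axis=-1)
            accessible = ~np.any(dist2 < R[nbr] ** 2, axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * R[i] ** 2
    return per_atom


def sasa(
    topology: Topology, frame: np.ndarray, params: SasaParams = SasaParams()
) -> tuple[float, np.ndarray]:
    """Total and per-atom solvent-accessible surface area for one frame."""
    frame = np.asarray(frame, dtype=float)
    per_atom = _sasa_coords(frame, atom_radii(topology, params), params)
    return float(per_atom.sum()), per_atom


def delta_sasa_per_atom(
    topology: Topology, frame: np.ndarray, params: SasaParams = SasaParams()
) -> np.ndarray:
    """Per-atom SASA change on binding: complex minus isolated species.

    Entries are <= 0 up to quadrature noise (burial can only remove surface).
    """
    topology.require_both_groups()
    frame = np.asarray(frame, dtype=float)
    radii = atom_radii(topology, params)
    complex_sasa = _sasa_coords(frame, radii, params)
    out = np.empty(topology.n_atoms)
    for idx in (topology.protein_index, topology.ligand_index):
        out[idx] = complex_sasa[idx] - _sasa_coords(frame[idx], radii[idx], params)
    return out


def delta_g_np(
    topology: Topology,
    frames: Union[Trajectory, np.ndarray],
    sasa_params: SasaParams = SasaParams(),
    np_params: NonpolarParams = NonpolarParams(),
    mode: str = "difference",
    beta_mode: str = "once",
) -> float:
    """Nonpolar solvation term gamma * SASA + beta, kcal/mol.

    mode="difference" (default) applies the linear formula to the
    frame-averaged dSASA of binding; the constant beta is added once.
    ``beta_mode="per_species"`` instead carries beta once per species,
    i.e. the difference picks up -beta.  mode="complex_only" applies the
    formula to the raw complex SASA (diagnostic).
    """
    coords = frames.coordinates if isinstance(frames, Trajectory) else np.asarray(frames, float)
    if coords.ndim == 2:
        coords = coords[None]
    if mode not in ("difference", "complex_only"):
        raise ValidationError(f"unknown mode: {mode}")
    if beta_mode not in ("once", "per_species"):
        raise ValidationError(f"unknown beta_mode: {beta_mode}")
    if mode == "complex_only":
        totals = [sasa(topology, c, sasa_params)[0] for c in coords]
        return np_params.gamma * float(np.mean(totals)) + np_params.beta_np
    dsasa = float(np.mean([delta_sasa_per_atom(topology, c, sasa_params).sum() for c in coords]))
    beta = -np_params.beta_np if beta_mode == "per_species" else np_params.beta_np
    return np_params.gamma * dsasa + beta


def attribute_np_per_residue(
    per_atom_delta_sasa: np.ndarray,
    topology: Topology,
    np_params: NonpolarParams = NonpolarParams(),
) -> pd.DataFrame:
    """Per-residue share of the surface term, gamma * (sum of its atoms' dSASA).

    The additive offset beta is reported separately by delta_g_np and is not
    attributed to residues; the shares therefore sum to gamma * total dSASA.
    """
    per_atom_delta_sasa = np.asarray(per_atom_delta_sasa, dtype=float)
    residues = np.unique(topology.residue_index)
    rows = []
    for r in residues:
        sel = topology.residue_index == r
        rows.append(
            (
                int(r),
                str(topology.residue_name[sel][0]),
                np_params.gamma * float(per_atom_delta_sasa[sel].sum()),
            )
        )
    return pd.DataFrame(rows, columns=["residue_index", "residue_name", "g_np_share"])
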