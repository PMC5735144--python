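import numpy as np
import pytest

from iebind.io_formats import Topology


def make_topology(n_protein: int, n_ligand: int, rng=None, neutral_ligand: bool = False) -> Topology:
    """Random small topology for energy/SASA tests."""
    rng = rng or np.random.default_rng(0)
    n = n_protein + n_ligand
    charge = rng.uniform(-0.8, 0.8, n)
    if neutral_ligand:
        charge[n_protein:] -= charge[n_protein:].mean()
    return Topology(
        atom_id=np.arange(n),
        atom_name=np.array([f"A{i}" for i in range(n)]),
        element=np.array(["C"] * n),
        residue_index=np.concatenate(
            [np.arange(n_protein) // 2, np.full(n_ligand, (n_protein + 1) // 2 + 1)]
        ),
        residue_name=np.array(["RES"] * n_protein + ["LIG"] * n_ligand),
        group=np.array(["protein"] * n_protein + ["ligand"] * n_ligand),
        charge=charge,
        lj_sigma=rng.uniform(2.5, 3.5, n),
        lj_epsilon=rng.uniform(0.05, 0.3, n),
        mass=np.full(n, 12.011),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
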