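import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from iebind.errors import GeometryError, ValidationError
from iebind.io_formats import Topology, Trajectory
from iebind.structural_analysis import (
    HBondCriteria,
    HBondDefinition,
    b_factor,
    detect_native_hbonds,
    hbond_stats,
    kabsch_superpose,
    native_hbond_fraction,
    rmsd_backbone,
)
from iebind.synthetic_data import ToyComplexSpec, generate_toy_complex


def _free_topology(n, names=None):
    return Topology(
        atom_id=np.arange(n),
        atom_name=np.array(names if names is not None else [f"A{i}" for i in range(n)]),
        element=np.array(["C"] * n),
        residue_index=np.arange(n),
        residue_name=np.array(["RES"] * n),
        group=np.array(["protein"] * (n - 1) + ["ligand"]),
        charge=np.zeros(n),
        lj_sigma=np.ones(n),
        lj_epsilon=np.zeros(n),
        mass=np.ones(n),
    )


def brute_force_rmsd(mobile, reference):
    """Numeric minimum RMSD over rotations (rotation-vector parametrization)."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def objective(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((mc @ rot.T - rc) ** 2, axis=-1)))

    best = np.inf
    rng = np.random.default_rng(0)
    for _ in range(20):
        res = minimize(objective, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestRmsd:
    def test_identical_trajectory_zero(self, rng):
        top = _free_topology(5)
        ref = rng.uniform(-3, 3, (5, 3))
        traj = Trajectory(np.stack([ref, ref]), np.arange(2.0))
        assert np.all(rmsd_backbone(traj, top, ref, "all") < 1e-12)

    def test_rigid_motion_removed(self, rng):
        top = _free_topology(6)
        ref = rng.uniform(-3, 3, (6, 3))
        frames = []
        for k in range(4):
            rot = Rotation.from_rotvec(rng.uniform(-2, 2, 3)).as_matrix()
            frames.append(ref @ rot.T + rng.uniform(-10, 10, 3))
        traj = Trajectory(np.stack(frames), np.arange(4.0))
        assert np.all(rmsd_backbone(traj, top, ref, "all") < 1e-6)

    def test_single_displaced_atom_bound(self, rng):
        m = 10
        top = _free_topology(m)
        ref = rng.uniform(-5, 5, (m, 3))
        moved = ref.copy()
        moved[0] += np.array([1.0, 0.0, 0.0])
        traj = Trajectory(moved[None], np.array([0.0]))
        value = rmsd_backbone(traj, top, ref, "all")[0]
        assert value <= 1.0 / np.sqrt(m) + 1e-12

    def test_matches_brute_force_rotation_search(self, rng):
        ref = rng.uniform(-4, 4, (5, 3))
        mobile = rng.uniform(-4, 4, (5, 3))
        top = _free_topology(5)
        traj = Trajectory(mobile[None], np.array([0.0]))
        closed_form = rmsd_backbone(traj, top, ref, "all")[0]
        assert closed_form == pytest.approx(brute_force_rmsd(mobile, ref), abs=1e-3)

    def test_backbone_selection_uses_nca_c(self):
        spec = ToyComplexSpec(n_protein_residues=3, hbond_schedule=[], n_frames=2)
        top, traj, _ = generate_toy_complex(spec)
        values = rmsd_backbone(traj, top, traj.coordinates[0], "backbone_nca_c")
        assert np.all(values < 1e-12)

    def test_too_few_atoms_rejected(self, rng):
        top = _free_topology(5, names=["CA", "X", "X", "X", "X"])
        traj = Trajectory(rng.normal(size=(1, 5, 3)), np.array([0.0]))
        with pytest.raises(ValidationError, match="3"):
            rmsd_backbone(traj, top, traj.coordinates[0], "backbone_nca_c")


class TestBFactor:
    def test_static_trajectory_zero(self, rng):
        top = _free_topology(4)
        frame = rng.uniform(-3, 3, (4, 3))
        traj = Trajectory(np.stack([frame] * 5), np.arange(5.0))
        assert np.all(b_factor(traj, top, "all") < 1e-20)

    def _jitter_fixture(self, sigma, n_frames, rng):
        # 49 anchor atoms on a big sphere + 1 jittered atom at the centroid:
        # the rigid fit then absorbs only a small share of the fluctuation
        n_fixed = 49
        base = 10.0 * Rotation.random(n_fixed, random_state=1).as_matrix()[:, :, 0]
        frames = np.empty((n_frames, n_fixed + 1, 3))
        frames[:, :n_fixed, :] = base
        frames[:, n_fixed, :] = rng.normal(0.0, sigma, (n_frames, 3))
        top = _free_topology(n_fixed + 1)
        return Trajectory(frames, np.arange(float(n_frames))), top

    def test_isotropic_jitter_recovers_expected_b(self, rng):
        sigma = 0.1
        traj, top = self._jitter_fixture(sigma, 10**4, rng)
        b = b_factor(traj, top, "all")
        expected = (8.0 * np.pi**2 / 3.0) * 3.0 * sigma**2
        assert b[-1] == pytest.approx(expected, rel=0.10)

    def test_b_scales_with_variance(self, rng):
        traj1, top = self._jitter_fixture(0.1, 4000, np.random.default_rng(5))
        traj2, _ = self._jitter_fixture(0.2, 4000, np.random.default_rng(6))
        ratio = b_factor(traj2, top, "all")[-1] / b_factor(traj1, top, "all")[-1]
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_single_frame_rejected(self, rng):
        top = _free_topology(4)
        traj = Trajectory(rng.normal(size=(1, 4, 3)), np.array([0.0]))
        with pytest.raises(ValidationError, match="2 frames"):
            b_factor(traj, top, "all")


class TestHBonds:
    def test_scheduled_occupancies(self):
        spec = ToyComplexSpec(
            n_protein_residues=3,
            hbond_schedule=[
                [((0, 100), True)],
                [((0, 50), True), ((50, 100), False)],
                [((0, 100), False)],
            ],
            n_frames=100,
        )
        top, traj, bonds = generate_toy_complex(spec)
        stats = hbond_stats(traj, top, bonds, HBondCriteria())
        np.testing.assert_allclose(stats.table["occupancy"].to_numpy(), [1.0, 0.5, 0.0])

    def test_occupancy_monotone_in_cutoffs(self, rng):
        spec = ToyComplexSpec(
            n_protein_residues=2,
            hbond_schedule=[[((0, 60), True), ((60, 120), False)],
                            [((0, 120), True)]],
            n_frames=120,
            jitter_sigma=0.4,
            seed=3,
        )
        top, traj, bonds = generate_toy_complex(spec)
        base = hbond_stats(traj, top, bonds, HBondCriteria(3.5, 120.0))
        looser_d = hbond_stats(traj, top, bonds, HBondCriteria(4.5, 120.0))
        looser_a = hbond_stats(traj, top, bonds, HBondCriteria(3.5, 100.0))
        for loose in (looser_d, looser_a):
            assert np.all(
                loose.table["occupancy"].to_numpy() >= base.table["occupancy"].to_numpy()
            )

    def test_mean_over_formed_frames_flag(self):
        spec = ToyComplexSpec(
            n_protein_residues=1,
            hbond_schedule=[[((0, 50), True), ((50, 100), False)]],
            n_frames=100,
        )
        top, traj, bonds = generate_toy_complex(spec)
        all_frames = hbond_stats(traj, top, bonds, mean_over="all")
        formed_only = hbond_stats(traj, top, bonds, mean_over="formed")
        assert formed_only.table["mean_distance"].iloc[0] == pytest.approx(2.8, abs=1e-9)
        assert all_frames.table["mean_distance"].iloc[0] == pytest.approx(3.9, abs=1e-9)

    def test_coincident_atoms_rejected(self):
        top = _free_topology(4)
        coords = np.zeros((1, 4, 3))
        coords[0, 2] = [3.0, 0, 0]
        bond = HBondDefinition(0, 1, 2)
        with pytest.raises(GeometryError):
            hbond_stats(Trajectory(coords, np.array([0.0])), top, [bond])


class TestNativeFraction:
    @pytest.fixture
    def intra_fixture(self):
        spec = ToyComplexSpec(
            n_protein_residues=2,
            hbond_schedule=[
                [((0, 80), True)],
                [((0, 40), True), ((40, 80), False)],
            ],
            n_frames=80,
            intra_protein=True,
        )
        return generate_toy_complex(spec)

    def test_native_set_matches_design(self, intra_fixture):
        top, traj, bonds = intra_fixture
        native = detect_native_hbonds(top, traj.coordinates[0])
        assert {(b.donor_atom, b.acceptor_atom) for b in native} == {
            (b.donor_atom, b.acceptor_atom) for b in bonds
        }

    def test_repeated_native_frame_gives_one(self, intra_fixture):
        top, traj, _ = intra_fixture
        native = traj.coordinates[0]
        static = Trajectory(np.stack([native] * 5), np.arange(5.0))
        np.testing.assert_allclose(native_hbond_fraction(static, top, native), 1.0)

    def test_scheduled_break_halves_fraction(self, intra_fixture):
        top, traj, _ = intra_fixture
        frac = native_hbond_fraction(traj, top, traj.coordinates[0])
        assert np.all(frac[:40] == 1.0)
        assert np.all(frac[40:] == 0.5)

    def test_displaced_donors_give_zero(self, intra_fixture):
        top, traj, _ = intra_fixture
        native = traj.coordinates[0]
        wrecked = native.copy()
        wrecked[top.protein_index] += np.array([10.0, 0.0, 0.0]) * (
            np.arange(len(top.protein_index)) % 3 == 0
        )[:, None]
        frac = native_hbond_fraction(
            Trajectory(wrecked[None], np.array([0.0])), top, native
        )
        assert frac[0] == 0.0

    def test_no_native_bonds_rejected(self, rng):
        top = _free_topology(4)
        traj = Trajectory(rng.normal(size=(2, 4, 3)), np.arange(2.0))
        with pytest.raises(GeometryError, match="native"):
            native_hbond_fraction(traj, top, traj.coordinates[0])
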