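import numpy as np
import pytest

from gpcrmsm.errors import (
    ParameterError,
    SelectionError,
    TopologyError,
)
from gpcrmsm.features import (
    STATE_CLOSED,
    STATE_INTERMEDIATE,
    STATE_OPEN,
    FeatureSeries,
    assign_states,
    backbone_rmsd,
    com_distance,
    count_hbonds,
    ecd_tilt_angle,
    helix_end_com,
    min_polar_distance,
    tm6_z_shift,
)
from gpcrmsm.io_core import Atom, Topology, Trajectory, select_atoms
from gpcrmsm.synthetic import build_ideal_helix

from conftest import make_topology, single_frame
from test_synthetic import helix_axis_by_ca_fit


def co_only_topology(n_res):
    """Residues with only C and O atoms, for constructed C=O geometries."""
    atoms = []
    i = 1
    for r in range(1, n_res + 1):
        atoms.append(Atom(i, "C", r, "ALA", "A", "C")); i += 1
        atoms.append(Atom(i, "O", r, "ALA", "A", "O")); i += 1
    return Topology(atoms)


class TestEcdTiltAngle:
    def test_aligned_co_vectors_give_zero(self):
        topo = co_only_topology(5)
        xyz = np.zeros((10, 3))
        xyz[1::2] = [0, 0, 1]  # every O one Å above its C
        xyz[:, 0] += np.repeat(np.arange(5), 2) * 5  # spread residues out
        t = ecd_tilt_angle(single_frame(topo, xyz), helix_residues=(1, 5))
        assert t.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_co_vectors_give_45(self):
        topo = co_only_topology(4)
        xyz = np.zeros((8, 3))
        xyz[1::2] = np.array([1, 0, 1]) / np.sqrt(2)
        t = ecd_tilt_angle(single_frame(topo, xyz), helix_residues=(1, 4))
        assert t.values[0] == pytest.approx(45.0, abs=1e-9)

    def test_ideal_helix_at_30_degrees(self):
        axis = np.array([np.sin(np.radians(30)), 0, np.cos(np.radians(30))])
        topo, xyz = build_ideal_helix(18, axis=axis)
        fit = helix_axis_by_ca_fit(topo, xyz)
        oracle = np.degrees(np.arccos(np.clip(fit @ [0, 0, 1], -1, 1)))
        t = ecd_tilt_angle(Trajectory(topo, xyz[None]), helix_residues=(1, 18))
        assert t.values[0] == pytest.approx(30.0, abs=5.0)
        assert t.values[0] == pytest.approx(oracle, abs=5.0)

    def test_translation_and_z_rotation_invariance(self):
        topo, xyz = build_ideal_helix(18, axis=(0.5, 0.3, 0.8))
        base = ecd_tilt_angle(Trajectory(topo, xyz[None]), (1, 18)).values[0]
        shifted = ecd_tilt_angle(Trajectory(topo, (xyz + [10, -4, 7])[None]),
                                 (1, 18)).values[0]
        a = np.radians(73.0)
        Rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        rotated = ecd_tilt_angle(Trajectory(topo, (xyz @ Rz.T)[None]), (1, 18)).values[0]
        assert shifted == pytest.approx(base, abs=1e-9)
        assert rotated == pytest.approx(base, abs=1e-9)

    def test_missing_atom_names_residue(self):
        topo = make_topology(5, names=("N", "CA", "C"))  # no O
        with pytest.raises(TopologyError, match="1"):
            ecd_tilt_angle(single_frame(topo, np.zeros((15, 3))), (1, 5))


class TestComDistance:
    def test_three_four_five(self, topo100):
        xyz = np.zeros((topo100.n_atoms, 3))
        b = select_atoms(topo100, "name CA and resid 2")
        xyz[b.indices[0]] = [3, 4, 0]
        a = select_atoms(topo100, "name CA and resid 1")
        d = com_distance(single_frame(topo100, xyz), a, b)
        assert d.values[0] == pytest.approx(5.0)

    def test_identical_selections_zero(self, topo100):
        xyz = np.random.default_rng(0).normal(size=(topo100.n_atoms, 3))
        s = select_atoms(topo100, "resid 1-10")
        d = com_distance(single_frame(topo100, xyz), s, s)
        assert d.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_square_corners_centroid(self):
        topo = make_topology(5, names=("CA",))
        xyz = np.array([[1, 1, 0], [1, -1, 0], [-1, -1, 0], [-1, 1, 0], [0, 0, 0]], float)
        d = com_distance(single_frame(topo, xyz),
                         select_atoms(topo, "resid 1-4"), select_atoms(topo, "resid 5"))
        assert d.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_selection_rejected(self, topo100):
        xyz = np.zeros((topo100.n_atoms, 3))
        with pytest.raises(SelectionError):
            com_distance(single_frame(topo100, xyz),
                         select_atoms(topo100, "resid 500"),
                         select_atoms(topo100, "resid 1"))


class TestHelixEndCom:
    def test_four_residue_helix_uses_all(self):
        topo = make_topology(4)
        xyz = np.random.default_rng(1).normal(size=(16, 3))
        com = helix_end_com(single_frame(topo, xyz), (1, 4), end="extracellular")
        np.testing.assert_allclose(com[0], xyz.mean(axis=0))

    def test_collinear_helix_z_mean(self):
        topo = make_topology(10)
        xyz = np.zeros((40, 3))
        xyz[:, 2] = np.repeat(np.arange(10), 4) * 1.5
        com = helix_end_com(single_frame(topo, xyz), (1, 10), end="extracellular")
        expected = xyz[np.repeat(np.arange(10), 4) >= 6, 2].mean()
        assert com[0, 2] == pytest.approx(expected)

    def test_ends_are_disjoint(self):
        topo = make_topology(10)
        xyz = np.zeros((40, 3))
        xyz[:, 2] = np.repeat(np.arange(10), 4)
        tr = single_frame(topo, xyz)
        hi = helix_end_com(tr, (1, 10), end="extracellular")
        lo = helix_end_com(tr, (1, 10), end="intracellular")
        assert hi[0, 2] > lo[0, 2]

    def test_short_helix_rejected(self):
        topo = make_topology(3)
        with pytest.raises(ParameterError):
            helix_end_com(single_frame(topo, np.zeros((12, 3))), (1, 3))


class TestTm6ZShift:
    def make_two_helix_traj(self, displacement):
        topo = make_topology(40)  # residues 1-20 "TM3", 21-40 "TM6"
        xyz = np.random.default_rng(2).normal(size=(topo.n_atoms, 3))
        frames = np.stack([xyz, xyz.copy()])
        tm6_atoms = np.repeat(np.arange(1, 41), 4)[: topo.n_atoms] >= 21
        frames[1, tm6_atoms] += displacement
        return Trajectory(topo, frames)

    def test_static_trajectory_zero(self):
        traj = self.make_two_helix_traj([0, 0, 0])
        s = tm6_z_shift(traj, (21, 40), (1, 20))
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)

    def test_constructed_minus_two(self):
        traj = self.make_two_helix_traj([0, 0, -2.0])
        s = tm6_z_shift(traj, (21, 40), (1, 20))
        assert s.values[1] == pytest.approx(-2.0, abs=1e-12)

    def test_rigid_translation_cancels(self):
        traj = self.make_two_helix_traj([0, 0, 0])
        traj.coords[1] += [5, 5, 9]  # whole-receptor drift
        s = tm6_z_shift(traj, (21, 40), (1, 20))
        assert s.values[1] == pytest.approx(0.0, abs=1e-12)

    def test_bad_reference_frame(self):
        traj = self.make_two_helix_traj([0, 0, 0])
        with pytest.raises(ParameterError):
            tm6_z_shift(traj, (21, 40), (1, 20), reference_frame=5)


class TestBackboneRmsd:
    def test_identity_and_translation(self, topo100):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(topo100.n_atoms, 3))
        sel = select_atoms(topo100, "backbone")
        frames = np.stack([ref, ref + [3, 4, 0]])
        traj = Trajectory(topo100, frames)
        aligned = backbone_rmsd(traj, ref, sel)
        np.testing.assert_allclose(aligned.values, 0.0, atol=1e-8)
        raw = backbone_rmsd(traj, ref, sel, align=False)
        assert raw.values[1] == pytest.approx(5.0, abs=1e-9)

    def test_random_rotations_align_to_zero(self, topo100):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        ref = rng.normal(size=(topo100.n_atoms, 3))
        sel = select_atoms(topo100, "backbone")
        frames = np.array([ref @ Rotation.random(random_state=s).as_matrix().T + rng.normal(size=3)
                           for s in range(100)])
        vals = backbone_rmsd(Trajectory(topo100, frames), ref, sel).values
        assert vals.max() < 1e-8

    def test_atom_count_mismatch(self, topo100):
        from gpcrmsm.errors import ConsistencyError

        with pytest.raises(ConsistencyError):
            backbone_rmsd(single_frame(topo100, np.zeros((topo100.n_atoms, 3))),
                          np.zeros((5, 3)), select_atoms(topo100, "backbone"))


class TestCountHbonds:
    def build_pair_system(self, d1, d2):
        """Two N/O pairs at distances d1, d2 along x, residues 1/2 vs 3/4."""
        atoms = [Atom(1, "N", 1, "ALA", "A", "N"), Atom(2, "N", 2, "ALA", "A", "N"),
                 Atom(3, "O", 3, "ALA", "A", "O"), Atom(4, "O", 4, "ALA", "A", "O")]
        topo = Topology(atoms)
        xyz = np.array([[0, 0, 0], [0, 50, 0], [d1, 0, 0], [d2, 50, 0]], float)
        return single_frame(topo, xyz)

    def test_two_contacts_at_29(self):
        traj = self.build_pair_system(2.9, 2.9)
        c = count_hbonds(traj, [("resid 1", "resid 3"), ("resid 2", "resid 4")])
        assert c.values[0] == 2

    def test_beyond_cutoff_not_counted(self):
        traj = self.build_pair_system(4.5, 2.9)
        c = count_hbonds(traj, [("resid 1", "resid 3"), ("resid 2", "resid 4")])
        assert c.values[0] == 1

    def test_cutoff_is_inclusive(self):
        traj = self.build_pair_system(3.6, 10.0)
        c = count_hbonds(traj, [("resid 1", "resid 3")])
        assert c.values[0] == 1

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        topo = make_topology(20, names=("N", "O"))
        xyz = rng.normal(scale=4, size=(topo.n_atoms, 3))
        traj = single_frame(topo, xyz)
        pairs = [(f"resid {i} and name N", f"resid {i + 10} and name O")
                 for i in range(1, 11)]
        counts = [count_hbonds(traj, pairs, cutoff=c).values[0]
                  for c in (2.0, 3.0, 3.6, 5.0, 8.0)]
        assert counts == sorted(counts)

    def test_angle_criterion_with_explicit_hydrogen(self):
        # donor N with H pointing at the acceptor: passes; pointing away: fails
        atoms = [Atom(1, "N", 1, "ALA", "A", "N"), Atom(2, "H", 1, "ALA", "A", "H"),
                 Atom(3, "O", 2, "ALA", "A", "O")]
        topo = Topology(atoms)
        toward = np.array([[0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]], float)
        away = np.array([[0, 0, 0], [-1.0, 0, 0], [2.9, 0, 0]], float)
        pair = [("resid 1 and name N", "resid 2 and name O")]
        assert count_hbonds(single_frame(topo, toward), pair, angle_min=120).values[0] == 1
        assert count_hbonds(single_frame(topo, away), pair, angle_min=120).values[0] == 0

    def test_empty_pair_list_rejected(self, topo100):
        with pytest.raises(ParameterError):
            count_hbonds(single_frame(topo100, np.zeros((topo100.n_atoms, 3))), [])


class TestMinPolarDistance:
    def glu_arg_system(self):
        atoms = [Atom(1, "OE1", 1, "GLU", "A", "O"), Atom(2, "OE2", 1, "GLU", "A", "O"),
                 Atom(3, "NH1", 2, "ARG", "A", "N"), Atom(4, "NH2", 2, "ARG", "A", "N")]
        xyz = np.array([[0, 0, 0], [0, 8, 0], [2.8, 0, 0], [9, 9, 9]], float)
        return single_frame(Topology(atoms), xyz)

    def test_constructed_minimum(self):
        d = min_polar_distance(self.glu_arg_system(), 1, 2)
        assert d.values[0] == pytest.approx(2.8)

    def test_same_residue_zero(self):
        d = min_polar_distance(self.glu_arg_system(), 1, 1)
        assert d.values[0] == 0.0

    def test_translation_shifts_single_pair_exactly(self):
        atoms = [Atom(1, "OE1", 1, "GLU", "A", "O"), Atom(2, "NH1", 2, "ARG", "A", "N")]
        xyz = np.array([[0, 0, 0], [2.0, 0, 0]], float)
        base = min_polar_distance(single_frame(Topology(atoms), xyz), 1, 2).values[0]
        xyz2 = xyz.copy()
        xyz2[1] += [10, 0, 0]
        moved = min_polar_distance(single_frame(Topology(atoms), xyz2), 1, 2).values[0]
        assert moved == pytest.approx(base + 10)

    def test_no_polar_atoms_rejected(self):
        atoms = [Atom(1, "CA", 1, "ALA", "A", "C"), Atom(2, "NH1", 2, "ARG", "A", "N")]
        with pytest.raises(TopologyError):
            min_polar_distance(single_frame(Topology(atoms), np.zeros((2, 3))), 1, 2)


class TestAssignStates:
    def test_printed_partition_values(self):
        tilt = FeatureSeries("t", [130.0, 40.0, 80.0, 15.0, 155.0], "degrees")
        seq = assign_states(tilt)
        assert list(seq.labels) == [STATE_CLOSED, STATE_OPEN, STATE_INTERMEDIATE,
                                    STATE_INTERMEDIATE, STATE_INTERMEDIATE]
        assert seq.m == 3 and seq.provenance == "threshold"

    def test_kmeans_scheme_is_seeded(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(40, 5, 200), rng.normal(125, 5, 200)])
        vals = np.clip(vals, 0, 180)
        tilt = FeatureSeries("t", vals, "degrees")
        a = assign_states(tilt, scheme="kmeans", n_states=2, seed=1)
        b = assign_states(tilt, scheme="kmeans", n_states=2, seed=1)
        np.testing.assert_array_equal(a.labels, b.labels)
        # clusters separate the two basins (up to label permutation)
        assert np.unique(a.labels[:200]).size == 1
        assert np.unique(a.labels[200:]).size == 1

    def test_empty_series_rejected(self):
        with pytest.raises(ParameterError):
            assign_states(FeatureSeries("t", [], "degrees"))
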