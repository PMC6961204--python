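"""Structural descriptors: correctness oracles and invariance properties."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tprspring as tp
from tprspring.geometry import _dihedral_values
from tprspring.io import StructureModel


def make_points_structure(coords, atom_names=None, res_ids=None,
                          res_names=None):
    n = len(coords)
    return StructureModel(
        atom_names=np.array(atom_names or ["CA"] * n, dtype="U6"),
        elements=np.array(["C"] * n, dtype="U2"),
        res_ids=np.array(res_ids if res_ids is not None else np.arange(1, n + 1)),
        res_names=np.array(res_names or ["ALA"] * n, dtype="U5"),
        chain_ids=np.array(["A"] * n, dtype="U4"),
        coords=np.asarray(coords, dtype=float),
        masses=np.full(n, 12.011))


def two_unit_annotation():
    from tprspring.io import RepeatAnnotation, RepeatUnit
    return RepeatAnnotation([
        RepeatUnit("U1", 1, 1, (1, 1), (1, 1), {1: 1, 30: 1}),
        RepeatUnit("U2", 2, 2, (2, 2), (2, 2), {1: 2, 30: 2}),
    ])


class TestDistances:
    def test_single_atom_units_five_angstrom_apart(self):
        model = make_points_structure([[0, 0, 0], [3, 4, 0]])
        ann = two_unit_annotation()
        s = tp.end_to_end_distance(model, ann, "U1", "U2")
        assert s.values[0] == pytest.approx(5.000, abs=1e-9)

    def test_solenoid_end_to_end_matches_ground_truth(self, solenoid,
                                                      solenoid_ann):
        s = tp.end_to_end_distance(solenoid, solenoid_ann, "R1", "R10")
        assert s.values[0] == pytest.approx(
            solenoid.metadata["end_to_end_distance"], abs=1e-3)

    def test_inter_tpr_matches_ground_truth_and_warns_when_not_adjacent(
            self, solenoid, solenoid_ann):
        s = tp.inter_tpr_distance(solenoid, solenoid_ann, "R3", "R4")
        assert s.values[0] == pytest.approx(
            solenoid.metadata["inter_repeat_distance"]["R3-R4"], abs=1e-3)
        with pytest.warns(UserWarning, match="not consecutive"):
            tp.inter_tpr_distance(solenoid, solenoid_ann, "R1", "R5")

    def test_identical_ranges_give_zero(self, solenoid, solenoid_ann):
        s = tp.end_to_end_distance(solenoid, solenoid_ann, "R2", "R2")
        assert s.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_intra_tpr_distance_of_constructed_pair(self):
        model = make_points_structure([[0, 0, 0], [6.63, 0, 0]])
        ann = two_unit_annotation()
        # unit U1 with Ψ1 -> res 1, Ψ30 -> res 2
        from tprspring.io import RepeatAnnotation, RepeatUnit
        ann = RepeatAnnotation([RepeatUnit("U1", 1, 2, (1, 1), (2, 2),
                                           {1: 1, 30: 2})])
        s = tp.intra_tpr_distance(model, ann, "U1")
        assert s.values[0] == pytest.approx(6.63, abs=1e-9)

    def test_atom_pair_distance_and_error_reporting(self):
        model = make_points_structure(
            [[0, 0, 0], [0, 0, 3.0]], atom_names=["O", "N"], res_ids=[280, 284],
            res_names=["GLU", "PRO"])
        s = tp.atom_pair_distance(model, "E280:O", (284, "N"))
        assert s.values[0] == pytest.approx(3.00, abs=1e-9)
        with pytest.raises(ValueError, match="E281:O"):
            tp.atom_pair_distance(model, "E281:O", (284, "N"))


class TestBABAngle:
    @staticmethod
    def three_anchor_annotation():
        from tprspring.io import RepeatAnnotation, RepeatUnit
        return RepeatAnnotation([
            RepeatUnit("U1", 1, 1, (1, 1), (1, 1), {1: 1, 30: 1}),
            RepeatUnit("U2", 2, 3, (2, 2), (3, 3), {1: 2, 2: 2, 30: 3}),
        ])

    def test_collinear_anchors_give_180(self):
        model = make_points_structure([[2, 0, 0], [1, 0, 0], [0, 0, 0]])
        s = tp.bab_angle(model, self.three_anchor_annotation(), "U2")
        assert s.values[0] == pytest.approx(180.0, abs=1e-6)

    def test_right_angle_anchors(self):
        model = make_points_structure([[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        s = tp.bab_angle(model, self.three_anchor_annotation(), "U2")
        assert s.values[0] == pytest.approx(90.0, abs=1e-9)

    def test_first_unit_has_no_predecessor(self, solenoid, solenoid_ann):
        with pytest.raises(ValueError, match="predecessor"):
            tp.bab_angle(solenoid, solenoid_ann, "R1")

    def test_solenoid_angle_matches_ground_truth(self, solenoid, solenoid_ann):
        s = tp.bab_angle(solenoid, solenoid_ann, "R5")
        assert s.values[0] == pytest.approx(
            solenoid.metadata["inter_repeat_angle"]["R5"], abs=1e-2)


def dihedral_fixture(angle_deg):
    """Four atoms built so the dihedral equals ``angle_deg`` by construction."""
    phi = np.deg2rad(angle_deg)
    return np.array([
        [1.0, 0.0, -1.0],
        [0.0, 0.0, 0.0],
        [0.0, 0.0, 1.5],
        [np.cos(phi), np.sin(phi), 2.5],
    ])


class TestDihedrals:
    @pytest.mark.parametrize("angle", [0.0, 90.0, -72.24, 179.0, -120.0])
    def test_constructed_rotation_is_recovered(self, angle):
        p = dihedral_fixture(angle)
        got = _dihedral_values(*[p[i][None] for i in range(4)])[0]
        assert got == pytest.approx(angle, abs=1e-3)

    def test_sign_convention_matches_biotite(self):
        import biotite.structure as struc
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.normal(size=(4, 3)) * 3
            ours = _dihedral_values(*[p[i][None] for i in range(4)])[0]
            theirs = np.degrees(struc.dihedral(p[0], p[1], p[2], p[3]))
            # biotite computes in float32
            assert ours == pytest.approx(float(theirs), abs=1e-4)

    def test_cis_zero_trans_180(self):
        assert _dihedral_values(*[dihedral_fixture(0.0)[i][None]
                                  for i in range(4)])[0] == pytest.approx(0.0, abs=1e-9)
        assert abs(_dihedral_values(*[dihedral_fixture(180.0)[i][None]
                                      for i in range(4)])[0]) == pytest.approx(180.0, abs=1e-9)

    def test_chi1_of_constructed_side_chain(self):
        target = -72.24
        p = dihedral_fixture(target)
        model = make_points_structure(
            p, atom_names=["N", "CA", "CB", "CG"], res_ids=[254] * 4,
            res_names=["LEU"] * 4)
        s = tp.dihedral_series(model, 254, "chi1")
        assert s.values[0] == pytest.approx(target, abs=1e-3)

    def test_chi1_of_gly_ala_raises(self):
        model = make_points_structure(
            dihedral_fixture(0), atom_names=["N", "CA", "CB", "CG"],
            res_ids=[10] * 4, res_names=["ALA"] * 4)
        with pytest.raises(ValueError, match="no χ1"):
            tp.dihedral_series(model, 10, "chi1")

    def test_circular_mean_of_wrapped_values_is_180_not_zero(self):
        s = tp.AngleSeries(times=[0, 1], values=[179.0, -179.0])
        assert abs(s.mean) == pytest.approx(180.0, abs=1e-6)
        assert s.std < 2.0


class TestRotamers:
    def test_single_state_occupancy_one(self):
        s = tp.AngleSeries(times=np.arange(100), values=np.full(100, -72.0))
        pops = tp.assign_rotamers(s)
        assert pops.occupancies.sum() == pytest.approx(1.0)
        gm = pops.state_names.index("gauche-")
        assert pops.occupancies[gm] == 1.0
        assert pops.means[gm] == pytest.approx(-72.0, abs=1e-9)

    def test_three_state_mixture_recovers_means(self, rng):
        # LF1/LF2/LF3-like χ1 states at -54.51 / 69.58 / -167.53 degrees
        parts = [rng.normal(-54.51, 13.94, 7000),
                 rng.normal(69.58, 9.74, 2500),
                 rng.normal(-167.53, 12.19, 500)]
        values = np.concatenate(parts)
        s = tp.AngleSeries(times=np.arange(len(values)), values=values)
        pops = tp.assign_rotamers(s)
        assert pops.occupancies.sum() == pytest.approx(1.0)
        got = {n: m for n, m, o in zip(pops.state_names, pops.means,
                                       pops.occupancies) if o > 0.01}
        assert got["gauche-"] == pytest.approx(-54.51, abs=2.0)
        assert got["gauche+"] == pytest.approx(69.58, abs=2.0)
        assert got["trans"] == pytest.approx(-167.53, abs=6.0)

    @given(st.lists(st.floats(-180.0, 180.0, exclude_min=True),
                    min_size=5, max_size=50),
           st.integers(2, 6))
    @settings(max_examples=50, deadline=None)
    def test_occupancies_sum_to_one_for_any_partition(self, values, n_cuts):
        cuts = tuple(np.linspace(-150, 150, n_cuts))
        s = tp.AngleSeries(times=np.arange(len(values)), values=values)
        pops = tp.assign_rotamers(s, boundaries=cuts)
        assert pops.occupancies.sum() == pytest.approx(1.0)
        assert np.all(pops.occupancies >= 0)


class TestKink:
    @pytest.mark.parametrize("angle", [0.0, 19.1, 30.0, 45.0])
    def test_constructed_kink_recovered_within_one_degree(self, angle):
        model = tp.build_kinked_helix(20, 10, angle)
        s = tp.helix_kink_angle(model, (1, 20), 10)
        assert s.values[0] == pytest.approx(angle, abs=1.0)

    def test_straight_helix_reads_below_two_degrees(self):
        model = tp.build_kinked_helix(30, 15, 0.0)
        s = tp.helix_kink_angle(model, (1, 30), 15)
        assert s.values[0] < 2.0

    def test_short_window_raises_with_minimum(self):
        model = tp.build_kinked_helix(8, 2, 10.0)
        with pytest.raises(ValueError, match="≥ 4"):
            tp.helix_kink_angle(model, (1, 8), 2)

    def test_robust_to_coordinate_noise(self):
        model = tp.build_kinked_helix(24, 12, 19.1)
        traj = tp.perturb_to_trajectory(model, 0.15, 200, seed=6)
        s = tp.helix_kink_angle(traj, (1, 24), 12)
        assert np.mean(s.values) == pytest.approx(19.1, abs=1.5)

    def test_profile_peaks_at_the_kink(self):
        model = tp.build_kinked_helix(24, 12, 30.0)
        prof = tp.kink_angle_profile(model, (1, 24))
        assert prof.shape[0] == 1
        assert prof[0].max() > 5.0


class TestRMSD:
    def test_identical_coordinates_give_zero(self, solenoid):
        s = tp.rmsd(solenoid, solenoid, superpose=False)
        assert s.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_superposition_removes_rigid_motion(self, solenoid, rng):
        from conftest import rigid_motion
        moved = dataclasses.replace(
            solenoid, coords=rigid_motion(solenoid.coords, rng))
        s = tp.rmsd(moved, solenoid, superpose=True)
        assert s.values[0] == pytest.approx(0.0, abs=1e-6)

    def test_uniform_displacement_without_superposition(self, solenoid):
        moved = dataclasses.replace(solenoid,
                                    coords=solenoid.coords + [1.0, 0, 0])
        s = tp.rmsd(moved, solenoid, superpose=False)
        assert s.values[0] == pytest.approx(1.000, abs=1e-9)


class TestRigidMotionInvariance:
    """Every descriptor must be invariant under global rotation+translation."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_descriptors_invariant(self, solenoid, solenoid_ann, seed):
        import dataclasses
        from conftest import rigid_motion
        rng = np.random.default_rng(seed)
        moved = dataclasses.replace(
            solenoid, coords=rigid_motion(solenoid.coords, rng))
        u = solenoid_ann.unit("R5")
        checks = [
            (tp.end_to_end_distance, (solenoid_ann, "R1", "R10")),
            (tp.inter_tpr_distance, (solenoid_ann, "R5", "R6")),
            (tp.intra_tpr_distance, (solenoid_ann, "R5")),
            (tp.bab_angle, (solenoid_ann, "R5")),
            (tp.helix_kink_angle, ((u.helix_b[0], u.helix_b[1]),
                                   u.helix_b[0] + 5)),
            (tp.atom_pair_distance, ((u.start, "CA"), (u.end, "CA"))),
        ]
        for fn, args in checks:
            ref_val = fn(solenoid, *args).values[0]
            mov_val = fn(moved, *args).values[0]
            assert mov_val == pytest.approx(
                ref_val, abs=max(1e-6 * abs(ref_val), 1e-7)), fn.__name__
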