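"""Generators: OU statistics, mixture occupancy, solenoid ground truth."""

import numpy as np
import pytest

import tprspring as tp
from tprspring.synthetic import ParameterError, _ou_path
from tprspring.units import thermal_variance_A2


def euler_maruyama_ou(rng, n, mean, sd, tau, dt):
    """Brute-force small-dt OU integrator (independent reference)."""
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    noise_sd = sd * np.sqrt(2.0 * dt / tau)
    xi = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = x[i - 1] - (x[i - 1] - mean) * dt / tau + noise_sd * xi[i - 1]
    return x


class TestOU:
    def test_stationary_variance_matches_closed_form(self):
        # wt-like stiffness: variance must equal k_BT/k = 19.78 A^2 (0.1978 nm^2)
        p = tp.OUParams(k=20.80, mean=71.6, tau=100.0, dt=10.0,
                        n_frames=100_000, seed=11)
        s = tp.simulate_ou_series(p)
        expected = thermal_variance_A2(20.80, 298.0)
        assert expected == pytest.approx(19.78, abs=0.01)
        assert np.var(s.values) == pytest.approx(expected, rel=0.03)
        assert np.mean(s.values) == pytest.approx(71.6, abs=0.15)

    @pytest.mark.parametrize("k,tau", [(20.80, 100.0), (12.61, 50.0), (80.0, 200.0)])
    def test_exact_update_agrees_with_small_dt_integrator(self, k, tau):
        """Exact AR(1) at coarse dt vs Euler-Maruyama at fine dt."""
        sd = np.sqrt(thermal_variance_A2(k, 298.0))
        p = tp.OUParams(k=k, mean=70.0, tau=tau, dt=tau / 10, n_frames=60_000,
                        seed=5)
        exact = tp.simulate_ou_series(p).values
        rng = np.random.default_rng(5)
        em = euler_maruyama_ou(rng, 60_000, 70.0, sd, tau, tau / 200)
        assert np.var(exact) == pytest.approx(sd**2, rel=0.05)
        assert np.var(em[::20]) == pytest.approx(np.var(exact), rel=0.08)

    def test_infinite_stiffness_limit_freezes_the_series(self):
        # stationary SD scales as k^(-1/2): 1e7 pN/nm pins it below 0.01 A
        p = tp.OUParams(k=1e7, mean=71.6, tau=100.0, dt=10.0, n_frames=5000,
                        seed=3)
        s = tp.simulate_ou_series(p)
        assert np.std(s.values) < 0.01
        assert np.all(np.abs(s.values - 71.6) < 0.05)

    def test_autocorrelation_time_close_to_tau(self):
        p = tp.OUParams(k=20.80, mean=71.6, tau=100.0, dt=10.0,
                        n_frames=200_000, seed=8)
        x = tp.simulate_ou_series(p).values - 71.6
        # lag-1 autocorrelation of AR(1) is exp(-dt/tau)
        rho1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
        assert rho1 == pytest.approx(np.exp(-10.0 / 100.0), abs=0.01)

    def test_deterministic_under_fixed_seed(self):
        p = tp.OUParams(k=20.80, mean=71.6, tau=100.0, dt=10.0, n_frames=1000,
                        seed=42)
        a, b = tp.simulate_ou_series(p), tp.simulate_ou_series(p)
        np.testing.assert_array_equal(a.values, b.values)

    def test_x0_override_starts_at_given_value(self):
        p = tp.OUParams(k=20.80, mean=71.6, tau=100.0, dt=10.0, n_frames=100,
                        seed=0)
        s = tp.simulate_ou_series(p, x0=101.7)
        assert s.values[0] == pytest.approx(101.7)

    @pytest.mark.parametrize("bad", [
        dict(k=-1.0), dict(k=np.nan), dict(tau=0.0), dict(dt=-5.0),
        dict(n_frames=1), dict(temperature=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(k=20.0, mean=70.0, tau=100.0, dt=10.0, n_frames=100)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            tp.OUParams(**kwargs)


class TestMixture:
    @staticmethod
    def make_spec(weights=(0.8, 0.2), switch_rate=1e-4, n_frames=200_000,
                  seed=1):
        comps = tuple(
            (tp.OUParams(k=k, mean=m, tau=100.0, dt=10.0, n_frames=n_frames,
                         seed=0), w)
            for (k, m), w in zip(((21.99, 73.0), (12.61, 82.9)), weights))
        return tp.MixtureSimSpec(components=comps, switch_rate=switch_rate,
                                 seed=seed)

    def test_occupancies_converge_to_weights(self):
        # fast switching -> many latent segments -> tight LLN check
        s = tp.simulate_mixture_series(self.make_spec(switch_rate=1e-3))
        occ = np.bincount(s.states, minlength=2) / len(s)
        assert occ[0] == pytest.approx(0.8, abs=0.03)
        assert occ[1] == pytest.approx(0.2, abs=0.03)

    def test_occupancies_at_slow_switching_average_to_weights(self):
        # at switch_rate 1e-4/ps a single run holds only ~200 segments, so
        # average the occupancy over seeds before applying the 3-point check
        occ0 = np.mean([
            np.mean(tp.simulate_mixture_series(
                self.make_spec(seed=s)).states == 0)
            for s in range(1, 6)])
        assert occ0 == pytest.approx(0.8, abs=0.03)

    def test_within_state_dynamics_are_the_component_ou(self):
        s = tp.simulate_mixture_series(self.make_spec())
        for c, (k, m) in enumerate(((21.99, 73.0), (12.61, 82.9))):
            v = s.values[s.states == c]
            assert np.mean(v) == pytest.approx(m, abs=0.3)
            assert np.var(v) == pytest.approx(
                thermal_variance_A2(k, 298.0), rel=0.1)

    def test_single_component_identical_in_law_to_plain_ou(self):
        p = tp.OUParams(k=20.80, mean=71.6, tau=100.0, dt=10.0,
                        n_frames=20_000, seed=9)
        mix = tp.MixtureSimSpec(components=((p, 1.0),), switch_rate=1e-4,
                                seed=9)
        a = tp.simulate_mixture_series(mix)
        b = tp.simulate_ou_series(p)
        # same seed path through the generator: moments must agree closely
        assert np.mean(a.values) == pytest.approx(np.mean(b.values), abs=0.15)
        assert np.var(a.values) == pytest.approx(np.var(b.values), rel=0.05)
        assert np.all(a.states == 0)

    def test_weights_must_sum_to_one(self):
        p = tp.OUParams(k=20.0, mean=70.0, tau=100.0, dt=10.0, n_frames=100)
        with pytest.raises(ParameterError, match="sum to 1"):
            tp.MixtureSimSpec(components=((p, 0.8), (p, 0.3)))

    def test_components_must_share_frame_grid(self):
        p1 = tp.OUParams(k=20.0, mean=70.0, tau=100.0, dt=10.0, n_frames=100)
        p2 = tp.OUParams(k=20.0, mean=70.0, tau=100.0, dt=5.0, n_frames=100)
        with pytest.raises(ParameterError, match="share"):
            tp.MixtureSimSpec(components=((p1, 0.5), (p2, 0.5)))


class TestSolenoid:
    def test_ground_truth_is_self_consistent(self, solenoid, solenoid_ann):
        """Generator metadata equals brute-force recomputation from coords."""
        model = solenoid
        for unit in solenoid_ann.units:
            mask = model.select(res_id_range=(unit.start, unit.end))
            ca1 = model.coords[model.select(res_id=unit.consensus[1],
                                            atom_name="CA")][0]
            ca30 = model.coords[model.select(res_id=unit.consensus[30],
                                             atom_name="CA")][0]
            d = np.linalg.norm(ca30 - ca1)
            assert d == pytest.approx(
                model.metadata["intra_repeat_distance"][unit.unit_id],
                abs=1e-6)
            assert mask.sum() > 0

    def test_twist_zero_inter_repeat_distance_equals_rise(self):
        spec = tp.SolenoidSpec(n_repeats=2, superhelical_rise=8.0,
                               superhelical_twist=0.0,
                               intra_repeat_distance=10.0)
        model = tp.build_solenoid(spec)
        assert model.metadata["inter_repeat_distance"]["R1-R2"] == \
            pytest.approx(8.0, abs=1e-6)

    def test_end_to_end_matches_brute_force_com(self, solenoid, solenoid_spec):
        ann = tp.solenoid_annotation(solenoid_spec)
        first, last = ann.units[0], ann.units[-1]
        coms = []
        for u in (first, last):
            mask = solenoid.select(res_id_range=(u.start, u.end))
            m = solenoid.masses[mask]
            coms.append((m[:, None] * solenoid.coords[mask]).sum(0) / m.sum())
        assert np.linalg.norm(coms[1] - coms[0]) == pytest.approx(
            solenoid.metadata["end_to_end_distance"], abs=1e-9)

    def test_intra_repeat_distance_hits_target(self):
        for target in (6.63, 8.83, 10.0):
            spec = tp.SolenoidSpec(n_repeats=2, intra_repeat_distance=target)
            model = tp.build_solenoid(spec)
            for v in model.metadata["intra_repeat_distance"].values():
                assert v == pytest.approx(target, abs=1e-6)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ParameterError):
            tp.build_solenoid(tp.SolenoidSpec(
                n_repeats=2, intra_repeat_distance=0.5))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            tp.SolenoidSpec(n_repeats=1)
        with pytest.raises(ParameterError):
            tp.SolenoidSpec(n_repeats=2, superhelical_rise=-1.0)
        with pytest.raises(ParameterError):
            tp.KinkSpec(unit=0, helix="B", residue=5, angle=95.0)


class TestKinkedHelix:
    def test_zero_kink_is_a_straight_helix(self):
        model = tp.build_kinked_helix(20, 10, 0.0)
        ca = model.coords[model.atom_names == "CA"]
        # axis-fit residual: distance of CA from the best-fit line < helix radius
        centred = ca - ca.mean(0)
        _, _, vt = np.linalg.svd(centred)
        residual = np.linalg.norm(
            centred - np.outer(centred @ vt[0], vt[0]), axis=1)
        assert np.all(np.abs(residual - 2.3) < 0.5)  # all CA on the cylinder

    def test_kink_position_bounds_enforced(self):
        with pytest.raises(ParameterError):
            tp.build_kinked_helix(20, 0, 10.0)
        with pytest.raises(ParameterError):
            tp.build_kinked_helix(20, 20, 10.0)
        with pytest.raises(ParameterError):
            tp.build_kinked_helix(20, 10, 90.0)


class TestPerturb:
    def test_zero_amplitude_reproduces_input(self, solenoid):
        traj = tp.perturb_to_trajectory(solenoid, 0.0, 5, seed=1)
        for f in range(5):
            np.testing.assert_array_equal(traj.frames[f], solenoid.coords)

    def test_rmsf_matches_isotropic_gaussian(self, solenoid):
        amp = 0.3
        traj = tp.perturb_to_trajectory(solenoid, amp, 500, seed=2)
        disp = traj.frames - solenoid.coords[None]
        rmsf = np.sqrt((disp**2).sum(-1).mean(0))
        assert np.mean(rmsf) == pytest.approx(amp * np.sqrt(3), rel=0.1)

    def test_bit_identical_under_fixed_seed(self, solenoid):
        a = tp.perturb_to_trajectory(solenoid, 0.3, 10, seed=7)
        b = tp.perturb_to_trajectory(solenoid, 0.3, 10, seed=7)
        np.testing.assert_array_equal(a.frames, b.frames)
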