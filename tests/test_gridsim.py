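"""Grid-cell simulator: lattices, rates, oscillator bank, Poisson spiking."""

import numpy as np
import pytest

from gridtorus import gridsim as gs


class TestLatticeAndCenters:
    def test_hexagonal_neighbor_structure(self):
        lat = gs.LatticeSpec("hexagonal", 0.5)
        centers = gs.make_centers(lat, np.array([0.3, 0.7]), arena=1.5,
                                  x0=0.4)
        d = np.sqrt(((centers[:, None] - centers[None, :])**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(0.5, abs=1e-9)
        # an interior point has exactly 6 nearest neighbors at the spacing
        interior = np.argmin(((centers - 0.75)**2).sum(1))
        at_spacing = np.isclose(d[interior], 0.5, atol=1e-9)
        assert at_spacing.sum() == 6

    def test_square_has_four_neighbors(self):
        lat = gs.LatticeSpec("square", 0.5)
        centers = gs.make_centers(lat, np.array([0.5, 0.5]), arena=1.5,
                                  x0=0.4)
        d = np.sqrt(((centers[:, None] - centers[None, :])**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        interior = np.argmin(((centers - 0.75)**2).sum(1))
        assert np.isclose(d[interior], 0.5, atol=1e-9).sum() == 4

    def test_shift_by_one_lattice_vector_is_periodic(self):
        lat = gs.LatticeSpec("hexagonal", 0.5)
        c0 = gs.make_centers(lat, np.array([0.0, 0.0]), arena=1.5, x0=0.4)
        c1 = gs.make_centers(lat, np.array([1.0, 0.0]), arena=1.5, x0=0.4)
        # interior centers coincide (boundary membership may differ)
        inner = lambda c: c[(c[:, 0] > 0) & (c[:, 0] < 1.5)
                            & (c[:, 1] > 0) & (c[:, 1] < 1.5)]
        s0 = {tuple(np.round(p, 9)) for p in inner(c0)}
        s1 = {tuple(np.round(p, 9)) for p in inner(c1)}
        assert s0 == s1


class TestFiringRate:
    def setup_method(self):
        self.pop = gs.GridPopulation(
            1, gs.FieldParams(), gs.LatticeSpec(),
            centers=[np.array([[0.75, 0.75]])])
        self.none = gs.build_oscillator_bank("none")

    def test_baseline_far_from_fields(self):
        r = gs.firing_rate(self.pop, self.none, 0, np.array([[0.1, 0.1]]), 0.0)
        assert r[0] == pytest.approx(0.05)

    def test_peak_rate_at_center(self):
        r = gs.firing_rate(self.pop, self.none, 0, np.array([[0.75, 0.75]]), 0.0)
        assert r[0] == pytest.approx(0.05 + 1.5 / (2 * np.pi * 0.12**2),
                                     rel=1e-6)

    def test_truncation_beyond_x0(self):
        r = gs.firing_rate(self.pop, self.none, 0,
                           np.array([[0.75 + 0.41, 0.75]]), 0.0)
        assert r[0] == pytest.approx(0.05)

    def test_rectification_keeps_rates_nonnegative(self):
        bank = gs.OscillatorBank(np.array([1.0]), np.array([3.0]),
                                 c1=-1.0, c2=1.0)
        t = np.linspace(0, 2, 400)
        rates = gs.firing_rate(self.pop, bank, 0,
                               np.tile([[0.75, 0.75]], (400, 1)), t)
        assert (rates >= 0).all()
        assert (rates == 0).any()  # the negative phase is clipped


class TestOscillatorBank:
    def test_none_preset_is_flat(self):
        bank = gs.build_oscillator_bank("none")
        t = np.linspace(0, 5, 100)
        assert np.allclose(bank.modulation(t), 1.0)

    def test_methods_default_structure(self):
        bank = gs.build_oscillator_bank("methods_default", calibrate=False)
        assert bank.m == 200
        assert 4.0 in bank.omegas and 8.0 in bank.omegas
        a4 = bank.amps[bank.omegas == 4.0][0]
        a8 = bank.amps[bank.omegas == 8.0][0]
        assert a8 / a4 == pytest.approx((0.8 / 0.5) * (8 / 4) ** -0.5,
                                        rel=1e-12)

    def test_single_preset_moves_dominant_line(self):
        bank = gs.build_oscillator_bank("single", freq=12.0, calibrate=False)
        assert 12.0 in bank.omegas
        assert 4.0 not in bank.omegas

    def test_calibration_single_oscillator_closed_form(self):
        # mean of [A sin]_+ is A/pi, so c2 = pi / A
        bank = gs.OscillatorBank(np.array([2.0]), np.array([0.7]),
                                 c1=0.0, c2=1.0)
        c2 = gs.calibrate_c2(bank, T=100.0, dt=0.0005)
        assert c2 == pytest.approx(np.pi / 0.7, rel=1e-3)

    def test_calibration_homogeneity(self):
        bank = gs.build_oscillator_bank("methods_default", calibrate=False)
        double = gs.OscillatorBank(bank.omegas, 2 * bank.amps, 0.0, 1.0)
        c2 = gs.calibrate_c2(bank, T=36.0, dt=0.001)
        c2d = gs.calibrate_c2(double, T=36.0, dt=0.001)
        assert c2d == pytest.approx(c2 / 2, rel=1e-9)

    def test_non_modulated_bank_rejected(self):
        with pytest.raises(ValueError, match="non-modulated"):
            gs.calibrate_c2(gs.build_oscillator_bank("none"))


class TestSimulate:
    def test_zero_rate_population_is_silent(self):
        pop = gs.GridPopulation(2, gs.FieldParams(lambda0=0.0),
                                gs.LatticeSpec(), centers=[np.empty((0, 2))] * 2)
        traj = gs.synth_trajectory(10.0, seed=1)
        spk = gs.simulate(pop, traj, seed=2)
        assert spk.counts().sum() == 0

    def test_stationary_peak_rate_is_poisson(self):
        pop = gs.GridPopulation(1, gs.FieldParams(), gs.LatticeSpec(),
                                centers=[np.array([[0.75, 0.75]])])
        T = 200.0
        traj = gs.Trajectory(np.arange(0, T, 0.01),
                             np.tile([0.75, 0.75], (20_000, 1)))
        lam = 0.05 + 1.5 / (2 * np.pi * 0.12**2)
        counts = [gs.simulate(pop, traj, seed=s).counts()[0]
                  for s in range(8)]
        expect = lam * T
        sd = np.sqrt(expect / 8)
        assert np.mean(counts) == pytest.approx(expect, abs=3.5 * sd)

    def test_oscillations_conserve_expected_spike_count(self):
        """With c2 calibrated over the simulation horizon the rectified
        modulation averages exactly one, so a neuron at a fixed position
        emits the same expected number of spikes with and without
        oscillations (paired Poisson test over 20 seeds)."""
        T = 120.0
        bank = gs.build_oscillator_bank("methods_default", calibrate=False)
        bank.c2 = gs.calibrate_c2(bank, T=T, dt=0.01)
        none = gs.build_oscillator_bank("none")
        pop = gs.GridPopulation(1, gs.FieldParams(), gs.LatticeSpec(),
                                centers=[np.array([[0.75, 0.75]])])
        traj = gs.Trajectory(np.arange(0, T, 0.01),
                             np.tile([0.75, 0.75], (12_000, 1)))
        diffs = []
        for s in range(20):
            c_osc = gs.simulate(pop, traj, bank, seed=50 + s).counts()[0]
            c_non = gs.simulate(pop, traj, none, seed=250 + s).counts()[0]
            diffs.append(c_osc - c_non)
        sem = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3.5 * sem

    def test_conservation_along_trajectory_within_covariance(self):
        """Along a moving trajectory the expected count matches the
        unmodulated one up to the (finite-duration) covariance between the
        spatial rate and the modulation — a few percent here."""
        T = 120.0
        bank = gs.build_oscillator_bank("methods_default", calibrate=False)
        bank.c2 = gs.calibrate_c2(bank, T=T, dt=0.01)
        traj = gs.synth_trajectory(T, seed=3)
        pop = gs.build_population(N=20, seed=4)
        factor = bank.modulation(traj.times)
        ratios = []
        for i in range(pop.N):
            spatial = gs._spatial_rate(pop.centers[i], pop.field_params,
                                       traj.positions)
            mod = np.maximum(spatial * factor, 0.0).sum()
            flat = spatial.sum()
            if flat > 0:
                ratios.append(mod / flat)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_reproducible_given_seed(self):
        pop = gs.build_population(N=5, seed=1)
        traj = gs.synth_trajectory(20.0, seed=2)
        a = gs.simulate(pop, traj, seed=7)
        b = gs.simulate(pop, traj, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a.spikes, b.spikes))


class TestDisplaceFields:
    def test_zero_fraction_is_identity(self):
        pop = gs.build_population(N=3, seed=1)
        out = gs.displace_fields(pop, 0.0, seed=2)
        assert all(np.array_equal(a, b)
                   for a, b in zip(pop.centers, out.centers))

    def test_fixed_magnitude_displacement(self):
        pop = gs.build_population(N=3, seed=1)
        out = gs.displace_fields(pop, 0.12, seed=2)
        for a, b in zip(pop.centers, out.centers):
            d = np.linalg.norm(a - b, axis=1)
            assert np.allclose(d, 0.12 * pop.lattice.spacing, rtol=1e-12)


@pytest.fixture(scope="module")
def traj():
    return gs.synth_trajectory(1800.0, seed=42)


class TestSynthTrajectory:

    def test_stays_in_the_arena(self, traj):
        assert traj.positions.min() >= 0.0
        assert traj.positions.max() <= 1.5

    def test_mean_speed_near_target(self, traj):
        assert 0.12 <= traj.speeds().mean() <= 0.18

    def test_mostly_moving(self, traj):
        assert (traj.speeds() > 0.025).mean() > 0.9

    def test_covers_the_arena(self, traj):
        H, _, _ = np.histogram2d(traj.positions[:, 0], traj.positions[:, 1],
                                 bins=30, range=[[0, 1.5], [0, 1.5]])
        assert (H > 0).mean() >= 0.95

    def test_resampling_roundtrip(self, traj):
        r = traj.resampled(0.02)
        assert r.dt == pytest.approx(0.02)
        assert np.allclose(r.positions[0], traj.positions[0])
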