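"""Synthetic structures, soft pair potential and the BAOAB Langevin engine."""
import numpy as np
import pytest

from sansmi.io_model import SiteSet
from sansmi.shape_analysis import find_aggregates, radius_of_gyration
from sansmi.toy_sim import (KB, PairParams, SimConfig, langevin_step,
                            make_dumbbell, make_uniform_sphere, pair_forces,
                            run_simulation)


class TestGenerators:
    def test_sphere_support_and_count(self, rng):
        ball = make_uniform_sphere(12.0, 500, 2.0, rng)
        assert ball.n_sites == 500
        assert np.all(np.linalg.norm(ball.positions, axis=1) <= 12.0)
        assert np.all(ball.scatlens == 2.0)

    def test_sphere_rg_approaches_uniform_ball_value(self, rng):
        # Rg^2 = (3/5) R^2 for a uniform ball
        ball = make_uniform_sphere(20.0, 5000, 1.0, rng)
        assert radius_of_gyration(ball) == pytest.approx(
            20.0 * np.sqrt(3.0 / 5.0), rel=0.02)

    def test_dumbbell_center_of_mass_at_midpoint(self, rng):
        d = make_dumbbell(5.0, 400, 30.0, 1.0, rng)
        com = d.positions.mean(axis=0)
        assert np.allclose(com, 0.0, atol=1.0)

    def test_dumbbell_zero_separation_like_single_ball(self, rng):
        merged = make_dumbbell(8.0, 2000, 0.0, 1.0, rng)
        ball = make_uniform_sphere(8.0, 4000, 1.0, rng)
        assert radius_of_gyration(merged) == pytest.approx(
            radius_of_gyration(ball), rel=0.03)

    def test_dumbbell_separates_into_two_aggregates(self, rng):
        d = make_dumbbell(4.0, 50, 40.0, 1.0, rng)
        agg = find_aggregates(d, cutoff=10.0)
        assert agg.n_clusters == 2
        assert agg.sizes == {50: 2}


class TestPairForces:
    def test_repulsion_vanishes_at_cutoff(self):
        params = PairParams(repulsion=1e-3, r_cut=6.0, attraction=0.0)
        f, u = pair_forces(np.array([[0.0, 0, 0], [6.0, 0, 0]]), params)
        assert np.allclose(f, 0.0, atol=1e-15)
        assert u == pytest.approx(0.0, abs=1e-15)

    def test_newtons_third_law(self, rng):
        params = PairParams(repulsion=2e-4, r_cut=6.0, attraction=1e-4,
                            r_attr=5.0, width=2.0)
        f, _ = pair_forces(rng.uniform(-6, 6, (10, 3)), params)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-16)

    def test_matches_finite_differences(self, rng):
        params = PairParams(repulsion=2e-4, r_cut=6.0, attraction=1e-4,
                            r_attr=5.0, width=2.0)
        x = rng.uniform(-6, 6, (10, 3))
        f, _ = pair_forces(x, params)
        h = 1e-6
        scale = max(np.abs(f).max(), 1e-12)
        for i in range(3):  # spot-check a few sites
            for a in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, a] += h
                xm[i, a] -= h
                _, up = pair_forces(xp, params)
                _, um = pair_forces(xm, params)
                assert f[i, a] == pytest.approx(-(up - um) / (2 * h),
                                                abs=1e-6 * scale + 1e-12)

    def test_overlap_warns_and_stays_finite(self):
        params = PairParams(repulsion=1e-3, r_cut=6.0)
        with pytest.warns(UserWarning, match="overlap"):
            f, _ = pair_forces(np.zeros((2, 3)), params)
        assert np.all(np.isfinite(f))


class TestLangevin:
    def test_identity_update_at_rest(self):
        cfg = SimConfig(dt=1.0, temperature=0.0, friction=1.0, steps=1)
        x = np.array([[1.0, 2.0, 3.0]])
        v = np.zeros_like(x)
        f = np.zeros_like(x)
        rng = np.random.default_rng(0)
        x2, v2, _ = langevin_step(x, v, f, lambda p: np.zeros_like(p),
                                  np.array([1.0]), cfg, rng)
        assert np.array_equal(x2, x) and np.array_equal(v2, v)

    def test_harmonic_equipartition(self):
        """Positional variance kT/k and velocity variance kT/m for many
        independent particles in a harmonic well (Maxwell-Boltzmann)."""
        k = 1e-4   # Da/fs^2
        mass = 10.0
        temp = 300.0
        cfg = SimConfig(dt=2.0, temperature=temp, friction=5.0, steps=1)
        rng = np.random.default_rng(2024)
        n = 256
        x = np.zeros((n, 3))
        v = np.zeros((n, 3))
        masses = np.full(n, mass)

        def forces(pos):
            return -k * pos  # independent 3-D harmonic wells

        f = forces(x)
        xs, vs = [], []
        for step in range(4000):
            x, v, f = langevin_step(x, v, f, forces, masses, cfg, rng)
            if step >= 1000:
                xs.append(x.copy())
                vs.append(v.copy())
        kT = KB * temp
        var_x = np.var(np.concatenate(xs))
        var_v = np.var(np.concatenate(vs))
        assert var_x == pytest.approx(kT / k, rel=0.05)
        assert var_v == pytest.approx(kT / mass, rel=0.05)

    def test_nve_energy_drift_small(self, rng):
        """Friction 0 reduces BAOAB to velocity Verlet; total energy is
        conserved to ~1e-4 relative over 10^4 steps at dt = 1 fs."""
        params = PairParams(repulsion=2e-4, r_cut=6.0, attraction=1e-4,
                            r_attr=5.0, width=2.0)
        x = make_uniform_sphere(5.0, 10, 1.0, rng, mass=50.0).positions
        masses = np.full(10, 50.0)
        v = 1e-3 * rng.standard_normal((10, 3))
        cfg = SimConfig(dt=1.0, temperature=300.0, friction=0.0, steps=1)

        def forces(pos):
            return pair_forces(pos, params)[0]

        def total_energy(pos, vel):
            _, u = pair_forces(pos, params)
            return u + 0.5 * np.sum(masses[:, None] * vel**2)

        f = forces(x)
        e0 = total_energy(x, v)
        for _ in range(10_000):
            x, v, f = langevin_step(x, v, f, forces, masses, cfg,
                                    np.random.default_rng(0))
        drift = abs(total_energy(x, v) - e0) / abs(e0)
        assert drift < 1e-4

    def test_nonfinite_forces_abort(self):
        cfg = SimConfig(dt=1.0, steps=1)
        with pytest.raises(FloatingPointError):
            langevin_step(np.zeros((1, 3)), np.zeros((1, 3)),
                          np.array([[np.nan, 0, 0]]),
                          lambda p: np.zeros_like(p), np.ones(1), cfg,
                          np.random.default_rng(0))


class TestRunSimulation:
    def params(self):
        return PairParams(repulsion=2e-4, r_cut=6.0, attraction=1e-4,
                          r_attr=5.0, width=2.0)

    def test_checkpoint_restart_bit_identical(self, rng):
        sites = make_uniform_sphere(6.0, 12, 1.0, rng)
        cfg_full = SimConfig(dt=4.0, steps=200, seed=5, log_stride=200)
        full = run_simulation(sites, cfg_full, self.params())

        cfg_half = SimConfig(dt=4.0, steps=100, seed=5, log_stride=100)
        gen = np.random.default_rng(5)
        first = run_simulation(sites, cfg_half, self.params(), rng=gen)
        second = run_simulation(sites.with_positions(first.positions),
                                cfg_half, self.params(),
                                velocities=first.velocities, rng=gen)
        assert np.array_equal(second.positions, full.positions)
        assert np.array_equal(second.velocities, full.velocities)

    def test_null_bias_leaves_dynamics_unbiased(self, rng):
        """sigma = 1e6 makes the restraint force negligible: the trajectory
        matches an unbiased run driven by an identical noise stream."""
        from sansmi.debye_forward import QGrid, compute_spectrum
        from sansmi.metainference import MetaInfState, SANSForwardModel

        sites = make_uniform_sphere(6.0, 12, 1.0, rng)
        grid = QGrid(np.linspace(0.05, 0.25, 5))
        target = compute_spectrum(sites, grid).scaled * 1.5  # mismatched
        model = SANSForwardModel(grid)
        huge = 1e6
        state = MetaInfState(sigma=np.full((1, 5), huge),
                             sigma_min=np.full(5, huge),
                             sigma_max=np.full(5, huge),
                             dsigma=np.zeros(5), kT=KB * 300.0)
        cfg = SimConfig(dt=4.0, steps=120, seed=11, bias_stride=20,
                        log_stride=120)
        biased = run_simulation(sites, cfg, self.params(), model=model,
                                state=state, target=target,
                                sample_nuisance=False)
        unbiased = run_simulation(sites, cfg, self.params())
        assert np.allclose(biased.positions, unbiased.positions, atol=1e-6)
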