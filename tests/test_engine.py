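"""Integrator correctness: stubbed-noise arithmetic, oracle equivalences for
neighbor lists / drift / collisions, and statistical sanity of full runs."""

import math

import numpy as np
import pytest
from scipy import stats

from nhdsim import (LJParams, ParticleState, SimConfig, build_neighbor_lists,
                    interaction_drift, ito_step, make_constant_profile,
                    milstein_step, resolve_collisions, simulate, wrap)
from nhdsim.engine import ConfigurationError, InitializationError
from nhdsim.interactions import lj_force_magnitude
from nhdsim.profiles import InvalidParameterError


def _well_amp(x):
    """Independent scalar arithmetic for the canonical well (images at +-2L
    are negligible below 1e-12 in (-1, 1))."""
    return 1.0 - 0.9 * (math.exp(-x * x / 0.1)
                        + math.exp(-((x - 2) ** 2) / 0.1)
                        + math.exp(-((x + 2) ** 2) / 0.1))


def _well_grad(x):
    g = 0.0
    for c in (0.0, 2.0, -2.0):
        g += 0.9 * (2.0 * (x - c) / 0.1) * math.exp(-((x - c) ** 2) / 0.1)
    return g


class TestDiffusionSteps:
    def test_constant_profile_increment_is_pure_noise(self, stub_rng_factory):
        prof = make_constant_profile(2.0, L=1.0, dim=1)
        state = ParticleState(np.array([[0.1], [0.5], [-0.3]]))
        z = [0.5, -1.0, 2.0]
        new = milstein_step(state, prof, 0.01, stub_rng_factory(z))
        expected = wrap(state.positions[:, 0] + math.sqrt(0.01) * 2.0 * np.array(z), 1.0)
        assert np.allclose(new.positions[:, 0], expected, atol=1e-14)

    def test_milstein_three_steps_hand_arithmetic(self, well_profile_1d,
                                                  stub_rng_factory):
        dt = 0.01
        zs = [0.7, -1.3, 0.4]
        x = 0.3
        for z in zs:
            x = x + math.sqrt(dt) * _well_amp(x) * z \
                + 0.5 * dt * _well_amp(x) * _well_grad(x) * z * z
            x = (x + 1.0) % 2.0 - 1.0
        state = ParticleState(np.array([[0.3]]))
        for z in zs:
            state = milstein_step(state, well_profile_1d, dt, stub_rng_factory([z]))
        assert state.positions[0, 0] == pytest.approx(x, abs=1e-10)
        assert state.time == pytest.approx(3 * dt)

    def test_ito_step_single_stub(self, well_profile_1d, stub_rng_factory):
        dt, z, x0 = 0.01, -0.8, 0.2
        state = ito_step(ParticleState(np.array([[x0]])), well_profile_1d, dt,
                         stub_rng_factory([z]))
        assert state.positions[0, 0] == pytest.approx(
            x0 + math.sqrt(dt) * _well_amp(x0) * z, abs=1e-10)

    def test_positions_stay_wrapped(self, well_profile_1d, rng):
        state = ParticleState(rng.uniform(-1, 1, (500, 1)))
        for _ in range(20):
            state = milstein_step(state, well_profile_1d, 0.01, rng)
        assert np.all(state.positions >= -1.0) and np.all(state.positions < 1.0)
        assert state.n == 500


class TestNeighborLists:
    def test_pair_within_cutoff(self):
        lists = build_neighbor_lists(np.array([[0.0, 0.0], [0.5, 0.0]]), 1.0, 10.0)
        assert list(lists[0]) == [1] and list(lists[1]) == [0]

    def test_seam_straddling_pair(self):
        pos = np.array([[-9.9, 0.0], [9.9, 0.0]])
        lists = build_neighbor_lists(pos, 1.0, 10.0)
        assert list(lists[0]) == [1] and list(lists[1]) == [0]

    def test_matches_brute_force_on_random_state(self, rng):
        L, cutoff = 10.0, 1.5
        pos = rng.uniform(-L, L, (200, 2))
        lists = build_neighbor_lists(pos, cutoff, L)
        for i in range(200):
            d = wrap(pos - pos[i], L)
            r = np.hypot(d[:, 0], d[:, 1])
            expected = sorted(j for j in range(200) if j != i and r[j] < cutoff)
            assert list(lists[i]) == expected

    def test_cutoff_must_be_below_L(self):
        with pytest.raises(InvalidParameterError):
            build_neighbor_lists(np.zeros((3, 2)), 10.0, 10.0)


class TestInteractionDrift:
    def test_zero_epsilon_zero_drift(self, patch_profile_2d):
        state = ParticleState(np.array([[0.0, 0.0], [1.0, 0.0]]))
        d = interaction_drift(state, patch_profile_2d, LJParams(0.0), 0.01)
        assert np.allclose(d, 0.0)

    def test_pair_at_sigma_feels_no_force(self, patch_profile_2d):
        lj = LJParams(epsilon=1000.0, sigma=2.5)
        state = ParticleState(np.array([[0.0, 0.0], [2.5, 0.0]]))
        d = interaction_drift(state, patch_profile_2d, lj, 0.01, epsilon_scale=1e-4)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_three_on_a_line_matches_all_pairs_sum(self):
        prof = make_constant_profile(1.0, L=20.0, dim=2)
        lj = LJParams(epsilon=5000.0, sigma=2.5)
        eps = 5000.0 * 1e-4
        pos = np.array([[-3.0, 0.0], [0.0, 0.0], [2.2, 0.0]])
        dt = 0.01
        drift = interaction_drift(ParticleState(pos), prof, lj, dt, 1e-4)
        # oracle: explicit double loop, no neighbor structure
        expect = np.zeros((3, 2))
        for j in range(3):
            for i in range(3):
                if i == j:
                    continue
                u = pos[j] - pos[i]
                r = np.linalg.norm(u)
                if r >= lj.cutoff:
                    continue
                s6 = (lj.sigma / r) ** 6
                f = (12 * eps / r) * (s6 * s6 - s6)
                expect[j] += f * u / r
        expect *= dt  # D = 1 on the constant profile
        assert np.allclose(drift, expect, rtol=1e-10)

    def test_isolated_pair_drift_is_momentum_free(self):
        prof = make_constant_profile(1.0, L=20.0, dim=2)
        lj = LJParams(epsilon=8000.0, sigma=2.5)
        state = ParticleState(np.array([[0.3, -0.2], [2.1, 1.4]]))
        d = interaction_drift(state, prof, lj, 0.01, 1e-4)
        assert np.allclose(d[0] + d[1], 0.0, atol=1e-12)
        assert np.linalg.norm(d[0]) > 0


class TestCollisions:
    def test_distant_moves_accepted(self, rng):
        prev = np.array([[0.0, 0.0], [5.0, 5.0]])
        prop = prev + 0.1
        out = resolve_collisions(prop, prev, 0.5, 10.0, rng=rng)
        assert np.allclose(out, prop)

    def test_head_on_overlap_rejected(self, rng):
        prev = np.array([[-0.4, 0.0], [0.4, 0.0]])
        prop = np.array([[0.0, 0.0], [0.01, 0.0]])
        out = resolve_collisions(prop, prev, 0.5, 10.0, rng=rng)
        d = np.linalg.norm(wrap(out[1] - out[0], 10.0))
        assert d >= 0.5
        # at least one of the two moves was rejected
        assert np.allclose(out[0], prev[0]) or np.allclose(out[1], prev[1])

    def test_dense_configuration_has_no_overlap_after_pass(self, rng):
        L, core = 5.0, 0.4
        prev = resolve_collisions(rng.uniform(-L, L, (120, 2)) * 0 + _rsa(rng, 120, L, core),
                                  _rsa(rng, 120, L, core), core, L, rng=rng)
        prop = wrap(prev + rng.normal(0, 0.3, prev.shape), L)
        out = resolve_collisions(prop, prev, core, L, rng=rng)
        for i in range(len(out)):
            d = wrap(out - out[i], L)
            r = np.hypot(d[:, 0], d[:, 1])
            r[i] = np.inf
            assert r.min() >= core - 1e-12

    def test_overlapping_start_raises(self, patch_profile_2d):
        cfg = SimConfig(n_particles=2, n_steps=10, sample_every=10,
                        collisions=True, core_diameter=1.0)
        with pytest.raises(InitializationError):
            simulate(cfg, patch_profile_2d,
                     initial_positions=np.array([[0.0, 0.0], [0.1, 0.0]]))


def _rsa(rng, n, L, core):
    """Random sequential adsorption oracle for non-overlapping starts."""
    pts = []
    while len(pts) < n:
        c = rng.uniform(-L, L, 2)
        if all(np.linalg.norm(wrap(c - p, L)) >= core for p in pts):
            pts.append(c)
    return np.array(pts)


class TestSimulate:
    def test_bit_reproducible(self, well_profile_1d):
        cfg = SimConfig(n_particles=200, n_steps=100, seed=42, sample_every=50)
        a = simulate(cfg, well_profile_1d)
        b = simulate(cfg, well_profile_1d)
        assert np.array_equal(a.positions, b.positions)

    def test_interacting_run_bit_reproducible(self, patch_profile_2d):
        cfg = SimConfig(n_particles=25, n_steps=200, seed=9, sample_every=100,
                        interaction=LJParams(epsilon=4000.0, sigma=2.5),
                        collisions=True, core_diameter=2.5)
        a = simulate(cfg, patch_profile_2d)
        b = simulate(cfg, patch_profile_2d)
        assert np.array_equal(a.positions, b.positions)

    def test_homogeneous_control_histogram_flat(self):
        prof = make_constant_profile(1.0, L=1.0, dim=1)
        cfg = SimConfig(n_particles=8000, n_steps=200, seed=3, sample_every=200)
        traj = simulate(cfg, prof)
        counts, edges = np.histogram(traj.positions[-1][:, 0], bins=20,
                                     range=(-1, 1))
        expect = 8000 / 20
        se = math.sqrt(expect * (1 - 1 / 20))
        assert np.max(np.abs(counts - expect)) < 4 * se

    def test_epsilon_zero_interaction_equals_collisions_only(self, patch_profile_2d):
        base = dict(n_particles=80, n_steps=300, seed=11, sample_every=100,
                    collisions=True, core_diameter=0.5)
        with_int = SimConfig(interaction=LJParams(epsilon=0.0, sigma=2.5), **base)
        without = SimConfig(**base)
        a = simulate(with_int, patch_profile_2d)
        b = simulate(without, patch_profile_2d)
        assert np.array_equal(a.positions, b.positions)

    def test_dt_halving_leaves_equilibrium_unchanged(self, well_profile_1d):
        # the stability criterion: the stationary histogram is dt-insensitive
        finals = []
        for dt, steps in [(0.02, 500), (0.01, 1000)]:
            cfg = SimConfig(n_particles=4000, n_steps=steps, dt=dt, seed=21,
                            sample_every=steps)
            finals.append(simulate(cfg, well_profile_1d).positions[-1][:, 0])
        ks = stats.ks_2samp(finals[0], finals[1])
        assert ks.pvalue > 0.005

    def test_dirac_start_matches_transient_theory(self, well_profile_1d):
        from nhdsim import transient_density_1d
        t = 0.5
        cfg = SimConfig(n_particles=20000, n_steps=int(t / 0.01), seed=17,
                        sample_every=int(t / 0.01))
        init = np.full((20000, 1), 0.5)
        traj = simulate(cfg, well_profile_1d, initial_positions=init)
        x, rho = transient_density_1d(well_profile_1d, ("dirac", 0.5), t)
        counts, edges = np.histogram(traj.positions[-1][:, 0], bins=50, range=(-1, 1))
        centers = 0.5 * (edges[1:] + edges[:-1])
        binw = edges[1] - edges[0]
        expect = np.interp(centers, x, rho) * binw * 20000
        z = (counts - expect) / np.sqrt(np.maximum(expect, 1.0))
        assert np.max(np.abs(z)) < 5.0

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_particles=10, n_steps=10, dt=0.0)
        with pytest.raises(ConfigurationError):
            SimConfig(n_particles=10, n_steps=10, formalism="heun")
        with pytest.raises(ConfigurationError):
            SimConfig(n_particles=10, n_steps=10, sample_every=100)

    def test_unstable_dt_rejected(self, well_profile_1d):
        cfg = SimConfig(n_particles=10, n_steps=10, dt=2.0, sample_every=10)
        with pytest.raises(ConfigurationError):
            simulate(cfg, well_profile_1d)


class TestKernelEquivalence:
    """The compiled 2D step must reproduce the public numpy operations."""

    def test_step_without_collisions(self, patch_profile_2d, rng):
        from nhdsim import _kernels as K
        prof = patch_profile_2d
        lj = LJParams(epsilon=10000.0, sigma=2.5)
        pos = rng.uniform(-12, 12, (40, 2))
        Z = rng.standard_normal((40, 2))
        dt = 0.01
        kind, params = prof.kernel_spec
        p1 = pos.copy()
        K._step(p1, Z, np.empty(0, np.int64), dt, 12.0, kind, params, True,
                1.0, lj.sigma, lj.cutoff, True, 0.0, False, 0.5 * lj.sigma)
        disp = interaction_drift(ParticleState(pos), prof, lj, dt, 1e-4)
        amp = prof.amplitude(pos)[:, None]
        grad = prof.gradient(pos)
        expected = wrap(pos + disp + math.sqrt(dt) * amp * Z
                        + 0.5 * dt * amp * grad * Z ** 2, 12.0)
        assert np.allclose(p1, expected, atol=1e-12)

    def test_collision_pass_matches_python_contract(self, rng):
        from nhdsim import _kernels as K
        prof = make_constant_profile(1.0, L=5.0, dim=2)
        core = 0.6
        pos = _rsa(rng, 50, 5.0, core)
        Z = rng.standard_normal((50, 2))
        perm = rng.permutation(50)
        kind, params = prof.kernel_spec
        p1 = pos.copy()
        K._step(p1, Z, perm, 0.02, 5.0, kind, params, True,
                0.0, 1.0, 3.0, True, core, True, 1.0)
        proposed = wrap(pos + math.sqrt(0.02) * 1.0 * Z, 5.0)
        expected = resolve_collisions(proposed, pos, core, 5.0, order=perm)
        assert np.allclose(p1, expected, atol=1e-12)
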