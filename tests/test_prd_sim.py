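"""PRD simulator: force process, velocity solve, integration, sampling."""

import numpy as np
import pytest

from prdcell import prd_sim
from prdcell.prd_sim import CellState, PRDParams, SimConfig


def base_params(**over):
    return prd_sim.preset("table2_35kPa").replace(**over)


def linear_params(**over):
    """All nonlinear couplings off: independent linear mode dynamics."""
    defaults = dict(alpha_v=0.0, gamma_v=0.0, alpha2=0.0, alpha3=0.0,
                    gamma3=0.0, beta3=0.0)
    defaults.update(over)
    return base_params(**defaults)


class TestStepForce:
    def test_deterministic_decay_step(self):
        f = prd_sim.step_force(1.0 + 0j, kappa_f=1.0, sigma=0.0, dt_h=1 / 120, xi=0j)
        assert f == pytest.approx(1 - 1 / 120)

    def test_zero_is_fixed_point_without_noise(self):
        f = 0j
        for _ in range(100):
            f = prd_sim.step_force(f, 2.0, 0.0, 1 / 120, 0j)
        assert f == 0j

    def test_stationary_sd_matches_closed_form(self):
        # per-component sd -> sigma * sqrt(kappa_f / 2)
        rng = np.random.default_rng(5)
        kf, sigma, dt = 2.0, 1.0, 1 / 120
        n = 200_000
        xi = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        f = 0j
        samples = np.empty(n, dtype=complex)
        for k in range(n):
            f = prd_sim.step_force(f, kf, sigma, dt, xi[k])
            samples[k] = f
        sd = np.real(samples[1000:]).std()
        assert sd == pytest.approx(sigma * np.sqrt(kf / 2), rel=0.05)


class TestSolveVelocity:
    def test_decoupled_reduction(self):
        p = linear_params()
        s = CellState(C2=1 + 2j, C3=0.5 - 1j, F2=3 + 0j, F3=0.2j, F6=0j)
        v = prd_sim.solve_velocity(s, p)
        expected = p.beta1 * (-p.kappa2 * np.conj(s.C2) + np.conj(s.F2)) * s.C3 \
            - p.beta2 * np.conj(s.C2) * (-p.kappa3 * s.C3 + s.F3)
        assert v == pytest.approx(expected, abs=1e-14)

    def test_zero_modes_give_zero_velocity(self):
        s = CellState(C2=0j, C3=0j, F2=5 + 1j, F3=-2j, F6=1 + 1j)
        assert prd_sim.solve_velocity(s, base_params()) == 0j

    def test_matches_brute_force_real_2x2_solve(self):
        rng = np.random.default_rng(17)
        p = base_params()
        for _ in range(50):
            s = CellState(
                C2=rng.standard_normal() * 4 + 1j * rng.standard_normal() * 4,
                C3=rng.standard_normal() + 1j * rng.standard_normal(),
                F2=rng.standard_normal() * 5 + 5j * rng.standard_normal(),
                F3=rng.standard_normal() + 1j * rng.standard_normal(),
                F6=rng.standard_normal() + 1j * rng.standard_normal(),
            )
            v = prd_sim.solve_velocity(s, p)
            # independent oracle: solve A v - alpha_v C2 conj(v) = b as a
            # real 2x2 linear system in (Re v, Im v)
            A, b = prd_sim._velocity_rhs_terms(s.C2, s.C3, s.F2, s.F3, s.F6, p)
            a = p.alpha_v
            M = np.array([
                [A - a * np.real(s.C2), -a * np.imag(s.C2)],
                [-a * np.imag(s.C2), A + a * np.real(s.C2)],
            ])
            sol = np.linalg.solve(M, [np.real(b), np.imag(b)])
            assert v == pytest.approx(sol[0] + 1j * sol[1], abs=1e-12 * max(1, abs(v)))

    def test_rotational_equivariance(self):
        rng = np.random.default_rng(3)
        p = base_params()
        s = CellState(C2=2 - 1j, C3=0.4 + 0.3j, F2=4 + 2j, F3=0.5 - 0.2j, F6=1j)
        theta0 = 1.1
        r = np.exp(1j * theta0)
        s_rot = CellState(C2=s.C2 * r**2, C3=s.C3 * r**3, F2=s.F2 * r**2,
                          F3=s.F3 * r**3, F6=s.F6 * r**6)
        v0 = prd_sim.solve_velocity(s, p)
        v1 = prd_sim.solve_velocity(s_rot, p)
        assert v1 == pytest.approx(v0 * r, abs=1e-12)


class TestStepAndIntegrate:
    def test_zero_state_is_fixed_point_without_noise(self):
        p = base_params(sigma2=0.0, sigma3=0.0, sigma6=0.0)
        s = CellState()
        for _ in range(50):
            s = prd_sim.step_cell(s, p, 1 / 120, np.zeros(3, dtype=complex))
        assert s.pos == 0j and s.C2 == 0j and s.C3 == 0j

    def test_modes_decay_monotonically_without_noise_or_couplings(self):
        p = linear_params(sigma2=0.0, sigma3=0.0, sigma6=0.0)
        s = CellState(C2=3 + 1j, C3=1 - 0.5j)
        mags2, mags3 = [abs(s.C2)], [abs(s.C3)]
        for _ in range(200):
            s = prd_sim.step_cell(s, p, 1 / 120, np.zeros(3, dtype=complex))
            mags2.append(abs(s.C2))
            mags3.append(abs(s.C3))
        assert np.all(np.diff(mags2) < 0) and np.all(np.diff(mags3) < 0)

    def test_linear_limit_c2_variance_matches_spectral_form(self):
        # Var per component of C2 -> (kf sigma2^2 / 2) / (k2 (k2 + kf))
        p = linear_params(sigma3=0.0, sigma6=0.0)
        rng = np.random.default_rng(23)
        n_steps, n_cells, dt = 6000, 64, 1 / 120
        raw = rng.standard_normal((n_steps, n_cells, 6))
        noise = raw[..., 0::2] + 1j * raw[..., 1::2]
        rec = prd_sim.integrate(p, n_steps, dt, noise, record_stride=10)
        c2 = rec["C2"][60:]  # discard 5 h burn-in
        var = np.real(c2).var()
        expected = (p.kappa_f * p.sigma2**2 / 2) / (p.kappa2 * (p.kappa2 + p.kappa_f))
        assert var == pytest.approx(expected, rel=0.15)

    def test_first_order_convergence_under_step_refinement(self):
        # one frozen Brownian path represented at three resolutions; the
        # end-state differences between successive refinements shrink
        p = base_params()
        rng = np.random.default_rng(8)
        n, dt = 240, 1 / 120

        def coarsen(z):
            # merge consecutive unit-normal increments: (a + b)/sqrt(2)
            return (z[0::2] + z[1::2]) / np.sqrt(2)

        finest = rng.standard_normal((4 * n, 1, 3)) + 1j * rng.standard_normal(
            (4 * n, 1, 3)
        )
        mid = coarsen(finest)
        coarse = coarsen(mid)
        end = {}
        for label, (steps, step_dt, noise) in {
            "dt": (n, dt, coarse),
            "dt/2": (2 * n, dt / 2, mid),
            "dt/4": (4 * n, dt / 4, finest),
        }.items():
            rec = prd_sim.integrate(p, steps, step_dt, noise, record_stride=steps)
            end[label] = rec["C2"][-1, 0]
        err1 = abs(end["dt"] - end["dt/2"])
        err2 = abs(end["dt/2"] - end["dt/4"])
        assert err2 < err1

    def test_trajectory_rotational_equivariance_on_frozen_noise(self):
        p = base_params()
        rng = np.random.default_rng(31)
        n, dt = 600, 1 / 120
        raw = rng.standard_normal((n, 1, 6))
        noise = raw[..., 0::2] + 1j * raw[..., 1::2]
        theta0 = 0.9
        r = np.exp(1j * theta0)
        rotated = noise * np.array([r**2, r**3, r**6])
        rec0 = prd_sim.integrate(p, n, dt, noise, record_stride=10)
        rec1 = prd_sim.integrate(p, n, dt, rotated, record_stride=10)
        assert np.allclose(rec1["pos"], rec0["pos"] * r, atol=1e-9)
        assert np.allclose(rec1["C2"], rec0["C2"] * r**2, atol=1e-9)
        assert np.allclose(rec1["C3"], rec0["C3"] * r**3, atol=1e-9)

    def test_lagged_scheme_converges_to_self_consistent(self):
        p = base_params()
        rng = np.random.default_rng(14)
        n, dt = 120, 1 / 120
        raw = rng.standard_normal((n, 1, 6))
        noise = raw[..., 0::2] + 1j * raw[..., 1::2]
        gaps = []
        for refine in (1, 4):
            nn = n * refine
            dts = dt / refine
            nz = np.repeat(noise, refine, axis=0) / np.sqrt(refine)
            a = prd_sim.integrate(p, nn, dts, nz, scheme="self-consistent",
                                  record_stride=nn)
            b = prd_sim.integrate(p, nn, dts, nz, scheme="lagged", record_stride=nn)
            gaps.append(abs(a["pos"][-1, 0] - b["pos"][-1, 0]))
        assert gaps[1] < gaps[0]


class TestSimulateAndSample:
    def test_frozen_dynamics_track_is_pure_observation_noise(self):
        p = linear_params(sigma2=0.0, sigma3=0.0, sigma6=0.0,
                          kappa2=1e-9, kappa3=1e-9)
        cfg = SimConfig(duration_h=16.0, sigma0_um=1.0, seed=2, burn_in_h=0.0)
        track, _ = prd_sim.simulate_cell(p, cfg)
        assert track.x.std() == pytest.approx(1.0, rel=0.15)
        assert abs(track.x.mean()) < 0.3

    def test_noiseless_zero_start_stays_at_origin(self):
        p = base_params(sigma2=0.0, sigma3=0.0, sigma6=0.0)
        cfg = SimConfig(duration_h=9.0, sigma0_um=0.0, seed=0)
        track, series = prd_sim.simulate_cell(p, cfg)
        assert np.allclose(track.x, 0) and np.allclose(track.y, 0)
        assert np.allclose(series.modes[2], 0)

    def test_fixed_seed_reproducibility(self):
        p = base_params()
        cfg = SimConfig(duration_h=9.0, seed=77)
        t1, s1 = prd_sim.simulate_cell(p, cfg)
        t2, s2 = prd_sim.simulate_cell(p, cfg)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.y, t2.y)
        assert np.array_equal(s1.modes[2], s2.modes[2])

    def test_ensemble_deterministic_and_prefix_stable(self):
        p = base_params()
        cfg = SimConfig(duration_h=9.0, n_cells=3, seed=5)
        e1 = prd_sim.simulate_ensemble(p, cfg)
        e2 = prd_sim.simulate_ensemble(p, cfg)
        assert all(np.array_equal(a[0].x, b[0].x) for a, b in zip(e1, e2))
        # first cells of a larger ensemble match the smaller one
        e3 = prd_sim.simulate_ensemble(p, cfg, n_cells=5,
                                       durations_h=[9.0] * 5)
        for a, b in zip(e1, e3[:3]):
            assert np.array_equal(a[0].x, b[0].x)

    def test_sampling_grid_is_five_minutes(self):
        track, series = prd_sim.simulate_cell(base_params(), SimConfig(seed=1))
        assert np.allclose(np.diff(track.times_min), 5.0)
        assert series.derivative_modes[2].size == series.times_min.size - 1


class TestCouplingRule:
    @pytest.mark.parametrize(
        "target, orders, ok",
        [
            (1, (-2, 3), True),    # conj(C2) C3 drives the velocity
            (1, (2, 3), False),
            (3, (-3, 6), True),    # conj(C3) F6 in the C3 equation
            (2, (-1, 3), True),    # conj(v) C3 in the C2 equation
            (3, (1, 2), True),     # v C2 in the C3 equation
            (2, (2, 2), False),
        ],
    )
    def test_selection_rule(self, target, orders, ok):
        assert prd_sim.validate_coupling_term(target, orders) is ok

    def test_zero_order_rejected(self):
        with pytest.raises(ValueError):
            prd_sim.validate_coupling_term(2, (0, 2))


class TestPresets:
    def test_noise_scales_recovered_from_nondimensional_force(self):
        p35 = prd_sim.preset("table2_35kPa")
        assert p35.sigma2 == pytest.approx(0.66 * 23.9 * 0.38)
        assert p35.sigma3 == pytest.approx(0.026 * 23.9 * 1.55)
        p410 = prd_sim.preset("table2_410kPa")
        assert p410.beta2 < p410.beta1
        assert p410.kappa3 == pytest.approx(0.51)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            prd_sim.preset("table2_9000kPa")

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            PRDParams(beta1=1, beta2=0.2, kappa2=-1, kappa3=1, sigma2=1,
                      sigma3=1, R0=20)
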