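"""Trajectory statistics: MSD, ACF, CV segmentation, rotation angles."""

import numpy as np
import pytest

from prdcell import track_stats as ts


def make_track(positions, cell_id="c0", dt_min=5.0):
    p = np.asarray(positions, dtype=complex)
    t = np.arange(p.size) * dt_min
    return ts.CellTrack(cell_id=cell_id, times_min=t, x=np.real(p), y=np.imag(p))


def straight_track(speed_um_h=30.0, n=200, direction=0.0):
    v = speed_um_h * np.exp(1j * direction)
    return make_track(v * np.arange(n) * (5.0 / 60.0))


class TestCellTrack:
    def test_velocity_of_uniform_motion(self):
        tr = straight_track(30.0)
        assert np.allclose(tr.velocity(), 30.0)

    def test_duration_and_filtering(self):
        short = make_track(np.zeros(49))   # 4 h
        long_ = make_track(np.zeros(200))  # 16.6 h
        kept = ts.filter_tracks([short, long_], min_hours=8.3)
        assert kept == [long_]


class TestMSD:
    def test_ballistic_closed_form(self):
        s = 24.0
        tr = straight_track(s, n=300)
        table = ts.msd([tr], max_lag_min=120)
        lags_h = table["lag_min"] / 60.0
        assert np.allclose(table["msd"], (s * lags_h) ** 2, rtol=1e-9)
        assert ts.msd_exponent(table) == pytest.approx(2.0, abs=1e-9)

    def test_static_track_is_zero(self):
        table = ts.msd([make_track(np.zeros(120))], max_lag_min=60)
        assert np.allclose(table["msd"], 0.0)

    def test_lattice_random_walk_is_diffusive(self):
        rng = np.random.default_rng(0)
        steps = rng.choice([1, -1, 1j, -1j], size=10_000)
        tr = make_track(np.concatenate([[0], np.cumsum(steps)]))
        table = ts.msd([tr], max_lag_min=300, smoothed=False)
        slope = ts.msd_exponent(table, lag_window=(5, 300))
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_exact_power_law_exponent(self):
        table = ts.msd([straight_track(n=100)], max_lag_min=80)
        table["msd"] = 3.0 * table["lag_min"] ** 1.65
        assert ts.msd_exponent(table) == pytest.approx(1.65, abs=1e-12)

    def test_lag_beyond_all_tracks_rejected(self):
        with pytest.raises(ValueError):
            ts.msd([make_track(np.zeros(10))], max_lag_min=500)

    def test_ensemble_combination_is_count_weighted(self):
        a = straight_track(10.0, n=120)
        b = straight_track(20.0, n=120)
        both = ts.msd([a, b], max_lag_min=60)
        ma = ts.msd([a], max_lag_min=60)
        mb = ts.msd([b], max_lag_min=60)
        assert np.allclose(both["msd"], (ma["msd"] + mb["msd"]) / 2)


class TestAutocorr:
    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(4)
        series = rng.standard_normal(5000) + 1j * rng.standard_normal(5000)
        acf = ts.autocorr([series], max_lag=20)
        assert acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(acf[1:]) < 3 / np.sqrt(5000))

    def test_ou_process_decays_at_its_rate(self):
        rng = np.random.default_rng(9)
        n, dt, kappa = 200_000, 0.01, 1.0
        x = np.empty(n)
        x[0] = 0.0
        for k in range(1, n):
            x[k] = x[k - 1] * (1 - kappa * dt) + np.sqrt(dt) * rng.standard_normal()
        lag = 50  # 0.5 time units
        acf = ts.autocorr([x], max_lag=lag)
        assert acf[lag] == pytest.approx(np.exp(-kappa * lag * dt), abs=0.05)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ts.autocorr([np.ones(100)], max_lag=5)


class TestPdfSymmetrized:
    def test_density_normalized_and_symmetric_bins(self, rng):
        z = rng.standard_normal(20_000) + 1j * rng.standard_normal(20_000)
        centers, dens = ts.pdf_symmetrized(z, bins=41)
        width = centers[1] - centers[0]
        assert (dens * width).sum() == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(centers, -centers[::-1])

    def test_laplace_log_density_is_linear_in_tail(self, rng):
        z = rng.laplace(size=50_000) + 1j * rng.laplace(size=50_000)
        centers, dens = ts.pdf_symmetrized(z, bins=np.linspace(-8, 8, 81))
        sel = (centers > 1) & (dens > 0)
        slope, _ = np.polyfit(centers[sel], np.log(dens[sel]), 1)
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_purely_real_series_contributes_zero_spike(self):
        centers, dens = ts.pdf_symmetrized(np.array([1.0, -1.0, 2.0, -2.0]),
                                           bins=np.linspace(-3, 3, 7))
        mid = np.argmin(np.abs(centers))
        assert dens[mid] > 0  # imaginary parts pile up at zero by design


class TestVelocityCorrelation:
    def test_constant_velocity(self):
        tr = straight_track(12.0)
        _, cv = ts.velocity_correlation_series(tr, dt_min=10.0)
        assert np.allclose(cv, 144.0)

    def test_instant_reversal_gives_negative_cv(self):
        s = 12.0 * (5 / 60)
        fwd = np.cumsum(np.full(50, s))
        back = fwd[-1] - np.cumsum(np.full(50, s))
        tr = make_track(np.concatenate([[0], fwd, back]))
        # raw (unsmoothed) velocities so the corner is not rounded off
        _, cv = ts.velocity_correlation_series(tr, dt_min=10.0, window=1)
        assert cv.min() == pytest.approx(-144.0, rel=0.01)

    def test_stopped_cell_has_zero_cv(self):
        _, cv = ts.velocity_correlation_series(make_track(np.zeros(60)), 10.0)
        assert np.allclose(cv, 0.0)

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            ts.velocity_correlation_series(make_track(np.zeros(6)), 30.0)


class TestPersistence:
    def test_uniform_motion_is_one_full_segment(self):
        tr = straight_track(30.0, n=100)
        seg = ts.persistent_segments(tr)
        assert len(seg.segments) == 1
        s = seg.segments[0]
        assert s.path_length_um == pytest.approx(abs(s.net_displacement), rel=1e-9)

    def test_straight_stop_straight_splits_in_two(self):
        s = 30.0 * (5 / 60)
        leg1 = np.cumsum(np.full(40, s))
        pause = np.full(40, leg1[-1])
        leg2 = leg1[-1] + 1j * np.cumsum(np.full(40, s))
        tr = make_track(np.concatenate([[0], leg1, pause, leg2]))
        seg = ts.persistent_segments(tr)
        assert len(seg.segments) == 2
        angles = ts.rotation_angles(seg)
        assert angles[0] == pytest.approx(90.0, abs=1.0)

    def test_noise_velocities_leave_gaps(self, rng):
        z = np.cumsum(rng.standard_normal(300) + 1j * rng.standard_normal(300))
        seg = ts.persistent_segments(make_track(z))
        persistent_samples = sum(s.end - s.start + 1 for s in seg.segments)
        assert 0 < persistent_samples < seg.cv.size

    def test_invariant_under_rotation_and_translation(self, rng):
        z = np.cumsum(rng.standard_normal(200) + 1j * rng.standard_normal(200)) * 3
        t1 = make_track(z)
        t2 = make_track(z * np.exp(0.7j) + (50 - 20j))
        s1 = ts.persistent_segments(t1)
        s2 = ts.persistent_segments(t2)
        assert [(s.start, s.end) for s in s1.segments] == \
            [(s.start, s.end) for s in s2.segments]
        assert np.allclose([s.path_length_um for s in s1.segments],
                           [s.path_length_um for s in s2.segments])
        assert np.allclose(ts.rotation_angles(s1), ts.rotation_angles(s2))


class TestRotationAngles:
    def test_collinear_segments_turn_zero(self):
        s = 30.0 * (5 / 60)
        leg1 = np.cumsum(np.full(40, s))
        pause = np.full(40, leg1[-1])
        leg2 = leg1[-1] + np.cumsum(np.full(40, s))
        tr = make_track(np.concatenate([[0], leg1, pause, leg2]))
        seg = ts.persistent_segments(tr)
        angles = ts.rotation_angles(seg)
        assert len(angles) >= 1
        assert angles[0] == pytest.approx(0.0, abs=1.0)

    def test_reversal_maps_to_180(self):
        s = 30.0 * (5 / 60)
        leg1 = np.cumsum(np.full(40, s))
        pause = np.full(40, leg1[-1])
        leg2 = leg1[-1] - np.cumsum(np.full(40, s))
        tr = make_track(np.concatenate([[0], leg1, pause, leg2]))
        angles = ts.rotation_angles(ts.persistent_segments(tr))
        assert angles[0] == pytest.approx(180.0, abs=1.0)

    def test_time_reversed_track_preserves_angle_magnitudes(self, rng):
        z = np.cumsum(rng.standard_normal(250) + 1j * rng.standard_normal(250)) * 3
        fwd = ts.rotation_angles(ts.persistent_segments(make_track(z)))
        rev = ts.rotation_angles(ts.persistent_segments(make_track(z[::-1])))
        fold = lambda a: np.minimum(a, 360 - a)  # unsigned turn magnitude
        assert np.allclose(np.sort(fold(fwd)), np.sort(fold(rev)), atol=1e-6)

    def test_histogram_bins_center_on_multiples_of_width(self):
        centers, counts = ts.rotation_angle_histogram(
            np.array([0.0, 355.0, 179.0, 181.0, 185.0]), bin_width=20.0
        )
        assert centers[0] == 0.0 and centers[9] == 180.0
        assert counts[0] == 2  # 0 and 355 both fall in the circular 0-bin
        assert counts[9] == 3


class TestCCDF:
    def test_single_value_steps_to_zero(self):
        table = ts.ccdf(np.array([5.0]))
        assert table["value"].tolist() == [5.0]
        assert table["ccdf"].tolist() == [0.0]

    def test_exponential_tail_is_log_linear(self, rng):
        x = rng.exponential(scale=2.0, size=50_000)
        table = ts.ccdf(x)
        sel = (table["value"] > 1) & (table["ccdf"] > 1e-3)
        slope, _ = np.polyfit(table["value"][sel], np.log(table["ccdf"][sel]), 1)
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_everything_above_below_minimum(self):
        table = ts.ccdf(np.array([3.0, 1.0, 2.0]))
        assert table["value"].is_monotonic_increasing
        assert table["ccdf"].iloc[0] == pytest.approx(2 / 3)
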