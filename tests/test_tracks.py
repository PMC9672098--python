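"""Unit tests of rate inference and time-series statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from mechanofeedback import tracks as T


def make_track(times, lengths, myosin, **kw):
    return T.EdgeTrack(edge_id=0, times=np.asarray(times, float),
                       lengths=np.asarray(lengths, float),
                       myosin_density=np.asarray(myosin, float), **kw)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.7)
        assert np.allclose(T.smooth_gaussian(x, 10.0, 1.0), x, atol=1e-14)

    def test_sigma_zero_is_identity(self, rng):
        x = rng.normal(size=40)
        assert np.array_equal(T.smooth_gaussian(x, 0.0, 1.0), x)

    def test_matches_bruteforce_renormalized_convolution(self, rng):
        x = rng.normal(size=80)
        sigma, dt = 7.3, 1.5
        got = T.smooth_gaussian(x, sigma, dt)
        s = sigma / dt
        half = int(math.ceil(4 * s))
        expected = np.empty_like(x)
        for i in range(x.size):
            num = den = 0.0
            for k in range(-half, half + 1):
                j = i + k
                if 0 <= j < x.size:
                    w = math.exp(-0.5 * (k / s) ** 2)
                    num += w * x[j]
                    den += w
            expected[i] = num / den
        assert np.max(np.abs(got - expected)) < 1e-12

    def test_interior_mean_conserved_on_long_series(self, rng):
        # stationary fluctuations around a nonzero level: the smoother must
        # not shift the level (boundary exchange is the only residual)
        x = 10.0 + 0.01 * rng.normal(size=50000)
        sm = T.smooth_gaussian(x, 10.0, 1.0)
        margin = 100
        a = np.mean(x[margin:-margin])
        b = np.mean(sm[margin:-margin])
        assert abs(b - a) / abs(a) < 1e-6

    @given(st.floats(min_value=0.0, max_value=25.0))
    def test_smoothing_stays_within_data_range(self, sigma):
        x = np.sin(np.arange(60) * 0.3)
        sm = T.smooth_gaussian(x, sigma, 1.0)
        assert sm.min() >= x.min() - 1e-12
        assert sm.max() <= x.max() + 1e-12


class TestRates:
    def test_constant_length_gives_zero_strain_rate(self):
        t = np.arange(10.0)
        track = make_track(t, np.full(10, 5.0), np.linspace(1, 2, 10))
        assert np.allclose(T.strain_rate(track, sigma=0.0), 0.0)

    def test_exponential_growth_recovers_rate(self):
        k = 0.01  # per second
        t = np.arange(0.0, 100.0, 1.0)
        track = make_track(t, 5.0 * np.exp(k * t), np.ones(t.size))
        rate = T.strain_rate(track, sigma=0.0)       # log method: exact
        assert np.allclose(rate, k * 60.0, rtol=1e-12)
        fwd = T.strain_rate(track, sigma=0.0, method="forward")
        assert np.allclose(fwd, (math.exp(k) - 1.0) * 60.0, rtol=1e-12)

    def test_integrated_strain_rate_is_log_fold_change(self, rng):
        t = np.arange(0.0, 200.0, 2.0)
        L = 5.0 * np.exp(0.002 * t + 0.05 * np.sin(t / 17.0))
        track = make_track(t, L, np.ones(t.size))
        rate = T.strain_rate(track, sigma=0.0) / 60.0   # per second
        integral = np.sum(rate) * track.dt
        assert integral == pytest.approx(math.log(L[-1] / L[0]), rel=1e-12)

    def test_myosin_doubling_rate(self):
        t = np.arange(0.0, 601.0, 10.0)
        m = 1.0 + t / 600.0          # doubles linearly over 10 min
        track = make_track(t, np.full(t.size, 5.0), m)
        mean_rate = np.mean(T.myosin_rate(track, sigma=0.0))
        assert mean_rate == pytest.approx(math.log(2) / 10.0, rel=0.05)

    def test_power_law_density_gives_proportional_rates(self):
        c = 1.7
        t = np.arange(0.0, 300.0, 5.0)
        L = 6.0 * np.exp(0.001 * t + 0.03 * np.sin(t / 23.0))
        track = make_track(t, L, 2.0 * (L / L[0]) ** c)
        s = T.strain_rate(track, sigma=10.0)
        m = T.myosin_rate(track, sigma=10.0)
        assert np.allclose(m, c * s, rtol=1e-10, atol=1e-12)

    def test_zero_density_rejected(self):
        t = np.arange(5.0)
        with pytest.raises(ValueError, match="non-positive"):
            track = make_track(t, np.ones(5), np.array([1, 1, 0, 1, 1.0]))
            T.myosin_rate(track)

    def test_track_invariants(self):
        with pytest.raises(ValueError, match="non-uniform"):
            make_track([0, 1, 3.0], [1, 1, 1.0], [1, 1, 1.0])
        with pytest.raises(ValueError, match=">= 3"):
            make_track([0, 1.0], [1, 1.0], [1, 1.0])


class TestCorrelation:
    def test_autocorrelation_is_one_at_zero_lag(self, rng):
        x = rng.normal(size=200)
        ac = T.autocorrelation(x, max_lag=20.0, dt=1.0)
        assert ac.values[ac.lags == 0] == pytest.approx(1.0)
        assert np.all(np.abs(ac.values) <= 1.0 + 1e-12)

    def test_delayed_sinusoid_peaks_at_delay(self):
        t = np.arange(0.0, 400.0, 1.0)
        omega = 2 * math.pi / 50.0
        delta = 7.0
        x = np.sin(omega * t)
        y = np.sin(omega * (t - delta))
        cc = T.cross_correlation(x, y, max_lag=30.0, dt=1.0)
        assert cc.lags[np.argmax(cc.values)] == pytest.approx(delta, abs=1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_lag_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(60, 200)
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.3 * x
        cc = T.cross_correlation(x, y, max_lag=15.0, dt=1.0)
        for lag, val in zip(cc.lags, cc.values):
            k = int(round(lag))
            a, b = (x[:n - k], y[k:]) if k >= 0 else (x[-k:], y[:n + k])
            assert val == pytest.approx(sps.pearsonr(a, b)[0], abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            T.autocorrelation(np.ones(50), max_lag=5.0, dt=1.0)

    def test_insufficient_overlap_rejected(self, rng):
        x = rng.normal(size=15)
        with pytest.raises(ValueError, match="overlap"):
            T.cross_correlation(x, x, max_lag=10.0, dt=1.0)


class TestDominantPeriod:
    def test_pure_sinusoid(self):
        t = np.arange(0.0, 600.0, 1.0)
        x = np.sin(2 * math.pi * t / 74.0)
        ac = T.autocorrelation(x, max_lag=200.0, dt=1.0)
        assert T.dominant_period(ac) == pytest.approx(74.0, abs=1.0)

    def test_white_noise_is_aperiodic_for_most_seeds(self):
        aperiodic = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=400)
            ac = T.autocorrelation(x, max_lag=100.0, dt=1.0)
            if math.isnan(T.dominant_period(ac)):
                aperiodic += 1
        assert aperiodic >= 17

    def test_noisy_sinusoid_within_five_percent(self):
        t = np.arange(0.0, 1000.0, 1.0)
        rng = np.random.default_rng(3)
        x = np.sin(2 * math.pi * t / 80.0) + 0.2 * rng.normal(size=t.size)
        ac = T.autocorrelation(x, max_lag=250.0, dt=1.0)
        assert T.dominant_period(ac) == pytest.approx(80.0, rel=0.05)


class TestPeaks:
    def test_monotone_series_has_no_peaks(self):
        assert T.find_strain_rate_peaks(np.arange(50.0), dt=1.0).size == 0

    def test_two_gaussians_found_at_modes(self):
        t = np.arange(0.0, 200.0)
        x = (np.exp(-0.5 * ((t - 50) / 6) ** 2)
             + np.exp(-0.5 * ((t - 140) / 6) ** 2))
        peaks = T.find_strain_rate_peaks(x, dt=1.0, min_separation=30.0)
        assert list(peaks) == [50, 140]

    def test_sinusoid_peak_spacing(self):
        t = np.arange(0.0, 500.0)
        x = np.sin(2 * math.pi * t / 60.0)
        peaks = T.find_strain_rate_peaks(x, dt=1.0, min_separation=30.0)
        assert np.allclose(np.diff(peaks), 60.0, atol=1.0)


class TestAlignedAverage:
    def _rates(self, strain, myosin, dt=1.0):
        n = strain.size
        return T.RateSeries(times=np.arange(n) * dt, strain_rate=strain,
                            myosin_rate=myosin, smoothing_sigma=0.0)

    def test_single_peak_returns_window_copy(self):
        t = np.arange(0.0, 200.0)
        strain = np.exp(-0.5 * ((t - 100) / 8) ** 2)
        myosin = np.cos(2 * math.pi * t / 45.0)
        avg = T.peak_aligned_average([self._rates(strain, myosin)],
                                     window=40.0)
        assert avg.n_events == 1
        assert np.array_equal(avg.strain_rate, strain[60:141])
        assert np.array_equal(avg.myosin_rate, myosin[60:141])

    def test_phase_randomized_sinusoids_give_null_asymmetry(self):
        # myosin with no phase relation to strain: the aligned myosin curve is
        # flat, so the timing statistic should sit at zero within the
        # bootstrap interval
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 800.0)
        rates = []
        for _ in range(150):
            phi_s, phi_m = rng.uniform(0, 2 * math.pi, size=2)
            strain = np.sin(2 * math.pi * t / 70.0 + phi_s)
            myosin = np.sin(2 * math.pi * t / 70.0 + phi_m)
            rates.append(self._rates(strain, myosin))
        avg = T.peak_aligned_average(rates, window=150.0)
        asym = T.alignment_asymmetry(avg)
        lo, hi = T.bootstrap_asymmetry(avg, n_boot=200, seed=0)
        assert lo <= 0.0 <= hi or abs(asym) <= 5.0

    def test_incomplete_windows_are_dropped(self):
        t = np.arange(0.0, 100.0)
        strain = np.exp(-0.5 * ((t - 10) / 4) ** 2)   # peak too close to edge
        with pytest.raises(ValueError, match="no complete events"):
            T.peak_aligned_average([self._rates(strain, strain)], window=40.0)


class TestCellShape:
    def test_unit_square(self):
        area, ecc, _ = T.cell_shape_metrics(
            [[0, 0], [1, 0], [1, 1], [0, 1]])
        assert area == pytest.approx(1.0)
        assert ecc == pytest.approx(0.0, abs=1e-9)

    def test_two_to_one_rectangle(self):
        area, ecc, theta = T.cell_shape_metrics(
            [[0, 0], [2, 0], [2, 1], [0, 1]])
        assert area == pytest.approx(2.0)
        assert ecc == pytest.approx(math.sqrt(3) / 2, rel=1e-12)
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_rotated_rectangle_orientation(self):
        ang = math.radians(35.0)
        R = np.array([[math.cos(ang), -math.sin(ang)],
                      [math.sin(ang), math.cos(ang)]])
        verts = np.array([[0, 0], [3, 0], [3, 1], [0, 1]], float) @ R.T
        _, _, theta = T.cell_shape_metrics(verts)
        assert theta == pytest.approx(35.0, abs=1e-6)

    def test_vertex_reversal_invariance(self, rng):
        angles = np.sort(rng.uniform(0, 2 * math.pi, size=8))
        verts = np.c_[np.cos(angles), 0.6 * np.sin(angles)]
        fwd = T.cell_shape_metrics(verts)
        rev = T.cell_shape_metrics(verts[::-1])
        assert fwd == pytest.approx(rev)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            T.cell_shape_metrics([[0, 0], [1, 1], [2, 2]])
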