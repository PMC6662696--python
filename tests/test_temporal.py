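"""Regional series, Pettitt change point, wavelets and cross-correlation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from reefheat.temporal import (
    ChangePointResult,
    cross_correlation,
    cross_wavelet,
    monthly_mean,
    pettitt,
    regional_series,
    wavelet,
)


def brute_force_pettitt(x):
    """O(n^2) double-sum oracle for the Pettitt statistic."""
    x = np.asarray(x, float)
    n = len(x)
    best_t, best_u = None, 0.0
    for t in range(1, n):
        u = sum(np.sign(x[j] - x[i]) for i in range(t) for j in range(t, n))
        if abs(u) > abs(best_u):
            best_u, best_t = u, t
    K = abs(best_u)
    p = min(1.0, 2.0 * np.exp(-6.0 * K**2 / (n**3 + n**2)))
    return K, best_t, p


class TestRegionalSeries:
    def _dhw_cube(self, vals):
        vals = np.asarray(vals, float)
        time = pd.date_range("1985-01-01", periods=vals.shape[0], freq="D")
        return xr.Dataset(
            {"dhw": (("time", "lat", "lon"), vals)},
            coords={
                "time": time,
                "lat": 15.0 + 0.05 * np.arange(vals.shape[1]),
                "lon": -80.0 + 0.05 * np.arange(vals.shape[2]),
            },
        )

    def _labels(self, cube, grid):
        return xr.DataArray(
            np.asarray(grid, int),
            coords={"lat": cube["lat"], "lon": cube["lon"]},
            dims=("lat", "lon"),
        )

    def test_single_pixel_region_equals_pixel(self, rng):
        vals = rng.gamma(2, 1, (30, 2, 2))
        cube = self._dhw_cube(vals)
        labels = self._labels(cube, [[1, 0], [0, 0]])
        out = regional_series(cube, labels)
        np.testing.assert_allclose(out[1].values, vals[:, 0, 0])

    def test_median_of_three_pixels(self):
        vals = np.zeros((5, 1, 3))
        vals[:, 0, 0], vals[:, 0, 1], vals[:, 0, 2] = 0.0, 4.0, 10.0
        cube = self._dhw_cube(vals)
        labels = self._labels(cube, [[1, 1, 1]])
        out = regional_series(cube, labels)
        np.testing.assert_allclose(out[1].values, 4.0)

    def test_invariant_under_pixel_permutation(self, rng):
        vals = rng.gamma(2, 1, (20, 1, 4))
        cube = self._dhw_cube(vals)
        perm = self._dhw_cube(vals[:, :, [2, 0, 3, 1]])
        labels = self._labels(cube, [[1, 1, 1, 1]])
        a = regional_series(cube, labels)
        b = regional_series(perm, labels)
        np.testing.assert_allclose(a[1].values, b[1].values)

    def test_monthly_mean_produces_period_index(self, rng):
        vals = rng.gamma(2, 1, (90, 1, 1))
        cube = self._dhw_cube(vals)
        daily = regional_series(cube, self._labels(cube, [[1]]))
        monthly = monthly_mean(daily)
        assert isinstance(monthly.index, pd.PeriodIndex)
        assert monthly.index[0] == pd.Period("1985-01", "M")
        jan = vals[:31, 0, 0].mean()
        assert monthly[1].iloc[0] == pytest.approx(jan)


class TestPettitt:
    def test_step_series_frozen_example(self):
        r = pettitt(np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1.0]))
        assert r.K == 25.0
        assert r.tau == 5

    def test_constant_series_is_degenerate(self):
        r = pettitt(np.full(20, 2.0))
        assert r.K == 0.0 and r.tau is None and r.p == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for n in (10, 25, 60, 120):
            x = rng.gamma(2.0, 1.0, n).round(1)  # rounding forces ties
            got = pettitt(x)
            K, tau, p = brute_force_pettitt(x)
            assert got.K == pytest.approx(K)
            assert got.tau == tau
            assert got.p == pytest.approx(p)

    def test_planted_step_located(self, rng):
        e = np.zeros(396)
        innov = rng.standard_normal(396) * 0.3
        for i in range(1, 396):
            e[i] = 0.5 * e[i - 1] + innov[i]
        x = e + (np.arange(396) >= 216) * 1.0
        r = pettitt(x)
        assert abs(r.tau - 216) <= 12
        assert r.p < 0.05

    def test_period_index_reported_as_tau_label(self):
        idx = pd.period_range("1985-01", periods=20, freq="M")
        series = pd.Series(np.r_[np.zeros(10), np.ones(10)], index=idx)
        r = pettitt(series)
        assert r.tau == 10
        assert r.tau_label == pd.Period("1985-10", "M")

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            pettitt(np.arange(5.0))


class TestWavelet:
    def test_annual_sinusoid_yields_12_month_band(self):
        x = 2.0 + np.sin(2 * np.pi * np.arange(396) / 12.0)
        w = wavelet(x)
        sig = w.sig_mask & w.in_coi()
        sig_periods = w.periods[sig.any(axis=1)]
        assert len(sig_periods) > 0
        assert 10.0 < np.median(sig_periods) < 15.0

    def test_zero_series_has_zero_power(self):
        w = wavelet(np.zeros(128))
        assert w.power.max() == 0.0
        assert not w.sig_mask.any()

    def test_negative_after_offset_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            wavelet(np.full(128, -2.0), log_offset=1.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="64"):
            wavelet(np.ones(30))

    def test_total_power_tracks_variance(self, rng):
        """Parseval-style: raw wavelet energy correlates with series variance."""
        energies, variances = [], []
        for _ in range(50):
            x = rng.gamma(2.0, rng.uniform(0.3, 3.0), 128)
            w = wavelet(x)
            # reconstruction weighting: total energy ~ sum |W|^2 / s, which is
            # exactly the bias-corrected power the result reports
            energies.append(w.power.mean())
            variances.append(np.var(np.log1p(x)))
        r = np.corrcoef(energies, variances)[0, 1]
        assert r >= 0.95


class TestCrossWavelet:
    def test_identical_series_cross_power_is_wavelet_power_phase_zero(self, rng):
        x = rng.gamma(2.0, 1.0, 200)
        xw = cross_wavelet(x, x)
        assert np.abs(xw.phase).max() < 1e-9
        # |W_x W_x*| / s equals bias-corrected |W_x|^2 / s
        from reefheat.temporal import _cwt_morlet

        W, scales, _, _ = _cwt_morlet(x)
        np.testing.assert_allclose(xw.power, np.abs(W) ** 2 / scales[:, None], rtol=1e-9)

    def test_shifted_series_phase_sign_consistent(self):
        t = np.arange(396)
        x = np.sin(2 * np.pi * t / 12.0)
        y = np.sin(2 * np.pi * (t - 8) / 12.0)  # y lags x by 8 months
        xw = cross_wavelet(x, y)
        band = (np.abs(xw.periods - 12.0) < 1.5)[:, None] & xw.in_coi() & xw.sig_mask
        phases = xw.phase[band]
        assert len(phases) > 0
        # 8/12 cycle lead wraps to a negative angle of 2*pi/3
        expected = 2 * np.pi * 8 / 12 - 2 * np.pi
        assert np.abs(np.median(phases) - expected) < 0.35
        assert (np.sign(phases) == np.sign(expected)).mean() > 0.9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            cross_wavelet(np.ones(100), np.ones(99))

    def test_independent_noise_rarely_significant(self, rng):
        fracs = []
        for _ in range(50):
            res = cross_wavelet(rng.standard_normal(396), rng.standard_normal(396))
            ic = res.in_coi()
            fracs.append((res.sig_mask & ic).sum() / ic.sum())
        assert np.mean(fracs) <= 0.10


class TestCrossCorrelation:
    def test_lag_zero_self_correlation_is_one(self, rng):
        x = rng.standard_normal(396)
        cc = cross_correlation(x, x)
        assert cc.loc[cc["lag"] == 0, "r"].iloc[0] == pytest.approx(1.0)
        assert (cc["lag"].values == np.arange(-38, 39)).all()

    def test_planted_eight_month_lead_recovered(self, rng):
        oni = np.sin(2 * np.pi * np.arange(396) / 40.0) + rng.standard_normal(396) * 0.2
        d = np.r_[np.zeros(8), oni[:-8]] + rng.standard_normal(396) * 0.1
        cc = cross_correlation(d, oni)
        peak = cc.loc[cc["r"].idxmax()]
        assert peak["lag"] == 8
        assert peak["sig"]

    def test_independent_noise_rarely_exceeds_bounds(self, rng):
        trials_ok = 0
        for _ in range(40):
            cc = cross_correlation(rng.standard_normal(396), rng.standard_normal(396))
            trials_ok += cc["sig"].mean() <= 0.10
        assert trials_ok >= 36  # per-lag 5% false-positive rate

    def test_short_overlap_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            cross_correlation(np.ones(100), np.ones(100), max_lag=38)
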