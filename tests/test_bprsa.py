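"""BPRSA and fetal-stress-index contracts, checked against brute-force
oracles and analytic constants."""

import numpy as np
import pytest

from fetalstress.bprsa import (
    AnchorSet,
    BPRSAConfig,
    bprsa_average,
    compute_fsi,
    find_anchors,
    fsi,
    interpolate_target,
)
from fetalstress.exceptions import (
    InsufficientPeaksError,
    InvalidConfigError,
    NoAnchorsError,
)
from fetalstress.heart_rate import HeartRateSeries, rr_from_peaks

SMALL = BPRSAConfig(L=50, S1=10, S2=30, fs=10)


def brute_force_fsi(X, L, S1, S2, mean_norm=False):
    """Literal double-loop evaluation of the index definition."""
    denom = (S2 - S1 + 1) if mean_norm else (S2 - S1)
    after = sum(X[i] for i in range(L + S1, L + S2 + 1)) / denom
    before = sum(X[i] for i in range(L - S2, L - S1 + 1)) / denom
    return after - before


class TestInterpolate:
    def test_constant_rate(self):
        s = rr_from_peaks(np.arange(0, 10, 60 / 140))
        out = interpolate_target(s, fs=100, duration=9)
        np.testing.assert_allclose(out, 140, rtol=1e-9)

    def test_linear_midpoint(self):
        # two intervals: hr 120 then 150; linear between their closing beats
        peaks = np.array([0.0, 0.5, 0.5 + 0.4])
        s = HeartRateSeries(peaks)
        out = interpolate_target(s, fs=1000, duration=0.9)
        t_mid = 0.5 * (0.5 + 0.9)
        assert out[int(t_mid * 1000)] == pytest.approx(135, abs=0.5)

    def test_matches_piecewise_linear_truth(self):
        from scipy.interpolate import interp1d

        rng = np.random.default_rng(0)
        peaks = np.cumsum(rng.uniform(0.6, 1.0, 50))
        s = HeartRateSeries(peaks)
        out = interpolate_target(s, fs=100, duration=peaks[-1])
        grid = np.arange(out.size) / 100
        truth = interp1d(
            s.peak_times[1:], s.hr_series, bounds_error=False,
            fill_value=(s.hr_series[0], s.hr_series[-1]),
        )(grid)
        assert np.max(np.abs(out - truth)) < 1e-9

    def test_single_beat_rejected(self):
        with pytest.raises(InsufficientPeaksError):
            HeartRateSeries(np.array([1.0]))


class TestFindAnchors:
    def test_increasing_series_has_no_anchors(self):
        with pytest.raises(NoAnchorsError):
            find_anchors(np.arange(200.0), SMALL)

    def test_decreasing_series_all_interior(self):
        x = -np.arange(110.0)
        a = find_anchors(x, SMALL)
        np.testing.assert_array_equal(a.indices_trigger, np.arange(50, 60))

    def test_matches_brute_force_on_random_walk(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.standard_normal(400))
        got = find_anchors(x, SMALL).indices_trigger
        want = [i for i in range(SMALL.L, x.size - SMALL.L) if x[i] < x[i - 1]]
        np.testing.assert_array_equal(got, want)

    def test_multisample_criterion(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.standard_normal(400))
        cfg = BPRSAConfig(L=50, S1=10, S2=30, fs=10, anchor_T=3)
        got = find_anchors(x, cfg).indices_trigger
        want = [
            i for i in range(cfg.L, x.size - cfg.L)
            if np.mean(x[i : i + 3]) < np.mean(x[i - 3 : i])
        ]
        np.testing.assert_array_equal(got, want)


class TestAverage:
    def test_single_anchor_returns_window(self):
        rng = np.random.default_rng(3)
        t = rng.standard_normal(300)
        a = AnchorSet(np.array([100]), np.array([100]))
        np.testing.assert_array_equal(bprsa_average(t, a, 50), t[50:150])

    def test_constant_target_stays_constant(self):
        a = AnchorSet(np.array([60, 80, 100]), np.array([60, 80, 100]))
        out = bprsa_average(np.full(300, 2.5), a, 50)
        np.testing.assert_array_equal(out, np.full(100, 2.5))

    def test_direct_path_matches_brute_force(self):
        rng = np.random.default_rng(4)
        t = rng.standard_normal(1000)
        idx = rng.integers(100, 900, size=50)
        a = AnchorSet(idx, idx)
        got = bprsa_average(t, a, 100)
        want = np.mean([t[i - 100 : i + 100] for i in idx], axis=0)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_fft_path_matches_direct(self):
        import fetalstress.bprsa as B

        rng = np.random.default_rng(5)
        t = rng.standard_normal(20000)
        idx = np.unique(rng.integers(2000, 18000, size=3000))
        a = AnchorSet(idx, idx)
        direct = np.mean([t[i - 2000 : i + 2000] for i in idx], axis=0)
        old = B._DIRECT_MAX_OPS
        try:
            B._DIRECT_MAX_OPS = 0  # force the FFT path
            got = bprsa_average(t, a, 2000)
        finally:
            B._DIRECT_MAX_OPS = old
        np.testing.assert_allclose(got, direct, atol=1e-9)

    def test_empty_anchors_rejected(self):
        with pytest.raises(NoAnchorsError):
            bprsa_average(np.zeros(300), AnchorSet(np.array([]), np.array([])), 50)


class TestFSI:
    def test_constant_curve_is_zero(self):
        assert fsi(np.full(18000, 3.7), BPRSAConfig()) == 0.0

    def test_unit_step_gives_literal_normalization_constant(self):
        X = np.zeros(18000)
        X[9000:] = 1.0
        assert fsi(X, BPRSAConfig()) == pytest.approx(901 / 900, abs=1e-12)

    def test_unit_step_under_mean_normalization(self):
        X = np.zeros(18000)
        X[9000:] = 1.0
        cfg = BPRSAConfig(mean_normalization=True)
        assert fsi(X, cfg) == pytest.approx(1.0, abs=1e-12)

    def test_matches_double_loop_on_random_curves(self):
        rng = np.random.default_rng(6)
        cfg = BPRSAConfig()
        for _ in range(5):
            X = rng.standard_normal(18000)
            assert fsi(X, cfg) == pytest.approx(
                brute_force_fsi(X, cfg.L, cfg.S1, cfg.S2), abs=1e-12
            )

    def test_linear_in_curve(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal(18000)
        cfg = BPRSAConfig()
        base = fsi(X, cfg)
        assert fsi(3.5 * X + 2.0, cfg) == pytest.approx(3.5 * base, abs=1e-9)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidConfigError):
            BPRSAConfig(S1=2000, S2=1000)
        with pytest.raises(InvalidConfigError):
            BPRSAConfig(L=100, S1=50, S2=200)


class TestComputeFSI:
    def test_constant_fetal_rate_gives_zero(self):
        m = HeartRateSeries(np.cumsum(np.tile([0.7, 0.8], 300)))
        f = HeartRateSeries(np.arange(0, 450, 60 / 140))
        cfg = BPRSAConfig(L=900, S1=135, S2=225, fs=90)
        res = compute_fsi(m, f, cfg)
        assert res.fsi == pytest.approx(0.0, abs=1e-9)
        assert res.n_anchors >= 1

    def test_smoke_on_coupled_dyad(self, clean_dyad):
        maternal, fetal = clean_dyad
        res = compute_fsi(maternal, fetal)
        assert res.n_anchors > 100
        assert np.isfinite(res.fsi)
        assert res.X.size == 2 * res.config.L

    def test_coupled_exceeds_uncoupled(self, clean_dyad):
        from fetalstress.synthetic_data import couple_fetal_rr

        maternal, fetal = clean_dyad
        f0 = couple_fetal_rr(
            maternal, 0.0, lag=0.5, fetal_base_hr=140,
            rng=np.random.default_rng(22), duration=600,
        )
        weak = compute_fsi(maternal, HeartRateSeries(f0))
        strong = compute_fsi(maternal, fetal)
        assert abs(strong.fsi) > abs(weak.fsi)

    def test_short_overlap_rejected(self):
        m = HeartRateSeries(np.arange(0, 10.0))
        f = HeartRateSeries(np.arange(0, 10, 0.5))
        with pytest.raises(InsufficientPeaksError):
            compute_fsi(m, f)


def test_default_window_constants():
    """L = 9000 at 900 Hz spans 20 s; S1 and S2 map to 1.5 s and 2.5 s."""
    cfg = BPRSAConfig()
    assert 2 * cfg.L / cfg.fs == 20.0
    assert cfg.S1 / cfg.fs == 1.5
    assert cfg.S2 / cfg.fs == 2.5
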