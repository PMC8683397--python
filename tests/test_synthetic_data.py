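"""Generator contracts: beat-time statistics, waveform round-trips,
coupling, mixing linearity, SQI marginals and cohort consistency."""

import numpy as np
import pytest

from fetalstress.exceptions import InvalidArgumentError
from fetalstress.heart_rate import HeartRateSeries, detect_rpeaks
from fetalstress.synthetic_data import (
    CohortConfig,
    HRVParams,
    SignalRecording,
    couple_fetal_rr,
    generate_cohort,
    generate_rr_series,
    maternal_deceleration_drive,
    mix_abdominal,
    simulate_sqi,
    synthesize_ecg,
)

ZERO_HRV = HRVParams(lf_amp=0.0, hf_amp=0.0, jitter_sd=0.0)


class TestGenerateRR:
    def test_zero_variability_is_metronomic(self, rng):
        ev = generate_rr_series(60, ZERO_HRV, 10, rng)
        np.testing.assert_allclose(ev, np.arange(1, 11), atol=1e-9)

    def test_mean_rr_matches_requested_rate(self):
        ev = generate_rr_series(80, HRVParams(), 600, np.random.default_rng(1))
        mean_rr = np.mean(np.diff(ev))
        assert 0.95 * 60 / 80 <= mean_rr <= 1.05 * 60 / 80

    def test_times_strictly_increasing(self, rng):
        ev = generate_rr_series(120, HRVParams(), 120, rng)
        assert np.all(np.diff(ev) > 0)
        assert ev[-1] <= 120 + 1e-9

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_duration_rejected(self, rng, bad):
        with pytest.raises(InvalidArgumentError):
            generate_rr_series(60, ZERO_HRV, bad, rng)

    def test_out_of_range_rate_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            generate_rr_series(20, ZERO_HRV, 10, rng)


class TestSynthesizeECG:
    def test_length_is_duration_times_fs(self):
        ev = np.arange(1, 60)
        assert synthesize_ecg(ev, 900, duration=60).size == 54000

    def test_zero_amplitude_gives_silence(self):
        ev = np.arange(1, 10, dtype=float)
        assert not np.any(synthesize_ecg(ev, 900, amplitude_scale=0.0))

    def test_rpeak_round_trip(self):
        ev = generate_rr_series(60, HRVParams(), 60, np.random.default_rng(3))
        x = synthesize_ecg(ev, 900, duration=60)
        peaks = detect_rpeaks(x, 900)
        dist = np.abs(peaks[:, None] - ev[None, :]).min(axis=0)
        assert np.mean(dist < 0.02) >= 0.99

    def test_empty_events_warn_and_return_silence(self, caplog):
        out = synthesize_ecg(np.array([]), 900, duration=2)
        assert out.size == 1800 and not np.any(out)


class TestCoupling:
    def test_zero_gain_is_independent(self):
        m_ev = generate_rr_series(80, HRVParams(), 600, np.random.default_rng(7))
        maternal = HeartRateSeries(m_ev)
        f_ev = couple_fetal_rr(
            maternal, 0.0, lag=0.5, fetal_base_hr=140,
            rng=np.random.default_rng(8), duration=600,
        )
        grid = np.arange(0, 590, 0.25)
        mh = np.interp(grid, m_ev[1:], 60 / np.diff(m_ev))
        fh = np.interp(grid, f_ev[1:], 60 / np.diff(f_ev))
        assert abs(np.corrcoef(mh, fh)[0, 1]) < 0.1

    def test_step_drop_transfers_with_gain(self):
        # maternal HR drops 20 bpm at t=300; drive is the negative deviation
        times = np.arange(1, 600, dtype=float)
        hr = np.where(times < 300, 90.0, 70.0)
        gain = 1.5
        f_ev = couple_fetal_rr(
            (times, hr), gain, lag=0.0, fetal_base_hr=140,
            rng=np.random.default_rng(9), duration=599,
            hrv_params=ZERO_HRV,
        )
        fhr = 60 / np.diff(f_ev)
        t_mid = f_ev[1:]
        before = fhr[(t_mid > 290) & (t_mid < 299)].mean()
        just_after = fhr[(t_mid > 301) & (t_mid < 305)].mean()
        assert before - just_after == pytest.approx(gain * 20.0, rel=0.1)

    def test_deceleration_drive_is_nonpositive(self):
        times = np.arange(1, 120, dtype=float)
        hr = 80 + 5 * np.sin(0.3 * times)
        _, drive = maternal_deceleration_drive(times, hr)
        assert np.all(drive <= 0)

    def test_unphysiological_base_hr_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            couple_fetal_rr((np.arange(1, 60.0), np.full(59, 80.0)), 1.0,
                            lag=0.5, fetal_base_hr=60, rng=rng)


class TestMixAbdominal:
    def _pair(self, n=9000):
        m = SignalRecording(np.sin(np.arange(n) / 7.0), 900, "mECG", "s0")
        f = SignalRecording(np.cos(np.arange(n) / 3.0), 900, "fECG", "s0")
        return m, f

    def test_zero_attenuation_zero_noise_is_identity(self):
        m, f = self._pair()
        out = mix_abdominal(m, f, fetal_attenuation=0.0, noise_sd=0.0)
        np.testing.assert_array_equal(out.samples, m.samples)
        assert out.role == "aECG"

    def test_mixture_is_linear(self):
        m, f = self._pair()
        out = mix_abdominal(m, f, fetal_attenuation=0.2, noise_sd=0.0)
        np.testing.assert_allclose(out.samples - m.samples, 0.2 * f.samples,
                                   atol=1e-12)

    def test_noise_is_reproducible(self):
        m, f = self._pair()
        a = mix_abdominal(m, f, 0.3, 0.05, np.random.default_rng(5))
        b = mix_abdominal(m, f, 0.3, 0.05, np.random.default_rng(5))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_residual_variance_matches_noise(self):
        n = 10 * 60 * 900  # 10-min record
        m = SignalRecording(np.sin(np.arange(n) / 7.0), 900, "mECG", "s0")
        f = SignalRecording(np.cos(np.arange(n) / 3.0), 900, "fECG", "s0")
        sd = 0.05
        out = mix_abdominal(m, f, 0.3, sd, np.random.default_rng(11))
        resid = out.samples - m.samples - 0.3 * f.samples
        assert np.var(resid) == pytest.approx(sd**2, rel=0.05)

    def test_mismatched_duration_rejected(self):
        m, _ = self._pair()
        f = SignalRecording(np.zeros(4500), 900, "fECG", "s0")
        with pytest.raises(InvalidArgumentError):
            mix_abdominal(m, f)


class TestSimulateSQI:
    def _rec(self, seconds=1000):
        return SignalRecording(np.zeros(int(seconds * 900)), 900, "mECG", "s0")

    def test_no_artifacts_all_clean(self, rng):
        out = simulate_sqi(self._rec(50), 0.0, rng)
        assert np.all(out.sqi >= 0.5)

    def test_all_artifacts_all_bad(self, rng):
        out = simulate_sqi(self._rec(50), 1.0, rng)
        assert np.all(out.sqi < 0.5)

    def test_artifact_fraction_near_rate(self):
        out = simulate_sqi(self._rec(1000), 0.041, np.random.default_rng(3))
        frac = np.mean(out.sqi < 0.5)
        assert 0.02 <= frac <= 0.07


class TestGenerateCohort:
    def test_shapes_and_group_counts(self):
        cfg = CohortConfig(n_subjects=10, recording_minutes=1.0, seed=11)
        recs, truth = generate_cohort(cfg)
        assert len(recs) == 10 and len(truth) == 10
        n_stressed = (truth.group == "stressed").sum()
        assert 0 < n_stressed < 10  # Binomial(10, 0.5) plausible at seed 11

    def test_pss_rule_consistent_with_group(self, tiny_cohort):
        _, _, truth = tiny_cohort
        stressed = truth.group == "stressed"
        assert np.all(truth.pss[stressed] >= 19)
        assert np.all(truth.pss[~stressed] < 19)

    def test_zero_prevalence_means_no_stressed(self):
        cfg = CohortConfig(n_subjects=4, recording_minutes=1.0,
                           stress_prevalence=0.0, seed=2)
        _, truth = generate_cohort(cfg)
        assert np.all(truth.pss < 19)

    def test_determinism(self):
        cfg = CohortConfig(n_subjects=3, recording_minutes=1.0, seed=5)
        recs_a, truth_a = generate_cohort(cfg)
        recs_b, truth_b = generate_cohort(cfg)
        assert truth_a.equals(truth_b)
        for a, b in zip(recs_a, recs_b):
            np.testing.assert_array_equal(a.aecg.samples, b.aecg.samples)
            np.testing.assert_array_equal(a.aecg.sqi, b.aecg.sqi)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(InvalidArgumentError):
            CohortConfig(n_subjects=1)

    def test_recordings_carry_all_roles_and_sqi(self, tiny_cohort):
        _, recs, _ = tiny_cohort
        for triple in recs:
            roles = {r.role for r in triple}
            assert roles == {"aECG", "mECG", "fECG"}
            assert all(r.sqi is not None for r in triple)
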