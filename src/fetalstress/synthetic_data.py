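"""Synthetic maternal/fetal abdominal-ECG cohort generator.

The clinical recordings this analysis was designed for are private, so the
package ships a generator that emulates their statistical structure: a
maternal ECG with PQRST morphology and LF/HF heart-rate variability, a
weaker, faster fetal ECG whose heart rate is coupled to maternal heart-rate
*decelerations* with a tunable gain (the ground truth the fetal stress index
measures), an additive abdominal mixture channel, a per-second signal
quality index with artifact epochs, and group-conditional psychometric /
endocrine labels (PSS-10, PDQ, hair cortisol).

Stress is encoded three ways, all driven by a latent severity variable:
higher maternal heart rate, reduced high-frequency RR variability, and a
flattened T wave — plus a larger maternal-to-fetal coupling gain.  Link
functions are documented package choices, not clinical claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .heart_rate import HeartRateSeries

logger = logging.getLogger(__name__)

ROLES = ("aECG", "mECG", "fECG")


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class SignalRecording:
    """A uniformly sampled 1-D physiological signal with metadata.

    ``sqi`` holds one quality value in [0, 1] per whole second of signal
    (length ``floor(len(samples)/fs)``); ``None`` until assigned.
    """

    samples: np.ndarray
    fs: float
    role: str
    subject_id: str
    sqi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if self.role not in ROLES:
            raise InvalidArgumentError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.sqi is not None:
            self.sqi = np.asarray(self.sqi, dtype=float)
            if self.sqi.size != self.n_seconds:
                raise InvalidArgumentError(
                    f"sqi length {self.sqi.size} != floor(duration) {self.n_seconds}"
                )
            if np.any((self.sqi < 0) | (self.sqi > 1)):
                raise InvalidArgumentError("sqi values must lie in [0, 1]")

    @property
    def n_seconds(self) -> int:
        return int(self.samples.size // self.fs)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class HRVParams:
    """Sinusoidal LF/HF RR modulation plus white jitter, as fractions of the
    base RR interval."""

    lf_freq: float = 0.095
    lf_amp: float = 0.03
    hf_freq: float = 0.25
    hf_amp: float = 0.08
    jitter_sd: float = 0.01


@dataclass(frozen=True)
class WaveKernel:
    """One Gaussian wave of the beat template; offsets/widths are fractions
    of the local RR interval, relative to the R peak."""

    offset: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class EcgMorphology:
    """Sum-of-Gaussians PQRST template."""

    waves: tuple[WaveKernel, ...] = (
        WaveKernel(-0.20, 0.050, 0.12),   # P
        WaveKernel(-0.035, 0.015, -0.12),  # Q
        WaveKernel(0.0, 0.018, 1.00),      # R
        WaveKernel(0.035, 0.015, -0.18),   # S
        WaveKernel(0.28, 0.070, 0.25),     # T
    )

    def with_t_amplitude(self, t_amp: float) -> "EcgMorphology":
        waves = list(self.waves)
        waves[-1] = replace(waves[-1], amplitude=t_amp)
        return EcgMorphology(waves=tuple(waves))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated acquisition protocol: 900 Hz abdominal
    recordings of roughly 46 min, ~4.1% artifact seconds, and a stressed /
    control split defined by the PSS-10 >= 19 rule.
    """

    n_subjects: int = 107
    stress_prevalence: float = 0.5
    recording_minutes: float = 46.0
    maternal_fs: float = 900.0
    coupling_gain_stressed: float = 1.5
    coupling_gain_control: float = 0.4
    label_noise_sd: float = 1.0
    artifact_rate: float = 0.041
    fetal_attenuation: float = 0.3
    mix_noise_sd: float = 0.02
    maternal_base_hr: float = 78.0
    fetal_base_hr: float = 140.0
    coupling_lag_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidArgumentError("n_subjects must be >= 2")
        if not 0.0 <= self.stress_prevalence <= 1.0:
            raise InvalidArgumentError("stress_prevalence must lie in [0, 1]")
        if self.maternal_fs <= 0:
            raise InvalidArgumentError("maternal_fs must be positive")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise InvalidArgumentError("artifact_rate must lie in [0, 1]")
        if self.recording_minutes <= 0:
            raise InvalidArgumentError("recording_minutes must be positive")


@dataclass
class SubjectTruth:
    """Ground-truth latent state and labels for one mother-fetus dyad."""

    subject_id: str
    group: str  # "stressed" | "control"
    latent_severity: float
    pss: int
    pdq: int
    cortisol: float
    coupling_gain: float
    fsi_true: float


@dataclass
class SubjectRecordings:
    """The per-subject channel triple."""

    mecg: SignalRecording
    fecg: SignalRecording
    aecg: SignalRecording

    def __iter__(self) -> Iterator[SignalRecording]:
        return iter((self.mecg, self.fecg, self.aecg))

    def by_role(self, role: str) -> SignalRecording:
        return {"mECG": self.mecg, "fECG": self.fecg, "aECG": self.aecg}[role]


# ---------------------------------------------------------------------------
# beat-time and waveform synthesis
# ---------------------------------------------------------------------------


def generate_rr_series(
    mean_hr: float,
    hrv_params: HRVParams,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate strictly increasing beat times over [0, duration] seconds.

    Each RR interval is the base interval 60/mean_hr modulated by the LF and
    HF sinusoids (evaluated at the current beat time) plus white jitter.
    With all amplitudes zero the beats fall exactly at multiples of the base
    interval.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    if not 30.0 <= mean_hr <= 250.0:
        raise InvalidArgumentError(f"mean_hr {mean_hr} outside [30, 250] bpm")
    base = 60.0 / mean_hr
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
    events = []
    t = 0.0
    while True:
        mod = (
            hrv_params.lf_amp * np.sin(2 * np.pi * hrv_params.lf_freq * t + phases[0])
            + hrv_params.hf_amp * np.sin(2 * np.pi * hrv_params.hf_freq * t + phases[1])
        )
        jit = hrv_params.jitter_sd * rng.standard_normal() if hrv_params.jitter_sd else 0.0
        rr = base * (1.0 + mod + jit)
        rr = float(np.clip(rr, 0.3 * base, 2.0 * base))
        t = t + rr
        if t > duration + 1e-9:
            break
        events.append(t)
    return np.asarray(events)


def synthesize_ecg(
    rr_events: np.ndarray,
    fs: float,
    morphology: EcgMorphology | None = None,
    amplitude_scale: float = 1.0,
    duration: float | None = None,
) -> np.ndarray:
    """Render beat times into an ECG waveform of Gaussian PQRST kernels.

    One beat template is centered at every event time, with wave offsets and
    widths scaled by the preceding RR interval.
    """
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    events = np.asarray(rr_events, dtype=float)
    if events.size and np.any(np.diff(events) <= 0):
        raise InvalidArgumentError("rr_events must be strictly increasing")
    if duration is None:
        duration = float(events[-1]) + (
            float(np.median(np.diff(events))) if events.size > 1 else 1.0
        ) if events.size else 0.0
    n = int(round(duration * fs))
    x = np.zeros(n)
    if events.size == 0:
        logger.warning("synthesize_ecg called with no beats; returning silence")
        return x
    rr_local = np.diff(events, prepend=events[0] if events.size == 1 else np.nan)
    if events.size > 1:
        rr_local[0] = rr_local[1]
    else:
        rr_local[0] = 1.0
    for t0, rr in zip(events, rr_local):
        for w in (morphology or EcgMorphology()).waves:
            mu = t0 + w.offset * rr
            sigma = max(w.width * rr, 1.5 / fs)
            lo = max(0, int(np.floor((mu - 4 * sigma) * fs)))
            hi = min(n, int(np.ceil((mu + 4 * sigma) * fs)) + 1)
            if hi <= lo:
                continue
            tt = np.arange(lo, hi) / fs
            x[lo:hi] += w.amplitude * np.exp(-0.5 * ((tt - mu) / sigma) ** 2)
    return amplitude_scale * x


# ---------------------------------------------------------------------------
# maternal -> fetal coupling
# ---------------------------------------------------------------------------

_FETAL_HRV = HRVParams(lf_freq=0.08, lf_amp=0.02, hf_freq=0.4, hf_amp=0.03, jitter_sd=0.008)


def maternal_deceleration_drive(
    times: np.ndarray,
    hr: np.ndarray,
    grid_fs: float = 4.0,
    baseline_s: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Negative part of the maternal HR deviation from its causal moving
    baseline — the deceleration component the fetus is coupled to.

    Returns (grid_times, drive_bpm) with drive <= 0.
    """
    t_end = float(times[-1])
    grid = np.arange(int(np.ceil(t_end * grid_fs)) + 1) / grid_fs
    m = np.interp(grid, times, hr)
    w = max(1, int(round(baseline_s * grid_fs)))
    c = np.concatenate([[0.0], np.cumsum(m)])
    idx = np.arange(m.size)
    lo = np.maximum(0, idx - w + 1)
    baseline = (c[idx + 1] - c[lo]) / (idx + 1 - lo)
    drive = np.minimum(m - baseline, 0.0)
    return grid, drive


def couple_fetal_rr(
    maternal_hr_series: HeartRateSeries | tuple[np.ndarray, np.ndarray],
    coupling_gain: float,
    lag: float,
    fetal_base_hr: float,
    rng: np.random.Generator,
    duration: float | None = None,
    hrv_params: HRVParams = _FETAL_HRV,
    baseline_s: float = 60.0,
) -> np.ndarray:
    """Generate fetal beat times whose instantaneous HR tracks lagged
    maternal decelerations with the given gain.

    ``fetal_hr(t) = base * (1 + HRV) + coupling_gain * drive(t - lag)`` where
    ``drive`` is the (non-positive) maternal deceleration component, in bpm.
    A gain of zero yields a fetal series statistically independent of the
    maternal one.
    """
    if lag < 0:
        raise InvalidArgumentError("lag must be non-negative")
    if not 80.0 <= fetal_base_hr <= 220.0:
        raise InvalidArgumentError(
            f"fetal_base_hr {fetal_base_hr} outside physiological [80, 220] bpm"
        )
    if isinstance(maternal_hr_series, HeartRateSeries):
        times, hr = maternal_hr_series.peak_times[1:], maternal_hr_series.hr_series
    else:
        times, hr = (np.asarray(a, dtype=float) for a in maternal_hr_series)
    grid, drive = maternal_deceleration_drive(times, hr, baseline_s=baseline_s)
    if duration is None:
        duration = float(grid[-1])
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
    events = []
    t = 0.0
    while True:
        mod = (
            hrv_params.lf_amp * np.sin(2 * np.pi * hrv_params.lf_freq * t + phases[0])
            + hrv_params.hf_amp * np.sin(2 * np.pi * hrv_params.hf_freq * t + phases[1])
        )
        jit = hrv_params.jitter_sd * rng.standard_normal() if hrv_params.jitter_sd else 0.0
        hr_t = fetal_base_hr * (1.0 + mod + jit)
        hr_t += coupling_gain * float(np.interp(t - lag, grid, drive, left=0.0))
        hr_t = float(np.clip(hr_t, 60.0, 250.0))
        t = t + 60.0 / hr_t
        if t > duration + 1e-9:
            break
        events.append(t)
    return np.asarray(events)


# ---------------------------------------------------------------------------
# channel mixing and quality index
# ---------------------------------------------------------------------------


def mix_abdominal(
    mecg: SignalRecording,
    fecg: SignalRecording,
    fetal_attenuation: float = 0.3,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
) -> SignalRecording:
    """Additive abdominal composite: mECG + attenuation * fECG + noise."""
    if mecg.fs != fecg.fs:
        raise InvalidArgumentError("mECG and fECG sampling rates differ")
    if mecg.samples.size != fecg.samples.size:
        raise InvalidArgumentError("mECG and fECG durations differ")
    noise = 0.0
    if noise_sd > 0:
        if rng is None:
            raise InvalidArgumentError("rng required when noise_sd > 0")
        noise = noise_sd * rng.standard_normal(mecg.samples.size)
    samples = mecg.samples + fetal_attenuation * fecg.samples + noise
    return SignalRecording(
        samples=samples, fs=mecg.fs, role="aECG", subject_id=mecg.subject_id
    )


def simulate_sqi(
    recording: SignalRecording,
    artifact_rate: float,
    rng: np.random.Generator,
) -> SignalRecording:
    """Attach a per-second SQI channel with Bernoulli(artifact_rate) artifact
    seconds (SQI in [0, 0.5)) and clean seconds (SQI in [0.5, 1])."""
    if not 0.0 <= artifact_rate <= 1.0:
        raise InvalidArgumentError("artifact_rate must lie in [0, 1]")
    n_sec = recording.n_seconds
    bad = rng.random(n_sec) < artifact_rate
    u = rng.random(n_sec)
    sqi = np.where(bad, 0.5 * u * (1 - 1e-9), 0.5 + 0.5 * u)
    return replace(recording, sqi=sqi)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _subject_truth(stressed: bool, config: CohortConfig, rng: np.random.Generator):
    """Draw latent severity and the label bundle for one subject."""
    severity = rng.normal(1.0 if stressed else -1.0, 0.6)
    noise = config.label_noise_sd
    pss = int(round(12.0 + 14.0 * sigmoid(severity) + noise * rng.standard_normal()))
    pss = int(np.clip(pss, 19, 40)) if stressed else int(np.clip(pss, 0, 18))
    pdq = int(max(0, round(10.0 + 4.0 * severity + noise * rng.standard_normal())))
    cortisol = float(np.exp(1.6 + 0.7 * severity + 0.15 * noise * rng.standard_normal()))
    gain = (
        config.coupling_gain_stressed if stressed else config.coupling_gain_control
    ) + 0.3 * (severity - (1.0 if stressed else -1.0))
    gain = max(0.0, gain)
    return severity, pss, pdq, cortisol, gain


def generate_subject(
    subject_id: str,
    stressed: bool,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[SubjectRecordings, SubjectTruth]:
    """Generate one mother-fetus dyad: recordings and ground truth."""
    from .bprsa import BPRSAConfig, compute_fsi  # deferred: bprsa imports heart_rate

    severity, pss, pdq, cortisol, gain = _subject_truth(stressed, config, rng)
    duration = config.recording_minutes * 60.0

    mean_hr = float(np.clip(config.maternal_base_hr + 5.0 * severity, 55.0, 110.0))
    m_hrv = HRVParams(hf_amp=0.04 + 0.05 * float(sigmoid(-2.0 * severity)))
    m_events = generate_rr_series(mean_hr, m_hrv, duration + 5.0, rng)
    m_series = HeartRateSeries(peak_times=m_events, fs_origin=config.maternal_fs)

    f_base = float(np.clip(config.fetal_base_hr + rng.normal(0.0, 3.0), 80.0, 220.0))
    f_events = couple_fetal_rr(
        m_series, gain, lag=config.coupling_lag_s, fetal_base_hr=f_base,
        rng=rng, duration=duration + 5.0,
    )
    f_series = HeartRateSeries(peak_times=f_events, fs_origin=config.maternal_fs)

    t_amp = 0.25 * (1.0 - 0.25 * float(np.tanh(severity)))
    m_morph = EcgMorphology().with_t_amplitude(t_amp)
    f_morph = EcgMorphology().with_t_amplitude(0.20)

    fs = config.maternal_fs
    mecg = SignalRecording(
        synthesize_ecg(m_events, fs, m_morph, duration=duration), fs, "mECG", subject_id
    )
    fecg = SignalRecording(
        synthesize_ecg(f_events, fs, f_morph, duration=duration), fs, "fECG", subject_id
    )
    aecg = mix_abdominal(
        mecg, fecg, config.fetal_attenuation, config.mix_noise_sd, rng
    )
    mecg = simulate_sqi(mecg, config.artifact_rate, rng)
    fecg = simulate_sqi(fecg, config.artifact_rate, rng)
    aecg = simulate_sqi(aecg, config.artifact_rate, rng)

    fsi_true = compute_fsi(m_series, f_series, BPRSAConfig()).fsi
    truth = SubjectTruth(
        subject_id=subject_id, group="stressed" if stressed else "control",
        latent_severity=float(severity), pss=pss, pdq=pdq, cortisol=cortisol,
        coupling_gain=float(gain), fsi_true=float(fsi_true),
    )
    return SubjectRecordings(mecg=mecg, fecg=fecg, aecg=aecg), truth


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecordings], pd.DataFrame]:
    """Generate a full cohort: per-subject channel triples and a truth table.

    Deterministic: the same config (including seed) reproduces recordings
    and labels bit-identically.
    """
    master = np.random.default_rng(config.seed)
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    recordings: list[SubjectRecordings] = []
    rows = []
    for i in range(config.n_subjects):
        stressed = bool(master.random() < config.stress_prevalence)
        recs, truth = generate_subject(
            f"s{i:03d}", stressed, config, np.random.default_rng(children[i])
        )
        recordings.append(recs)
        rows.append(vars(truth))
    truth_table = pd.DataFrame(rows)
    return recordings, truth_table


TRUTH_CSV_COLUMNS = [
    "subject_id", "group", "pss", "pdq", "cortisol", "coupling_gain", "fsi_true",
]


def write_truth_csv(truth_table: pd.DataFrame, path) -> None:
    truth_table[TRUTH_CSV_COLUMNS].to_csv(path, index=False)
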