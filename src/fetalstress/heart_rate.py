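"""R-peak detection and RR-interval / heart-rate series extraction.

Maternal and fetal beats are detected on their respective single-heart
channels (mECG, fECG).  The detector is a Pan-Tompkins-style chain —
zero-phase band-pass, squared energy, moving-window integration, adaptive
threshold with a refractory period — built on :mod:`scipy.signal`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import InsufficientPeaksError, InvalidArgumentError, NoPeaksError

# physiological RR bounds (s) used when cleaning interval series
RR_MIN_S = 0.2
RR_MAX_S = 3.0


@dataclass
class HeartRateSeries:
    """Beat times with derived RR intervals and instantaneous heart rate.

    ``rr[i] = peak_times[i+1] - peak_times[i]`` (seconds) and
    ``hr_series = 60 / rr`` (bpm).  ``fs_origin`` records the sampling rate
    of the signal the peaks were detected on.
    """

    peak_times: np.ndarray
    rr: np.ndarray = field(init=False)
    hr_series: np.ndarray = field(init=False)
    fs_origin: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise InsufficientPeaksError("need at least 2 peaks to form RR intervals")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("peak times must be strictly increasing")
        self.peak_times = t
        self.rr = np.diff(t)
        self.hr_series = 60.0 / self.rr

    @property
    def duration(self) -> float:
        return float(self.peak_times[-1] - self.peak_times[0])


def detect_rpeaks(
    ecg: np.ndarray,
    fs: float,
    refractory_s: float = 0.25,
    band: tuple[float, float] = (5.0, 35.0),
) -> np.ndarray:
    """Detect R-peak times (seconds) in a single-heart ECG channel.

    Parameters
    ----------
    ecg : 1-D signal.
    fs : sampling rate in Hz (>= 100).
    refractory_s : minimum inter-peak distance; never below 0.2 s.
    band : band-pass corner frequencies for QRS enhancement.
    """
    x = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise InvalidArgumentError(f"fs must be >= 100 Hz, got {fs}")
    if x.ndim != 1 or x.size < 2 * fs:
        raise InvalidArgumentError("signal must be 1-D and at least 2 s long")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("signal contains non-finite values")
    if np.ptp(x) == 0:
        raise NoPeaksError("flat signal: no QRS complexes present")

    high = min(band[1], 0.45 * fs)
    sos = sps.butter(3, [band[0], high], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    energy = filt**2
    win = max(1, int(round(0.12 * fs)))
    energy = sps.convolve(energy, np.ones(win) / win, mode="same")

    refractory_s = max(refractory_s, RR_MIN_S)
    height = 0.2 * np.percentile(energy, 99.5)
    locs, _ = sps.find_peaks(energy, height=height, distance=int(refractory_s * fs))
    if locs.size == 0:
        raise NoPeaksError("no peaks above the adaptive threshold")

    # refine each integrated-energy peak to the local extremum of the
    # band-passed signal (zero-phase filtering, so no group delay to undo)
    half = int(round(0.05 * fs))
    refined = np.empty(locs.size, dtype=np.int64)
    for j, loc in enumerate(locs):
        lo, hi = max(0, loc - half), min(x.size, loc + half + 1)
        refined[j] = lo + int(np.argmax(np.abs(filt[lo:hi])))
    refined = np.unique(refined)
    # re-enforce the refractory period after refinement
    keep = [0]
    for i in range(1, refined.size):
        if refined[i] - refined[keep[-1]] >= refractory_s * fs:
            keep.append(i)
    return refined[keep] / fs


def rr_from_peaks(peak_times: np.ndarray, fs_origin: float = 0.0) -> HeartRateSeries:
    """Build a :class:`HeartRateSeries`, dropping physiologically impossible beats.

    Peaks closer than 0.2 s to their predecessor are treated as duplicate
    detections and removed.  Gaps longer than 3 s are left in place — they
    mark missing data, not beats.
    """
    t = np.asarray(peak_times, dtype=float)
    if t.size < 2:
        raise InsufficientPeaksError("need at least 2 peaks")
    kept = [t[0]]
    for ti in t[1:]:
        if ti - kept[-1] >= RR_MIN_S:
            kept.append(ti)
    if len(kept) < 2:
        raise InsufficientPeaksError("fewer than 2 peaks after cleaning")
    return HeartRateSeries(peak_times=np.asarray(kept), fs_origin=fs_origin)


def mean_hr(series: HeartRateSeries) -> float:
    """Arithmetic mean of the instantaneous heart rate, in bpm."""
    if series.hr_series.size == 0:
        raise InsufficientPeaksError("empty heart-rate series")
    return float(np.mean(series.hr_series))


def export_rr_csv(series: HeartRateSeries, path) -> None:
    """Write the interval series as two-column CSV (time_s, rr_s)."""
    pd.DataFrame(
        {"time_s": series.peak_times[1:], "rr_s": series.rr}
    ).to_csv(path, index=False)


def import_rr_csv(path) -> HeartRateSeries:
    """Read a two-column (time_s, rr_s) CSV back into a series."""
    df = pd.read_csv(path)
    if not {"time_s", "rr_s"}.issubset(df.columns):
        raise InvalidArgumentError("RR CSV needs columns time_s, rr_s")
    t_end = df["time_s"].to_numpy(float)
    rr = df["rr_s"].to_numpy(float)
    peaks = np.concatenate([[t_end[0] - rr[0]], t_end])
    return HeartRateSeries(peak_times=peaks)
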