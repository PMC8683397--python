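"""Quality filtering, resampling, segmentation and normalization.

The model operates on 10-s windows at 256 Hz.  Whole 1-s blocks whose SQI
falls below 0.5 are discarded (strictly below: an SQI of exactly 0.5 is
kept) and the survivors concatenated; segments may therefore straddle a
splice, which is counted and logged.  Resampling is polyphase FIR
(anti-aliased, deterministic); each segment is z-normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .exceptions import (
    ConstantSegmentError,
    EmptyRecordingError,
    InvalidArgumentError,
)
from .synthetic_data import SignalRecording

logger = logging.getLogger(__name__)

TARGET_FS = 256.0
WINDOW_S = 10.0
SQI_THRESHOLD = 0.5


@dataclass
class Segment:
    """One fixed-length normalized window of a recording."""

    samples: np.ndarray
    subject_id: str
    source_role: str
    origin_index: int


@dataclass
class LabelBundle:
    """Per-subject labels broadcast to that subject's segments."""

    group: str
    pss: float
    pdq: float
    cortisol: float
    fsi: float


@dataclass
class SegmentDataset:
    """Stacked segments with aligned subject ids and per-subject labels.

    ``X`` is (n_segments, window_samples) float32; ``subject_ids`` aligns
    row-wise; ``labels`` maps subject_id -> LabelBundle.
    """

    X: np.ndarray
    subject_ids: np.ndarray
    source_role: str
    labels: dict[str, LabelBundle]

    def __post_init__(self) -> None:
        missing = set(np.unique(self.subject_ids)) - set(self.labels)
        if missing:
            raise InvalidArgumentError(f"segments without labels: {sorted(missing)}")

    def __len__(self) -> int:
        return int(self.X.shape[0])

    def label_array(self, field: str) -> np.ndarray:
        """Per-segment broadcast of a label field; group becomes 1/0."""
        vals = []
        for sid in self.subject_ids:
            lb = self.labels[str(sid)]
            v = getattr(lb, field)
            vals.append(1.0 if v == "stressed" else 0.0 if v == "control" else v)
        return np.asarray(vals, dtype=float)


def sqi_filter(
    recording: SignalRecording, threshold: float = SQI_THRESHOLD
) -> SignalRecording:
    """Concatenate the 1-s blocks whose SQI >= threshold.

    The discarded fraction and the number of splices (joins of
    non-contiguous blocks) are logged.
    """
    if recording.sqi is None:
        raise InvalidArgumentError("recording has no SQI channel")
    fs = recording.fs
    keep = recording.sqi >= threshold
    if not np.any(keep):
        raise EmptyRecordingError("all 1-s blocks fell below the SQI threshold")
    n_blocks = keep.size
    spb = int(round(fs))
    blocks = [recording.samples[i * spb : (i + 1) * spb] for i in np.nonzero(keep)[0]]
    kept_idx = np.nonzero(keep)[0]
    splices = int(np.sum(np.diff(kept_idx) > 1))
    discarded = 1.0 - keep.sum() / n_blocks
    logger.info(
        "sqi_filter %s/%s: discarded %.1f%% of seconds, %d splices",
        recording.subject_id, recording.role, 100 * discarded, splices,
    )
    return replace(
        recording,
        samples=np.concatenate(blocks),
        sqi=recording.sqi[keep],
    )


def resample_signal(
    recording: SignalRecording, target_fs: float = TARGET_FS
) -> SignalRecording:
    """Polyphase FIR resampling to the model rate (anti-aliased)."""
    if target_fs <= 0:
        raise InvalidArgumentError("target_fs must be positive")
    if recording.fs == target_fs:
        return recording
    ratio = Fraction(target_fs / recording.fs).limit_denominator(10_000)
    out = sps.resample_poly(recording.samples, ratio.numerator, ratio.denominator)
    sqi = recording.sqi
    if sqi is not None:
        n_sec = int(out.size // target_fs)
        sqi = sqi[:n_sec]
    return replace(recording, samples=out, fs=target_fs, sqi=sqi)


def segment_signal(
    recording: SignalRecording,
    window_s: float = WINDOW_S,
    drop_partial: bool = True,
    expected_fs: float | None = TARGET_FS,
) -> list[Segment]:
    """Cut the recording into non-overlapping fixed windows.

    A trailing partial window is dropped when ``drop_partial``; recordings
    shorter than one window yield an empty list with a warning.
    """
    if expected_fs is not None and recording.fs != expected_fs:
        raise InvalidArgumentError(
            f"expected fs {expected_fs}, got {recording.fs}; resample first"
        )
    wlen = int(round(window_s * recording.fs))
    n = recording.samples.size // wlen
    if n == 0:
        logger.warning(
            "recording %s/%s shorter than one %.0f-s window",
            recording.subject_id, recording.role, window_s,
        )
        return []
    if not drop_partial and recording.samples.size % wlen:
        raise InvalidArgumentError("partial windows unsupported without drop_partial")
    return [
        Segment(
            samples=recording.samples[i * wlen : (i + 1) * wlen],
            subject_id=recording.subject_id,
            source_role=recording.role,
            origin_index=i,
        )
        for i in range(n)
    ]


def normalize_segment(segment: Segment) -> Segment:
    """Zero-mean, unit-sd normalization of one segment."""
    x = segment.samples
    sd = float(np.std(x))
    if sd == 0.0:
        raise ConstantSegmentError("constant segment cannot be z-normalized")
    return replace(segment, samples=(x - np.mean(x)) / sd)


def preprocess_recording(
    recording: SignalRecording,
    sqi_threshold: float = SQI_THRESHOLD,
    target_fs: float = TARGET_FS,
    window_s: float = WINDOW_S,
) -> list[Segment]:
    """Full chain: SQI filter -> resample -> segment -> normalize.

    Constant segments (unnormalizable) are excluded.
    """
    rec = recording
    if rec.sqi is not None:
        rec = sqi_filter(rec, sqi_threshold)
    rec = resample_signal(rec, target_fs)
    out = []
    for seg in segment_signal(rec, window_s, expected_fs=target_fs):
        try:
            out.append(normalize_segment(seg))
        except ConstantSegmentError:
            logger.warning(
                "dropping constant segment %s/%s #%d",
                seg.subject_id, seg.source_role, seg.origin_index,
            )
    return out


def build_segment_dataset(
    cohort_recordings,
    truth_table,
    role: str = "mECG",
    sqi_threshold: float = SQI_THRESHOLD,
    target_fs: float = TARGET_FS,
    window_s: float = WINDOW_S,
) -> SegmentDataset:
    """Preprocess one channel of a generated cohort into a labeled dataset."""
    segs: list[Segment] = []
    for recs in cohort_recordings:
        segs.extend(
            preprocess_recording(
                recs.by_role(role), sqi_threshold, target_fs, window_s
            )
        )
    if not segs:
        raise EmptyRecordingError("no segments survived preprocessing")
    X = np.stack([s.samples for s in segs]).astype(np.float32)
    subject_ids = np.asarray([s.subject_id for s in segs])
    labels = {
        str(r.subject_id): LabelBundle(
            group=r.group, pss=float(r.pss), pdq=float(r.pdq),
            cortisol=float(r.cortisol), fsi=float(r.fsi_true),
        )
        for r in truth_table.itertuples()
    }
    return SegmentDataset(X=X, subject_ids=subject_ids, source_role=role, labels=labels)
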