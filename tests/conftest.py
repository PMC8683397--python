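"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from fetalstress.heart_rate import HeartRateSeries
from fetalstress.preprocess import preprocess_recording
from fetalstress.synthetic_data import (
    CohortConfig,
    HRVParams,
    SignalRecording,
    generate_cohort,
    generate_rr_series,
    simulate_sqi,
    synthesize_ecg,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects x 2 min: enough for one BPRSA window and a few segments."""
    cfg = CohortConfig(n_subjects=4, recording_minutes=2.0, seed=7)
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_dyad():
    """A 10-min maternal/fetal beat-time pair with strong coupling."""
    from fetalstress.synthetic_data import couple_fetal_rr

    m_ev = generate_rr_series(80, HRVParams(), 600, np.random.default_rng(21))
    maternal = HeartRateSeries(m_ev)
    f_ev = couple_fetal_rr(
        maternal, coupling_gain=1.5, lag=0.5, fetal_base_hr=140,
        rng=np.random.default_rng(22), duration=600,
    )
    return maternal, HeartRateSeries(f_ev)


@pytest.fixture(scope="session")
def ecg_segments():
    """~250 normalized 10-s mECG windows at 256 Hz from five synthetic hearts."""
    segs = []
    for i in range(5):
        ev = generate_rr_series(
            70 + 5 * i, HRVParams(), 520, np.random.default_rng(100 + i)
        )
        x = synthesize_ecg(ev, 900, duration=520)
        rec = SignalRecording(x, 900, "mECG", f"s{i}")
        rec = simulate_sqi(rec, 0.04, np.random.default_rng(200 + i))
        segs += [s.samples for s in preprocess_recording(rec)]
    return np.stack(segs).astype(np.float32)
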