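"""Container formats, experiment configuration and end-to-end orchestration.

Cohorts are stored in one HDF5 file with a group per subject and a dataset
per channel (attributes: fs, role, subject_id; SQI stored alongside).
Single signals can also be imported from one-column CSV with the sampling
rate in a header comment.  ``run_experiment`` ties the stages into the two
published approaches: pretext-training on the evaluation cohort itself
(``from_scratch``) or on an independent corpus followed by head-only
transfer (``transfer``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError
from .preprocess import build_segment_dataset
from .synthetic_data import (
    CohortConfig,
    SignalRecording,
    SubjectRecordings,
    generate_cohort,
    write_truth_csv,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# signal containers
# ---------------------------------------------------------------------------


def write_signal_container(recordings: list[SignalRecording], path) -> None:
    """Lossless HDF5 round-trip of samples, fs, role, subject_id and SQI."""
    with h5py.File(path, "w") as f:
        for rec in recordings:
            grp = f.require_group(f"subjects/{rec.subject_id}")
            ds = grp.create_dataset(rec.role, data=rec.samples)
            ds.attrs["fs"] = rec.fs
            ds.attrs["role"] = rec.role
            ds.attrs["subject_id"] = rec.subject_id
            if rec.sqi is not None:
                grp.create_dataset(f"{rec.role}_sqi", data=rec.sqi)


def read_signal_container(path) -> list[SignalRecording]:
    out: list[SignalRecording] = []
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            raise FormatError("container missing 'subjects' group")
        for sid in f["subjects"]:
            grp = f[f"subjects/{sid}"]
            for name in grp:
                if name.endswith("_sqi"):
                    continue
                ds = grp[name]
                if "fs" not in ds.attrs:
                    raise FormatError(f"dataset {sid}/{name} missing fs metadata")
                sqi = grp[f"{name}_sqi"][:] if f"{name}_sqi" in grp else None
                out.append(
                    SignalRecording(
                        samples=ds[:], fs=float(ds.attrs["fs"]),
                        role=str(ds.attrs["role"]),
                        subject_id=str(ds.attrs["subject_id"]), sqi=sqi,
                    )
                )
    return out


def read_signal_csv(path, role: str = "mECG", subject_id: str = "s000") -> SignalRecording:
    """One-column CSV of samples; the header comment must carry the sampling
    rate, e.g. ``# fs=900``."""
    path = Path(path)
    fs = None
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            for tok in line[1:].replace(",", " ").split():
                if tok.startswith("fs="):
                    fs = float(tok[3:])
    if fs is None:
        raise FormatError(f"{path}: no '# fs=<Hz>' header comment")
    samples = np.loadtxt(path, comments="#", ndmin=1)
    return SignalRecording(samples=samples, fs=fs, role=role, subject_id=subject_id)


def write_signal_csv(recording: SignalRecording, path) -> None:
    np.savetxt(
        path, recording.samples,
        header=f"fs={recording.fs} role={recording.role} subject_id={recording.subject_id}",
    )


# ---------------------------------------------------------------------------
# experiment configuration and orchestration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Everything that determines one end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    approach: str = "from_scratch"  # or "transfer"
    sources: tuple[str, ...] = ("aECG", "mECG")
    tasks: tuple[str, ...] = (
        "classify_stress", "regress_cortisol", "regress_fsi",
        "regress_pdq", "regress_pss",
    )
    sqi_threshold: float = 0.5
    target_fs: float = 256.0
    window_s: float = 10.0
    pretext_epochs: int = 2
    head_epochs: int = 40
    lr: float = 0.001
    batch_size: int = 128
    k_folds: int = 5
    seed: int = 0
    # independent corpus for the transfer approach
    pretrain_cohort: CohortConfig | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(_to_plain(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        return _config_from_dict(d)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    d["cohort"] = CohortConfig(**d.get("cohort", {}))
    if d.get("pretrain_cohort"):
        d["pretrain_cohort"] = CohortConfig(**d["pretrain_cohort"])
    for key in ("sources", "tasks"):
        if key in d:
            d[key] = tuple(d[key])
    return ExperimentConfig(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def default_pretrain_config(config: ExperimentConfig) -> CohortConfig:
    """Independent pretraining corpus: a separate generator draw standing in
    for the public affect datasets (different seed, smaller cohort)."""
    return dataclasses.replace(
        config.cohort,
        n_subjects=max(10, config.cohort.n_subjects // 2),
        seed=config.cohort.seed + 104729,  # decorrelated stream
    )


def run_experiment(config: ExperimentConfig, out_dir) -> pd.DataFrame:
    """Run the full grid {sources} x {tasks} for the configured approach.

    Writes per-fold metrics, a mean +/- sd report, the truth table, a config
    snapshot and artifact checksums into ``out_dir``; returns the per-fold
    metric frame.
    """
    from .evaluate import evaluate_task, summarize_panel
    from .ssl import TransformationRecognitionEncoder, encode_segments

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recordings, truth = generate_cohort(config.cohort)
    write_truth_csv(truth, out / "truth.csv")

    datasets = {
        role: build_segment_dataset(
            recordings, truth, role=role,
            sqi_threshold=config.sqi_threshold,
            target_fs=config.target_fs, window_s=config.window_s,
        )
        for role in config.sources
    }

    def fit_encoder(X, seed):
        enc = TransformationRecognitionEncoder(
            epochs=config.pretext_epochs, lr=config.lr,
            batch_size=config.batch_size, random_state=seed,
        )
        return enc.fit(X).state_

    if config.approach == "transfer":
        pre_cfg = config.pretrain_cohort or default_pretrain_config(config)
        pre_recs, pre_truth = generate_cohort(pre_cfg)
        pre_ds = build_segment_dataset(
            pre_recs, pre_truth, role="mECG",
            sqi_threshold=config.sqi_threshold,
            target_fs=config.target_fs, window_s=config.window_s,
        )
        shared = fit_encoder(pre_ds.X, config.seed)
        encoders = {role: shared for role in config.sources}
    elif config.approach == "from_scratch":
        encoders = {
            role: fit_encoder(datasets[role].X, config.seed + i)
            for i, role in enumerate(config.sources)
        }
    else:
        raise FormatError(f"unknown approach {config.approach!r}")

    frames = []
    for role in config.sources:
        feats = encode_segments(encoders[role], datasets[role].X)
        for task in config.tasks:
            df = evaluate_task(
                datasets[role], encoders[role], task,
                k=config.k_folds, random_state=config.seed,
                epochs=config.head_epochs, lr=config.lr,
                batch_size=config.batch_size, features=feats,
            )
            df.insert(0, "source", role)
            frames.append(df)
    fold_frame = pd.concat(frames, ignore_index=True)
    fold_frame.to_csv(out / "fold_metrics.csv", index=False)
    report = summarize_panel(fold_frame)
    report.to_csv(out / "report.csv", index=False)
    (out / "report.txt").write_text(report.to_string(index=False) + "\n")
    config.to_yaml(out / "config.yaml")
    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".txt", ".yaml")
    }
    (out / "checksums.json").write_text(json.dumps(checksums, indent=2) + "\n")
    return fold_frame
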