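"""Stage-2 affect recognition on frozen self-supervised representations.

The convolutional trunk learned on the transformation-recognition pretext
task is transferred and kept frozen; only small fully connected heads are
trained — a sigmoid head for stress-group classification (binary
cross-entropy) and linear-output heads for biomarker regression (hair
cortisol, fetal stress index, PDQ, PSS; mean-absolute-error loss).
Regression targets are z-scored on the training data and predictions
inverse-transformed.  Because the trunk is frozen, features are computed
once per dataset and head training operates on them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import _nn
from .exceptions import (
    DegenerateLabelsError,
    InvalidArgumentError,
    TrainingDivergedError,
)
from .preprocess import SegmentDataset
from .ssl import EncoderState, TransformationRecognitionEncoder, encode_segments

CLASSIFY_TASK = "classify_stress"
REGRESS_TASKS = ("regress_cortisol", "regress_fsi", "regress_pdq", "regress_pss")
TASKS = (CLASSIFY_TASK, *REGRESS_TASKS)

TASK_LABEL_FIELD = {
    CLASSIFY_TASK: "group",
    "regress_cortisol": "cortisol",
    "regress_fsi": "fsi",
    "regress_pdq": "pdq",
    "regress_pss": "pss",
}


def _resolve_state(encoder) -> EncoderState:
    if isinstance(encoder, EncoderState):
        return encoder
    if isinstance(encoder, TransformationRecognitionEncoder):
        if not hasattr(encoder, "state_"):
            raise InvalidArgumentError("encoder must be fitted before transfer")
        return encoder.state_
    raise InvalidArgumentError("encoder must be an EncoderState or fitted encoder")


def _build_head(
    feature_dim: int, hidden: int, dropout: float, rng: np.random.Generator
) -> _nn.Sequential:
    return _nn.Sequential(
        [
            _nn.Dense(feature_dim, hidden, rng),
            _nn.LeakyReLU(0.1),
            _nn.Dropout(dropout, rng),
            _nn.Dense(hidden, 1, rng, init_scale=0.0),
        ]
    )


def _train_head(
    head: _nn.Sequential,
    features: np.ndarray,
    y: np.ndarray,
    kind: str,
    rng: np.random.Generator,
    lr: float = 0.001,
    batch_size: int = 128,
    epochs: int = 40,
) -> list[float]:
    opt = _nn.Adam(head.params(), lr=lr)
    F = features.astype(_nn.DTYPE, copy=False)
    log: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(F.shape[0])
        for s in range(0, F.shape[0], batch_size):
            idx = order[s : s + batch_size]
            z = head.forward(F[idx], train=True).ravel()
            if kind == "bce":
                loss, dz = _nn.bce_with_logits(z, y[idx])
            else:
                loss, dz = _nn.mae_loss(z, y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite affect loss {loss}")
            head.backward(dz.reshape(-1, 1))
            opt.step(head.grads())
            log.append(loss)
    return log


@dataclass
class AffectModel:
    """Frozen trunk + task head.  ``trunk_checksum_at_build`` witnesses the
    freeze contract: it must equal the encoder checksum after any amount of
    head training."""

    encoder_state: EncoderState
    task: str
    head: _nn.Sequential
    y_mean: float = 0.0
    y_sd: float = 1.0
    loss_log: list[float] = field(default_factory=list)
    trunk_checksum_at_build: str = ""

    @property
    def is_classifier(self) -> bool:
        return self.task == CLASSIFY_TASK


def build_affect_model(
    encoder, task: str, random_state: int = 0, hidden: int = 64, dropout: float = 0.5
) -> AffectModel:
    """Assemble an affect model: transferred frozen trunk, fresh head."""
    state = _resolve_state(encoder)
    if task not in TASKS:
        raise InvalidArgumentError(f"unknown task {task!r}; one of {TASKS}")
    rng = np.random.default_rng(random_state)
    head = _build_head(state.config.feature_dim, hidden, dropout, rng)
    return AffectModel(
        encoder_state=state,
        task=task,
        head=head,
        trunk_checksum_at_build=state.checksum(),
    )


def _task_targets(model: AffectModel, dataset: SegmentDataset) -> np.ndarray:
    return dataset.label_array(TASK_LABEL_FIELD[model.task])


def train_affect(
    model: AffectModel,
    train_segments: SegmentDataset,
    lr: float = 0.001,
    batch_size: int = 128,
    epochs: int = 40,
    random_state: int = 0,
    features: np.ndarray | None = None,
) -> AffectModel:
    """Train only the head; the trunk is frozen by construction.

    ``features`` may carry precomputed trunk features for the dataset (they
    are recomputed otherwise).
    """
    y = _task_targets(model, train_segments)
    if model.is_classifier and len(np.unique(y)) < 2:
        raise DegenerateLabelsError("classification training set has one class")
    if features is None:
        features = encode_segments(model.encoder_state, train_segments.X)
    rng = np.random.default_rng(random_state)
    if model.is_classifier:
        kind, y_t = "bce", y
    else:
        model.y_mean = float(np.mean(y))
        model.y_sd = float(np.std(y)) or 1.0
        kind, y_t = "mae", (y - model.y_mean) / model.y_sd
    model.loss_log += _train_head(
        model.head, features, y_t, kind, rng, lr, batch_size, epochs
    )
    return model


def predict(
    model: AffectModel, segments: np.ndarray, features: np.ndarray | None = None
) -> np.ndarray:
    """Per-segment predictions: probability of the stressed class for the
    classifier, biomarker value (original units) for regressors."""
    if features is None:
        features = encode_segments(model.encoder_state, segments)
    z = model.head.forward(features.astype(_nn.DTYPE, copy=False), train=False).ravel()
    if model.is_classifier:
        return _nn.sigmoid(z)
    return z.astype(float) * model.y_sd + model.y_mean


def aggregate_subject(
    predictions: np.ndarray, subject_ids: np.ndarray
) -> pd.Series:
    """Subject score = mean of the subject's segment predictions."""
    s = pd.Series(np.asarray(predictions, dtype=float), name="score")
    return s.groupby(np.asarray(subject_ids)).mean()


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------


class _FrozenTrunkHead(BaseEstimator):
    """Shared machinery: encode with the frozen trunk, train a small head."""

    _kind = "bce"

    def __init__(
        self,
        encoder=None,
        hidden=64,
        dropout=0.5,
        lr=0.001,
        batch_size=128,
        epochs=40,
        random_state=0,
    ):
        self.encoder = encoder
        self.hidden = hidden
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def _encode(self, X) -> np.ndarray:
        return encode_segments(self._state_, np.asarray(X, dtype=np.float32))

    def _fit_head(self, X, y_t):
        self._state_ = _resolve_state(self.encoder)
        rng = np.random.default_rng(self.random_state)
        self.head_ = _build_head(
            self._state_.config.feature_dim, self.hidden, self.dropout, rng
        )
        feats = self._encode(X)
        self.loss_log_ = _train_head(
            self.head_, feats, y_t, self._kind, rng,
            self.lr, self.batch_size, self.epochs,
        )
        self.trunk_checksum_ = self._state_.checksum()

    def _head_raw(self, X) -> np.ndarray:
        return self.head_.forward(self._encode(X), train=False).ravel()


class StressClassifier(ClassifierMixin, _FrozenTrunkHead):
    """Stress-group classifier: frozen pretext trunk + sigmoid FC head."""

    _kind = "bce"

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise DegenerateLabelsError("need both classes to fit")
        self._fit_head(X, y)
        return self

    def predict_proba(self, X):
        p = _nn.sigmoid(self._head_raw(X))
        return np.column_stack([1 - p, p])

    def decision_function(self, X):
        return self._head_raw(X).astype(float)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)


class BiomarkerRegressor(RegressorMixin, _FrozenTrunkHead):
    """Biomarker regressor: frozen trunk + linear-output FC head, MAE loss,
    targets z-scored during training."""

    _kind = "mae"

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        self.y_mean_ = float(np.mean(y))
        self.y_sd_ = float(np.std(y)) or 1.0
        self._fit_head(X, (y - self.y_mean_) / self.y_sd_)
        return self

    def predict(self, X):
        return self._head_raw(X).astype(float) * self.y_sd_ + self.y_mean_
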