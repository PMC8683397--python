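"""Self-supervised ECG representation learning via transformation recognition.

Six label-free signal transformations (noise addition, scaling, negation,
temporal inversion, permutation, time-warping) are applied to each ECG
segment; a multi-task 1-D convolutional network — three blocks of two
convolutions with leaky-ReLU and max pooling, a global max pool, then one
parallel binary head per transformation — learns to recognize which
transformation (if any) a segment underwent.  The convolutional trunk is
the transferable representation.

Transformation parameters and layer widths are desk-scale package defaults
(configurable); see docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _nn
from .exceptions import (
    InvalidArgumentError,
    InvalidConfigError,
    TrainingDivergedError,
)

TRANSFORM_KINDS = ("noise", "scale", "negate", "time_invert", "permute", "time_warp")


# ---------------------------------------------------------------------------
# the six transformations
# ---------------------------------------------------------------------------


def t_noise(x: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Add zero-mean Gaussian noise of the given standard deviation."""
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be non-negative")
    x = np.asarray(x)
    return x + noise_sd * rng.standard_normal(x.shape).astype(x.dtype, copy=False)


def t_scale(x: np.ndarray, factor: float) -> np.ndarray:
    """Scale the signal magnitude."""
    if factor <= 0:
        raise InvalidArgumentError("scale factor must be positive")
    return np.asarray(x) * factor


def t_negate(x: np.ndarray) -> np.ndarray:
    """Flip the signal vertically."""
    return -np.asarray(x)


def t_time_invert(x: np.ndarray) -> np.ndarray:
    """Flip the signal horizontally (reverse time)."""
    return np.asarray(x)[::-1].copy()


def _split_points(n: int, n_segments: int) -> np.ndarray:
    """Equal-length split; the last piece absorbs the remainder."""
    size = n // n_segments
    return np.arange(1, n_segments) * size


def t_permute(x: np.ndarray, n_segments: int, rng: np.random.Generator) -> np.ndarray:
    """Split into equal pieces and concatenate them in random order."""
    x = np.asarray(x)
    if n_segments < 1 or n_segments > x.size:
        raise InvalidArgumentError("n_segments must lie in [1, len(x)]")
    if n_segments == 1:
        return x.copy()
    pieces = np.split(x, _split_points(x.size, n_segments))
    order = rng.permutation(n_segments)
    return np.concatenate([pieces[i] for i in order])


def t_time_warp(
    x: np.ndarray, n_segments: int, warp_ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """Stretch half the pieces by ``warp_ratio`` and squeeze the other half,
    then resample the concatenation back to the original length."""
    x = np.asarray(x, dtype=float)
    if warp_ratio <= 1.0:
        raise InvalidArgumentError("warp_ratio must be > 1")
    if n_segments < 2 or n_segments > x.size:
        raise InvalidArgumentError("n_segments must lie in [2, len(x)]")
    pieces = np.split(x, _split_points(x.size, n_segments))
    stretch = np.zeros(n_segments, dtype=bool)
    stretch[: n_segments // 2] = True
    stretch = stretch[rng.permutation(n_segments)]
    warped = []
    for piece, up in zip(pieces, stretch):
        ratio = warp_ratio if up else 1.0 / warp_ratio
        m = max(2, int(round(piece.size * ratio)))
        warped.append(
            np.interp(
                np.linspace(0, piece.size - 1, m), np.arange(piece.size), piece
            )
        )
    cat = np.concatenate(warped)
    out = np.interp(
        np.linspace(0, cat.size - 1, x.size), np.arange(cat.size), cat
    )
    return out.astype(x.dtype, copy=False)


@dataclass(frozen=True)
class TransformSpec:
    """One pretext transformation with its parameters."""

    kind: str
    noise_sd: float = 0.05
    scale_choices: tuple[float, ...] = (0.7, 1.3)
    n_segments: int = 20
    warp_ratio: float = 1.05

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise InvalidConfigError(f"unknown transformation {self.kind!r}")

    def apply(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "noise":
            return t_noise(x, self.noise_sd, rng)
        if self.kind == "scale":
            return t_scale(x, float(rng.choice(self.scale_choices)))
        if self.kind == "negate":
            return t_negate(x)
        if self.kind == "time_invert":
            return t_time_invert(x)
        if self.kind == "permute":
            return t_permute(x, self.n_segments, rng)
        return t_time_warp(x, self.n_segments, self.warp_ratio, rng)


def default_transform_specs() -> tuple[TransformSpec, ...]:
    return tuple(TransformSpec(kind=k) for k in TRANSFORM_KINDS)


# ---------------------------------------------------------------------------
# pretext dataset
# ---------------------------------------------------------------------------


@dataclass
class PretextBatch:
    """Stacked transformed segments with one binary label column per head.

    Each row is either an untouched segment (all-zero label row) or carries
    exactly one positive head.
    """

    inputs: np.ndarray  # (n_rows, window)
    labels: np.ndarray  # (n_rows, n_heads)


def build_pretext_dataset(
    segments: np.ndarray,
    specs: tuple[TransformSpec, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> PretextBatch:
    """Each segment yields one original row plus one row per transformation;
    the rows are shuffled (labels kept aligned)."""
    rng = rng or np.random.default_rng(0)
    specs = specs or default_transform_specs()
    X = np.asarray(segments, dtype=np.float32)
    if X.ndim != 2:
        raise InvalidArgumentError("segments must be a 2-D (n, window) array")
    n, L = X.shape
    n_heads = len(specs)
    rows = np.empty(((n_heads + 1) * n, L), dtype=np.float32)
    labels = np.zeros(((n_heads + 1) * n, n_heads), dtype=np.float32)
    rows[:n] = X
    for h, spec in enumerate(specs):
        block = slice((h + 1) * n, (h + 2) * n)
        for i in range(n):
            rows[block][i] = spec.apply(X[i], rng)
        labels[block, h] = 1.0
    order = rng.permutation(rows.shape[0])
    return PretextBatch(inputs=rows[order], labels=labels[order])


# ---------------------------------------------------------------------------
# encoder network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the transformation-recognition trunk.

    Three convolutional blocks (two conv layers + leaky ReLU each, then max
    pooling), global max pooling, and parallel binary heads.
    """

    channels: tuple[int, int, int] = (8, 16, 64)
    kernels: tuple[int, int, int] = (16, 8, 8)
    pool_size: int = 8
    leaky_slope: float = 0.1
    dropout: float = 0.5
    feature_gain: float = 5.0
    n_heads: int = 6
    input_len: int = 2560

    def __post_init__(self) -> None:
        if len(self.channels) != 3 or len(self.kernels) != 3:
            raise InvalidConfigError("the trunk has exactly three blocks")
        if any(c <= 0 for c in self.channels):
            raise InvalidConfigError("channel widths must be positive")
        if self.input_len // self.pool_size**3 < 1:
            raise InvalidConfigError(
                f"input_len {self.input_len} collapses to zero after three "
                f"pool-{self.pool_size} stages"
            )

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]


def build_trunk(config: EncoderConfig, rng: np.random.Generator) -> _nn.Sequential:
    layers: list[_nn.Layer] = []
    c_in = 1
    for c_out, k in zip(config.channels, config.kernels):
        layers += [
            _nn.Conv1d(c_in, c_out, k, rng),
            _nn.LeakyReLU(config.leaky_slope),
            _nn.Conv1d(c_out, c_out, k, rng),
            _nn.LeakyReLU(config.leaky_slope),
            _nn.MaxPool1d(config.pool_size),
        ]
        c_in = c_out
    layers.append(_nn.GlobalMaxPool())
    if config.feature_gain != 1.0:
        layers.append(_nn.Scale(config.feature_gain))
    return _nn.Sequential(layers)


def _build_pretext_heads(
    config: EncoderConfig, rng: np.random.Generator
) -> list[_nn.Sequential]:
    return [
        _nn.Sequential(
            [
                _nn.Dropout(config.dropout, rng),
                _nn.Dense(config.feature_dim, 1, rng, init_scale=0.0),
            ]
        )
        for _ in range(config.n_heads)
    ]


@dataclass
class EncoderState:
    """Trained trunk + per-head weights, with the training loss log."""

    config: EncoderConfig
    trunk_params: list[np.ndarray]
    head_params: list[list[np.ndarray]]
    loss_log: list[float] = field(default_factory=list)

    def checksum(self) -> str:
        """SHA-256 of the trunk weights (freeze-contract witness)."""
        return _nn.weights_checksum(self.trunk_params)

    def save(self, path) -> None:
        arrays = {f"trunk_{i}": p for i, p in enumerate(self.trunk_params)}
        for h, head in enumerate(self.head_params):
            for i, p in enumerate(head):
                arrays[f"head_{h}_{i}"] = p
        arrays["loss_log"] = np.asarray(self.loss_log)
        cfg = asdict(self.config)
        arrays["config_json"] = np.frombuffer(
            repr(cfg).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "EncoderState":
        import ast

        with np.load(path) as z:
            cfg = ast.literal_eval(bytes(z["config_json"]).decode())
            cfg["channels"] = tuple(cfg["channels"])
            cfg["kernels"] = tuple(cfg["kernels"])
            config = EncoderConfig(**cfg)
            trunk = [z[f"trunk_{i}"] for i in range(sum(1 for k in z.files if k.startswith("trunk_")))]
            heads: list[list[np.ndarray]] = []
            h = 0
            while f"head_{h}_0" in z.files:
                head, i = [], 0
                while f"head_{h}_{i}" in z.files:
                    head.append(z[f"head_{h}_{i}"])
                    i += 1
                heads.append(head)
                h += 1
            return cls(config, trunk, heads, list(z["loss_log"]))


def _copy_params(dst: list[np.ndarray], src: list[np.ndarray]) -> None:
    for d, s in zip(dst, src):
        d[...] = s


def restore_trunk(state: EncoderState) -> _nn.Sequential:
    trunk = build_trunk(state.config, np.random.default_rng(0))
    _copy_params(trunk.params(), state.trunk_params)
    return trunk


def encode_segments(
    state: EncoderState, X: np.ndarray, batch_size: int = 512
) -> np.ndarray:
    """Frozen-trunk features for a stack of segments, (n, feature_dim)."""
    trunk = restore_trunk(state)
    X = np.asarray(X, dtype=_nn.DTYPE)
    out = [
        trunk.forward(X[i : i + batch_size, None, :], train=False)
        for i in range(0, X.shape[0], batch_size)
    ]
    return np.concatenate(out, axis=0)


def train_pretext(
    config: EncoderConfig,
    batch: PretextBatch,
    lr: float = 0.001,
    batch_size: int = 128,
    epochs: int = 2,
    rng: np.random.Generator | None = None,
) -> EncoderState:
    """Train the multi-task transformation-recognition network with Adam and
    a summed per-head binary cross-entropy loss."""
    if batch.inputs.shape[0] == 0:
        raise InvalidArgumentError("empty pretext dataset")
    rng = rng or np.random.default_rng(0)
    trunk = build_trunk(config, rng)
    heads = _build_pretext_heads(config, rng)
    params = trunk.params() + [p for h in heads for p in h.params()]
    opt = _nn.Adam(params, lr=lr)
    X = batch.inputs.astype(_nn.DTYPE, copy=False)
    Y = batch.labels
    log: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(X.shape[0])
        for s in range(0, X.shape[0], batch_size):
            idx = order[s : s + batch_size]
            xb = X[idx][:, None, :]
            feat = trunk.forward(xb, train=True)
            dfeat = np.zeros_like(feat)
            loss = 0.0
            for h, head in enumerate(heads):
                z = head.forward(feat, train=True)
                # one positive per (n_heads+1)-row block: rebalance classes
                lh, dz = _nn.bce_with_logits(
                    z.ravel(), Y[idx, h], pos_weight=float(config.n_heads)
                )
                loss += lh
                dfeat += head.backward(dz.reshape(-1, 1))
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite pretext loss {loss}")
            trunk.backward(dfeat)
            grads = trunk.grads() + [g for h in heads for g in h.grads()]
            opt.step(grads)
            log.append(loss)
    return EncoderState(
        config=config,
        trunk_params=trunk.params(),
        head_params=[h.params() for h in heads],
        loss_log=log,
    )


def pretext_head_accuracy(
    state: EncoderState, batch: PretextBatch, batch_size: int = 512
) -> dict[int, float]:
    """Per-head recognition accuracy (threshold 0.5) on a pretext batch."""
    feat = encode_segments(state, batch.inputs, batch_size)
    acc: dict[int, float] = {}
    for h, head_p in enumerate(state.head_params):
        W, b = head_p[-2], head_p[-1]
        z = feat @ W + b
        pred = (_nn.sigmoid(z.ravel()) >= 0.5).astype(float)
        acc[h] = float(np.mean(pred == batch.labels[:, h]))
    return acc


class TransformationRecognitionEncoder(TransformerMixin, BaseEstimator):
    """Sklearn-style wrapper: fit learns the pretext task on raw segments,
    transform emits frozen-trunk features.

    Parameters mirror :class:`EncoderConfig` plus the Adam hyperparameters
    (lr 0.001, batch 128 by default).
    """

    def __init__(
        self,
        channels=(8, 16, 64),
        kernels=(16, 8, 8),
        pool_size=8,
        leaky_slope=0.1,
        dropout=0.5,
        feature_gain=5.0,
        lr=0.001,
        batch_size=128,
        epochs=2,
        specs=None,
        random_state=0,
    ):
        self.channels = channels
        self.kernels = kernels
        self.pool_size = pool_size
        self.leaky_slope = leaky_slope
        self.dropout = dropout
        self.feature_gain = feature_gain
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.specs = specs
        self.random_state = random_state

    def _config(self, input_len: int) -> EncoderConfig:
        specs = self.specs or default_transform_specs()
        return EncoderConfig(
            channels=tuple(self.channels),
            kernels=tuple(self.kernels),
            pool_size=self.pool_size,
            leaky_slope=self.leaky_slope,
            dropout=self.dropout,
            feature_gain=self.feature_gain,
            n_heads=len(specs),
            input_len=input_len,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2:
            raise InvalidArgumentError("X must be (n_segments, window)")
        rng = np.random.default_rng(self.random_state)
        specs = self.specs or default_transform_specs()
        batch = build_pretext_dataset(X, specs, rng)
        self.state_ = train_pretext(
            self._config(X.shape[1]), batch,
            lr=self.lr, batch_size=self.batch_size, epochs=self.epochs, rng=rng,
        )
        self.loss_log_ = self.state_.loss_log
        self.n_features_out_ = self.state_.config.feature_dim
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "state_"):
            raise InvalidArgumentError("encoder is not fitted")
        return encode_segments(self.state_, np.asarray(X, dtype=np.float32))
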