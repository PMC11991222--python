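"""Window classifiers: embedding + 1-D U-Net, and FCN / LSTM baselines.

All three consume index-encoded sensor-event windows (``(B, W)`` integer
arrays, zeros = left padding). The U-Net is trained as a sequence labeller
— it emits a class distribution at every window position — and a window
prediction is the argmax of the mean probability over non-padding
positions. The FCN and LSTM predict a single class per window directly.

Each model can encode its input either through a learned dense embedding
(the "+Embedding" variants) or through fixed one-hot channels
(the raw-index ablation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn


def _scaled(filters: list[int], scale: float) -> list[int]:
    return [max(1, int(round(f * scale))) for f in filters]


@dataclass
class UNetConfig:
    """Architecture of the 1-D U-Net.

    Defaults are the full-size network: five encoder stages with filter
    counts 64..1024 (the last is the bottleneck), four decoder stages
    512..64, kernel 3, pool/upsample factor 2, and a 64-dimensional input
    embedding. ``depth_scale`` multiplies every filter count so that
    desk-scale experiments train in seconds while keeping the topology.
    """

    n_classes: int = 2
    embed_dim: int = 64
    encoder_filters: list[int] = field(default_factory=lambda: [64, 128, 256, 512, 1024])
    decoder_filters: list[int] = field(default_factory=lambda: [512, 256, 128, 64])
    kernel: int = 3
    pool: int = 2
    upsample: int = 2
    depth_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.decoder_filters) != len(self.encoder_filters) - 1:
            raise ValueError("decoder must have one fewer stage than the encoder")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        if self.pool != self.upsample:
            raise ValueError("pool and upsample factors must match")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    @property
    def n_pools(self) -> int:
        return len(self.encoder_filters) - 1

    def scaled_encoder_filters(self) -> list[int]:
        return _scaled(self.encoder_filters, self.depth_scale)

    def scaled_decoder_filters(self) -> list[int]:
        return _scaled(self.decoder_filters, self.depth_scale)


class WindowClassifier:
    """Shared training/prediction interface of the three models."""

    window_size: int
    n_classes: int

    def parameters(self) -> list[nn.Parameter]:
        raise NotImplementedError

    def loss_and_grad(self, X: np.ndarray, y: np.ndarray) -> float:
        """Forward + backward on one batch; accumulates parameter grads."""
        raise NotImplementedError

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        raise NotImplementedError

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Predicted class indices; ties resolve to the lowest class index."""
        return self.predict_proba(X, batch_size).argmax(axis=1)

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value[...] = v

    def _check_indices(self, X: np.ndarray) -> None:
        if X.shape[1] != self.window_size:
            raise ValueError(f"window length {X.shape[1]} != model window {self.window_size}")
        if X.max(initial=0) >= self.n_indices:
            raise ValueError("vocabulary index out of range for this model's encoder")


class UNet1d(WindowClassifier):
    """Embedding + 1-D U-Net sequence labeller.

    Encoder: repeated [conv(k) -> ReLU -> conv(k) -> ReLU] blocks with the
    configured filter counts, max-pooled between blocks, so a length-64
    input passes feature lengths 64 -> 32 -> 16 -> 8 -> 4. Decoder:
    nearest-neighbour upsample, channel concatenation with the same-length
    encoder feature (skip connection), then two convolutions. A 1x1
    projection produces per-position class logits.

    Windows whose length is not divisible by ``pool ** n_pools`` are
    left-padded internally to the next admissible length; the padding is
    masked out of the loss and of the window-level prediction.
    """

    def __init__(self, cfg: UNetConfig, window_size: int, n_indices: int,
                 *, embedding: bool = True, seed: int = 0):
        if window_size < 2:
            raise ValueError("window_size must be >= 2")
        self.cfg = cfg
        self.window_size = window_size
        self.n_classes = cfg.n_classes
        self.n_indices = n_indices
        self.embedding = embedding
        rng = np.random.default_rng(seed)

        factor = cfg.pool ** cfg.n_pools
        if window_size < factor:
            raise ValueError(
                f"window {window_size} cannot pass {cfg.n_pools} poolings of {cfg.pool} "
                f"(needs >= {factor} events even with internal padding); "
                "use a larger window or fewer encoder stages"
            )
        self.padded_size = -(-window_size // factor) * factor  # ceil to multiple
        self.encoder_lengths = [self.padded_size // (cfg.pool ** i)
                                for i in range(len(cfg.encoder_filters))]

        enc_f = cfg.scaled_encoder_filters()
        dec_f = cfg.scaled_decoder_filters()
        if self.embedding:
            self.encoder_in = nn.Embedding(n_indices, cfg.embed_dim, rng)
            cin = cfg.embed_dim
        else:
            self.encoder_in = nn.OneHot(n_indices)
            cin = n_indices

        self.enc_blocks = []
        for f in enc_f:
            self.enc_blocks.append([
                nn.Conv1d(cin, f, cfg.kernel, rng), nn.ReLU(),
                nn.Conv1d(f, f, cfg.kernel, rng), nn.ReLU(),
            ])
            cin = f
        self.pools = [nn.MaxPool1d(cfg.pool) for _ in range(cfg.n_pools)]

        self.dec_blocks = []
        self.ups = []
        for i, f in enumerate(dec_f):
            self.ups.append(nn.Upsample1d(cfg.upsample))
            skip_channels = enc_f[-2 - i]
            self.dec_blocks.append([
                nn.Conv1d(cin + skip_channels, f, cfg.kernel, rng), nn.ReLU(),
                nn.Conv1d(f, f, cfg.kernel, rng), nn.ReLU(),
            ])
            cin = f
        self.head = nn.Conv1d(cin, cfg.n_classes, 1, rng)

    def parameters(self):
        params = list(getattr(self.encoder_in, "parameters", lambda: [])())
        for block in self.enc_blocks + self.dec_blocks:
            for layer in block:
                params.extend(layer.parameters())
        params.extend(self.head.parameters())
        return params

    # -- forward/backward -------------------------------------------------

    def _pad(self, X: np.ndarray) -> np.ndarray:
        extra = self.padded_size - self.window_size
        if extra == 0:
            return X
        return np.pad(X, ((0, 0), (extra, 0)))

    def _forward(self, X: np.ndarray) -> np.ndarray:
        """Per-position logits (B, K, padded_size)."""
        self._check_indices(X)
        Xp = self._pad(X)
        h = self.encoder_in.forward(Xp)
        self._skips = []
        for i, block in enumerate(self.enc_blocks):
            for layer in block:
                h = layer.forward(h)
            if i < len(self.pools):
                self._skips.append(h)
                h = self.pools[i].forward(h)
        self._concat_channels = []
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(self._skips)):
            h = up.forward(h)
            self._concat_channels.append((h.shape[1], skip.shape[1]))
            h = np.concatenate([h, skip], axis=1)
            for layer in block:
                h = layer.forward(h)
        return self.head.forward(h)

    def _backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        dskips = []
        for up, block, (c_up, c_skip) in zip(
            reversed(self.ups), reversed(self.dec_blocks), reversed(self._concat_channels)
        ):
            for layer in reversed(block):
                dh = layer.backward(dh)
            dskips.append(dh[:, c_up:, :])
            dh = up.backward(dh[:, :c_up, :])
        dskips.reverse()  # dskips[i] pairs with enc block i (shallowest first)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.pools):
                dh = self.pools[i].backward(dh)
                dh = dh + dskips[len(self.pools) - 1 - i]
            for layer in reversed(self.enc_blocks[i]):
                dh = layer.backward(dh)
        self.encoder_in.backward(dh)

    def per_position_proba(self, X: np.ndarray) -> np.ndarray:
        """(B, K, W) class probabilities at each original window position."""
        logits = self._forward(X)
        return nn.softmax(logits[:, :, -self.window_size:], axis=1)

    def loss_and_grad(self, X: np.ndarray, y: np.ndarray) -> float:
        logits = self._forward(X)
        Xp = self._pad(X)
        mask = Xp > 0  # every non-padding position inherits the window label
        labels = np.broadcast_to(y[:, None], Xp.shape)
        loss, dlogits = nn.cross_entropy_per_position(logits, labels, mask)
        self._backward(dlogits)
        return loss

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = np.empty((len(X), self.n_classes), dtype=nn.DTYPE)
        for lo in range(0, len(X), batch_size):
            xb = X[lo:lo + batch_size]
            probs = self.per_position_proba(xb)
            mask = (xb > 0).astype(nn.DTYPE)[:, None, :]
            denom = np.maximum(mask.sum(axis=2), 1.0)
            out[lo:lo + len(xb)] = (probs * mask).sum(axis=2) / denom
        return out


class FCN1d(WindowClassifier):
    """Three-block fully convolutional baseline.

    Convolutions of 128 filters / kernel 8, 256 / kernel 5 and 128 /
    kernel 3 (stride 1, zero-padded to preserve length), global average
    pooling, and a softmax classifier. ``width_scale`` shrinks the filter
    counts proportionally for desk-scale runs.
    """

    LAYER_SPEC = [(128, 8), (256, 5), (128, 3)]

    def __init__(self, n_classes: int, window_size: int, n_indices: int,
                 *, embedding: bool = True, embed_dim: int = 64,
                 width_scale: float = 1.0, seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.n_classes = n_classes
        self.window_size = window_size
        self.n_indices = n_indices
        self.embedding = embedding
        rng = np.random.default_rng(seed)
        self.layer_spec = [(max(1, int(round(f * width_scale))), k) for f, k in self.LAYER_SPEC]

        if embedding:
            self.encoder_in = nn.Embedding(n_indices, embed_dim, rng)
            cin = embed_dim
        else:
            self.encoder_in = nn.OneHot(n_indices)
            cin = n_indices
        self.layers = []
        for f, k in self.layer_spec:
            self.layers += [nn.Conv1d(cin, f, k, rng), nn.ReLU()]
            cin = f
        self.gap = nn.GlobalAvgPool()
        self.out = nn.Dense(cin, n_classes, rng)

    def parameters(self):
        params = list(getattr(self.encoder_in, "parameters", lambda: [])())
        for layer in self.layers:
            params.extend(layer.parameters())
        params.extend(self.out.parameters())
        return params

    def _forward(self, X: np.ndarray) -> np.ndarray:
        self._check_indices(X)
        h = self.encoder_in.forward(X)
        for layer in self.layers:
            h = layer.forward(h)
        return self.out.forward(self.gap.forward(h))

    def _backward(self, dlogits: np.ndarray) -> None:
        dh = self.gap.backward(self.out.backward(dlogits))
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        self.encoder_in.backward(dh)

    def loss_and_grad(self, X: np.ndarray, y: np.ndarray) -> float:
        loss, dlogits = nn.cross_entropy(self._forward(X), y)
        self._backward(dlogits)
        return loss

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = np.empty((len(X), self.n_classes), dtype=nn.DTYPE)
        for lo in range(0, len(X), batch_size):
            out[lo:lo + batch_size] = nn.softmax(self._forward(X[lo:lo + batch_size]), axis=1)
        return out


class LSTMClassifier(WindowClassifier):
    """Embedding + LSTM(64) + softmax baseline.

    Padding positions are masked out of the recurrence, so the final
    hidden state is that of the last real event (and an all-padding window
    still yields a valid forward pass).
    """

    def __init__(self, n_classes: int, window_size: int, n_indices: int,
                 *, embedding: bool = True, embed_dim: int = 64,
                 units: int = 64, seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.n_classes = n_classes
        self.window_size = window_size
        self.n_indices = n_indices
        self.embedding = embedding
        self.units = units
        rng = np.random.default_rng(seed)
        if embedding:
            self.encoder_in = nn.Embedding(n_indices, embed_dim, rng)
            dim = embed_dim
        else:
            self.encoder_in = nn.OneHot(n_indices)
            dim = n_indices
        self.lstm = nn.LSTM(dim, units, rng)
        self.out = nn.Dense(units, n_classes, rng)

    def parameters(self):
        params = list(getattr(self.encoder_in, "parameters", lambda: [])())
        params.extend(self.lstm.parameters())
        params.extend(self.out.parameters())
        return params

    def _forward(self, X: np.ndarray) -> np.ndarray:
        self._check_indices(X)
        h = self.encoder_in.forward(X).transpose(0, 2, 1)  # (B, L, D)
        mask = (X > 0).astype(nn.DTYPE)
        return self.out.forward(self.lstm.forward(h, mask))

    def _backward(self, dlogits: np.ndarray) -> None:
        dh = self.lstm.backward(self.out.backward(dlogits))
        self.encoder_in.backward(dh.transpose(0, 2, 1))

    def loss_and_grad(self, X: np.ndarray, y: np.ndarray) -> float:
        loss, dlogits = nn.cross_entropy(self._forward(X), y)
        self._backward(dlogits)
        return loss

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = np.empty((len(X), self.n_classes), dtype=nn.DTYPE)
        for lo in range(0, len(X), batch_size):
            out[lo:lo + batch_size] = nn.softmax(self._forward(X[lo:lo + batch_size]), axis=1)
        return out


# ---------------------------------------------------------------------------
# builders and window-level prediction


def build_unet(cfg: UNetConfig, window_size: int, n_indices: int,
               *, embedding: bool = True, seed: int = 0) -> UNet1d:
    return UNet1d(cfg, window_size, n_indices, embedding=embedding, seed=seed)


def build_fcn(n_classes: int, window_size: int, n_indices: int, **kwargs) -> FCN1d:
    return FCN1d(n_classes, window_size, n_indices, **kwargs)


def build_lstm(n_classes: int, window_size: int, n_indices: int, **kwargs) -> LSTMClassifier:
    return LSTMClassifier(n_classes, window_size, n_indices, **kwargs)


def build_model(name: str, n_classes: int, window_size: int, n_indices: int,
                *, embedding: bool = True, depth_scale: float = 1.0,
                seed: int = 0) -> WindowClassifier:
    """Build a classifier by name ('unet' | 'fcn' | 'lstm')."""
    if name == "unet":
        cfg = UNetConfig(n_classes=n_classes, depth_scale=depth_scale)
        return build_unet(cfg, window_size, n_indices, embedding=embedding, seed=seed)
    if name == "fcn":
        return build_fcn(n_classes, window_size, n_indices, embedding=embedding,
                         width_scale=depth_scale, seed=seed)
    if name == "lstm":
        return build_lstm(n_classes, window_size, n_indices, embedding=embedding, seed=seed)
    raise ValueError(f"unknown model {name!r}")


@dataclass
class ModelOutput:
    """Prediction for a single window."""

    window_label: int
    probabilities: np.ndarray                 # (K,) window-level distribution
    per_position: Optional[np.ndarray] = None  # (K, W), U-Net only


def predict_window(model: WindowClassifier, indices: np.ndarray) -> ModelOutput:
    """Classify one index-encoded window.

    For the U-Net the window label is the class with the highest mean
    per-position probability over non-padding positions; for the FCN and
    LSTM it is the softmax argmax. Ties break to the lowest class index.
    """
    X = np.asarray(indices)[None, :]
    probs = model.predict_proba(X)[0]
    per_position = None
    if isinstance(model, UNet1d):
        per_position = model.per_position_proba(X)[0]
    return ModelOutput(int(probs.argmax()), probs, per_position)


def clone_model(model: WindowClassifier) -> WindowClassifier:
    return copy.deepcopy(model)
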