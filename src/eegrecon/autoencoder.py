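"""Stacked 1-D convolutional autoencoder, implemented directly on numpy.

The network follows the classic one-class reconstruction design: three
strided convolutional encoder layers (E1-E3, each conv + ReLU) compress a
length-L signal into a latent feature map, and three mirrored transposed
convolutions (D1-D3) reconstruct it; the output layer is a logistic sigmoid
because inputs are min-max normalized to [0, 1].  Training minimizes the
mean squared reconstruction error

    L(theta) = (1/N) sum_i || x_i - x_hat_i ||^2

with the Adam optimizer (learning rate 0.001 by default), using *only*
records of a single reference class — the interictal set in the intended
protocol — so that off-class signals reconstruct poorly.

Convolutions are evaluated as im2col patch extraction followed by a BLAS
matrix multiply, with the exact adjoint used for gradients; everything is
float32 and deterministic for a fixed seed and record order.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_io import EegDataset, EegRecord

_CHECKPOINT_TAG = "eegrecon-ae-v1"


@dataclass(frozen=True)
class AeConfig:
    """Architecture and optimization settings.

    ``channels`` gives the encoder channel widths for E1..E3; the decoder
    mirrors them in reverse.  All layers share ``kernel`` and ``stride``;
    padding is ``kernel // 2`` so each encoder layer halves the length
    exactly (stride 2) and each decoder layer doubles it.
    """

    length: int = 4096
    channels: tuple[int, ...] = (16, 32, 64)
    kernel: int = 7
    stride: int = 2
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd (symmetric padding)")
        stride_product = self.stride ** len(self.channels)
        if self.length % stride_product != 0:
            raise ValueError(
                f"working length {self.length} not divisible by the product of "
                f"encoder strides {stride_product}"
            )


# ---------------------------------------------------------------------------
# layer primitives


def _im2col(xp: np.ndarray, kernel: int, stride: int, n_out: int) -> np.ndarray:
    """(B, C, Lp) -> (B*n_out, C*kernel) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)[:, :, ::stride, :]
    # win: (B, C, n_out, K) -> (B, n_out, C, K)
    return win.transpose(0, 2, 1, 3).reshape(xp.shape[0] * n_out, -1)


class _Conv1d:
    """Strided 1-D convolution with 'same'-style padding (kernel odd)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        bound = 1.0 / np.sqrt(c_in * kernel)
        self.w = rng.uniform(-bound, bound, size=(c_out, c_in * kernel)).astype(np.float32)
        self.b = rng.uniform(-bound, bound, size=c_out).astype(np.float32)
        self._cache: tuple | None = None

    def out_length(self, n: int) -> int:
        return (n + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, _, n = x.shape
        n_out = self.out_length(n)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = _im2col(xp, self.kernel, self.stride, n_out)
        y = cols @ self.w.T + self.b
        if train:
            self._cache = (cols, b, n, n_out)
        return y.reshape(b, n_out, self.c_out).transpose(0, 2, 1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, b, n, n_out = self._cache
        gyr = gy.transpose(0, 2, 1).reshape(b * n_out, self.c_out)
        self.gw = gyr.T @ cols
        self.gb = gyr.sum(axis=0)
        gcols = (gyr @ self.w).reshape(b, n_out, self.c_in, self.kernel).transpose(0, 2, 1, 3)
        gxp = np.zeros((b, self.c_in, n + 2 * self.pad), dtype=np.float32)
        s = self.stride
        for k in range(self.kernel):
            gxp[:, :, k : k + s * n_out : s] += gcols[:, :, :, k]
        return gxp[:, :, self.pad : self.pad + n]

    @property
    def params(self):
        return [("w", self.w), ("b", self.b)]


class _ConvTranspose1d:
    """Transposed counterpart of :class:`_Conv1d`; doubles length for stride 2.

    Output length is ``n * stride`` (output padding ``stride - 1`` implied by
    the symmetric-padding convention).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        bound = 1.0 / np.sqrt(c_in * kernel)
        self.w = rng.uniform(-bound, bound, size=(c_in, c_out * kernel)).astype(np.float32)
        self.b = rng.uniform(-bound, bound, size=c_out).astype(np.float32)
        self._cache: tuple | None = None

    def out_length(self, n: int) -> int:
        return n * self.stride

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, _, n = x.shape
        n_out = self.out_length(n)
        full = (n - 1) * self.stride + self.kernel
        xr = x.transpose(0, 2, 1).reshape(b * n, self.c_in)
        contrib = (xr @ self.w).reshape(b, n, self.c_out, self.kernel).transpose(0, 2, 1, 3)
        y = np.zeros((b, self.c_out, full), dtype=np.float32)
        s = self.stride
        for k in range(self.kernel):
            y[:, :, k : k + s * n : s] += contrib[:, :, :, k]
        if train:
            self._cache = (xr, b, n, full)
        return y[:, :, self.pad : self.pad + n_out] + self.b[:, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xr, b, n, full = self._cache
        n_out = gy.shape[2]
        gfull = np.zeros((b, self.c_out, full), dtype=np.float32)
        gfull[:, :, self.pad : self.pad + n_out] = gy
        s = self.stride
        gcontrib = np.empty((b, self.c_out, n, self.kernel), dtype=np.float32)
        for k in range(self.kernel):
            gcontrib[:, :, :, k] = gfull[:, :, k : k + s * n : s]
        gcr = gcontrib.transpose(0, 2, 1, 3).reshape(b * n, self.c_out * self.kernel)
        self.gw = xr.T @ gcr
        self.gb = gy.sum(axis=(0, 2))
        gx = (gcr @ self.w.T).reshape(b, n, self.c_in).transpose(0, 2, 1)
        return gx

    @property
    def params(self):
        return [("w", self.w), ("b", self.b)]


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class _Sigmoid:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._y * (1.0 - self._y)


# ---------------------------------------------------------------------------
# model


class ConvAutoencoder:
    """The stacked conv encoder/decoder with its training state.

    Built untrained by :func:`build_autoencoder`; :func:`train_autoencoder`
    fills ``loss_history`` (per-epoch mean training MSE) in place and
    returns the model.
    """

    def __init__(self, config: AeConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, s = config.kernel, config.stride
        chans = (1, *config.channels)
        self.layers: list = []
        for c_in, c_out in zip(chans[:-1], chans[1:]):
            self.layers += [_Conv1d(c_in, c_out, k, s, rng), _ReLU()]
        rev = tuple(reversed(chans))
        for i, (c_in, c_out) in enumerate(zip(rev[:-1], rev[1:])):
            self.layers.append(_ConvTranspose1d(c_in, c_out, k, s, rng))
            self.layers.append(_Sigmoid() if i == len(chans) - 2 else _ReLU())
        self.loss_history: list[float] = []

    # -- inference ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a (B, L) batch to its (B, L) reconstruction."""
        h = np.ascontiguousarray(x, dtype=np.float32)[:, None, :]
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return h[:, 0, :]

    def reconstruct(self, record: EegRecord | np.ndarray) -> np.ndarray:
        """Reconstruction x_hat of one signal, as float64, same length."""
        x = record.samples if isinstance(record, EegRecord) else np.asarray(record)
        if x.ndim != 1 or x.size != self.config.length:
            raise ValueError(
                f"record length {x.size} does not match model working length "
                f"{self.config.length}"
            )
        return self.forward(x[None, :]).astype(np.float64)[0]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a single-archive checkpoint (config JSON + weight arrays)."""
        arrays = {"__tag__": np.array(_CHECKPOINT_TAG)}
        arrays["__config__"] = np.array(json.dumps(self.config.__dict__))
        arrays["__loss_history__"] = np.asarray(self.loss_history, dtype=np.float64)
        for i, layer in enumerate(self.layers):
            for name, value in layer.params:
                arrays[f"layer{i}.{name}"] = value
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ConvAutoencoder":
        with np.load(path) as data:
            if str(data["__tag__"]) != _CHECKPOINT_TAG:
                raise ValueError(f"{path}: not a {_CHECKPOINT_TAG} checkpoint")
            cfg_dict = json.loads(str(data["__config__"]))
            cfg_dict["channels"] = tuple(cfg_dict["channels"])
            model = cls(AeConfig(**cfg_dict))
            model.loss_history = list(data["__loss_history__"])
            for i, layer in enumerate(model.layers):
                for name, _ in layer.params:
                    setattr(layer, name, data[f"layer{i}.{name}"])
        return model

    # -- training ----------------------------------------------------------

    def _parameters(self):
        for layer in self.layers:
            for name, _ in layer.params:
                yield layer, name

    def train_epochs(self, x: np.ndarray, rng: np.random.Generator) -> None:
        """Run ``config.epochs`` of Adam over the (n, L) training matrix."""
        cfg = self.config
        lr, b1, b2, eps = cfg.learning_rate, 0.9, 0.999, 1e-8
        slots = list(self._parameters())
        m = [np.zeros_like(getattr(layer, nm)) for layer, nm in slots]
        v = [np.zeros_like(getattr(layer, nm)) for layer, nm in slots]
        step = 0
        n = x.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                batch = x[order[start : start + cfg.batch_size]]
                xhat = self.forward(batch, train=True)
                resid = (xhat - batch.astype(np.float32)).astype(np.float32)
                loss = float(np.mean(resid**2))
                total += loss * batch.shape[0]
                gy = (2.0 / resid.size) * resid
                g = gy[:, None, :]
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                step += 1
                bc1 = 1.0 - b1**step
                bc2 = 1.0 - b2**step
                for j, (layer, nm) in enumerate(slots):
                    grad = getattr(layer, "g" + nm)
                    m[j] = b1 * m[j] + (1 - b1) * grad
                    v[j] = b2 * v[j] + (1 - b2) * grad**2
                    p = getattr(layer, nm)
                    p -= (lr * (m[j] / bc1) / (np.sqrt(v[j] / bc2) + eps)).astype(np.float32)
            self.loss_history.append(total / n)


#: Public alias: a model whose ``loss_history`` has been populated.
TrainedAutoencoder = ConvAutoencoder


def build_autoencoder(config: AeConfig | None = None) -> ConvAutoencoder:
    """Create an untrained model with seeded fan-in-scaled uniform weights."""
    return ConvAutoencoder(config or AeConfig())


def train_autoencoder(
    model: ConvAutoencoder, data: EegDataset, config: AeConfig | None = None
) -> ConvAutoencoder:
    """Fit the autoencoder on a single-class dataset (one-class protocol).

    ``data`` must contain at least two records, all sharing one label
    (interictal in the intended use).  Returns the trained model with
    ``loss_history`` holding the per-epoch mean training MSE.
    """
    cfg = config or model.config
    labels = set(r.label for r in data)
    if len(data) == 0:
        raise ValueError("training dataset is empty")
    if len(labels) > 1:
        raise ValueError(
            f"one-class training requires a single label, got {sorted(labels)}"
        )
    if len(data) < 2:
        raise ValueError("need at least 2 records to train")
    x = data.matrix().astype(np.float32)
    if x.shape[1] != cfg.length:
        raise ValueError(
            f"record length {x.shape[1]} does not match configured length {cfg.length}"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    model.config = cfg
    model.train_epochs(x, rng)
    return model
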