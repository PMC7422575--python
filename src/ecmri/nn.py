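"""A compact CPU convolutional-network engine.

The networks this package trains are small (a handful of 3x3 conv
layers on 64-256 pixel images), so the engine is deliberately minimal:
im2col convolutions backed by BLAS matrix products, ReLU activations,
an optional global skip projection, Xavier (Glorot) initialization and
Adam with an L2 weight-decay term folded into the gradient.  Arrays are
laid out channel-last ``(N, H, W, C)`` in float32; all randomness flows
through an explicit ``numpy.random.Generator``, so training runs are
bit-reproducible on a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Conv2d", "ConvNet", "Adam", "TrainConfig", "mse_loss", "xavier_uniform",
           "complex_to_channels", "channels_to_complex"]


def complex_to_channels(arr: np.ndarray, dtype=np.float32) -> np.ndarray:
    """Stack real and imaginary parts as a trailing channel axis."""
    arr = np.asarray(arr)
    return np.stack([arr.real, arr.imag], axis=-1).astype(dtype)


def channels_to_complex(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`complex_to_channels` for a trailing 2-channel axis."""
    if x.shape[-1] != 2:
        raise ValueError(f"expected trailing channel axis of size 2, got {x.shape}")
    return x[..., 0].astype(np.float64) + 1j * x[..., 1].astype(np.float64)


def xavier_uniform(
    rng: np.random.Generator, c_in: int, c_out: int, ksize: int, dtype=np.float32
) -> np.ndarray:
    """Glorot-uniform filter bank of shape ``(c_in * k * k, c_out)``."""
    fan_in = c_in * ksize * ksize
    fan_out = c_out * ksize * ksize
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, c_out)).astype(dtype)


def _im2col(x: np.ndarray, ksize: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, C*k*k) patches with zero 'same' padding."""
    if ksize == 1:
        n, h, w, c = x.shape
        return x.reshape(n * h * w, c)
    p = (ksize - 1) // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (ksize, ksize), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> contiguous (N*H*W, C*k*k)
    n, h, w, c = x.shape
    return np.ascontiguousarray(win).reshape(n * h * w, c * ksize * ksize)


def _col2im(dcol: np.ndarray, shape: tuple, ksize: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of overlapping patches)."""
    n, h, w, c = shape
    if ksize == 1:
        return dcol.reshape(n, h, w, c)
    p = (ksize - 1) // 2
    dcol = dcol.reshape(n, h, w, c, ksize, ksize)
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dcol.dtype)
    for i in range(ksize):
        for j in range(ksize):
            dxp[:, i:i + h, j:j + w, :] += dcol[:, :, :, :, i, j]
    return dxp[:, p:p + h, p:p + w, :]


class Conv2d:
    """'Same'-padded 2-D convolution with stride 1."""

    def __init__(self, c_in: int, c_out: int, ksize: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        self.W = xavier_uniform(rng, c_in, c_out, ksize, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        col = _im2col(x, self.ksize)
        out = col @ self.W + self.b
        if keep_cache:
            self._cache = (col, x.shape)
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        col, xshape = self._cache  # type: ignore[misc]
        dflat = dout.reshape(-1, self.c_out)
        dW = col.T @ dflat
        db = dflat.sum(axis=0)
        dx = _col2im(dflat @ self.W.T, xshape, self.ksize)
        return dx, [dW, db]


class ConvNet:
    """Plain conv stack: ReLU after every layer except the last (identity
    output, so the network can emit negative residual values), with an
    optional global skip — a learned 1x1 projection of the input added
    to the final layer's output."""

    def __init__(self, in_channels: int, out_channels: int, n_layers: int,
                 features: int, ksize: int = 3, skip: bool = True,
                 seed: int = 0, dtype=np.float32, zero_init_output: bool = True) -> None:
        if n_layers < 2:
            raise ValueError("need at least 2 conv layers")
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.in_channels, self.out_channels = in_channels, out_channels
        chans = [in_channels] + [features] * (n_layers - 1) + [out_channels]
        self.layers = [Conv2d(chans[i], chans[i + 1], ksize, rng, dtype)
                       for i in range(n_layers)]
        self.skip = Conv2d(in_channels, out_channels, 1, rng, dtype) if skip else None
        if zero_init_output:
            # residual-learning init: hidden layers keep Xavier weights but
            # the output path starts at zero, so the untrained network is
            # the neutral (zero) correction and training descends from the
            # zero-predictor baseline instead of from a random O(1) output
            self.layers[-1].W[...] = 0.0
            if self.skip is not None:
                self.skip.W[...] = 0.0
        self._relu_masks: list[np.ndarray] = []
        self._skip_cache: np.ndarray | None = None

    @property
    def params(self) -> list[np.ndarray]:
        out = [p for layer in self.layers for p in layer.params]
        if self.skip is not None:
            out += self.skip.params
        return out

    def set_params(self, values: list[np.ndarray]) -> None:
        own = self.params
        if len(values) != len(own):
            raise ValueError(f"expected {len(own)} parameter arrays, got {len(values)}")
        for dst, src in zip(own, values):
            if dst.shape != src.shape:
                raise ValueError(f"parameter shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src.astype(dst.dtype)

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        x = x.astype(self.dtype, copy=False)
        self._relu_masks = []
        h = x
        for layer in self.layers[:-1]:
            h = layer.forward(h, keep_cache)
            mask = h > 0
            h = h * mask
            if keep_cache:
                self._relu_masks.append(mask)
        out = self.layers[-1].forward(h, keep_cache)
        if self.skip is not None:
            out = out + self.skip.forward(x, keep_cache)
        return out

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Returns (gradient w.r.t. the input, flat parameter gradients)."""
        grads: list[list[np.ndarray]] = [[] for _ in self.layers]
        skip_grads: list[np.ndarray] = []
        dskip = 0.0
        if self.skip is not None:
            dskip, skip_grads = self.skip.backward(dout)
        d, grads[-1] = self.layers[-1].backward(dout)
        for i in range(len(self.layers) - 2, -1, -1):
            d = d * self._relu_masks[i]
            d, grads[i] = self.layers[i].backward(d)
        flat = [g for gl in grads for g in gl]
        return d + dskip, flat + skip_grads

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, keep_cache=False)


@dataclass
class TrainConfig:
    """Optimization hyperparameters shared by the cascade guide and the
    error-correction network.

    Defaults follow common practice for small image-restoration nets:
    Adam at learning rate 1e-4 with momenta (0.9, 0.99), weight decay
    5e-4, batches of 4, Xavier initialization.  ``iterations`` is the
    number of gradient steps; reference-scale runs use 40000 (error
    correction) and 20000 (cascade guide), desk-scale runs far fewer.
    """

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.99
    weight_decay: float = 5e-4
    batch_size: int = 4
    iterations: int = 2000
    seed: int = 0
    log_every: int = 50

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.iterations < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, iterations and batch_size must be positive")


class Adam:
    """Adam with an L2 penalty added to the raw gradient (classic
    'weight decay' regularization; biases are decayed too — the nets
    are small enough that this makes no practical difference)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.99,
                 weight_decay: float = 5e-4, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.weight_decay, self.eps = weight_decay, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g + self.weight_decay * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """0.5 * mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target.astype(pred.dtype, copy=False)
    loss = 0.5 * float(np.mean(diff.astype(np.float64) ** 2))
    return loss, diff / diff.size


def training_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Training objective 0.5 * ||pred - target||^2 summed over pixels and
    channels, averaged over the batch; returns (per-element MSE for
    logging, gradient).  The sum form keeps loss gradients on the same
    scale as the weight-decay term, so the L2 penalty acts as the mild
    regularizer it is meant to be instead of dominating the update."""
    diff = pred - target.astype(pred.dtype, copy=False)
    mse = float(np.mean(diff.astype(np.float64) ** 2))
    return mse, diff / pred.shape[0]
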