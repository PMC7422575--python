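"""Guide ("template") reconstruction algorithms.

The error-correction framework treats the guide as a black box
``x_guide = invMRI(y)``: any CS-MRI solver that maps undersampled
k-space to an image can serve.  Built in are

* :class:`ZeroFilledGuide` — the adjoint reconstruction (fast, aliased),
* :class:`IterativeSparseGuide` — proximal-gradient (ISTA) minimization
  of the classic sparsity-regularized objective
  ``||F_u x - y||^2 + lam * ||Psi x||_1``,
* :class:`CascadeCNNGuide` — a small deep-cascade CNN with interleaved
  data-fidelity layers, trained on fully-sampled images,
* :class:`StaticGuide` — precomputed guide images produced by external
  software (published solvers plug in through files).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pywt

from .fidelity import FidelityConfig, fidelity_correct
from .fourier import (ComplexImage, KSpaceMeasurements, SamplingMask,
                      forward_fft, inverse_fft, undersample, zero_fill)
from .nn import (Adam, ConvNet, TrainConfig, channels_to_complex,
                 complex_to_channels, training_loss)

__all__ = [
    "GuideAlgorithm", "ZeroFilledGuide", "SparseSolverConfig",
    "IterativeSparseGuide", "CascadeGuideConfig", "CascadeCNNGuide",
    "StaticGuide", "train_cascade_guide",
]


class GuideAlgorithm(Protocol):
    """Anything with a ``name`` and ``reconstruct(y) -> ComplexImage``."""

    name: str

    def reconstruct(self, y: KSpaceMeasurements) -> ComplexImage: ...


class ZeroFilledGuide:
    """The zero-filled adjoint, wrapped as a guide algorithm."""

    name = "zero_filled"

    def reconstruct(self, y: KSpaceMeasurements) -> ComplexImage:
        return zero_fill(y)


class StaticGuide:
    """Guide images computed offline (e.g. by a published solver).

    ``images[i]`` must correspond to the i-th measurement passed to
    :meth:`reconstruct`; calls are matched by sequence order.
    """

    def __init__(self, images: Sequence[ComplexImage], name: str = "external") -> None:
        self.name = name
        self._images = list(images)
        self._cursor = 0

    def reset(self) -> None:
        self._cursor = 0

    def reconstruct(self, y: KSpaceMeasurements) -> ComplexImage:
        if self._cursor >= len(self._images):
            raise IndexError("StaticGuide exhausted: more measurements than images")
        img = self._images[self._cursor]
        self._cursor += 1
        if img.shape != y.shape:
            raise ValueError(f"guide image shape {img.shape} != k-space {y.shape}")
        return img


# ---------------------------------------------------------------------------
# iterative sparse solver
# ---------------------------------------------------------------------------

@dataclass
class SparseSolverConfig:
    """Proximal-gradient solver settings.

    transform
        'wavelet' (orthonormal DWT, exact soft-threshold prox) or 'tv'
        (isotropic total variation, Chambolle prox).
    reg_weight
        the l1 regularization weight; larger = smoother/sparser.
    step_size
        'auto' uses 1/L = 0.5, exact for the unit-norm sampling operator.
    accelerate
        Nesterov (FISTA) momentum; off by default because plain ISTA
        guarantees a monotone objective.
    """

    transform: str = "wavelet"
    wavelet: str = "db4"
    levels: int = 3
    reg_weight: float = 1e-3
    max_iters: int = 200
    tol: float = 1e-6
    step_size: float | str = "auto"
    accelerate: bool = False

    def __post_init__(self) -> None:
        if self.max_iters < 1 or self.tol <= 0 or self.reg_weight <= 0:
            raise ValueError("max_iters >= 1, tol > 0 and reg_weight > 0 required")
        if self.transform not in ("wavelet", "tv"):
            raise ValueError(f"unknown transform {self.transform!r}")


class _WaveletTransform:
    """Orthonormal 2-D DWT on complex images (periodization mode, so the
    analysis operator is square and unitary for orthogonal wavelets)."""

    def __init__(self, wavelet: str, levels: int) -> None:
        self.wavelet, self.levels = wavelet, levels
        self._slices = None

    def analyze(self, x: np.ndarray) -> np.ndarray:
        coeffs = pywt.wavedec2(x, self.wavelet, level=self.levels, mode="periodization")
        arr, self._slices = pywt.coeffs_to_array(coeffs)
        return arr

    def synthesize(self, arr: np.ndarray) -> np.ndarray:
        coeffs = pywt.array_to_coeffs(arr, self._slices, output_format="wavedec2")
        return pywt.waverec2(coeffs, self.wavelet, mode="periodization")


def _soft_threshold(c: np.ndarray, t: float) -> np.ndarray:
    """Complex soft-thresholding: shrink the magnitude, keep the phase."""
    mag = np.abs(c)
    scale = np.maximum(1.0 - t / np.maximum(mag, 1e-30), 0.0)
    return c * scale


def _tv_seminorm(x: np.ndarray) -> float:
    gx = np.diff(x, axis=1, append=x[:, -1:])
    gy = np.diff(x, axis=0, append=x[-1:, :])
    return float(np.sum(np.sqrt(np.abs(gx) ** 2 + np.abs(gy) ** 2)))


class IterativeSparseGuide:
    """ISTA for ``||F_u x - y||^2 + lam ||Psi x||_1``.

    The data-term gradient is ``2 F_u^H (F_u x - y)`` with Lipschitz
    constant 2 (the sampling operator has unit spectral norm under the
    unitary FFT), so the auto step size is 0.5.  Each iteration takes a
    gradient step and applies the transform-domain proximal operator;
    the composite objective is non-increasing.  Stops on relative
    change < tol or at max_iters.
    """

    def __init__(self, cfg: SparseSolverConfig | None = None, name: str | None = None) -> None:
        self.cfg = cfg or SparseSolverConfig()
        self.name = name or f"sparse_{self.cfg.transform}"
        self.last_objectives: list[float] = []

    def _objective(self, x: np.ndarray, y: KSpaceMeasurements,
                   psi: _WaveletTransform | None) -> float:
        data = float(np.linalg.norm(y.mask.data * forward_fft(x) - y.data) ** 2)
        lam = self.cfg.reg_weight
        if self.cfg.transform == "wavelet":
            reg = lam * float(np.sum(np.abs(psi.analyze(x))))  # type: ignore[union-attr]
        else:
            reg = lam * _tv_seminorm(x)
        return data + reg

    def _prox(self, x: np.ndarray, t: float, psi: _WaveletTransform | None) -> np.ndarray:
        lam = self.cfg.reg_weight
        if self.cfg.transform == "wavelet":
            return psi.synthesize(_soft_threshold(psi.analyze(x), t * lam))  # type: ignore[union-attr]
        from skimage.restoration import denoise_tv_chambolle
        w = t * lam
        return (denoise_tv_chambolle(x.real, weight=w)
                + 1j * denoise_tv_chambolle(x.imag, weight=w))

    def reconstruct(self, y: KSpaceMeasurements) -> ComplexImage:
        cfg = self.cfg
        step = 0.5 if cfg.step_size == "auto" else float(cfg.step_size)
        psi = (_WaveletTransform(cfg.wavelet, cfg.levels)
               if cfg.transform == "wavelet" else None)
        mask = y.mask.data

        x = inverse_fft(y.data)  # zero-filled warm start
        z = x
        t_mom = 1.0
        self.last_objectives = [self._objective(x, y, psi)]
        for _ in range(cfg.max_iters):
            grad = 2.0 * inverse_fft(mask * forward_fft(z) - y.data)
            x_new = self._prox(z - step * grad, step, psi)
            obj = self._objective(x_new, y, psi)
            if (not cfg.accelerate and obj > self.last_objectives[-1] * (1 + 1e-9)
                    and cfg.step_size != "auto"):
                raise ValueError(
                    "objective increased: step size too large; use step_size='auto'")
            if cfg.accelerate:
                t_next = (1 + np.sqrt(1 + 4 * t_mom**2)) / 2
                z = x_new + (t_mom - 1) / t_next * (x_new - x)
                t_mom = t_next
            else:
                z = x_new
            self.last_objectives.append(obj)
            rel = np.linalg.norm(x_new - x) / max(np.linalg.norm(x), 1e-30)
            x = x_new
            if rel < cfg.tol:
                break
        return ComplexImage(x)


# ---------------------------------------------------------------------------
# cascade CNN guide
# ---------------------------------------------------------------------------

@dataclass
class CascadeGuideConfig:
    """Deep-cascade architecture: ``n_blocks`` blocks, each a stack of
    ``convs_per_block`` 3x3 convs (ReLU, last conv linear with 2 output
    channels) with an identity shortcut, followed by a data-fidelity
    layer.  Reference scale: 4 blocks x 4 convs x 64 feature maps.
    """

    n_blocks: int = 4
    convs_per_block: int = 4
    feature_maps: int = 64
    ksize: int = 3
    consistency_mode: str = "hard"  # 'hard' or 'soft'
    alpha: float = 5e-5  # used only in soft mode

    def __post_init__(self) -> None:
        if min(self.n_blocks, self.convs_per_block, self.feature_maps) < 1:
            raise ValueError("architecture sizes must be positive")
        if self.ksize % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.consistency_mode not in ("hard", "soft"):
            raise ValueError(f"unknown consistency mode {self.consistency_mode!r}")

    @property
    def df_alpha(self) -> float:
        return 0.0 if self.consistency_mode == "hard" else self.alpha


def _df_weights(mask: np.ndarray, alpha: float) -> np.ndarray:
    """k-space weights of the data-fidelity operator's homogeneous part."""
    return np.where(mask > 0, alpha / (1.0 + alpha), 1.0)


class CascadeCNNGuide:
    """Cascade of conv blocks and data-fidelity layers on two-channel
    (real/imaginary) images.  With all-zero conv weights and hard
    consistency the cascade is the identity on the zero-filled input."""

    def __init__(self, cfg: CascadeGuideConfig | None = None, seed: int = 0,
                 name: str = "cascade_cnn") -> None:
        self.cfg = cfg or CascadeGuideConfig()
        self.name = name
        rng = np.random.default_rng(seed)
        self.blocks = [
            ConvNet(2, 2, self.cfg.convs_per_block, self.cfg.feature_maps,
                    ksize=self.cfg.ksize, skip=False,
                    seed=int(rng.integers(0, 2**31 - 1)))
            for _ in range(self.cfg.n_blocks)
        ]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for b in self.blocks for p in b.params]

    def set_params(self, values: list[np.ndarray]) -> None:
        i = 0
        for b in self.blocks:
            k = len(b.params)
            b.set_params(values[i:i + k])
            i += k
        if i != len(values):
            raise ValueError("parameter count mismatch for cascade")

    def zero_params(self) -> None:
        for p in self.params:
            p[...] = 0.0

    def _forward_batch(self, ys: list[KSpaceMeasurements],
                       keep_cache: bool = False) -> np.ndarray:
        """Run the cascade on a batch; returns (N, H, W, 2) channels."""
        alpha = self.cfg.df_alpha
        x = np.stack([complex_to_channels(inverse_fft(y.data)) for y in ys])
        for block in self.blocks:
            h = block.forward(x, keep_cache=keep_cache) + x
            hc = channels_to_complex(h)
            out = [
                fidelity_correct(ComplexImage(hc[i]), ys[i], alpha).data
                for i in range(len(ys))
            ]
            x = complex_to_channels(np.stack(out))
        return x

    def reconstruct(self, y: KSpaceMeasurements) -> ComplexImage:
        out = self._forward_batch([y], keep_cache=False)[0]
        return ComplexImage(channels_to_complex(out))


def _df_backward(d: np.ndarray, ys: list[KSpaceMeasurements], alpha: float) -> np.ndarray:
    """Jacobian-transpose of the data-fidelity layer on channel tensors.

    The layer is x -> F^H (w . F x) + const with real diagonal w, a
    Hermitian complex-linear map, so its real-channel transpose is the
    same masked filtering without the measurement offset.
    """
    dc = channels_to_complex(d)
    out = np.empty_like(dc)
    for i, y in enumerate(ys):
        w = _df_weights(y.mask.data, alpha)
        out[i] = inverse_fft(w * forward_fft(dc[i]))
    return complex_to_channels(out).astype(d.dtype)


def train_cascade_guide(
    dataset,
    mask: SamplingMask,
    cfg: CascadeGuideConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple[CascadeCNNGuide, list[float]]:
    """Train a cascade guide to map undersampled measurements to the
    fully-sampled image (MSE loss on two-channel targets).

    The sampling mask is fixed for the whole run — a trained cascade is
    specific to one mask family, like the error-correction net.
    Returns the trained guide and the per-iteration loss history.
    """
    cfg = cfg or CascadeGuideConfig()
    train_cfg = train_cfg or TrainConfig()
    if not dataset.train:
        raise ValueError("dataset has an empty training split")

    guide = CascadeCNNGuide(cfg, seed=train_cfg.seed)
    opt = Adam(guide.params, lr=train_cfg.learning_rate, beta1=train_cfg.beta1,
               beta2=train_cfg.beta2, weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)
    alpha = cfg.df_alpha

    ys = [undersample(img, mask) for img in dataset.train]
    targets = [complex_to_channels(img.data) for img in dataset.train]

    history: list[float] = []
    for _ in range(train_cfg.iterations):
        idx = rng.integers(0, len(ys), size=min(train_cfg.batch_size, len(ys)))
        batch_y = [ys[i] for i in idx]
        target = np.stack([targets[i] for i in idx])

        # forward, keeping caches block by block
        x_in: list[np.ndarray] = []
        x = np.stack([complex_to_channels(inverse_fft(y.data)) for y in batch_y])
        for block in guide.blocks:
            x_in.append(x)
            h = block.forward(x, keep_cache=True) + x
            hc = channels_to_complex(h)
            out = [fidelity_correct(ComplexImage(hc[i]), batch_y[i], alpha).data
                   for i in range(len(batch_y))]
            x = complex_to_channels(np.stack(out))

        loss, dout = training_loss(x, target)
        history.append(loss)
        if not np.isfinite(loss):
            raise FloatingPointError(f"cascade training diverged (loss={loss})")

        grads_per_block: list[list[np.ndarray]] = []
        d = dout
        for block in reversed(guide.blocks):
            d = _df_backward(d, batch_y, alpha)
            dx, g = block.backward(d)
            grads_per_block.append(g)
            d = d + dx  # identity shortcut
        flat = [g for gl in reversed(grads_per_block) for g in gl]
        opt.step(flat)

    return guide, history
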