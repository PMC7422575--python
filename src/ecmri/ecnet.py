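"""The error-correction network.

A guide reconstruction is imperfect in a *structured* way: sparse
solvers smooth away low-contrast detail that even the aliased
zero-filled image retains.  The error-correction net f_theta therefore
sees the concatenation of the zero-filled image Z(y) and the guide
image x_guide (four real channels: real/imaginary of each) and is
trained to predict the residual

    target = x_true - x_guide

by minimizing 0.5 * || target - f_theta(Z(y), x_guide) ||^2 over the
training split.  At test time the corrected image
x_guide + f_theta(...) is handed to the data-fidelity module.

Reference-scale architecture: 18 conv layers, 64 feature maps, 3x3
kernels, stride 1, ReLU except the (identity) last layer, plus a global
skip; desk-scale defaults (6 layers, 16 maps) train in minutes on a CPU.
A trained net is paired with the guide algorithm and mask family it was
trained against; that provenance travels with the checkpoint.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fourier import ComplexImage, KSpaceMeasurements, SamplingMask, undersample, zero_fill
from .guides import GuideAlgorithm
from .nn import (Adam, ConvNet, TrainConfig, channels_to_complex,
                 complex_to_channels, training_loss)

__all__ = ["ECNetConfig", "ECNetwork", "TrainConfig", "ec_input",
           "predict_residual", "train_ec"]


@dataclass
class ECNetConfig:
    """Architecture of the error-correction network."""

    n_layers: int = 18
    feature_maps: int = 64
    ksize: int = 3
    skip: bool = True
    in_channels: int = 4   # Re/Im of zero-filled + Re/Im of guide
    out_channels: int = 2  # Re/Im of the predicted residual

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.ksize % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.in_channels not in (2, 4) or self.out_channels != 2:
            raise ValueError("in_channels must be 2 or 4; out_channels must be 2")


def desk_config() -> ECNetConfig:
    """Small architecture for CPU-scale experiments and tests."""
    return ECNetConfig(n_layers=6, feature_maps=16)


def reference_train_config(seed: int = 0) -> TrainConfig:
    """Reference-scale training budget (40000 iterations)."""
    return TrainConfig(iterations=40000, seed=seed)


@dataclass
class ECNetwork:
    """A (possibly trained) error-correction net plus its provenance:
    the guide algorithm name and mask pattern it was trained against.
    Applying it with a different guide gives meaningless corrections,
    so mismatches raise a warning."""

    config: ECNetConfig
    net: ConvNet
    guide_name: str = "untrained"
    mask_pattern: str = "unknown"
    target_mode: str = "residual"  # 'residual' or 'full'
    seed: int = 0
    loss_history: list = field(default_factory=list)
    val_history: list = field(default_factory=list)

    @classmethod
    def fresh(cls, config: ECNetConfig | None = None, seed: int = 0, **prov) -> "ECNetwork":
        config = config or desk_config()
        net = ConvNet(config.in_channels, config.out_channels, config.n_layers,
                      config.feature_maps, ksize=config.ksize, skip=config.skip,
                      seed=seed)
        return cls(config=config, net=net, seed=seed, **prov)

    @classmethod
    def zero(cls, config: ECNetConfig | None = None, **prov) -> "ECNetwork":
        """A network whose output is identically zero (useful as the
        neutral element: the pipeline then reduces to data-fidelity-
        corrected guide)."""
        ecn = cls.fresh(config, seed=0, **prov)
        for p in ecn.net.params:
            p[...] = 0.0
        ecn.guide_name = prov.get("guide_name", "any")
        return ecn

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint: ``<path>.npz`` (weights) + ``<path>.json`` (config,
        provenance, seed) + ``<path>.csv`` (loss log)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"param_{i}": p for i, p in enumerate(self.net.params)})
        meta = {"format_version": 1,
                "config": self.config.__dict__,
                "guide_name": self.guide_name,
                "mask_pattern": self.mask_pattern,
                "target_mode": self.target_mode,
                "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        with path.with_suffix(".csv").open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "train_loss"])
            writer.writerows(enumerate(self.loss_history))

    @classmethod
    def load(cls, path: str | Path) -> "ECNetwork":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        config = ECNetConfig(**meta["config"])
        ecn = cls.fresh(config, seed=meta["seed"], guide_name=meta["guide_name"],
                        mask_pattern=meta["mask_pattern"],
                        target_mode=meta.get("target_mode", "residual"))
        with np.load(path.with_suffix(".npz")) as npz:
            ecn.net.set_params([npz[f"param_{i}"] for i in range(len(npz.files))])
        return ecn


def ec_input(zf: ComplexImage, guide: ComplexImage | None) -> np.ndarray:
    """Network input tensor of shape (H, W, C), channel-last.

    Channel order is fixed: [Re(zf), Im(zf), Re(guide), Im(guide)].
    With ``guide=None`` (no-concatenation ablation) only the first two
    channels are produced from ``zf``.
    """
    z = complex_to_channels(zf.data)
    if guide is None:
        return z
    if guide.shape != zf.shape:
        raise ValueError(f"shape mismatch: zf {zf.shape} vs guide {guide.shape}")
    return np.concatenate([z, complex_to_channels(guide.data)], axis=-1)


def _net_input(ecn: ECNetwork, zf: ComplexImage, guide: ComplexImage) -> np.ndarray:
    if ecn.config.in_channels == 4:
        return ec_input(zf, guide)
    return ec_input(guide, None)  # guide-only ablation input


def predict_residual(ecn: ECNetwork, zf: ComplexImage, guide: ComplexImage,
                     guide_name: str | None = None) -> ComplexImage:
    """Feed-forward prediction, reassembled as a complex image."""
    if guide_name is not None and ecn.guide_name not in ("any", guide_name):
        warnings.warn(
            f"EC network was trained with guide {ecn.guide_name!r} "
            f"but is being applied to {guide_name!r}", stacklevel=2)
    x = _net_input(ecn, zf, guide)[None]
    out = ecn.net(x)[0]
    return ComplexImage(channels_to_complex(out))


def train_ec(
    dataset,
    guide_alg: GuideAlgorithm,
    mask: SamplingMask,
    net_cfg: ECNetConfig | None = None,
    train_cfg: TrainConfig | None = None,
    target_mode: str = "residual",
    guides: list[ComplexImage] | None = None,
) -> ECNetwork:
    """Train the error-correction net on a dataset's training split.

    For every training image the measurements, zero-filled image and
    guide reconstruction are precomputed once; minibatches then only
    run the network.  ``target_mode='residual'`` trains on
    ``x_true - x_guide`` (the framework's formulation);
    ``'full'`` trains on ``x_true`` directly (ablation baselines).
    Precomputed ``guides`` (one per training image, in order) skip the
    guide solver, e.g. for externally generated guide images.
    """
    if target_mode not in ("residual", "full"):
        raise ValueError(f"unknown target_mode {target_mode!r}")
    net_cfg = net_cfg or desk_config()
    train_cfg = train_cfg or TrainConfig()
    if not dataset.train:
        raise ValueError("dataset has an empty training split")

    ecn = ECNetwork.fresh(net_cfg, seed=train_cfg.seed,
                          guide_name=guide_alg.name, mask_pattern=mask.pattern,
                          target_mode=target_mode)
    opt = Adam(ecn.net.params, lr=train_cfg.learning_rate, beta1=train_cfg.beta1,
               beta2=train_cfg.beta2, weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)

    def prepare(images, precomputed=None):
        xs, ts = [], []
        for i, img in enumerate(images):
            y = undersample(img, mask)
            zf = zero_fill(y)
            g = precomputed[i] if precomputed is not None else guide_alg.reconstruct(y)
            xs.append(_net_input(ecn, zf, g))
            target = img.data - g.data if target_mode == "residual" else img.data
            ts.append(complex_to_channels(target))
        return np.stack(xs), np.stack(ts)

    X, T = prepare(dataset.train, guides)
    Xv = Tv = None
    if dataset.val:
        Xv, Tv = prepare(dataset.val)

    n = len(dataset.train)
    for it in range(train_cfg.iterations):
        idx = rng.integers(0, n, size=min(train_cfg.batch_size, n))
        pred = ecn.net.forward(X[idx], keep_cache=True)
        loss, dout = training_loss(pred, T[idx])
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"EC training diverged at iteration {it} (loss={loss}); "
                f"lr={train_cfg.learning_rate}, batch={train_cfg.batch_size}")
        ecn.loss_history.append(loss)
        _, grads = ecn.net.backward(dout)
        opt.step(grads)
        if Xv is not None and (it + 1) % train_cfg.log_every == 0:
            vloss, _ = training_loss(ecn.net(Xv), Tv)
            ecn.val_history.append((it + 1, vloss))
    return ecn
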