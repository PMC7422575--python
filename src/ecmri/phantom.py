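"""Synthetic complex-valued brain-like phantoms and train/val/test datasets.

The generator emulates the statistics the reconstruction method relies
on, not anatomy: a piecewise-smooth magnitude (a stack of anti-aliased
random ellipses, optionally with a little smooth texture) and a smooth
random polynomial phase, normalized to unit maximum magnitude.  Real MR
magnitude images are piecewise smooth and carry a slowly varying phase
from field inhomogeneity and coil geometry; that is exactly the
structure that makes them compressible under a wavelet transform and
makes sparse reconstruction leave *structured* residual errors — the
signal the error-correction network learns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .fourier import ComplexImage

__all__ = ["PhantomConfig", "Dataset", "make_phantom", "normalize", "make_dataset"]


@dataclass
class PhantomConfig:
    """Parameters of one random phantom.

    size
        image shape ``(H, W)``, at least 32x32
    n_ellipses
        number of random ellipses summed into the magnitude
    phase_order
        degree of the random 2-D polynomial phase field (0 = constant)
    texture_level
        amplitude of the smooth additive texture, 0 disables it
    seed
        RNG seed; identical configs produce identical phantoms
    """

    size: tuple[int, int] = (64, 64)
    n_ellipses: int = 8
    phase_order: int = 2
    texture_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.size) < 32:
            raise ValueError(f"phantom size must be >= 32x32, got {self.size}")
        if self.n_ellipses < 1:
            raise ValueError("n_ellipses must be >= 1")
        if self.texture_level < 0:
            raise ValueError("texture_level must be >= 0")


@dataclass
class Dataset:
    """Fully-sampled ground-truth images partitioned into disjoint splits."""

    train: list[ComplexImage]
    val: list[ComplexImage]
    test: list[ComplexImage]
    seed: int = 0
    config: PhantomConfig | None = None

    @property
    def n(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)

    def save(self, directory: str | Path) -> None:
        """Persist as one ``.npy`` per image plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"seed": self.seed, "splits": {}}
        if self.config is not None:
            cfg = self.config.__dict__.copy()
            cfg["size"] = list(cfg["size"])
            manifest["config"] = cfg
        for split in ("train", "val", "test"):
            names = []
            for i, img in enumerate(getattr(self, split)):
                name = f"{split}_{i:04d}.npy"
                np.save(directory / name, img.data)
                names.append(name)
            manifest["splits"][split] = names
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "Dataset":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        splits = {
            split: [ComplexImage(np.load(directory / name))
                    for name in manifest["splits"][split]]
            for split in ("train", "val", "test")
        }
        cfg = None
        if "config" in manifest:
            c = dict(manifest["config"])
            c["size"] = tuple(c["size"])
            cfg = PhantomConfig(**c)
        return cls(seed=manifest["seed"], config=cfg, **splits)


def normalize(img: ComplexImage) -> ComplexImage:
    """Divide by the largest pixel magnitude; phase is untouched.

    Raises ``ValueError`` on an all-zero image.
    """
    peak = float(np.max(np.abs(img.data)))
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero image")
    return ComplexImage(img.data / peak)


def _ellipse_field(H: int, W: int, rng: np.random.Generator, n_ellipses: int) -> np.ndarray:
    """Sum of random ellipses with smoothstep (anti-aliased) edges."""
    yy, xx = np.mgrid[0:H, 0:W]
    u = (xx - W / 2) / (W / 2)
    v = (yy - H / 2) / (H / 2)
    mag = np.zeros((H, W))

    # enclosing "skull" ellipse so phantoms have a compact support
    q = (u / 0.92) ** 2 + (v / 0.92) ** 2
    support = np.clip((1.0 - q) / (4.0 / min(H, W)) + 0.5, 0.0, 1.0)
    mag += 0.35 * support

    for _ in range(n_ellipses):
        cx, cy = rng.uniform(-0.55, 0.55, size=2)
        a = rng.uniform(0.08, 0.45)
        b = rng.uniform(0.08, 0.45)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(-0.35, 0.6)
        ur = (u - cx) * np.cos(theta) + (v - cy) * np.sin(theta)
        vr = -(u - cx) * np.sin(theta) + (v - cy) * np.cos(theta)
        q = (ur / a) ** 2 + (vr / b) ** 2
        edge = np.clip((1.0 - q) / (4.0 / min(H, W)) + 0.5, 0.0, 1.0)
        mag += amp * edge * support
    return np.clip(mag, 0.0, None)


def _polynomial_phase(H: int, W: int, rng: np.random.Generator, order: int) -> np.ndarray:
    """Smooth random 2-D polynomial, rescaled into [-pi, pi]."""
    u = np.linspace(-1, 1, W)[None, :]
    v = np.linspace(-1, 1, H)[:, None]
    phase = np.zeros((H, W))
    for p in range(order + 1):
        for qq in range(order + 1 - p):
            phase = phase + rng.normal() * (u ** p) * (v ** qq)
    span = np.max(np.abs(phase))
    if span > 0:
        phase = phase / span * np.pi * rng.uniform(0.3, 1.0)
    return phase


def make_phantom(cfg: PhantomConfig) -> ComplexImage:
    """Generate one normalized complex phantom, deterministic given the seed."""
    H, W = cfg.size
    rng = np.random.default_rng(cfg.seed)
    mag = _ellipse_field(H, W, rng, cfg.n_ellipses)
    if cfg.texture_level > 0:
        texture = gaussian_filter(rng.normal(size=(H, W)), sigma=min(H, W) / 24)
        texture /= max(np.max(np.abs(texture)), 1e-12)
        mag = np.clip(mag + cfg.texture_level * texture, 0.0, None)
    phase = _polynomial_phase(H, W, rng, cfg.phase_order)
    return normalize(ComplexImage(mag * np.exp(1j * phase)))


def _split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n samples over the split fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([-(r - c) for r, c in zip(raw, counts)], kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return tuple(counts)  # type: ignore[return-value]


def make_dataset(
    n: int,
    cfg: PhantomConfig | None = None,
    split: tuple[float, float, float] = (0.75, 0.05, 0.20),
    seed: int = 0,
) -> Dataset:
    """Generate ``n`` independent phantoms and partition them 75/5/20.

    Each phantom gets its own child seed spawned from ``seed``; the
    partition is a deterministic shuffle, so splits are disjoint and the
    whole dataset is reproducible from ``(n, cfg, split, seed)``.
    """
    if n < 5:
        raise ValueError("need at least 5 samples to populate three splits")
    if cfg is None:
        cfg = PhantomConfig()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    images = [
        make_phantom(PhantomConfig(size=cfg.size, n_ellipses=cfg.n_ellipses,
                                   phase_order=cfg.phase_order,
                                   texture_level=cfg.texture_level, seed=int(s)))
        for s in child_seeds
    ]
    n_train, n_val, n_test = _split_counts(n, split)
    perm = rng.permutation(n)
    train = [images[i] for i in perm[:n_train]]
    val = [images[i] for i in perm[n_train:n_train + n_val]]
    test = [images[i] for i in perm[n_train + n_val:]]
    return Dataset(train=train, val=val, test=test, seed=seed, config=cfg)
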