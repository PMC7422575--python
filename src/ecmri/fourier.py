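"""Acquisition forward model: centered unitary 2D Fourier transforms,
k-space sampling masks, undersampling and the zero-filled adjoint.

Conventions
-----------
All transforms are *centered* (DC component at the array center, i.e.
``fftshift`` applied) and *unitary* (``norm="ortho"``), so that

* Parseval's identity holds exactly: ``||F x||_2 == ||x||_2``,
* the adjoint of the undersampling operator ``F_u = M . F`` is simply
  ``F^H . M`` (mask-then-inverse-transform), and
* the pointwise closed form used by the data-fidelity module is exact,
  because ``F F_u^H F_u F^H`` reduces to the 0/1 diagonal mask.

Cartesian 1-D masks sample whole *rows* (axis 0 is the phase-encode
direction); 2-D random masks sample individual points.  Both are
variable-density: sampling probability is highest near the k-space
center, where most image energy lives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "ComplexImage",
    "SamplingMask",
    "KSpaceMeasurements",
    "forward_fft",
    "inverse_fft",
    "make_cartesian_mask",
    "make_random_mask",
    "undersample",
    "zero_fill",
    "add_measurement_noise",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ComplexImage:
    """A 2-D complex-valued MR image (dimensionless normalized intensity).

    Wraps an ``(H, W)`` complex ndarray.  Ground-truth images are
    normalized so the maximum pixel magnitude is 1; intermediate
    reconstructions may exceed that slightly.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError(f"ComplexImage must be 2-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ComplexImage entries must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    def copy(self) -> "ComplexImage":
        return ComplexImage(self.data.copy())


MaskPattern = Literal["cartesian_1d", "random_2d", "custom"]


@dataclass
class SamplingMask:
    """Binary k-space sampling mask plus the metadata that generated it.

    ``data`` is an ``(H, W)`` 0/1 float array on the *centered* k-space
    grid; ``ratio`` is the requested fill fraction.
    """

    data: np.ndarray
    pattern: MaskPattern = "custom"
    ratio: float = float("nan")
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"SamplingMask must be 2-D, got shape {self.data.shape}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("SamplingMask entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def achieved_ratio(self) -> float:
        return float(self.data.mean())

    def save(self, path: str | Path) -> None:
        """Persist as ``<path>.npy`` + ``<path>.json`` sidecar."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data.astype(np.uint8))
        sidecar = {"pattern": self.pattern, "ratio": self.ratio, "seed": self.seed,
                   "meta": self.meta}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SamplingMask":
        path = Path(path)
        data = np.load(path.with_suffix(".npy")).astype(np.float64)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(data=data, pattern=sidecar["pattern"], ratio=sidecar["ratio"],
                   seed=sidecar["seed"], meta=sidecar.get("meta", {}))


@dataclass
class KSpaceMeasurements:
    """Measured k-space on the full grid, zero at unsampled positions."""

    data: np.ndarray
    mask: SamplingMask

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.shape != self.mask.shape:
            raise ValueError(
                f"k-space shape {self.data.shape} != mask shape {self.mask.shape}")
        off = self.data[self.mask.data == 0]
        if off.size and np.max(np.abs(off)) > 0:
            raise ValueError("measurements are nonzero at unsampled positions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _as_array(img: ComplexImage | np.ndarray) -> np.ndarray:
    arr = img.data if isinstance(img, ComplexImage) else np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
    return arr


def forward_fft(img: ComplexImage | np.ndarray) -> np.ndarray:
    """Centered unitary 2-D DFT (image domain -> k-space)."""
    arr = _as_array(img)
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(arr), norm="ortho"))


def inverse_fft(ksp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`forward_fft` (k-space -> image domain)."""
    arr = _as_array(ksp)
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(arr), norm="ortho"))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def _check_ratio(ratio: float) -> None:
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"sampling ratio must lie in (0, 1], got {ratio}")


def make_cartesian_mask(
    H: int,
    W: int,
    ratio: float,
    seed: int = 0,
    center_fraction: float | None = None,
    density_power: float = 3.0,
) -> SamplingMask:
    """1-D Cartesian mask: whole phase-encode rows (axis 0) are sampled.

    ``round(ratio * H)`` rows are kept.  A centered block of
    ``round(center_fraction * H)`` rows is always included (low spatial
    frequencies carry most energy); the remaining rows are drawn without
    replacement with probability decaying as a power law in distance
    from the center row.

    center_fraction defaults to ``0.08 * ratio`` of the rows.
    """
    _check_ratio(ratio)
    n_rows = int(round(ratio * H))
    n_rows = max(n_rows, 1)
    if center_fraction is None:
        center_fraction = 0.08 * ratio
    if center_fraction > ratio + 1e-12:
        raise ValueError("center_fraction must not exceed ratio")
    n_center = min(int(round(center_fraction * H)), n_rows)

    center = H // 2
    rows = np.arange(H)
    center_block = rows[(rows >= center - n_center // 2)
                        & (rows < center - n_center // 2 + n_center)]

    rng = np.random.default_rng(seed)
    remaining = np.setdiff1d(rows, center_block)
    n_extra = n_rows - center_block.size
    dist = np.abs(remaining - center) / max(center, 1)
    weights = 1.0 / (1e-3 + dist) ** density_power
    weights /= weights.sum()
    extra = rng.choice(remaining, size=n_extra, replace=False, p=weights)

    mask = np.zeros((H, W))
    mask[np.concatenate([center_block, extra]).astype(int)] = 1.0
    return SamplingMask(mask, pattern="cartesian_1d", ratio=ratio, seed=seed,
                        meta={"center_fraction": center_fraction,
                              "density_power": density_power})


def make_random_mask(
    H: int,
    W: int,
    ratio: float,
    seed: int = 0,
    density_power: float = 3.0,
) -> SamplingMask:
    """2-D random mask: individual k-space points, center-weighted.

    ``round(ratio * H * W)`` points are drawn without replacement with
    probability decaying as a power law in radial distance from the
    k-space center; the DC position is always sampled.
    """
    _check_ratio(ratio)
    n_pts = max(int(round(ratio * H * W)), 1)

    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = H // 2, W // 2
    r = np.hypot((yy - cy) / max(cy, 1), (xx - cx) / max(cx, 1)).ravel()
    weights = 1.0 / (1e-3 + r) ** density_power

    dc = cy * W + cx
    weights_wo_dc = weights.copy()
    weights_wo_dc[dc] = 0.0
    weights_wo_dc /= weights_wo_dc.sum()

    rng = np.random.default_rng(seed)
    chosen = rng.choice(H * W, size=n_pts - 1, replace=False, p=weights_wo_dc)

    mask = np.zeros(H * W)
    mask[dc] = 1.0
    mask[chosen] = 1.0
    return SamplingMask(mask.reshape(H, W), pattern="random_2d", ratio=ratio,
                        seed=seed, meta={"density_power": density_power})


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------

def undersample(img: ComplexImage | np.ndarray, mask: SamplingMask) -> KSpaceMeasurements:
    """Simulate acquisition: ``y = M . F x`` on the full grid."""
    arr = _as_array(img)
    if arr.shape != mask.shape:
        raise ValueError(f"image shape {arr.shape} != mask shape {mask.shape}")
    return KSpaceMeasurements(mask.data * forward_fft(arr), mask)


def add_measurement_noise(
    y: KSpaceMeasurements, sigma: float, seed: int = 0
) -> KSpaceMeasurements:
    """Add i.i.d. complex Gaussian noise of std ``sigma`` at sampled positions."""
    if sigma < 0:
        raise ValueError("noise std must be nonnegative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=sigma / np.sqrt(2), size=(2,) + y.shape)
    noisy = y.data + y.mask.data * (noise[0] + 1j * noise[1])
    return KSpaceMeasurements(noisy, y.mask)


def zero_fill(y: KSpaceMeasurements) -> ComplexImage:
    """Adjoint (zero-filled) reconstruction ``Z(y) = F_u^H y``."""
    return ComplexImage(inverse_fft(y.data))
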