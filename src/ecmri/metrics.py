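"""Image-quality metrics and diagnostic maps.

PSNR and SSIM are computed on *magnitude* images with data range 1.0
(ground truths are unit-normalized); this is the usual convention for
complex MRI evaluation.  The filtered difference map highlights pixels
where the guide reconstruction is *less* accurate than plain zero-fill
— the information loss the error-correction network is built to win
back:

    m_d = ( |x_true - x_guide| - |x_true - Z(y)| )_+
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .fourier import ComplexImage

__all__ = ["PSNR_CAP_DB", "psnr", "ssim", "error_map",
           "filtered_difference_map", "ReconstructionReport"]

PSNR_CAP_DB = 300.0  # reported for bit-identical images (MSE == 0)


def _magnitudes(ref: ComplexImage, test: ComplexImage) -> tuple[np.ndarray, np.ndarray]:
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return np.abs(ref.data), np.abs(test.data)


def psnr(ref: ComplexImage, test: ComplexImage, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(peak^2 / MSE), in dB."""
    r, t = _magnitudes(ref, test)
    mse = float(np.mean((r - t) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(10.0 * np.log10(peak**2 / mse), PSNR_CAP_DB)


def ssim(ref: ComplexImage, test: ComplexImage, data_range: float = 1.0) -> float:
    """Mean structural similarity on magnitude images.

    Gaussian window (sigma 1.5, 11x11), K1=0.01, K2=0.03 — the standard
    reference constants.
    """
    r, t = _magnitudes(ref, test)
    if min(r.shape) < 11:
        raise ValueError(f"image {r.shape} smaller than the 11x11 SSIM window")
    return float(structural_similarity(
        r, t, data_range=data_range, gaussian_weights=True, sigma=1.5,
        win_size=11, K1=0.01, K2=0.03, use_sample_covariance=False))


def error_map(ref: ComplexImage, test: ComplexImage) -> np.ndarray:
    """Pointwise complex error magnitude |ref - test| (display range for
    rendering is conventionally [0, 0.2]; clipping happens only there)."""
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return np.abs(ref.data - test.data)


def filtered_difference_map(
    x_true: ComplexImage, guide: ComplexImage, zf: ComplexImage
) -> np.ndarray:
    """Rectified excess of the guide's error over the zero-filled error
    (nonnegative; bright where zero-fill beat the guide).  Rendered with
    display range [0, 0.1]."""
    md = error_map(x_true, guide) - error_map(x_true, zf)
    return np.maximum(md, 0.0)


def save_map_png(m: np.ndarray, path: str | Path, vmax: float = 0.2) -> None:
    """Render a diagnostic map to PNG with a fixed display range."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(m, cmap="inferno", vmin=0.0, vmax=vmax)
    fig.colorbar(im, ax=ax, fraction=0.046)
    ax.axis("off")
    fig.savefig(Path(path), dpi=120, bbox_inches="tight")
    plt.close(fig)


@dataclass
class ReconstructionReport:
    """Per-stage images and metrics for one reconstruction.

    Stages (in pipeline order): ``zero_filled``, ``guide``,
    ``corrected`` (guide + predicted residual), ``final`` (after data
    fidelity).  Metrics are present only when a ground truth was
    available.
    """

    stages: dict[str, ComplexImage]
    psnr_db: dict[str, float] = field(default_factory=dict)
    ssim_val: dict[str, float] = field(default_factory=dict)
    guide_name: str = ""
    mask_pattern: str = ""
    mask_ratio: float = float("nan")
    alpha: float = float("nan")

    def __post_init__(self) -> None:
        shapes = {img.shape for img in self.stages.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent stage shapes: {shapes}")

    def compute_metrics(self, x_true: ComplexImage) -> None:
        for name, img in self.stages.items():
            self.psnr_db[name] = psnr(x_true, img)
            self.ssim_val[name] = ssim(x_true, img)

    def to_row(self) -> dict:
        row: dict = {"guide": self.guide_name, "mask": self.mask_pattern,
                     "ratio": self.mask_ratio, "alpha": self.alpha}
        for name in self.stages:
            if name in self.psnr_db:
                row[f"psnr_{name}"] = self.psnr_db[name]
                row[f"ssim_{name}"] = self.ssim_val[name]
        return row

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_row(), indent=2))

    @staticmethod
    def table(reports: list["ReconstructionReport"]) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in reports])
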