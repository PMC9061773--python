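"""Filament-image enhancement, line scoring and adaptive binarization.

The filament component coming out of the decomposition is low-contrast and
slightly blurred.  Three steps turn it into a binary map of line pixels:

1. ``enhance_filament_image`` — Gaussian smoothing, a sign-flipped Laplacian
   (so ridges come out positive), then a per-pixel maximum over a bank of
   rotated anisotropic Gaussians that re-connects fragmented ridges along
   their direction.
2. ``line_probability_map`` — correlation with zero-mean line kernels
   (length = 3 x width) over a grid of widths and orientations; the maximum
   normalized response scores each pixel's membership in a line and records
   the best-fitting width and angle.  Scores are normalized to [0, 1] for
   ranking, not calibrated probabilities.
3. ``wellner_binarize`` — Wellner-style adaptive thresholding: a pixel is
   foreground iff it exceeds its local box mean by a fixed percentage.
   Ratio-based, hence invariant to global intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .io_formats import Image2D

__all__ = [
    "EnhancementParams",
    "LineProbabilityMap",
    "BinaryMask",
    "enhance_filament_image",
    "line_probability_map",
    "wellner_binarize",
]

_LAPLACE_4 = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
_LAPLACE_8 = np.array([[1, 1, 1], [1, -8, 1], [1, 1, 1]], dtype=float)


@dataclass(frozen=True)
class EnhancementParams:
    gaussian_sigma: float = 1.0
    laplace_kernel: str = "4-neighbor"
    sigma_along: float = 6.0
    sigma_across: float = 1.5
    n_orientations: int = 16

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if not (self.sigma_along > self.sigma_across > 0):
            raise ValueError("need sigma_along > sigma_across > 0")
        if self.n_orientations < 8:
            raise ValueError("n_orientations must be >= 8")
        if self.laplace_kernel not in ("4-neighbor", "8-neighbor"):
            raise ValueError(f"unknown laplace_kernel {self.laplace_kernel!r}")


@dataclass(frozen=True)
class LineProbabilityMap:
    prob: np.ndarray
    best_width: np.ndarray
    best_angle: np.ndarray
    widths_evaluated: tuple[int, ...]


@dataclass(frozen=True)
class BinaryMask:
    mask: np.ndarray
    window_px: int
    offset_percent: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            raise ValueError("mask must be boolean")
        object.__setattr__(self, "mask", m)


def _rotated_gaussian_kernel(sigma_along: float, sigma_across: float,
                             theta_deg: float) -> np.ndarray:
    half = int(np.ceil(3.0 * sigma_along))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    t = np.deg2rad(theta_deg)
    # angles are CCW from +x with y pointing down, so the y term is negated
    u = np.cos(t) * x - np.sin(t) * y
    v = np.sin(t) * x + np.cos(t) * y
    k = np.exp(-u ** 2 / (2 * sigma_along ** 2) - v ** 2 / (2 * sigma_across ** 2))
    return k / k.sum()


def enhance_filament_image(img: Image2D, params: EnhancementParams | None = None) -> Image2D:
    """Gaussian -> sign-flipped Laplacian -> max over directed Gaussians.

    Output is rescaled to [0, 1]; an image with no ridge structure (constant
    or all-zero) maps to all zeros.
    """
    if params is None:
        params = EnhancementParams()
    x = ndimage.gaussian_filter(img.pixels, params.gaussian_sigma, mode="nearest")
    lap = _LAPLACE_4 if params.laplace_kernel == "4-neighbor" else _LAPLACE_8
    # bright ridges have negative Laplacian; flip so they score positive
    ridge = -ndimage.correlate(x, lap, mode="nearest")
    out = np.full_like(ridge, -np.inf)
    for j in range(params.n_orientations):
        theta = 180.0 * j / params.n_orientations
        k = _rotated_gaussian_kernel(params.sigma_along, params.sigma_across, theta)
        # kernels are even-symmetric, so convolution == correlation
        np.maximum(out, fftconvolve(ridge, k, mode="same"), out=out)
    out = np.clip(out, 0.0, None)
    m = out.max()
    if m > 0:
        out /= m
    return Image2D(out)


def _line_kernel(width: int, theta_deg: float) -> np.ndarray:
    """Zero-mean rotated bar kernel: length 3*width, thickness width.

    Difference-of-boxes ridge detector: a positive bar of the given width
    minus two flanking bars of the same thickness at lateral offset
    ``+-width``, each contrast-normalized, rasterized with a half-pixel soft
    edge so responses vary smoothly with angle.  The response on an ideal
    line of matching width equals its amplitude, and the matching width wins
    the across-width maximum on the line's support.
    """
    length = 3.0 * width
    half = int(np.ceil(length / 2)) + width + 1
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    t = np.deg2rad(theta_deg)
    # angles are CCW from +x with y pointing down, so the y term is negated
    u = np.cos(t) * x - np.sin(t) * y
    v = np.sin(t) * x + np.cos(t) * y
    along = np.clip(length / 2 + 0.5 - np.abs(u), 0.0, 1.0)
    bar = along * np.clip(width / 2 + 0.5 - np.abs(v), 0.0, 1.0)
    flanks = along * np.clip(width / 2 + 0.5 - np.abs(np.abs(v) - width), 0.0, 1.0)
    return bar / bar.sum() - flanks / flanks.sum()


def line_probability_map(img: Image2D, widths=(1, 3, 5),
                         n_orientations: int = 16) -> LineProbabilityMap:
    """Score every pixel's membership in a line of each candidate width."""
    widths = tuple(int(w) for w in widths)
    if not widths or any(w < 1 for w in widths):
        raise ValueError("widths must be a non-empty list of values >= 1")
    limit = min(img.shape) / 3
    if any(w > limit for w in widths):
        raise ValueError(
            f"width exceeds min(image dims)/3 = {limit:.0f} px"
        )
    x = img.pixels
    best = np.full(x.shape, -np.inf)
    best_w = np.zeros(x.shape, dtype=int)
    best_a = np.zeros(x.shape)
    for w in widths:
        for j in range(n_orientations):
            theta = 180.0 * j / n_orientations
            resp = fftconvolve(x, _line_kernel(w, theta), mode="same")
            better = resp > best
            best[better] = resp[better]
            best_w[better] = w
            best_a[better] = theta
    prob = np.clip(best, 0.0, None)
    m = prob.max()
    if m > 0:
        prob /= m
    return LineProbabilityMap(prob=prob, best_width=best_w, best_angle=best_a,
                              widths_evaluated=widths)


def wellner_binarize(img: Image2D, window_px: int = 15,
                     offset_percent: float = 15.0) -> BinaryMask:
    """Adaptive threshold: foreground iff v > local mean * (100 + offset)/100.

    The local mean is a ``window_px`` x ``window_px`` box average with
    edge-replicated borders — the standard 2D generalization of Wellner's
    running-mean rule.  Bright structure on a dark background is foreground.
    """
    if window_px < 1:
        raise ValueError("window_px must be >= 1")
    if not (0 <= offset_percent < 100):
        raise ValueError("offset_percent must be in [0, 100)")
    x = img.pixels
    local_mean = ndimage.uniform_filter(x, size=window_px, mode="nearest")
    # the box filter's running sums can leave ~1e-18 negatives on flat zero
    # background; a relative epsilon keeps the strict inequality honest
    eps = 1e-9 * float(np.abs(x).max(initial=0.0))
    mask = x > local_mean * (100.0 + offset_percent) / 100.0 + eps
    return BinaryMask(mask=mask, window_px=window_px, offset_percent=offset_percent)
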