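"""Image input and tabular/summary/overlay output.

Conventions used across the package
-----------------------------------
* Pixels are indexed 0-based, ``x`` = column, ``y`` = row, origin top-left.
* Orientations are measured counter-clockwise from the +x axis (i.e. from
  +x toward -y when the image is displayed with row 0 on top), reported in
  degrees folded into the half-open nematic interval [0, 180).
* Images are rescaled per image to [0, 1] on load by ``(v - min)/(max - min)``;
  only geometry, not absolute intensity, is compared downstream.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Image2D",
    "read_intensity_image",
    "write_filaments_table",
    "read_filaments_table",
    "write_summary",
    "render_overlay",
]

FILAMENT_CSV_HEADER = "segment_id,x1,y1,x2,y2,length_px,angle_deg"


@dataclass(frozen=True)
class Image2D:
    """A 2D scalar intensity field with [0, 1] pixel values."""

    pixels: np.ndarray
    source_path: str | None = None
    bit_depth_original: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected a 2D image, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixel values")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @classmethod
    def from_array(cls, arr: np.ndarray, source_path: str | None = None,
                   bit_depth_original: int = 0) -> "Image2D":
        """Wrap an array, min-max normalizing it into [0, 1]."""
        arr = np.asarray(arr, dtype=np.float64)
        lo, hi = float(arr.min()), float(arr.max())
        if hi > lo:
            arr = (arr - lo) / (hi - lo)
        else:
            arr = np.zeros_like(arr)
        return cls(arr, source_path=source_path,
                   bit_depth_original=bit_depth_original)


def _first_plane(arr: np.ndarray, path: str) -> np.ndarray:
    """Reduce a possibly multi-frame / multi-channel array to one 2D plane."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        # Channel-last RGB(A): accept only if gray-identical or single channel.
        if arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            rgb = arr[..., :3].astype(np.float64)
            if np.allclose(rgb[..., 0], rgb[..., 1]) and np.allclose(rgb[..., 0], rgb[..., 2]):
                return rgb[..., 0]
            raise ValueError(
                f"{path}: multi-channel color image has no unambiguous single channel"
            )
        logger.warning("%s: multi-frame image; reading only the first frame", path)
        return arr[0]
    raise ValueError(f"{path}: cannot interpret array of shape {arr.shape} as one image")


def read_intensity_image(path: str | os.PathLike) -> Image2D:
    """Read a single-channel TIFF/PNG micrograph, normalized to [0, 1].

    Multi-frame TIFFs are truncated to their first frame with a logged
    warning.  The original integer bit depth is recorded for provenance.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    plane = _first_plane(arr, path)
    bit_depth = plane.dtype.itemsize * 8 if plane.dtype.kind in "ui" else 0
    return Image2D.from_array(plane.astype(np.float64), source_path=path,
                              bit_depth_original=bit_depth)


def write_image(img: Image2D, path: str | os.PathLike) -> None:
    """Save an Image2D as 16-bit grayscale TIFF (PNG if the suffix says so)."""
    path = os.fspath(path)
    arr16 = np.round(np.clip(img.pixels, 0.0, 1.0) * 65535).astype(np.uint16)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr16)
    else:
        iio.imwrite(path, arr16)


def write_filaments_table(fs, path: str | os.PathLike) -> None:
    """Write extracted segments as CSV.

    Columns: ``segment_id,x1,y1,x2,y2,length_px,angle_deg``; endpoints and
    lengths to 3 decimals, angles to 4; one row per segment.
    """
    lines = [FILAMENT_CSV_HEADER]
    for seg in fs.segments:
        lines.append(
            f"{seg.id},{seg.x1:.3f},{seg.y1:.3f},{seg.x2:.3f},{seg.y2:.3f},"
            f"{seg.length_px:.3f},{seg.angle_deg:.4f}"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_filaments_table(path: str | os.PathLike):
    """Read a segments CSV produced by :func:`write_filaments_table`."""
    from .segmentation import FilamentSet, Segment

    segments = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != FILAMENT_CSV_HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            sid, x1, y1, x2, y2, _length, _angle = line.split(",")
            segments.append(
                Segment.from_endpoints(int(sid), float(x1), float(y1),
                                       float(x2), float(y2))
            )
    return FilamentSet(segments=segments, image_shape=None)


def write_summary(result, stats, path: str | os.PathLike,
                  config: dict | None = None) -> None:
    """Write a per-image JSON summary (sorted keys, deterministic bytes).

    Contains the OOP, director, segment count, total extracted length and the
    full extraction configuration so a run can be replayed exactly.
    """
    payload = {
        "oop": None if not np.isfinite(result.oop) else result.oop,
        "director_deg": None if not np.isfinite(result.director_deg)
        else result.director_deg,
        "n_segments": stats.n_segments,
        "total_length_px": stats.total_length_px,
        "config": config if config is not None else {},
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")


def render_overlay(img: Image2D, fs, path: str | os.PathLike,
                   color: tuple[int, int, int] = (255, 64, 64)) -> None:
    """Save a PNG with extracted segments drawn over the grayscale image."""
    from skimage.draw import line as draw_line

    h, w = img.shape
    gray = np.round(np.clip(img.pixels, 0, 1) * 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    for seg in fs.segments:
        pts = [(seg.x1, seg.y1), (seg.x2, seg.y2)]
        for x, y in pts:
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise ValueError(
                    f"segment {seg.id} endpoint ({x:.1f}, {y:.1f}) "
                    f"outside {w}x{h} image"
                )
        rr, cc = draw_line(int(round(seg.y1)), int(round(seg.x1)),
                           int(round(seg.y2)), int(round(seg.x2)))
        rgb[rr, cc] = color
    iio.imwrite(os.fspath(path), rgb)
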