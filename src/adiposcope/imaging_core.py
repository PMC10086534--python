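"""Shared image substrate.

Raster containers on a common 0-255 intensity scale, color-space
conversion, Z-projection, abutting mosaic tiling, polygon-ROI
rasterization, interval thresholding, and the intermodes automatic
histogram threshold.

Conventions
-----------
* Pixel coordinates are 0-based, row-major; polygon vertices are
  ``(row, col)`` pairs in pixel units.
* All intensities live on the 8-bit-equivalent float scale [0, 255];
  16-bit TIFF input is divided by 257 on load.
* Threshold intervals are inclusive at both ends.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import ConvergenceError, ShapeError, ValidationError

__all__ = [
    "RasterImage",
    "RGBImage",
    "HSBImage",
    "ChannelStack",
    "PolygonROI",
    "BinaryMask",
    "rgb_to_hsb",
    "hsb_to_rgb",
    "zmax_project",
    "tile_mosaic",
    "split_mosaic",
    "downsample_bin",
    "rasterize_roi",
    "threshold_mask",
    "intermodes_threshold",
    "load_raster_tiff",
    "save_raster_tiff",
    "load_stack_tiff",
    "save_mask_tiff",
    "load_roi",
    "save_roi",
]

INTENSITY_MAX = 255.0


def _as_intensity_plane(arr: np.ndarray, name: str = "pixels") -> np.ndarray:
    out = np.asarray(arr, dtype=np.float64)
    if out.ndim != 2:
        raise ShapeError(f"{name} must be 2-D, got shape {out.shape}")
    if out.shape[0] < 1 or out.shape[1] < 1:
        raise ShapeError(f"{name} must have both dimensions >= 1")
    if out.min() < 0.0 or out.max() > INTENSITY_MAX:
        raise ValidationError(
            f"{name} values must lie within [0, {INTENSITY_MAX:.0f}]; "
            f"got range [{out.min():.3g}, {out.max():.3g}]"
        )
    return out


@dataclass(frozen=True)
class RasterImage:
    """Single-channel intensity grid on the [0, 255] scale.

    Parameters
    ----------
    pixels : ndarray
        2-D float array, values in [0, 255].
    pixel_size_um : float
        Physical edge length of one pixel in micrometers (> 0).
    channel_label : str
        Free-text channel description.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _as_intensity_plane(self.pixels))
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RGBImage:
    """Three aligned intensity planes (R, G, B), each on [0, 255]."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        planes = {}
        for name in ("r", "g", "b"):
            planes[name] = _as_intensity_plane(getattr(self, name), name)
        if not (planes["r"].shape == planes["g"].shape == planes["b"].shape):
            raise ShapeError(
                "RGB planes must share one shape, got "
                f"{planes['r'].shape}, {planes['g'].shape}, {planes['b'].shape}"
            )
        for name, arr in planes.items():
            object.__setattr__(self, name, arr)
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")

    @classmethod
    def from_array(cls, arr: np.ndarray, pixel_size_um: float = 1.0) -> "RGBImage":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ShapeError(f"expected (H, W, 3) array, got {arr.shape}")
        return cls(arr[..., 0], arr[..., 1], arr[..., 2], pixel_size_um)

    def to_array(self) -> np.ndarray:
        return np.stack([self.r, self.g, self.b], axis=-1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class HSBImage:
    """Hue / saturation / brightness planes.

    Hue lives on a 0-255 wraparound scale (360 degrees mapped linearly to
    256 levels); saturation and brightness are 0-255.
    """

    hue: np.ndarray
    saturation: np.ndarray
    brightness: np.ndarray

    def __post_init__(self) -> None:
        planes = {}
        for name in ("hue", "saturation", "brightness"):
            planes[name] = _as_intensity_plane(getattr(self, name), name)
        if not (
            planes["hue"].shape
            == planes["saturation"].shape
            == planes["brightness"].shape
        ):
            raise ShapeError("HSB planes must share one shape")
        for name, arr in planes.items():
            object.__setattr__(self, name, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ChannelStack:
    """Ordered list of equally shaped single-channel slices."""

    slices: tuple[RasterImage, ...]
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if len(slices) < 1:
            raise ValidationError("ChannelStack requires at least one slice")
        shape0 = slices[0].shape
        for s in slices[1:]:
            if s.shape != shape0:
                raise ShapeError(
                    f"all slices must share shape {shape0}, got {s.shape}"
                )
        object.__setattr__(self, "slices", slices)
        if not self.z_step_um > 0:
            raise ValidationError("z_step_um must be > 0")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def to_array(self) -> np.ndarray:
        return np.stack([s.pixels for s in self.slices], axis=0)


def _shoelace_area(vertices: np.ndarray) -> float:
    r = vertices[:, 0]
    c = vertices[:, 1]
    return 0.5 * abs(float(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1))))


@dataclass(frozen=True)
class PolygonROI:
    """Implicitly closed polygon; vertices as (row, col) pixel coordinates."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=np.float64)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise ValidationError(f"vertices must be (N, 2), got {verts.shape}")
        if verts.shape[0] < 3:
            raise ValidationError("a polygon needs at least 3 vertices")
        if _shoelace_area(verts) <= 0.0:
            raise ValidationError("polygon encloses zero area (degenerate)")
        object.__setattr__(self, "vertices", verts)

    @property
    def area(self) -> float:
        """Enclosed area by the shoelace formula, in squared pixel units."""
        return _shoelace_area(self.vertices)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean pixel-selection grid with a provenance note."""

    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ShapeError(f"mask must be 2-D, got shape {data.shape}")
        object.__setattr__(self, "data", data.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def area_px(self) -> int:
        """Number of selected pixels."""
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# Color conversion
# ---------------------------------------------------------------------------

def rgb_to_hsb(image: RGBImage) -> HSBImage:
    """Convert RGB to hue/saturation/brightness on the 0-255 scale.

    Standard RGB->HSV with hue rescaled linearly from degrees to 0-255
    (so 360 deg maps back to 0 and pure green, 120 deg, maps to 85.0)
    and brightness defined as max(R, G, B).  Achromatic pixels get hue 0
    and saturation 0 by convention.
    """
    r, g, b = image.r, image.g, image.b
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc

    safe_delta = np.where(delta == 0, 1.0, delta)
    hue_deg = np.select(
        [delta == 0, maxc == r, maxc == g],
        [
            0.0,
            (60.0 * (g - b) / safe_delta) % 360.0,
            60.0 * (b - r) / safe_delta + 120.0,
        ],
        default=60.0 * (r - g) / safe_delta + 240.0,
    )
    hue = np.clip(hue_deg * (255.0 / 360.0), 0.0, 255.0)

    safe_max = np.where(maxc == 0, 1.0, maxc)
    saturation = np.clip(np.where(maxc == 0, 0.0, 255.0 * delta / safe_max), 0.0, 255.0)
    return HSBImage(hue=hue, saturation=saturation, brightness=maxc)


def hsb_to_rgb(hue: np.ndarray, saturation: np.ndarray, brightness: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsb`; returns an (H, W, 3) array on [0, 255].

    Used mainly by the synthetic-data generators to paint pixels with
    prescribed hue-class membership.
    """
    h = np.asarray(hue, dtype=np.float64) * (360.0 / 255.0) / 60.0  # sector units
    s = np.asarray(saturation, dtype=np.float64) / 255.0
    v = np.asarray(brightness, dtype=np.float64)

    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))

    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 255.0)


# ---------------------------------------------------------------------------
# Projection / tiling / binning
# ---------------------------------------------------------------------------

def zmax_project(stack: ChannelStack) -> RasterImage:
    """Pixel-wise maximum-intensity projection along Z."""
    arr = stack.to_array()
    return RasterImage(
        pixels=arr.max(axis=0),
        pixel_size_um=stack.slices[0].pixel_size_um,
        channel_label=stack.slices[0].channel_label,
    )


def tile_mosaic(tiles: Sequence[Sequence[RasterImage]]) -> RasterImage:
    """Assemble a rows x cols grid of equal-shape tiles into one abutting mosaic."""
    rows = len(tiles)
    if rows == 0 or len(tiles[0]) == 0:
        raise ValidationError("tile grid must be non-empty")
    cols = len(tiles[0])
    if any(len(row) != cols for row in tiles):
        raise ShapeError("tile grid is ragged (rows of unequal length)")
    shape0 = tiles[0][0].shape
    for row in tiles:
        for t in row:
            if t.shape != shape0:
                raise ShapeError(f"all tiles must share shape {shape0}, got {t.shape}")
    blocks = [[t.pixels for t in row] for row in tiles]
    return RasterImage(
        pixels=np.block(blocks),
        pixel_size_um=tiles[0][0].pixel_size_um,
        channel_label=tiles[0][0].channel_label,
    )


def split_mosaic(mosaic: RasterImage, rows: int, cols: int) -> list[list[RasterImage]]:
    """Inverse of :func:`tile_mosaic` for an evenly divisible mosaic."""
    h, w = mosaic.shape
    if h % rows or w % cols:
        raise ShapeError(f"mosaic {h}x{w} not divisible into {rows}x{cols} tiles")
    th, tw = h // rows, w // cols
    return [
        [
            RasterImage(
                mosaic.pixels[i * th : (i + 1) * th, j * tw : (j + 1) * tw],
                mosaic.pixel_size_um,
                mosaic.channel_label,
            )
            for j in range(cols)
        ]
        for i in range(rows)
    ]


def _bin_weight_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic matrix averaging n_in samples into n_out equal intervals."""
    scale = n_in / n_out
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / scale


def downsample_bin(image: RasterImage, target_width: int) -> RasterImage:
    """Reduce an image to ``target_width`` columns by area-weighted block means.

    The row count is chosen to preserve the aspect ratio to the nearest
    integer.  Block means conserve the overall mean intensity exactly.
    """
    h, w = image.shape
    if not 1 <= target_width <= w:
        raise ValidationError(
            f"target_width must be in [1, {w}], got {target_width}"
        )
    if target_width == w:
        return image
    target_height = max(1, round(h * target_width / w))
    out = _bin_weight_matrix(h, target_height) @ image.pixels @ _bin_weight_matrix(w, target_width).T
    return RasterImage(
        pixels=np.clip(out, 0.0, INTENSITY_MAX),
        pixel_size_um=image.pixel_size_um * (w / target_width),
        channel_label=image.channel_label,
    )


# ---------------------------------------------------------------------------
# ROI rasterization
# ---------------------------------------------------------------------------

def rasterize_roi(roi: PolygonROI, shape: tuple[int, int]) -> BinaryMask:
    """Even-odd fill of a polygon onto a pixel grid.

    A pixel (r, c) is selected when a ray from its center crosses the
    polygon boundary an odd number of times.  Vertices outside the image
    are effectively clipped by the grid bounds.
    """
    h, w = shape
    verts = roi.vertices
    r0 = max(0, int(np.floor(verts[:, 0].min())))
    r1 = min(h, int(np.ceil(verts[:, 0].max())) + 1)
    c0 = max(0, int(np.floor(verts[:, 1].min())))
    c1 = min(w, int(np.ceil(verts[:, 1].max())) + 1)
    mask = np.zeros((h, w), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return BinaryMask(mask, provenance="rasterize_roi (fully outside grid)")

    rr, cc = np.meshgrid(
        np.arange(r0, r1, dtype=np.float64),
        np.arange(c0, c1, dtype=np.float64),
        indexing="ij",
    )
    inside = np.zeros(rr.shape, dtype=bool)
    n = len(verts)
    for k in range(n):
        y1, x1 = verts[k]
        y2, x2 = verts[(k + 1) % n]
        if y1 == y2:
            continue  # horizontal edge never crossed by a horizontal ray rule
        crosses = (y1 > rr) != (y2 > rr)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (rr - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (cc < x_at)
    mask[r0:r1, c0:c1] = inside
    return BinaryMask(mask, provenance=f"rasterize_roi ({n} vertices, even-odd)")


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def threshold_mask(image: RasterImage, lo: float, hi: float = INTENSITY_MAX) -> BinaryMask:
    """Select pixels with ``lo <= value <= hi`` (both ends inclusive)."""
    if not 0 <= lo <= hi <= INTENSITY_MAX:
        raise ValidationError(f"require 0 <= lo <= hi <= 255, got lo={lo}, hi={hi}")
    data = (image.pixels >= lo) & (image.pixels <= hi)
    return BinaryMask(data, provenance=f"threshold [{lo}, {hi}]")


def _count_peaks(hist: np.ndarray) -> list[int]:
    """Local maxima of a 1-D array; a plateau counts once, at its leftmost bin."""
    peaks: list[int] = []
    n = len(hist)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and hist[j + 1] == hist[i]:
            j += 1
        left_lower = i == 0 or hist[i - 1] < hist[i]
        right_lower = j == n - 1 or hist[j + 1] < hist[i]
        if left_lower and right_lower and hist[i] > 0:
            peaks.append(i)
        i = j + 1
    return peaks


def intermodes_threshold(
    data: RasterImage | np.ndarray,
    max_iter: int = 10_000,
) -> int:
    """Intermodes automatic threshold.

    The 256-bin histogram is repeatedly smoothed with a 3-bin moving mean
    until exactly two local maxima remain; the threshold is the integer
    mean of the two peak bin indices.  Raises
    :class:`~adiposcope.errors.ConvergenceError` when the histogram is
    unimodal or never becomes bimodal within ``max_iter`` passes.

    Parameters
    ----------
    data : RasterImage or ndarray
        Either an image (histogrammed over [0, 255] into 256 bins) or a
        precomputed 256-bin histogram.
    """
    if isinstance(data, RasterImage):
        hist, _ = np.histogram(data.pixels, bins=256, range=(0.0, 256.0))
        hist = hist.astype(np.float64)
    else:
        hist = np.asarray(data, dtype=np.float64)
        if hist.ndim != 1 or len(hist) != 256:
            raise ValidationError("histogram must be a 1-D, 256-bin array")
        if np.any(hist < 0):
            raise ValidationError("histogram counts must be nonnegative")
    if np.count_nonzero(hist) < 2:
        raise ConvergenceError("histogram has fewer than 2 nonempty bins")

    kernel = np.array([1.0, 1.0, 1.0]) / 3.0
    for _ in range(max_iter):
        peaks = _count_peaks(hist)
        if len(peaks) == 2:
            return int((peaks[0] + peaks[1]) // 2)
        if len(peaks) < 2:
            raise ConvergenceError(
                "histogram is unimodal; intermodes threshold undefined "
                "(supply a manual threshold override)"
            )
        hist = np.convolve(hist, kernel, mode="same")
    raise ConvergenceError(
        f"histogram did not become bimodal within {max_iter} smoothing passes"
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _rescale_loaded(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 257.0
    return arr.astype(np.float64)


def load_raster_tiff(path: str | Path, pixel_size_um: float = 1.0, channel_label: str = "") -> RasterImage:
    """Load a single-channel TIFF; 16-bit data is rescaled to [0, 255]."""
    arr = _rescale_loaded(tifffile.imread(str(path)))
    if arr.ndim != 2:
        raise ShapeError(f"{path}: expected single-channel 2-D TIFF, got {arr.shape}")
    return RasterImage(arr, pixel_size_um, channel_label)


def save_raster_tiff(image: RasterImage, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.clip(np.round(image.pixels), 0, 255).astype(np.uint8))


def load_rgb_tiff(path: str | Path, pixel_size_um: float = 1.0) -> RGBImage:
    arr = _rescale_loaded(tifffile.imread(str(path)))
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ShapeError(f"{path}: expected (H, W, 3) RGB TIFF, got {arr.shape}")
    return RGBImage.from_array(arr[..., :3], pixel_size_um)


def save_rgb_tiff(image: RGBImage, path: str | Path) -> None:
    arr = np.clip(np.round(image.to_array()), 0, 255).astype(np.uint8)
    tifffile.imwrite(str(path), arr)


def load_stack_tiff(path: str | Path, z_step_um: float = 1.0, pixel_size_um: float = 1.0, channel_label: str = "") -> ChannelStack:
    """Load a multi-page TIFF as a Z-stack."""
    arr = _rescale_loaded(tifffile.imread(str(path)))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ShapeError(f"{path}: expected (Z, H, W) stack, got {arr.shape}")
    slices = tuple(RasterImage(p, pixel_size_um, channel_label) for p in arr)
    return ChannelStack(slices, z_step_um)


def save_stack_tiff(stack: ChannelStack, path: str | Path) -> None:
    arr = np.clip(np.round(stack.to_array()), 0, 255).astype(np.uint8)
    tifffile.imwrite(str(path), arr)


def save_mask_tiff(mask: BinaryMask, path: str | Path) -> None:
    """Export a mask as an 8-bit TIFF with 0/255 values."""
    tifffile.imwrite(str(path), (mask.data.astype(np.uint8) * 255))


def load_roi(path: str | Path) -> PolygonROI:
    """Read a polygon from a CSV vertex list (columns: row, col) or a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        verts = payload["vertices"] if isinstance(payload, dict) else payload
        return PolygonROI(np.asarray(verts, dtype=np.float64))
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for rec in reader:
            if not rec or rec[0].strip().lower() in ("row", "r"):
                continue
            rows.append((float(rec[0]), float(rec[1])))
    return PolygonROI(np.asarray(rows, dtype=np.float64))


def save_roi(roi: PolygonROI, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({"vertices": roi.vertices.tolist()}, fh)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col"])
        writer.writerows(roi.vertices.tolist())
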