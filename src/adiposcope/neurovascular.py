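"""Adipose neurovascular quantification.

Whole-depot nerve/vessel relative densities from tiled maximum-intensity
projections, engineered channel masks from high-magnification Z-stacks
(background subtraction, unsharp sharpening, interval thresholds,
morphological cleanup), Mander's overlap coefficients between the two
masks, and tallies of point annotations on the depot mosaic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ShapeError, UndefinedFieldError, ValidationError
from .imaging_core import (
    BinaryMask,
    ChannelStack,
    RasterImage,
    threshold_mask,
    zmax_project,
)

__all__ = [
    "FilterChainSpec",
    "DensityResult",
    "MandersResult",
    "NanAnnotationSet",
    "subtract_background",
    "unsharp",
    "make_nerve_mask",
    "make_vessel_mask",
    "relative_density",
    "manders_overlap",
    "nan_summary",
]


@dataclass(frozen=True)
class FilterChainSpec:
    """Parameters of the mask-engineering filter chain.

    Defaults reproduce the pinned analysis chain: background subtraction
    with a sigma-80 Gaussian, an unsharp mask (radius 1, weight 0.60) on
    the vessel channel only, channel-specific intensity gates, then
    dilation / hole filling / median smoothing on the vessel mask.
    """

    background_sigma_px: float = 80.0
    unsharp_radius_px: float = 1.0
    unsharp_weight: float = 0.60
    nerve_depot_gate: tuple[float, float] = (35.0, 255.0)
    vessel_depot_gate: tuple[float, float] = (45.0, 255.0)
    nerve_highmag_gate: tuple[float, float] = (100.0, 255.0)
    vessel_highmag_gate: tuple[float, float] = (15.0, 255.0)
    vessel_dilate: bool = True
    vessel_fill_holes: bool = True
    vessel_median_radius: int = 1

    def __post_init__(self) -> None:
        if not self.background_sigma_px > 0:
            raise ValidationError("background_sigma_px must be > 0")
        if not 0.0 < self.unsharp_weight < 1.0:
            raise ValidationError("unsharp_weight must lie in (0, 1)")
        for name in ("nerve_depot_gate", "vessel_depot_gate", "nerve_highmag_gate", "vessel_highmag_gate"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi <= 255:
                raise ValidationError(f"{name} must be a valid interval in [0, 255]")


@dataclass(frozen=True)
class DensityResult:
    """Mask area normalized to ROI area."""

    mask_area_px: int
    roi_area_px: int
    relative_density: float


@dataclass(frozen=True)
class MandersResult:
    """Mander's coefficients between two binary masks.

    m1 = |A∩B| / |A| (fraction of mask A inside B),
    m2 = |A∩B| / |B|,
    moc = |A∩B| / sqrt(|A|·|B|) (symmetric overlap coefficient).
    """

    m1: float
    m2: float
    moc: float


@dataclass(frozen=True)
class NanAnnotationSet:
    """Point annotations (row, col) on a whole-depot mosaic."""

    points: np.ndarray
    overlap_radius_px: float = 50.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(f"points must be (N, 2), got {pts.shape}")
        if not self.overlap_radius_px > 0:
            raise ValidationError("overlap_radius_px must be > 0")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def subtract_background(image: RasterImage, sigma_px: float = 80.0) -> RasterImage:
    """Remove smooth background: output = max(0, input - gaussian(input, sigma))."""
    if not sigma_px > 0:
        raise ValidationError("sigma_px must be > 0")
    blurred = ndimage.gaussian_filter(image.pixels, sigma=sigma_px)
    out = np.clip(image.pixels - blurred, 0.0, 255.0)
    return RasterImage(out, image.pixel_size_um, image.channel_label)


def unsharp(image: RasterImage, radius_px: float = 1.0, weight: float = 0.60) -> RasterImage:
    """Unsharp mask: (input - w·gaussian(input, radius)) / (1 - w), clamped to [0, 255].

    The division by ``1 - w`` keeps constant regions at their original
    value, which is the convention under which a fractional "mask weight"
    parameter is meaningful.
    """
    if not 0.0 < weight < 1.0:
        raise ValidationError("unsharp weight must lie strictly in (0, 1)")
    blurred = ndimage.gaussian_filter(image.pixels, sigma=radius_px)
    out = (image.pixels - weight * blurred) / (1.0 - weight)
    return RasterImage(np.clip(out, 0.0, 255.0), image.pixel_size_um, image.channel_label)


# ---------------------------------------------------------------------------
# Mask engineering
# ---------------------------------------------------------------------------

def make_nerve_mask(stack: ChannelStack, spec: FilterChainSpec | None = None) -> BinaryMask:
    """Nerve-channel mask from a high-magnification stack.

    Chain: Z-max projection -> background subtraction -> intensity gate.
    """
    spec = spec or FilterChainSpec()
    proj = zmax_project(stack)
    clean = subtract_background(proj, spec.background_sigma_px)
    lo, hi = spec.nerve_highmag_gate
    mask = threshold_mask(clean, lo, hi)
    return BinaryMask(mask.data, provenance=f"nerve: zmax > bgsub(σ={spec.background_sigma_px:g}) > [{lo:g},{hi:g}]")


def make_vessel_mask(stack: ChannelStack, spec: FilterChainSpec | None = None) -> BinaryMask:
    """Vessel-channel mask from a high-magnification stack.

    Chain: Z-max projection -> background subtraction -> unsharp mask ->
    intensity gate -> binary dilation (3x3, once) -> fill holes ->
    median filter (radius 1).
    """
    spec = spec or FilterChainSpec()
    proj = zmax_project(stack)
    clean = subtract_background(proj, spec.background_sigma_px)
    sharp = unsharp(clean, spec.unsharp_radius_px, spec.unsharp_weight)
    lo, hi = spec.vessel_highmag_gate
    data = threshold_mask(sharp, lo, hi).data
    if spec.vessel_dilate:
        data = ndimage.binary_dilation(data, structure=np.ones((3, 3), dtype=bool))
    if spec.vessel_fill_holes:
        # 4-connected background flood from the border; enclosed holes fill.
        data = ndimage.binary_fill_holes(data, structure=ndimage.generate_binary_structure(2, 1))
    r = spec.vessel_median_radius
    if r > 0:
        data = ndimage.median_filter(data.astype(np.uint8), size=2 * r + 1).astype(bool)
    return BinaryMask(
        data,
        provenance=(
            f"vessel: zmax > bgsub(σ={spec.background_sigma_px:g}) > "
            f"unsharp({spec.unsharp_radius_px:g},{spec.unsharp_weight:g}) > "
            f"[{lo:g},{hi:g}] > dilate > fill > median({r})"
        ),
    )


def depot_density_masks(
    nerve_mosaic: RasterImage,
    vessel_mosaic: RasterImage,
    spec: FilterChainSpec | None = None,
) -> tuple[BinaryMask, BinaryMask]:
    """Whole-depot nerve/vessel masks: plain intensity gates on the projected mosaic."""
    spec = spec or FilterChainSpec()
    nerve = threshold_mask(nerve_mosaic, *spec.nerve_depot_gate)
    vessel = threshold_mask(vessel_mosaic, *spec.vessel_depot_gate)
    return nerve, vessel


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def relative_density(mask: BinaryMask, roi: BinaryMask) -> DensityResult:
    """Mask area inside the ROI, normalized to the ROI area."""
    if mask.shape != roi.shape:
        raise ShapeError(f"mask {mask.shape} and roi {roi.shape} must share a shape")
    roi_area = roi.area_px
    if roi_area == 0:
        raise UndefinedFieldError("ROI is empty; relative density undefined")
    inside = int(np.count_nonzero(mask.data & roi.data))
    return DensityResult(inside, roi_area, inside / roi_area)


def manders_overlap(a: BinaryMask, b: BinaryMask) -> MandersResult:
    """Mander's split coefficients and overlap coefficient for two masks."""
    if a.shape != b.shape:
        raise ShapeError(f"masks must share a shape: {a.shape} vs {b.shape}")
    na, nb = a.area_px, b.area_px
    empty = [name for name, n in (("A", na), ("B", nb)) if n == 0]
    if empty:
        raise UndefinedFieldError(
            f"mask(s) {', '.join(empty)} empty; Mander's coefficients undefined"
        )
    inter = int(np.count_nonzero(a.data & b.data))
    return MandersResult(
        m1=inter / na,
        m2=inter / nb,
        moc=inter / float(np.sqrt(na) * np.sqrt(nb)),
    )


def nan_summary(
    annotations: NanAnnotationSet,
    roi: BinaryMask,
) -> tuple[int, np.ndarray]:
    """Count point annotations inside the ROI and their local crowding.

    Returns the total in-ROI count and, per in-ROI point, the number of
    other in-ROI points within the overlap radius (for density color
    coding of the annotation display).
    """
    h, w = roi.shape
    pts = annotations.points
    if len(pts) == 0:
        return 0, np.zeros(0, dtype=np.int64)
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() >= h
        or pts[:, 1].max() >= w
    ):
        raise ValidationError("annotation point outside mosaic bounds")
    rows = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
    cols = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
    keep = roi.data[rows, cols]
    pts = pts[keep]
    n = len(pts)
    if n == 0:
        return 0, np.zeros(0, dtype=np.int64)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    neighbors = (dist <= annotations.overlap_radius_px).sum(axis=1) - 1
    return n, neighbors.astype(np.int64)
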