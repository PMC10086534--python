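"""Intraepidermal nerve-fiber (IENF) density.

Pan-neuronal signal is auto-thresholded per image with the intermodes
algorithm (separating fibers from skin autofluorescence) and the
resulting nerve area is normalized to the epidermal ROI area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UndefinedFieldError, ValidationError
from .imaging_core import (
    BinaryMask,
    PolygonROI,
    RasterImage,
    intermodes_threshold,
    rasterize_roi,
)

__all__ = ["IenfResult", "ienf_density", "ienf_tissue_mean"]


@dataclass(frozen=True)
class IenfResult:
    threshold_used: int
    nerve_area_px: int
    roi_area_px: int
    density: float


def ienf_density(
    image: RasterImage,
    epidermis: PolygonROI | BinaryMask,
    manual_threshold: int | None = None,
    histogram_scope: str = "roi",
) -> IenfResult:
    """IENF density of one skin section.

    The lower intensity gate comes from the intermodes threshold of the
    histogram (ROI-restricted by default; set ``histogram_scope='image'``
    to use the whole section); the upper gate is fixed at 255.  A pixel
    is nerve when its intensity >= threshold and it lies inside the ROI.
    ``manual_threshold`` bypasses the automatic threshold (QC override).
    """
    if histogram_scope not in ("roi", "image"):
        raise ValidationError("histogram_scope must be 'roi' or 'image'")
    if isinstance(epidermis, PolygonROI):
        roi = rasterize_roi(epidermis, image.shape)
    else:
        roi = epidermis
    roi_area = roi.area_px
    if roi_area == 0:
        raise UndefinedFieldError("epidermal ROI covers no pixels")

    if manual_threshold is not None:
        if not 0 <= manual_threshold <= 255:
            raise ValidationError("manual_threshold must lie in [0, 255]")
        thr = int(manual_threshold)
    else:
        values = image.pixels[roi.data] if histogram_scope == "roi" else image.pixels
        hist, _ = np.histogram(values, bins=256, range=(0.0, 256.0))
        thr = intermodes_threshold(hist.astype(np.float64))

    nerve = (image.pixels >= thr) & roi.data
    nerve_area = int(nerve.sum())
    return IenfResult(
        threshold_used=thr,
        nerve_area_px=nerve_area,
        roi_area_px=roi_area,
        density=nerve_area / roi_area,
    )


def ienf_tissue_mean(results: Sequence[IenfResult]) -> float:
    """Per-tissue IENF density: arithmetic mean over section results."""
    if len(results) == 0:
        raise ValidationError("need at least one section result")
    return float(np.mean([r.density for r in results]))
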