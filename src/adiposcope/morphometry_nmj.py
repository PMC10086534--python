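"""Neuromuscular-junction occupancy summaries and adipocyte morphometry.

NMJ scoring itself is manual; this module tallies annotation tables
(occupied / altered / unoccupied status plus optional terminal-Schwann-
cell counts) and measures adipocyte area/perimeter from label masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ShapeError, UndefinedFieldError, ValidationError
from .imaging_core import BinaryMask

__all__ = [
    "NMJ_STATUSES",
    "NmjRecord",
    "NmjSummary",
    "CellLabelMask",
    "CellMetrics",
    "nmj_summary",
    "nmj_summaries_by_tissue",
    "read_nmj_csv",
    "cell_metrics",
    "occupancy_score",
]

logger = logging.getLogger(__name__)

NMJ_STATUSES = ("occupied", "altered", "unoccupied")
EXPECTED_JUNCTIONS_PER_TISSUE = 50


@dataclass(frozen=True)
class NmjRecord:
    tissue: str
    junction: str
    status: str
    tsc_count: int | None = None

    def __post_init__(self) -> None:
        if self.status not in NMJ_STATUSES:
            raise ValidationError(
                f"status must be one of {NMJ_STATUSES}, got {self.status!r}"
            )
        if self.tsc_count is not None and self.tsc_count < 0:
            raise ValidationError("tsc_count must be >= 0")


@dataclass(frozen=True)
class NmjSummary:
    n_junctions: int
    status_counts: dict[str, int]
    fraction_occupied: float
    mean_tsc_per_nmj: float  # NaN when no record carries a count


def nmj_summary(records: Sequence[NmjRecord]) -> NmjSummary:
    """Summarize one tissue's NMJ annotations.

    Altered and unoccupied junctions both count as *not fully occupied*.
    The tSC mean runs over every record carrying a count, regardless of
    occupancy status.  A junction count other than the conventional 50
    triggers a warning, not an error.
    """
    if len(records) == 0:
        raise ValidationError("no NMJ records supplied")
    n = len(records)
    if n != EXPECTED_JUNCTIONS_PER_TISSUE:
        logger.warning(
            "expected %d junctions per tissue, got %d",
            EXPECTED_JUNCTIONS_PER_TISSUE,
            n,
        )
    counts = {s: 0 for s in NMJ_STATUSES}
    for r in records:
        counts[r.status] += 1
    tsc = [r.tsc_count for r in records if r.tsc_count is not None]
    return NmjSummary(
        n_junctions=n,
        status_counts=counts,
        fraction_occupied=counts["occupied"] / n,
        mean_tsc_per_nmj=float(np.mean(tsc)) if tsc else float("nan"),
    )


def nmj_summaries_by_tissue(records: Iterable[NmjRecord]) -> dict[str, NmjSummary]:
    """Group records by tissue id and summarize each group."""
    groups: dict[str, list[NmjRecord]] = {}
    for r in records:
        groups.setdefault(r.tissue, []).append(r)
    return {tissue: nmj_summary(recs) for tissue, recs in groups.items()}


def read_nmj_csv(path: str | Path) -> list[NmjRecord]:
    """Read an annotation table (columns: tissue, junction, status[, tsc_count])."""
    df = pd.read_csv(path, dtype={"tissue": str, "junction": str})
    required = {"tissue", "junction", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"NMJ CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        tsc = getattr(row, "tsc_count", None)
        if tsc is not None and pd.isna(tsc):
            tsc = None
        records.append(
            NmjRecord(
                tissue=str(row.tissue),
                junction=str(row.junction),
                status=str(row.status).strip().lower(),
                tsc_count=None if tsc is None else int(tsc),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Adipocyte morphometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellLabelMask:
    """Integer label grid (0 = background) with a physical pixel size."""

    labels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ShapeError("label mask must be 2-D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError("label mask must be integer-typed")
        if labels.min() < 0:
            raise ValidationError("labels must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class CellMetrics:
    labels: tuple[int, ...]
    area_um2: dict[int, float]
    perimeter_um: dict[int, float]
    mean_area_um2: float
    mean_perimeter_um: float


def _edge_trace_perimeter(region: np.ndarray) -> float:
    """Outer boundary length by pixel-edge counting.

    Every exposed unit edge of a foreground pixel (a side facing
    background or the image border) contributes 1; exact for
    axis-aligned shapes.
    """
    padded = np.pad(region, 1, constant_values=False)
    edges = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbor = np.roll(padded, shift, axis=axis)
        edges += int(np.count_nonzero(padded & ~neighbor))
    return float(edges)


def _crofton_perimeter(region: np.ndarray) -> float:
    from skimage.measure import perimeter_crofton

    return float(perimeter_crofton(region, directions=4))


def cell_metrics(mask: CellLabelMask, perimeter_estimator: str = "edge") -> CellMetrics:
    """Per-cell area and perimeter in physical units, plus per-image means.

    Area = pixel count x pixel_size^2.  ``perimeter_estimator`` is
    ``'edge'`` (pixel-edge tracing, the default) or ``'crofton'``.
    """
    if perimeter_estimator not in ("edge", "crofton"):
        raise ValidationError("perimeter_estimator must be 'edge' or 'crofton'")
    labels = mask.labels
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise UndefinedFieldError("label mask contains no cells")
    px = mask.pixel_size_um
    areas: dict[int, float] = {}
    perims: dict[int, float] = {}
    slices = ndimage.find_objects(labels)
    for lab in ids:
        sl = slices[lab - 1]
        region = labels[sl] == lab
        areas[int(lab)] = float(np.count_nonzero(region)) * px * px
        if perimeter_estimator == "edge":
            perims[int(lab)] = _edge_trace_perimeter(region) * px
        else:
            perims[int(lab)] = _crofton_perimeter(region) * px
    return CellMetrics(
        labels=tuple(int(i) for i in ids),
        area_um2=areas,
        perimeter_um=perims,
        mean_area_um2=float(np.mean(list(areas.values()))),
        mean_perimeter_um=float(np.mean(list(perims.values()))),
    )


def occupancy_score(
    pre_mask: BinaryMask,
    post_mask: BinaryMask,
    tau_occupied: float = 0.8,
    tau_unoccupied: float = 0.2,
) -> tuple[float, str]:
    """Advisory occupancy suggestion from pre/post-synaptic mask coverage.

    coverage = |pre ∩ post| / |post|; >= tau_occupied suggests
    'occupied', <= tau_unoccupied suggests 'unoccupied', otherwise
    'altered'.  Intended as an annotation aid, never a replacement for
    manual scoring.
    """
    if pre_mask.shape != post_mask.shape:
        raise ShapeError("pre and post masks must share a shape")
    if not 0 <= tau_unoccupied < tau_occupied <= 1:
        raise ValidationError("require 0 <= tau_unoccupied < tau_occupied <= 1")
    n_post = post_mask.area_px
    if n_post == 0:
        raise UndefinedFieldError("post-synaptic mask is empty; coverage undefined")
    coverage = int(np.count_nonzero(pre_mask.data & post_mask.data)) / n_post
    if coverage >= tau_occupied:
        status = "occupied"
    elif coverage <= tau_unoccupied:
        status = "unoccupied"
    else:
        status = "altered"
    return coverage, status
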