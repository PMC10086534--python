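"""Picrosirius-red (PSR) collagen quantification.

Two measurements per field of view, from a paired bright-field /
polarized-light acquisition of the same region:

1. *Total collagen ratio* — birefringent (polarized-light) collagen area
   divided by total bright-field PSR stain area.  Being a ratio of areas
   in the same field, it is insensitive to uniform changes in cell size
   or number.
2. *Fiber-thickness composition* — birefringent pixels binned by hue:
   green and yellow hues count as thin fibers, orange and red as thick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ShapeError, UndefinedFieldError, ValidationError
from .imaging_core import BinaryMask, RGBImage, rgb_to_hsb

__all__ = [
    "HueBinSpec",
    "PsrFieldResult",
    "PsrTissueResult",
    "segment_psr_brightfield",
    "classify_birefringence",
    "total_collagen_ratio",
    "fiber_thickness_fractions",
    "analyze_psr_tissue",
]

logger = logging.getLogger(__name__)

HUE_CLASSES = ("green", "yellow", "orange", "red")

#: Default hue intervals (inclusive, 0-255 hue scale) per birefringence class.
DEFAULT_HUE_INTERVALS: dict[str, tuple[tuple[int, int], ...]] = {
    "green": ((52, 128),),
    "yellow": ((39, 51),),
    "orange": ((10, 38),),
    "red": ((0, 9), (230, 255)),
}

#: Classes pooled as thin vs thick fibers.
DEFAULT_THIN_CLASSES = ("green", "yellow")
DEFAULT_THICK_CLASSES = ("orange", "red")


@dataclass(frozen=True)
class HueBinSpec:
    """Hue intervals per class plus the brightness gate.

    Intervals are inclusive on both ends on the 0-255 hue scale and must
    be pairwise disjoint across classes.  Pixels failing the brightness
    gate are excluded before hue classification.
    """

    intervals: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(DEFAULT_HUE_INTERVALS)
    )
    brightness_gate: tuple[int, int] = (35, 255)
    thin_classes: tuple[str, ...] = DEFAULT_THIN_CLASSES
    thick_classes: tuple[str, ...] = DEFAULT_THICK_CLASSES

    def __post_init__(self) -> None:
        lo, hi = self.brightness_gate
        if not 0 <= lo <= hi <= 255:
            raise ValidationError(f"invalid brightness gate {self.brightness_gate}")
        owner = {}
        for cls, spans in self.intervals.items():
            for a, b in spans:
                if not 0 <= a <= b <= 255:
                    raise ValidationError(f"invalid hue interval ({a}, {b}) for {cls!r}")
                for h in range(int(a), int(b) + 1):
                    if h in owner and owner[h] != cls:
                        raise ValidationError(
                            f"hue {h} claimed by both {owner[h]!r} and {cls!r}: "
                            "class intervals must be disjoint"
                        )
                    owner[h] = cls
        for cls in self.thin_classes + self.thick_classes:
            if cls not in self.intervals:
                raise ValidationError(f"thin/thick class {cls!r} has no hue interval")

    def classify_hue(self, hue: float) -> str | None:
        """Class owning an (integer-rounded) hue value, or None if unclaimed."""
        h = int(round(hue))
        for cls, spans in self.intervals.items():
            for a, b in spans:
                if a <= h <= b:
                    return cls
        return None

    def class_lookup(self) -> np.ndarray:
        """256-entry array mapping integer hue -> class index (-1 = unclassified)."""
        classes = list(self.intervals)
        table = np.full(256, -1, dtype=np.int64)
        for idx, cls in enumerate(classes):
            for a, b in self.intervals[cls]:
                table[int(a) : int(b) + 1] = idx
        return table


@dataclass(frozen=True)
class PsrFieldResult:
    """Per-field PSR quantification."""

    psr_area_px: int
    class_counts_px: dict[str, int]
    unclassified_bright_px: int
    total_collagen_ratio: float
    thin_fraction: float
    thick_fraction: float

    @property
    def birefringent_area_px(self) -> int:
        return int(sum(self.class_counts_px.values()))

    @property
    def class_fractions(self) -> dict[str, float]:
        total = self.birefringent_area_px
        if total == 0:
            return {k: float("nan") for k in self.class_counts_px}
        return {k: v / total for k, v in self.class_counts_px.items()}


@dataclass(frozen=True)
class PsrTissueResult:
    """Per-tissue aggregate: field results plus arithmetic means over fields."""

    fields: tuple[PsrFieldResult, ...]
    excluded_fields: tuple[int, ...]  # indices dropped (zero PSR area)
    mean_total_collagen_ratio: float
    mean_thin_fraction: float
    mean_thick_fraction: float
    mean_class_fractions: dict[str, float]


def segment_psr_brightfield(
    image: RGBImage,
    hue_band: tuple[tuple[int, int], ...] = ((0, 38), (230, 255)),
    min_saturation: float = 60.0,
) -> BinaryMask:
    """Mask of red/orange PSR-stained pixels in a bright-field image.

    The default gate selects hue in the red-orange band with saturation
    >= 60, which separates the stain from the unstained (near-white,
    desaturated) background; both knobs are configurable.
    """
    hsb = rgb_to_hsb(image)
    hue = np.round(hsb.hue)
    in_band = np.zeros(image.shape, dtype=bool)
    for a, b in hue_band:
        in_band |= (hue >= a) & (hue <= b)
    data = in_band & (hsb.saturation >= min_saturation)
    return BinaryMask(data, provenance=f"psr brightfield gate hue={hue_band} sat>={min_saturation}")


def classify_birefringence(
    polarized: RGBImage,
    spec: HueBinSpec | None = None,
) -> tuple[dict[str, int], dict[str, BinaryMask], int]:
    """Hue-bin the birefringent pixels of a polarized-light image.

    The brightness gate is applied first; each gate-passing pixel is then
    assigned to at most one hue class by its integer-rounded hue.
    Saturation is deliberately ignored.

    Returns
    -------
    (class_counts, class_masks, unclassified_bright_px)
        ``class_counts`` maps class name to pixel count; pixels passing
        the gate whose hue falls in no class interval are tallied as
        ``unclassified_bright_px``.
    """
    spec = spec or HueBinSpec()
    hsb = rgb_to_hsb(polarized)
    lo, hi = spec.brightness_gate
    gate = (hsb.brightness >= lo) & (hsb.brightness <= hi)

    hue_idx = np.clip(np.round(hsb.hue).astype(np.int64), 0, 255)
    table = spec.class_lookup()
    assignment = np.where(gate, table[hue_idx], -2)  # -2 = gate-failed

    classes = list(spec.intervals)
    counts: dict[str, int] = {}
    masks: dict[str, BinaryMask] = {}
    for idx, cls in enumerate(classes):
        m = assignment == idx
        counts[cls] = int(m.sum())
        masks[cls] = BinaryMask(m, provenance=f"hue class {cls}")
    unclassified = int((assignment == -1).sum())
    return counts, masks, unclassified


def total_collagen_ratio(birefringent_area_px: float, psr_area_px: float) -> float:
    """Birefringent collagen area over total bright-field PSR stain area."""
    if birefringent_area_px < 0 or psr_area_px < 0:
        raise ValidationError("areas must be nonnegative")
    if psr_area_px == 0:
        raise UndefinedFieldError(
            "total PSR stain area is zero; ratio undefined for this field"
        )
    return float(birefringent_area_px) / float(psr_area_px)


def fiber_thickness_fractions(
    class_counts: Mapping[str, int],
    spec: HueBinSpec | None = None,
) -> tuple[float, float, dict[str, float]]:
    """Thin/thick fiber fractions and per-class fractions of classified pixels."""
    spec = spec or HueBinSpec()
    if any(v < 0 for v in class_counts.values()):
        raise ValidationError("class counts must be nonnegative")
    classified = sum(class_counts.get(c, 0) for c in spec.intervals)
    if classified == 0:
        raise UndefinedFieldError("no classified birefringent pixels in this field")
    thin = sum(class_counts.get(c, 0) for c in spec.thin_classes) / classified
    thick = sum(class_counts.get(c, 0) for c in spec.thick_classes) / classified
    per_class = {c: class_counts.get(c, 0) / classified for c in spec.intervals}
    return thin, thick, per_class


def analyze_psr_field(
    brightfield: RGBImage,
    polarized: RGBImage,
    spec: HueBinSpec | None = None,
    invert_ratio: bool = False,
    **brightfield_gate,
) -> PsrFieldResult:
    """Full per-field analysis of one bright-field / polarized pair."""
    if brightfield.shape != polarized.shape:
        raise ShapeError(
            f"bright-field {brightfield.shape} and polarized {polarized.shape} "
            "images must share a shape"
        )
    spec = spec or HueBinSpec()
    psr_mask = segment_psr_brightfield(brightfield, **brightfield_gate)
    counts, _masks, unclassified = classify_birefringence(polarized, spec)
    birefringent = sum(counts.values())
    ratio = total_collagen_ratio(birefringent, psr_mask.area_px)
    if invert_ratio:
        if ratio == 0:
            raise UndefinedFieldError("birefringent area is zero; inverted ratio undefined")
        ratio = 1.0 / ratio
    try:
        thin, thick, _ = fiber_thickness_fractions(counts, spec)
    except UndefinedFieldError:
        thin = thick = float("nan")
    return PsrFieldResult(
        psr_area_px=psr_mask.area_px,
        class_counts_px=counts,
        unclassified_bright_px=unclassified,
        total_collagen_ratio=ratio,
        thin_fraction=thin,
        thick_fraction=thick,
    )


def analyze_psr_tissue(
    field_pairs: Sequence[tuple[RGBImage, RGBImage]],
    spec: HueBinSpec | None = None,
    invert_ratio: bool = False,
    **brightfield_gate,
) -> PsrTissueResult:
    """Analyze all field pairs of one tissue and average the per-field values.

    Fields with zero PSR stain area are excluded from the means (with a
    warning) rather than poisoning them.
    """
    if len(field_pairs) < 1:
        raise ValidationError("need at least one field pair")
    spec = spec or HueBinSpec()
    results: list[PsrFieldResult] = []
    excluded: list[int] = []
    for i, (bf, pol) in enumerate(field_pairs):
        try:
            results.append(
                analyze_psr_field(bf, pol, spec, invert_ratio, **brightfield_gate)
            )
        except UndefinedFieldError as exc:
            logger.warning("field %d excluded: %s", i, exc)
            excluded.append(i)
    if not results:
        raise UndefinedFieldError("every field was undefined; no tissue means")

    ratios = [r.total_collagen_ratio for r in results]
    thins = [r.thin_fraction for r in results if np.isfinite(r.thin_fraction)]
    thicks = [r.thick_fraction for r in results if np.isfinite(r.thick_fraction)]
    per_class: dict[str, list[float]] = {c: [] for c in spec.intervals}
    for r in results:
        fr = r.class_fractions
        for c in per_class:
            if np.isfinite(fr[c]):
                per_class[c].append(fr[c])
    return PsrTissueResult(
        fields=tuple(results),
        excluded_fields=tuple(excluded),
        mean_total_collagen_ratio=float(np.mean(ratios)),
        mean_thin_fraction=float(np.mean(thins)) if thins else float("nan"),
        mean_thick_fraction=float(np.mean(thicks)) if thicks else float("nan"),
        mean_class_fractions={
            c: (float(np.mean(v)) if v else float("nan")) for c, v in per_class.items()
        },
    )
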