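"""Seeded synthetic-data generators with machine-readable ground truth.

Every pipeline input the package consumes can be fabricated here:
paired bright-field/polarized PSR fields with programmed hue-class
composition, two-channel depot scenes with a programmed nerve-on-vessel
overlap fraction, bimodal-intensity skin sections, and the three CSV
table kinds (NMJ annotations, von Frey trials, dose-response traces).

All generators are pure functions of their spec plus a seed: reruns are
bit-identical.  Scenes are built so that signal pixels pass the relevant
intensity/brightness gates and background does not — a recovery failure
therefore points at the analysis pipeline, not at the fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .collagen_psr import DEFAULT_HUE_INTERVALS, HueBinSpec
from .errors import ValidationError
from .imaging_core import (
    ChannelStack,
    PolygonROI,
    RasterImage,
    RGBImage,
    hsb_to_rgb,
)

__all__ = [
    "GroundTruth",
    "PsrSceneSpec",
    "DepotSceneSpec",
    "gen_psr_pair",
    "gen_depot_scene",
    "gen_ienf_section",
    "gen_tables",
    "DEFAULT_DOSE_LADDER_M",
]

#: Phenylephrine/acetylcholine-style dose ladder, 2 nM to 10 uM (molar).
DEFAULT_DOSE_LADDER_M = (2e-9, 6e-9, 2e-8, 6e-8, 2e-7, 6e-7, 2e-6, 6e-6, 1e-5)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters and true masks/values for one synthetic scene."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    values: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        if key in self.values:
            return self.values[key]
        return self.masks[key]


# ---------------------------------------------------------------------------
# PSR collagen scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsrSceneSpec:
    """Parameters of a synthetic picrosirius-red field pair."""

    shape: tuple[int, int] = (512, 512)
    stained_fraction: float = 0.30
    n_fibers: int = 40
    fiber_width_px: tuple[int, int] = (1, 3)
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"green": 0.45, "yellow": 0.25, "orange": 0.20, "red": 0.10}
    )
    fiber_brightness: float = 200.0
    background_brightness: float = 2.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        fr = dict(self.class_fractions)
        if any(v < 0 for v in fr.values()):
            raise ValidationError("class fractions must be >= 0")
        total = sum(fr.values())
        if total > 1.0 + 1e-9:
            raise ValidationError(f"class fractions sum to {total:.3f} > 1")
        unknown = set(fr) - set(DEFAULT_HUE_INTERVALS)
        if unknown:
            raise ValidationError(f"unknown hue classes {sorted(unknown)}")
        if not 0.0 <= self.stained_fraction <= 1.0:
            raise ValidationError("stained_fraction must lie in [0, 1]")
        if self.fiber_brightness < 35:
            raise ValidationError("fiber brightness must pass the 35-255 gate")
        if self.background_brightness >= 35:
            raise ValidationError("background brightness must fail the 35-255 gate")
        object.__setattr__(self, "class_fractions", fr)


def _draw_fiber_pixels(
    shape: tuple[int, int],
    n_fibers: int,
    width_range: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask of randomly oriented fiber strokes."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_fibers):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        angle = rng.uniform(0, np.pi)
        length = rng.integers(min(h, w) // 4, min(h, w))
        r1 = int(np.clip(r0 + length * np.sin(angle), 0, h - 1))
        c1 = int(np.clip(c0 + length * np.cos(angle), 0, w - 1))
        n_pts = max(abs(r1 - r0), abs(c1 - c0)) + 1
        rr = np.round(np.linspace(r0, r1, n_pts)).astype(int)
        cc = np.round(np.linspace(c0, c1, n_pts)).astype(int)
        stroke = np.zeros(shape, dtype=bool)
        stroke[rr, cc] = True
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        if width > 1:
            stroke = ndimage.binary_dilation(stroke, iterations=width - 1)
        mask |= stroke
    return mask


def _partition_exact(n_items: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder split of n_items into the requested proportions."""
    raw = {k: n_items * v for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = int(round(sum(raw.values()))) - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def gen_psr_pair(
    spec: PsrSceneSpec,
    seed: int,
    hue_spec: HueBinSpec | None = None,
) -> tuple[RGBImage, RGBImage, GroundTruth]:
    """Generate a paired bright-field / polarized PSR field.

    Birefringent fiber pixels are painted with hues sampled inside the
    requested class intervals (exact pixel counts per class by largest-
    remainder apportionment); the bright-field image shows red stain over
    the fibers plus diffuse stained matrix up to ``stained_fraction``.
    """
    rng = np.random.default_rng(seed)
    hue_spec = hue_spec or HueBinSpec()
    h, w = spec.shape
    n_px = h * w

    fiber_mask = _draw_fiber_pixels(spec.shape, spec.n_fibers, spec.fiber_width_px, rng)
    fiber_idx = np.flatnonzero(fiber_mask.ravel())
    rng.shuffle(fiber_idx)
    n_fiber = len(fiber_idx)

    counts = _partition_exact(n_fiber, spec.class_fractions)
    # Paint the polarized image in HSB then convert.
    hue = np.zeros(n_px)
    sat = np.zeros(n_px)
    bright = np.full(n_px, spec.background_brightness)
    pos = 0
    class_masks: dict[str, np.ndarray] = {}
    for cls, n_cls in counts.items():
        idx = fiber_idx[pos : pos + n_cls]
        pos += n_cls
        spans = hue_spec.intervals[cls]
        # sample hues inside the class spans, center-weighted (Beta(3,3))
        # so boundary hues are rare and speckle noise rarely flips class
        widths = np.array([b - a + 1 for a, b in spans], dtype=float)
        which = rng.choice(len(spans), size=n_cls, p=widths / widths.sum())
        lo_edge = np.array([a for a, _ in spans])[which]
        hi_edge = np.array([b for _, b in spans])[which]
        hue[idx] = np.round(lo_edge + (hi_edge - lo_edge) * rng.beta(3.0, 3.0, size=n_cls))
        sat[idx] = 255.0
        bright[idx] = spec.fiber_brightness
        m = np.zeros(n_px, dtype=bool)
        m[idx] = True
        class_masks[cls] = m.reshape(spec.shape)
    birefringent_idx = fiber_idx[:pos]

    pol_rgb = hsb_to_rgb(hue.reshape(spec.shape), sat.reshape(spec.shape), bright.reshape(spec.shape))

    # Bright-field: stain covers the fibers plus diffuse matrix.
    n_stained = int(round(spec.stained_fraction * n_px))
    stained = np.zeros(n_px, dtype=bool)
    stained[fiber_idx] = True
    deficit = n_stained - int(stained.sum())
    if deficit > 0:
        candidates = np.flatnonzero(~stained)
        extra = rng.choice(candidates, size=deficit, replace=False)
        stained[extra] = True
    elif deficit < 0:
        drop = rng.choice(np.flatnonzero(stained), size=-deficit, replace=False)
        stained[drop] = False
    bf_hue = np.where(stained, rng.integers(0, 10, size=n_px).astype(float), 0.0)
    bf_sat = np.where(stained, 220.0, 0.0)
    bf_bright = np.where(stained, 190.0, 255.0)
    bf_rgb = hsb_to_rgb(bf_hue.reshape(spec.shape), bf_sat.reshape(spec.shape), bf_bright.reshape(spec.shape))

    if spec.noise_sd > 0:
        pol_rgb = pol_rgb + rng.normal(0.0, spec.noise_sd, pol_rgb.shape)
        bf_rgb = bf_rgb + rng.normal(0.0, spec.noise_sd, bf_rgb.shape)
    pol_rgb = np.clip(pol_rgb, 0.0, 255.0)
    bf_rgb = np.clip(bf_rgb, 0.0, 255.0)

    classified = sum(counts.values())
    thin = sum(counts[c] for c in hue_spec.thin_classes if c in counts)
    thick = sum(counts[c] for c in hue_spec.thick_classes if c in counts)
    truth = GroundTruth(
        masks={
            "stained": stained.reshape(spec.shape),
            "birefringent": np.isin(
                np.arange(n_px), birefringent_idx, assume_unique=False
            ).reshape(spec.shape),
            **{f"class_{c}": m for c, m in class_masks.items()},
        },
        values={
            "class_counts": counts,
            "stained_px": int(stained.sum()),
            "birefringent_px": classified,
            "total_collagen_ratio": classified / max(int(stained.sum()), 1),
            "thin_fraction": thin / classified if classified else float("nan"),
            "thick_fraction": thick / classified if classified else float("nan"),
            "seed": seed,
        },
    )
    return (
        RGBImage.from_array(bf_rgb),
        RGBImage.from_array(pol_rgb),
        truth,
    )


# ---------------------------------------------------------------------------
# Depot (nerve/vessel) scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepotSceneSpec:
    """Parameters of a synthetic two-channel nerve/vessel scene."""

    shape: tuple[int, int] = (512, 512)
    n_slices: int = 3
    z_step_um: float = 2.5
    n_vessel_walks: int = 4
    vessel_radius_px: int = 2
    branch_prob: float = 0.01
    n_nerve_px: int = 2000
    overlap_fraction: float = 0.5
    nerve_intensity: float = 255.0
    vessel_intensity: float = 200.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValidationError("overlap_fraction must lie in [0, 1]")
        if self.n_nerve_px < 1:
            raise ValidationError("n_nerve_px must be >= 1")
        if self.n_nerve_px > self.shape[0] * self.shape[1] // 4:
            raise ValidationError("nerve density infeasible for scene size")


def _vessel_tree(spec: DepotSceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Vessel mask from seeded branching random walks with disk-shaped cross-section."""
    h, w = spec.shape
    mask = np.zeros(spec.shape, dtype=bool)
    stack = []
    for _ in range(spec.n_vessel_walks):
        edge = rng.integers(0, 4)
        if edge == 0:
            pos = np.array([0.0, rng.uniform(0, w)])
        elif edge == 1:
            pos = np.array([h - 1.0, rng.uniform(0, w)])
        elif edge == 2:
            pos = np.array([rng.uniform(0, h), 0.0])
        else:
            pos = np.array([rng.uniform(0, h), w - 1.0])
        # head toward the image center (with jitter) so walks stay in frame
        center = np.array([h / 2.0, w / 2.0])
        heading = float(np.arctan2(*(center - pos))) + rng.normal(0.0, 0.4)
        stack.append((pos, heading, int(min(h, w) * 1.5)))
    path = np.zeros(spec.shape, dtype=bool)
    while stack:
        pos, heading, steps = stack.pop()
        for _ in range(steps):
            heading += rng.normal(0.0, 0.15)
            pos = pos + np.array([np.sin(heading), np.cos(heading)])
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < h and 0 <= c < w):
                break
            path[r, c] = True
            if rng.random() < spec.branch_prob and len(stack) < 16:
                stack.append((pos.copy(), heading + rng.uniform(-1.2, 1.2), steps // 2))
    if spec.vessel_radius_px > 0:
        mask = ndimage.binary_dilation(path, iterations=spec.vessel_radius_px)
    else:
        mask = path
    return mask


def gen_depot_scene(
    spec: DepotSceneSpec,
    seed: int,
) -> tuple[ChannelStack, ChannelStack, PolygonROI, GroundTruth]:
    """Two-channel depot scene with a programmed nerve-on-vessel fraction.

    A fraction ``overlap_fraction`` of the nerve pixels is placed on
    vessel interior pixels; the rest are kept well clear of the vessel
    tree (outside its filled, dilated footprint) so that the programmed
    fraction survives the vessel-mask morphology of the analysis chain.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    vessel_mask = _vessel_tree(spec, rng)
    if not vessel_mask.any():
        raise ValidationError("vessel tree generation produced no vessel pixels")

    interior = ndimage.binary_erosion(vessel_mask, iterations=1)
    on_candidates = np.flatnonzero((interior if interior.any() else vessel_mask).ravel())
    exclusion = ndimage.binary_fill_holes(ndimage.binary_dilation(vessel_mask, iterations=3))
    off_candidates = np.flatnonzero(~exclusion.ravel())

    n_on = int(round(spec.overlap_fraction * spec.n_nerve_px))
    n_off = spec.n_nerve_px - n_on
    if n_on > len(on_candidates) or n_off > len(off_candidates):
        raise ValidationError("requested nerve density infeasible for this vessel tree")
    on_idx = rng.choice(on_candidates, size=n_on, replace=False)
    off_idx = rng.choice(off_candidates, size=n_off, replace=False)
    nerve_mask = np.zeros(h * w, dtype=bool)
    nerve_mask[on_idx] = True
    nerve_mask[off_idx] = True
    nerve_mask = nerve_mask.reshape(spec.shape)

    # Distribute signal over Z: each signal pixel lives in one random slice.
    def to_stack(sig_mask: np.ndarray, intensity: float, label: str) -> ChannelStack:
        slices = np.zeros((spec.n_slices, h, w))
        slice_of = rng.integers(0, spec.n_slices, size=int(sig_mask.sum()))
        rr, cc = np.nonzero(sig_mask)
        slices[slice_of, rr, cc] = intensity
        if spec.noise_sd > 0:
            slices = slices + rng.normal(0.0, spec.noise_sd, slices.shape)
        slices = np.clip(slices, 0.0, 255.0)
        return ChannelStack(
            tuple(RasterImage(s, channel_label=label) for s in slices),
            z_step_um=spec.z_step_um,
        )

    nerve_stack = to_stack(nerve_mask, spec.nerve_intensity, "nerve")
    vessel_stack = ChannelStack(
        tuple(
            RasterImage(
                np.clip(
                    vessel_mask * spec.vessel_intensity
                    + (rng.normal(0.0, spec.noise_sd, spec.shape) if spec.noise_sd > 0 else 0.0),
                    0.0,
                    255.0,
                ),
                channel_label="vessel",
            )
            for _ in range(spec.n_slices)
        ),
        z_step_um=spec.z_step_um,
    )

    margin = 2
    roi = PolygonROI(
        np.array(
            [
                [margin, margin],
                [margin, w - margin],
                [h - margin, w - margin],
                [h - margin, margin],
            ],
            dtype=float,
        )
    )
    truth = GroundTruth(
        masks={"vessel": vessel_mask, "nerve": nerve_mask},
        values={
            "overlap_fraction": spec.overlap_fraction,
            "n_nerve_px": spec.n_nerve_px,
            "n_on_vessel": n_on,
            "seed": seed,
        },
    )
    return nerve_stack, vessel_stack, roi, truth


# ---------------------------------------------------------------------------
# IENF skin sections
# ---------------------------------------------------------------------------

def gen_ienf_section(
    fiber_fraction: float,
    seed: int,
    shape: tuple[int, int] = (256, 256),
    background_intensity: float = 40.0,
    fiber_intensity: float = 200.0,
    noise_sd: float = 0.0,
    band: tuple[float, float] = (0.30, 0.60),
) -> tuple[RasterImage, PolygonROI, GroundTruth]:
    """Skin section with a bimodal-intensity epidermal band.

    Exactly ``round(fiber_fraction x ROI area)`` pixels inside the
    epidermal band carry the fiber intensity; the rest sit at the
    autofluorescence level, giving a two-mode ROI histogram by
    construction (one mode when ``fiber_fraction`` is 0, which is itself
    a useful degenerate test case).
    """
    if not 0.0 <= fiber_fraction <= 0.5:
        raise ValidationError("fiber_fraction must lie in [0, 0.5]")
    if abs(fiber_intensity - background_intensity) < 20:
        raise ValidationError("fiber and background intensity modes must be separated")
    rng = np.random.default_rng(seed)
    h, w = shape
    r_top, r_bot = int(band[0] * h), int(band[1] * h)
    img = np.full(shape, background_intensity)

    roi = PolygonROI(
        np.array([[r_top, 0], [r_top, w], [r_bot, w], [r_bot, 0]], dtype=float)
    )
    band_rows = np.arange(r_top, r_bot)
    roi_area = len(band_rows) * w
    n_fiber = int(round(fiber_fraction * roi_area))

    fiber = np.zeros(shape, dtype=bool)
    if n_fiber > 0:
        # wiggly near-vertical strokes crossing the band, trimmed/padded
        # to the exact programmed pixel count
        n_strokes = max(3, n_fiber // max(len(band_rows), 1))
        for _ in range(n_strokes):
            c = float(rng.uniform(0, w))
            for r in band_rows:
                c += rng.normal(0.0, 0.7)
                ci = int(np.clip(round(c), 0, w - 1))
                fiber[r, ci] = True
        flat = np.flatnonzero(fiber.ravel())
        if len(flat) > n_fiber:
            drop = rng.choice(flat, size=len(flat) - n_fiber, replace=False)
            fiber.ravel()[drop] = False
        elif len(flat) < n_fiber:
            band_flat = np.zeros(shape, dtype=bool)
            band_flat[r_top:r_bot, :] = True
            candidates = np.flatnonzero(band_flat.ravel() & ~fiber.ravel())
            add = rng.choice(candidates, size=n_fiber - len(flat), replace=False)
            fiber.ravel()[add] = True
    img[fiber] = fiber_intensity
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, shape), 0.0, 255.0)

    truth = GroundTruth(
        masks={"fiber": fiber},
        values={
            "fiber_fraction": fiber_fraction,
            "n_fiber_px": int(fiber.sum()),
            "roi_area_px": roi_area,
            "seed": seed,
        },
    )
    return RasterImage(img, channel_label="pan-neuronal"), roi, truth


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _gen_nmj_table(params: Mapping[str, Any], rng: np.random.Generator) -> tuple[pd.DataFrame, GroundTruth]:
    n_tissues = int(params.get("n_tissues", 3))
    n_junctions = int(params.get("n_junctions", 50))
    p_occupied = float(params.get("p_occupied", 0.8))
    p_altered = float(params.get("p_altered", 0.1))
    tsc_lambda = float(params.get("tsc_lambda", 3.0))
    if p_occupied + p_altered > 1.0:
        raise ValidationError("p_occupied + p_altered must be <= 1")
    probs = [p_occupied, p_altered, max(0.0, 1.0 - p_occupied - p_altered)]
    probs = [p / sum(probs) for p in probs]
    rows = []
    for t in range(n_tissues):
        statuses = rng.choice(["occupied", "altered", "unoccupied"], size=n_junctions, p=probs)
        tsc = rng.poisson(tsc_lambda, size=n_junctions)
        for j, (s, k) in enumerate(zip(statuses, tsc)):
            rows.append({"tissue": f"T{t}", "junction": f"J{j}", "status": s, "tsc_count": int(k)})
    df = pd.DataFrame(rows)
    truth = GroundTruth(values={"p_occupied": p_occupied, "p_altered": p_altered, "tsc_lambda": tsc_lambda, "n_junctions": n_junctions})
    return df, truth


def _gen_vonfrey_table(params: Mapping[str, Any], rng: np.random.Generator) -> tuple[pd.DataFrame, GroundTruth]:
    strengths = tuple(params.get("strengths_g", (4.00, 2.00, 1.00, 0.40, 0.02)))
    n_trials = int(params.get("n_trials", 5))
    n_animals = int(params.get("n_animals", 1))
    s50 = float(params.get("s50_g", 1.0))
    slope = float(params.get("slope", 2.0))
    p_max = float(params.get("p_max", 1.0))
    rows = []
    p_by_strength = {}
    for s in strengths:
        p = p_max / (1.0 + (s50 / s) ** slope)
        p_by_strength[s] = p
    for a in range(n_animals):
        for s in strengths:
            outcomes = rng.random(n_trials) < p_by_strength[s]
            for t, o in enumerate(outcomes):
                rows.append({"animal": f"A{a}", "filament_g": s, "trial": t, "response": int(o)})
    df = pd.DataFrame(rows)
    truth = GroundTruth(values={"s50_g": s50, "slope": slope, "p_max": p_max, "p_by_strength": p_by_strength})
    return df, truth


def _gen_dose_response_table(params: Mapping[str, Any], rng: np.random.Generator) -> tuple[pd.DataFrame, GroundTruth]:
    doses = tuple(params.get("doses_m", DEFAULT_DOSE_LADDER_M))
    bottom = float(params.get("bottom", 0.0))
    top = float(params.get("top", 100.0))
    # defaults are typical of phenylephrine aortic contraction: EC50 in the
    # middle of the ladder with a moderately steep slope
    hill = float(params.get("hill", 2.0))
    ec50 = float(params.get("ec50_m", 2e-7))
    noise_pct = float(params.get("noise_pct", 0.0))
    doses_arr = np.asarray(doses)
    resp = bottom + (top - bottom) / (1.0 + (ec50 / doses_arr) ** hill)
    if noise_pct > 0:
        resp = resp + rng.normal(0.0, noise_pct / 100.0 * (top - bottom), size=resp.shape)
    df = pd.DataFrame({"dose_M": doses_arr, "response_pct": resp})
    truth = GroundTruth(values={"bottom": bottom, "top": top, "hill": hill, "ec50_m": ec50, "noise_pct": noise_pct})
    return df, truth


def gen_tables(
    kind: str,
    params: Mapping[str, Any] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a CSV-shaped fixture table of the given kind.

    ``kind`` is one of ``'nmj'``, ``'vonfrey'``, ``'dose_response'``.
    Von Frey positives are drawn per filament from a logistic
    psychometric function, NMJ statuses from a multinomial, and
    dose-response points from a 4PL curve plus optional Gaussian noise.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    if kind == "nmj":
        return _gen_nmj_table(params, rng)
    if kind == "vonfrey":
        return _gen_vonfrey_table(params, rng)
    if kind == "dose_response":
        return _gen_dose_response_table(params, rng)
    raise ValidationError(f"unknown table kind {kind!r}")
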