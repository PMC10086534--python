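"""Sensory and vascular physiology readouts.

Von Frey monofilament response curves with trapezoidal area-under-curve,
and wire-myography dose-response normalization with four-parameter
logistic (4PL) EC50 fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, ValidationError

__all__ = [
    "DEFAULT_FILAMENTS_G",
    "VonFreyTable",
    "SensitivityCurve",
    "DoseResponse",
    "EC50Fit",
    "response_curve",
    "vonfrey_auc",
    "normalize_contraction",
    "normalize_relaxation",
    "fit_ec50",
    "read_vonfrey_csv",
]

#: Conventional filament set, in grams.
DEFAULT_FILAMENTS_G = (4.00, 2.00, 1.00, 0.40, 0.02)
DEFAULT_TRIALS_PER_FILAMENT = 5


@dataclass(frozen=True)
class VonFreyTable:
    """Trial outcomes for one animal: filament strength (g) -> boolean trials."""

    trials: Mapping[float, tuple[bool, ...]]
    trials_per_filament: int = DEFAULT_TRIALS_PER_FILAMENT

    def __post_init__(self) -> None:
        if len(self.trials) == 0:
            raise ValidationError("no filaments in table")
        cleaned: dict[float, tuple[bool, ...]] = {}
        for strength, outcomes in self.trials.items():
            s = float(strength)
            if not s > 0:
                raise ValidationError(f"filament strength must be > 0, got {s}")
            if s in cleaned:
                raise ValidationError(f"duplicate filament strength {s}")
            outcomes = tuple(bool(o) for o in outcomes)
            if len(outcomes) != self.trials_per_filament:
                raise ValidationError(
                    f"filament {s} g has {len(outcomes)} trials, "
                    f"expected {self.trials_per_filament}"
                )
            cleaned[s] = outcomes
        object.__setattr__(self, "trials", cleaned)


@dataclass(frozen=True)
class SensitivityCurve:
    """Response fractions ordered by ascending filament strength."""

    strengths_g: tuple[float, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.strengths_g) != len(self.fractions):
            raise ValidationError("strengths and fractions must align")
        if any(not 0 <= f <= 1 for f in self.fractions):
            raise ValidationError("fractions must lie in [0, 1]")
        if any(
            b <= a for a, b in zip(self.strengths_g, self.strengths_g[1:])
        ):
            raise ValidationError("strengths must be strictly ascending")


@dataclass(frozen=True)
class DoseResponse:
    """Dose ladder (molar, ascending) with responses in percent."""

    doses_m: tuple[float, ...]
    responses_pct: tuple[float, ...]

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses_m)
        if len(doses) != len(self.responses_pct):
            raise ValidationError("doses and responses must align")
        if any(d <= 0 for d in doses):
            raise ValidationError("doses must be positive")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValidationError("doses must be strictly increasing")
        object.__setattr__(self, "doses_m", doses)
        object.__setattr__(
            self, "responses_pct", tuple(float(r) for r in self.responses_pct)
        )


@dataclass(frozen=True)
class EC50Fit:
    """Canonicalized 4PL parameters (bottom <= top) with fit diagnostics."""

    bottom: float
    top: float
    hill_slope: float
    ec50_m: float
    rss: float


# ---------------------------------------------------------------------------
# Von Frey
# ---------------------------------------------------------------------------

def response_curve(table: VonFreyTable) -> SensitivityCurve:
    """Per-filament response fraction (positives / trials), ascending strength."""
    strengths = sorted(table.trials)
    fractions = [sum(table.trials[s]) / len(table.trials[s]) for s in strengths]
    return SensitivityCurve(tuple(strengths), tuple(fractions))


def vonfrey_auc(curve: SensitivityCurve) -> float:
    """Trapezoidal area under the response curve on a linear gram axis."""
    if len(curve.strengths_g) < 2:
        raise ValidationError("AUC needs at least 2 filaments")
    return float(np.trapezoid(curve.fractions, curve.strengths_g))


def read_vonfrey_csv(path: str | Path) -> dict[str, VonFreyTable]:
    """Read a long-format trial table (columns: animal, filament_g, trial, response)."""
    df = pd.read_csv(path)
    required = {"animal", "filament_g", "trial", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"von Frey CSV missing columns: {sorted(missing)}")
    tables: dict[str, VonFreyTable] = {}
    for animal, adf in df.groupby("animal"):
        trials: dict[float, tuple[bool, ...]] = {}
        n_trials = None
        for strength, fdf in adf.groupby("filament_g"):
            outcomes = tuple(bool(int(v)) for v in fdf.sort_values("trial")["response"])
            trials[float(strength)] = outcomes
            n_trials = len(outcomes)
        tables[str(animal)] = VonFreyTable(trials, trials_per_filament=n_trials or 0)
    return tables


# ---------------------------------------------------------------------------
# Myography
# ---------------------------------------------------------------------------

def normalize_contraction(
    trace_peaks: Mapping[float, float] | Sequence[tuple[float, float]],
    kcl_max: float,
) -> DoseResponse:
    """Contraction as percent of maximal KCl contraction."""
    if not kcl_max > 0:
        raise ValidationError("kcl_max must be > 0")
    items = sorted(dict(trace_peaks).items())
    doses = tuple(d for d, _ in items)
    responses = tuple(100.0 * f / kcl_max for _, f in items)
    return DoseResponse(doses, responses)


def normalize_relaxation(
    trace: Mapping[float, float] | Sequence[tuple[float, float]],
    precontraction: float,
) -> DoseResponse:
    """Relaxation as percent of the pre-contraction force."""
    if not precontraction > 0:
        raise ValidationError("precontraction must be > 0")
    items = sorted(dict(trace).items())
    doses = tuple(d for d, _ in items)
    responses = tuple(
        100.0 * (precontraction - f) / precontraction for _, f in items
    )
    return DoseResponse(doses, responses)


def _four_pl(log_dose: np.ndarray, bottom: float, top: float, hill: float, log_ec50: float) -> np.ndarray:
    # response = bottom + (top - bottom) / (1 + (ec50/dose)^hill), on log10 dose
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - log_dose)))


def fit_ec50(dr: DoseResponse, min_span_pct: float = 1e-6) -> EC50Fit:
    """Least-squares 4PL fit on log dose; returns canonicalized parameters.

    Deterministic initialization: bottom/top from the response extrema,
    EC50 at the dose whose response is nearest half-range, Hill slope 1.
    EC50 is bounded within [min dose / 10, max dose x 10].  Degenerate
    (flat) data raise :class:`~adiposcope.errors.FitError`.
    """
    doses = np.asarray(dr.doses_m, dtype=np.float64)
    resp = np.asarray(dr.responses_pct, dtype=np.float64)
    if len(doses) < 4:
        raise FitError("4PL fit needs at least 4 doses")
    span = resp.max() - resp.min()
    if span <= min_span_pct:
        raise FitError(
            f"responses are flat (span {span:.3g}); EC50 undefined"
        )
    log_d = np.log10(doses)
    half = resp.min() + span / 2.0
    ec50_init = doses[int(np.argmin(np.abs(resp - half)))]
    x0 = np.array([resp.min(), resp.max(), 1.0, np.log10(ec50_init)])
    lo = np.array([-np.inf, -np.inf, -50.0, np.log10(doses.min() / 10.0)])
    hi = np.array([np.inf, np.inf, 50.0, np.log10(doses.max() * 10.0)])

    def residuals(p: np.ndarray) -> np.ndarray:
        return _four_pl(log_d, *p) - resp

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise FitError(f"4PL fit did not converge: {sol.message}")
    bottom, top, hill, log_ec50 = sol.x
    rss = float(np.sum(sol.fun**2))
    flat_rss = float(np.sum((resp - resp.mean()) ** 2))
    if rss > flat_rss * (1.0 + 1e-9):
        raise FitError("4PL fit no better than a flat model; data degenerate")
    # Canonical form: bottom <= top (flip hill sign to compensate).
    if bottom > top:
        bottom, top, hill = top, bottom, -hill
    return EC50Fit(
        bottom=float(bottom),
        top=float(top),
        hill_slope=float(hill),
        ec50_m=float(10.0**log_ec50),
        rss=rss,
    )
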