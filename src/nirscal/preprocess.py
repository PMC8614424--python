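"""Scatter corrections and WinISI-style math treatments.

A pretreatment pairs a scatter correction (SNV, detrend, MSC variants,
mean-scaling) with a math treatment written as four numerals
"derivative, gap, smooth, smooth2" — e.g. "1,4,4,1" is a first
derivative over a 4-point gap after a 4-point running average.  Scatter
correction is applied first, then the math treatment; derivatives and
smoothing trim the wavelength grid rather than padding, and the trimmed
grid travels with the output.

MSC is the only set-level operator: its reference mean spectrum (and,
for the weighted variant, per-wavelength weights) is fitted on the
calibration set only and replayed unchanged on validation samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset import SpectraSet
from .errors import DegenerateSpectrumError, GridError, WindowError

SCATTER_LABELS = (
    "none",
    "snv_only",
    "detrend_only",
    "snv_detrend",
    "msc_standard",
    "msc_weighted",
    "scale_linear",
    "scale_quadratic",
)

# short codes used in the "1,4,4,1+SNV" serialization
_SCATTER_CODE = {
    "none": "none",
    "snv_only": "SNV",
    "detrend_only": "DT",
    "snv_detrend": "SNV-DT",
    "msc_standard": "MSC",
    "msc_weighted": "WMSC",
    "scale_linear": "SL",
    "scale_quadratic": "SQ",
}
_CODE_SCATTER = {v: k for k, v in _SCATTER_CODE.items()}

_MSC_EPS = 1e-8    # floor on residual variance in weighted-MSC weights
_MSC_B_TOL = 1e-12 # |slope| below this aborts the MSC inversion


@dataclass(frozen=True)
class MathTreatment:
    """Four-numeral math treatment: derivative order, gap, two smooths."""

    derivative: int
    gap: int
    smooth1: int
    smooth2: int

    def __post_init__(self) -> None:
        if self.derivative not in (0, 1, 2):
            raise ValueError(f"derivative order must be 0, 1 or 2, got {self.derivative}")
        if self.derivative and self.gap < 1:
            raise ValueError("gap must be >= 1 for derivative treatments")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.smooth1 < 1 or self.smooth2 < 1:
            raise ValueError("smoothing widths must be >= 1")

    def __str__(self) -> str:
        return f"{self.derivative},{self.gap},{self.smooth1},{self.smooth2}"

    @classmethod
    def parse(cls, text: str) -> "MathTreatment":
        parts = [int(p) for p in text.replace(" ", "").split(",")]
        if len(parts) != 4:
            raise ValueError(f"expected four numerals, got {text!r}")
        return cls(*parts)


@dataclass(frozen=True)
class Pretreatment:
    """A math treatment paired with a scatter correction label."""

    math: MathTreatment
    scatter: str = "none"

    def __post_init__(self) -> None:
        if self.scatter not in SCATTER_LABELS:
            raise ValueError(
                f"unknown scatter correction {self.scatter!r}; "
                f"choose one of {SCATTER_LABELS}"
            )

    def __str__(self) -> str:
        return f"{self.math}+{_SCATTER_CODE[self.scatter]}"

    @classmethod
    def parse(cls, text: str) -> "Pretreatment":
        math_part, _, scatter_part = text.partition("+")
        scatter = scatter_part.strip() or "none"
        if scatter in _CODE_SCATTER:
            scatter = _CODE_SCATTER[scatter]
        return cls(math=MathTreatment.parse(math_part), scatter=scatter)


@dataclass
class ScatterState:
    """Fitted state a scatter correction needs to replay on new samples.

    Only the MSC variants carry state (the calibration mean spectrum and,
    for weighted MSC, per-wavelength weights); the rest are row-local.
    """

    kind: str
    grid: np.ndarray | None = None
    mean: np.ndarray | None = None
    weights: np.ndarray | None = None


# ---------------------------------------------------------------------------
# row-local corrections
# ---------------------------------------------------------------------------

def snv(rows: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to mean 0,
    population SD 1."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    mean = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, keepdims=True)  # divisor n
    if np.any(sd <= 0):
        i = int(np.argmax(sd.ravel() <= 0))
        raise DegenerateSpectrumError(f"constant spectrum (row {i}) cannot be SNV-scaled")
    return (rows - mean) / sd


def _poly_basis(wavelengths: np.ndarray, degree: int) -> np.ndarray:
    # orthonormal polynomial basis on a conditioning-friendly scaled axis
    x = (wavelengths - wavelengths.mean()) / (np.ptp(wavelengths) / 2)
    v = np.vander(x, degree + 1, increasing=True)
    q, _ = np.linalg.qr(v)
    return q  # (p, degree+1)


def detrend(rows: np.ndarray, wavelengths: np.ndarray, degree: int = 2) -> np.ndarray:
    """Remove each spectrum's least-squares polynomial baseline in wavelength."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if degree not in (1, 2):
        raise ValueError("detrend degree must be 1 or 2")
    if rows.shape[1] <= degree + 1:
        raise WindowError("spectrum too short for the detrend degree")
    q = _poly_basis(np.asarray(wavelengths, dtype=float), degree)
    return rows - (rows @ q) @ q.T


def scale_polynomial(
    rows: np.ndarray, wavelengths: np.ndarray, degree: int
) -> np.ndarray:
    """Divide each spectrum by its own mean, then detrend at ``degree``.

    This is the reading adopted for the WinISI "Scale and linear /
    quadratic" treatments; it makes the result invariant to per-sample
    multiplicative scaling.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    mean = rows.mean(axis=1, keepdims=True)
    if np.any(mean == 0):
        raise DegenerateSpectrumError("zero-mean spectrum cannot be mean-scaled")
    return detrend(rows / mean, wavelengths, degree)


# ---------------------------------------------------------------------------
# MSC (set-level)
# ---------------------------------------------------------------------------

def fit_msc(calibration: SpectraSet, weighted: bool = False) -> ScatterState:
    """Fit MSC state on the calibration set.

    Weighted MSC uses per-wavelength weights 1 / max(residual variance
    about the mean across calibration samples, eps) — an interpretation,
    since the originating software does not document its weighting.
    """
    if calibration.n_samples < 2:
        raise DegenerateSpectrumError("MSC needs at least two calibration samples")
    mean = calibration.absorbance.mean(axis=0)
    weights = None
    if weighted:
        resid_var = ((calibration.absorbance - mean) ** 2).mean(axis=0)
        weights = 1.0 / np.maximum(resid_var, _MSC_EPS)
    kind = "msc_weighted" if weighted else "msc_standard"
    return ScatterState(kind=kind, grid=calibration.wavelengths.copy(),
                        mean=mean, weights=weights)


def apply_msc(rows: np.ndarray, state: ScatterState) -> np.ndarray:
    """Regress each spectrum on the stored mean (with intercept; WLS for
    the weighted variant) and return (row - intercept) / slope."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    m = state.mean
    if m is None or rows.shape[1] != m.size:
        raise GridError("MSC state fitted on a different wavelength grid")
    w = state.weights if state.weights is not None else np.ones_like(m)
    sw = w.sum()
    mw = (w * m).sum() / sw
    xw = (rows * w).sum(axis=1) / sw
    mvar = (w * (m - mw) ** 2).sum() / sw
    cov = ((rows - xw[:, None]) * (m - mw) * w).sum(axis=1) / sw
    b = cov / mvar
    if np.any(np.abs(b) < _MSC_B_TOL):
        raise DegenerateSpectrumError("MSC regression slope ~ 0; cannot invert")
    a = xw - b * mw
    return (rows - a[:, None]) / b[:, None]


# ---------------------------------------------------------------------------
# math treatment
# ---------------------------------------------------------------------------

def _boxcar(rows: np.ndarray, wavelengths: np.ndarray, width: int):
    if width == 1:
        return rows, wavelengths
    if rows.shape[1] < width:
        raise WindowError(
            f"spectrum of {rows.shape[1]} points shorter than smoothing "
            f"window {width}"
        )
    sw = np.lib.stride_tricks.sliding_window_view(rows, width, axis=1)
    out = sw.mean(axis=-1)
    wl = np.lib.stride_tricks.sliding_window_view(wavelengths, width).mean(axis=-1)
    return out, wl


def _derivative(rows, wavelengths, order: int, gap: int):
    if order == 0:
        return rows, wavelengths
    if order == 1:
        h = math.ceil(gap / 2)
        if rows.shape[1] <= 2 * h:
            raise WindowError("spectrum too short for the derivative gap")
        out = rows[:, 2 * h:] - rows[:, :-2 * h]
        wl = wavelengths[h:-h]
        return out, wl
    g = gap
    if rows.shape[1] <= 2 * g:
        raise WindowError("spectrum too short for the derivative gap")
    out = rows[:, 2 * g:] - 2 * rows[:, g:-g] + rows[:, :-2 * g]
    wl = wavelengths[g:-g]
    return out, wl


def apply_math_treatment(s: SpectraSet, t: MathTreatment) -> SpectraSet:
    """Apply smooth -> gap derivative -> secondary smooth, trimming the
    grid wherever a window is incomplete.

    Derivatives are symmetric finite differences over the stated gap
    (order 1: y(i+h) - y(i-h) with h = ceil(gap/2); order 2:
    y(i+g) - 2 y(i) + y(i-g) with g = gap); smoothing is a running
    average ("boxcar").  Differences are not divided by the wavelength
    step — the scale is absorbed by the regression.
    """
    rows, wl = _boxcar(s.absorbance, s.wavelengths, t.smooth1)
    rows, wl = _derivative(rows, wl, t.derivative, t.gap)
    rows, wl = _boxcar(rows, wl, t.smooth2)
    if rows.shape[1] < 2:
        raise WindowError("math treatment consumed the whole spectrum")
    return s.with_matrix(rows, wl)


# ---------------------------------------------------------------------------
# full pretreatment
# ---------------------------------------------------------------------------

def _apply_scatter(
    s: SpectraSet, scatter: str, state: ScatterState | None
) -> tuple[SpectraSet, ScatterState]:
    if scatter == "none":
        return s, state or ScatterState(kind="none")
    if scatter == "snv_only":
        return s.with_matrix(snv(s.absorbance)), state or ScatterState(kind=scatter)
    if scatter == "detrend_only":
        return (
            s.with_matrix(detrend(s.absorbance, s.wavelengths, degree=2)),
            state or ScatterState(kind=scatter),
        )
    if scatter == "snv_detrend":
        out = detrend(snv(s.absorbance), s.wavelengths, degree=2)
        return s.with_matrix(out), state or ScatterState(kind=scatter)
    if scatter == "scale_linear":
        return (
            s.with_matrix(scale_polynomial(s.absorbance, s.wavelengths, 1)),
            state or ScatterState(kind=scatter),
        )
    if scatter == "scale_quadratic":
        return (
            s.with_matrix(scale_polynomial(s.absorbance, s.wavelengths, 2)),
            state or ScatterState(kind=scatter),
        )
    if scatter in ("msc_standard", "msc_weighted"):
        if state is None:
            state = fit_msc(s, weighted=(scatter == "msc_weighted"))
        elif state.kind != scatter:
            raise GridError(
                f"scatter state of kind {state.kind!r} cannot apply {scatter!r}"
            )
        return s.with_matrix(apply_msc(s.absorbance, state)), state
    raise ValueError(f"unknown scatter correction {scatter!r}")


def apply_pretreatment(
    s: SpectraSet,
    p: Pretreatment,
    state: ScatterState | None = None,
) -> tuple[SpectraSet, ScatterState]:
    """Scatter correction first, then the math treatment.

    When ``state`` is absent and the scatter correction is an MSC
    variant, ``s`` is taken to be the calibration set and the state is
    fitted on it; pass the returned state to process validation samples
    identically.
    """
    corrected, state = _apply_scatter(s, p.scatter, state)
    return apply_math_treatment(corrected, p.math), state
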