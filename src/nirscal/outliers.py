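"""Spectral (PCA/Mahalanobis GH) and compositional (3xSECV) outlier screens.

GH is the Mahalanobis distance of a sample in standardized PCA score
space divided by the number of retained components, so its mean over the
fitting set is 1 by construction; samples above a threshold (3.0 by
convention) are atypical spectra regardless of chemistry.  The
compositional screen removes calibration samples whose cross-validated
prediction error exceeds a multiple (3 by convention) of the SECV —
samples whose chemistry disagrees with their spectrum — and refits, for
a bounded number of passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import SpectraSet
from .errors import ScreeningError
from .mpls import (
    DEFAULT_CV_GROUPS,
    DEFAULT_MAX_FACTORS,
    DEFAULT_SECV_TOLERANCE,
    CVResult,
    MPLSModel,
    cross_validate,
    fit_mpls,
    predict,
)

log = logging.getLogger(__name__)

DEFAULT_GH_THRESHOLD = 3.0
DEFAULT_GH_VARIANCE = 0.99
DEFAULT_GH_MAX_COMPONENTS = 20
DEFAULT_SECV_MULTIPLIER = 3.0
DEFAULT_MAX_PASSES = 2

_MIN_GH_SAMPLES = 10


@dataclass
class GHReport:
    """Per-sample GH values and the keep decision."""

    sample_ids: list[str]
    gh: np.ndarray
    n_components: int
    threshold: float

    @property
    def keep(self) -> np.ndarray:
        return self.gh <= self.threshold

    @property
    def kept_ids(self) -> list[str]:
        return [s for s, k in zip(self.sample_ids, self.keep) if k]


def pca_gh_screen(
    s: SpectraSet,
    threshold: float = DEFAULT_GH_THRESHOLD,
    variance: float = DEFAULT_GH_VARIANCE,
    max_components: int = DEFAULT_GH_MAX_COMPONENTS,
) -> GHReport:
    """Score spectra by GH = (Mahalanobis distance)^2 / K in PCA space.

    PCA is run on centered spectra; the smallest component count
    explaining at least ``variance`` of the total (capped at
    ``max_components`` and n - 1) is retained, scores are standardized
    by their population SDs, and GH_i = sum_k (score_ik / SD_k)^2 / K.
    """
    n = s.n_samples
    if n < _MIN_GH_SAMPLES:
        raise ScreeningError(
            f"GH screening needs >= {_MIN_GH_SAMPLES} samples, got {n}"
        )
    Xc = s.absorbance - s.absorbance.mean(axis=0)
    u, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    var = sv**2
    total = var.sum()
    if total == 0:
        raise ScreeningError("all spectra identical; GH undefined")
    frac = np.cumsum(var) / total
    k = int(np.argmax(frac >= variance)) + 1
    k = min(k, max_components, n - 1)
    scores = u[:, :k] * sv[:k]           # (n, k)
    sd = sv[:k] / np.sqrt(n)             # population SD of each score column
    gh = ((scores / sd) ** 2).sum(axis=1) / k
    flagged = int((gh > threshold).sum())
    log.info(
        "GH screen: %d components, %d/%d samples flagged at GH > %g",
        k, flagged, n, threshold,
    )
    return GHReport(
        sample_ids=list(s.sample_ids), gh=gh, n_components=k, threshold=threshold
    )


@dataclass
class CompositionalScreenResult:
    """Cumulative keep-mask plus the model fitted on the kept samples."""

    keep: np.ndarray          # (n,) over the input order
    model: MPLSModel
    cv: CVResult              # final cross-validation on the kept set
    n_passes: int
    removed_per_pass: list[int]


def compositional_screen(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = DEFAULT_CV_GROUPS,
    multiplier: float = DEFAULT_SECV_MULTIPLIER,
    max_passes: int = DEFAULT_MAX_PASSES,
    max_factors: int = DEFAULT_MAX_FACTORS,
    seed: int = 0,
    standardize_residuals: bool = True,
    secv_tolerance: float = DEFAULT_SECV_TOLERANCE,
) -> CompositionalScreenResult:
    """Iteratively drop samples with |cv error| > multiplier x SECV.

    Each pass cross-validates on the kept set, flags, drops and repeats;
    the loop stops when a pass flags nothing or after ``max_passes``
    removal passes.  A final cross-validation on the surviving set picks
    the factor count for the returned model.
    """
    if multiplier <= 0:
        raise ScreeningError("SECV multiplier must be positive")
    if max_passes < 1:
        raise ScreeningError("max_passes must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    keep = np.ones(n, dtype=bool)
    removed_per_pass: list[int] = []
    cv = None
    n_passes = 0
    for pass_i in range(1, max_passes + 1):
        idx = np.flatnonzero(keep)
        if idx.size < 2 * folds:
            if idx.size == n:
                raise ScreeningError(
                    f"only {n} samples for {folds}-group cross-validation"
                )
            raise ScreeningError(
                "compositional screening removed too many samples "
                f"({n - idx.size} of {n})"
            )
        cv = cross_validate(
            X[idx], y[idx], groups=folds, max_factors=max_factors, seed=seed,
            standardize_residuals=standardize_residuals,
            secv_tolerance=secv_tolerance,
        )
        secv = cv.secv[cv.chosen_factors - 1]
        resid = np.abs(cv.cv_predictions - y[idx])
        with np.errstate(invalid="ignore"):
            flags = resid > multiplier * secv if secv > 0 else np.zeros_like(resid, bool)
        n_passes = pass_i
        if not flags.any():
            break
        for j in np.flatnonzero(flags):
            log.info(
                "compositional screen pass %d: sample %d removed "
                "(|residual|/SECV = %.2f)", pass_i, idx[j], resid[j] / secv,
            )
        keep[idx[flags]] = False
        removed_per_pass.append(int(flags.sum()))
        cv = None  # stale after removal
    idx = np.flatnonzero(keep)
    if idx.size < 2 * folds:
        raise ScreeningError("compositional screening removed too many samples")
    if cv is None:  # last pass removed samples (or max_passes hit)
        cv = cross_validate(
            X[idx], y[idx], groups=folds, max_factors=max_factors, seed=seed,
            standardize_residuals=standardize_residuals,
            secv_tolerance=secv_tolerance,
        )
    model = fit_mpls(
        X[idx], y[idx], max_factors=cv.chosen_factors,
        standardize_residuals=standardize_residuals,
    )
    model.chosen_factors = min(cv.chosen_factors, model.n_factors)
    return CompositionalScreenResult(
        keep=keep, model=model, cv=cv, n_passes=n_passes,
        removed_per_pass=removed_per_pass,
    )
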