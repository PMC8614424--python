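"""Calibration and validation statistics, and model-quality bands.

Conventions (stated here because the field's software rarely documents
them): SEC uses divisor n - 1 - k because each PLS factor consumes a
degree of freedom; SECV and SEP use divisor n; SEP(C), the bias-
corrected SEP, uses n - 1.  Bias is predicted minus reference.  The
slope is the least-squares regression of the laboratory value on the
prediction.  RPD = SD of the validation set divided by SEP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ModelError


@dataclass
class CalibrationStats:
    n: int
    k: int
    sec: float
    secv: float
    rsq_c: float
    one_minus_vr: float


@dataclass
class ValidationStats:
    n: int
    bias: float
    sep: float
    sep_c: float
    slope: float
    rsq_v: float
    rpd: float
    sd_val: float


#: Quality bands after Malley: (label, RSQ lower bound, RPD lower bound),
#: best first; lower bounds inclusive, both must be met.
QUALITY_BANDS = (
    ("excellent", 0.95, 4.0),
    ("successful", 0.90, 3.0),
    ("moderately_successful", 0.80, 2.25),
    ("moderately_useful", 0.70, 1.75),
)

SCREENING_ONLY = "screening_only"
MODEL_CLASSES = tuple(label for label, _, _ in QUALITY_BANDS) + (SCREENING_ONLY,)


def calibration_stats(
    y: np.ndarray, y_hat: np.ndarray, y_cv: np.ndarray, k: int
) -> CalibrationStats:
    """SEC, SECV, RSQ_C and 1-VR from in-sample and cross-validated fits.

    SEC = sqrt(sum (yhat - y)^2 / (n - 1 - k));
    SECV = sqrt(sum (ycv - y)^2 / n);
    RSQ_C = 1 - SS_res / SS_tot;  1-VR = its cross-validated analogue.
    """
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    y_cv = np.asarray(y_cv, float).ravel()
    n = y.size
    if not (y_hat.size == n and y_cv.size == n):
        raise ModelError("length mismatch in calibration statistics")
    if n < k + 2:
        raise ModelError(f"n = {n} too small for k = {k} factors")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ModelError("zero variance in reference values")
    ss_res = float(((y_hat - y) ** 2).sum())
    ss_cv = float(((y_cv - y) ** 2).sum())
    return CalibrationStats(
        n=n,
        k=k,
        sec=np.sqrt(ss_res / (n - 1 - k)),
        secv=np.sqrt(ss_cv / n),
        rsq_c=1.0 - ss_res / ss_tot,
        one_minus_vr=1.0 - ss_cv / ss_tot,
    )


def validation_stats(
    y: np.ndarray, y_hat: np.ndarray, sd_val: float | None = None
) -> ValidationStats:
    """External-validation statistics: bias, SEP, SEP(C), slope, RSQ_V, RPD.

    ``sd_val`` is the SD of the validation reference values (computed
    with divisor n - 1 when not supplied).  Errors are predicted minus
    reference.
    """
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    n = y.size
    if y_hat.size != n:
        raise ModelError("length mismatch in validation statistics")
    if n < 3:
        raise ModelError("validation needs at least 3 samples")
    if sd_val is None:
        sd_val = float(np.std(y, ddof=1))
    if sd_val <= 0:
        raise ModelError("validation-set SD must be positive")
    e = y_hat - y
    bias = float(e.mean())
    sep = float(np.sqrt((e**2).mean()))
    if sep == 0:
        raise ModelError("SEP is zero; RPD undefined")
    sep_c = float(np.sqrt(((e - bias) ** 2).sum() / (n - 1)))
    var_hat = float(((y_hat - y_hat.mean()) ** 2).sum())
    if var_hat == 0:
        raise ModelError("constant predictions; slope undefined")
    cov = float(((y_hat - y_hat.mean()) * (y - y.mean())).sum())
    slope = cov / var_hat
    var_y = float(((y - y.mean()) ** 2).sum())
    if var_y == 0:
        raise ModelError("constant reference values; correlation undefined")
    rsq_v = cov**2 / (var_hat * var_y)
    return ValidationStats(
        n=n, bias=bias, sep=sep, sep_c=sep_c, slope=slope,
        rsq_v=rsq_v, rpd=rpd(sd_val, sep), sd_val=float(sd_val),
    )


def rpd(sd_val: float, sep: float) -> float:
    """Ratio of prediction to deviation: validation-set SD / SEP."""
    if sep <= 0:
        raise ModelError("SEP must be positive to form an RPD")
    return sd_val / sep


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV (%) = 100 * SD / mean, reported to 2 decimals."""
    if mean <= 0:
        raise ModelError("CV requires a positive mean")
    return round(100.0 * sd / mean, 2)


def hemicellulose_from_fiber(ndf: float, adf: float) -> float:
    """Hemicellulose (% DM) = NDF - ADF."""
    if not 0 <= adf <= ndf:
        raise ModelError(f"need NDF >= ADF >= 0, got NDF = {ndf}, ADF = {adf}")
    return ndf - adf


def classify_model(rsq: float, rpd_value: float) -> str:
    """Assign the quality band met by BOTH the RSQ and RPD lower bounds.

    Bands are evaluated best to worst with inclusive lower bounds; a
    model meeting neither bound of any band is usable for screening only.
    """
    if not 0 <= rsq <= 1:
        raise ModelError(f"RSQ must lie in [0, 1], got {rsq}")
    if rpd_value < 0:
        raise ModelError(f"RPD must be non-negative, got {rpd_value}")
    for label, rsq_lo, rpd_lo in QUALITY_BANDS:
        if rsq >= rsq_lo and rpd_value >= rpd_lo:
            return label
    return SCREENING_ONLY
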