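"""Modified partial least squares (PLS1) with residual standardization.

Standard NIPALS PLS1 deflates the spectral matrix after each factor; the
"modified" variant additionally divides every wavelength's residual
column by its standard deviation before the next factor is extracted, so
wavelengths that still carry variance after early factors are not
drowned out by a few dominant bands.  With standardization off the
procedure is exactly PLS1.  Prediction replays the stored per-factor
deflation and scaling, which keeps the model linear: the composed
coefficient vector is available and reproduces the factor-by-factor
prediction.

Factor count is chosen by grouped cross-validation with a parsimony
rule: the smallest count whose SECV is within a small tolerance (default
2%) of the minimum over all counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .errors import ModelError

log = logging.getLogger(__name__)

_RESID_SD_FLOOR = 1e-12   # floor before dividing by residual SDs
_RANK_TOL = 1e-12         # relative tolerance for rank truncation

DEFAULT_MAX_FACTORS = 16
DEFAULT_CV_GROUPS = 4
DEFAULT_SECV_TOLERANCE = 1.02


@dataclass
class MPLSModel:
    """Fitted modified-PLS state sufficient to replay prediction."""

    x_mean: np.ndarray            # (p,)
    y_mean: float
    weights: np.ndarray           # (K, p) unit-norm factor weights
    loadings: np.ndarray          # (K, p) x-loadings
    y_loadings: np.ndarray        # (K,)
    resid_scales: np.ndarray | None  # (K, p) per-factor residual SDs, or None
    chosen_factors: int
    pretreatment: str | None = None

    @property
    def n_factors(self) -> int:
        return self.weights.shape[0]

    @property
    def standardized(self) -> bool:
        return self.resid_scales is not None

    def coefficients(self, k: int | None = None) -> np.ndarray:
        """Composed coefficient vector b such that
        yhat = y_mean + (x - x_mean) @ b at k factors."""
        k = self.chosen_factors if k is None else k
        p = self.x_mean.size
        b = np.zeros(p)
        for f in range(k):
            v = self.weights[f].copy()
            for j in range(f - 1, -1, -1):
                if self.resid_scales is not None:
                    v = v / self.resid_scales[j]
                v = v - self.weights[j] * (self.loadings[j] @ v)
            b += self.y_loadings[f] * v
        return b

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "resid_scales": None
            if self.resid_scales is None
            else self.resid_scales.tolist(),
            "chosen_factors": self.chosen_factors,
            "pretreatment": self.pretreatment,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "MPLSModel":
        doc = json.loads(text)
        return cls(
            x_mean=np.array(doc["x_mean"]),
            y_mean=float(doc["y_mean"]),
            weights=np.array(doc["weights"]),
            loadings=np.array(doc["loadings"]),
            y_loadings=np.array(doc["y_loadings"]),
            resid_scales=None
            if doc["resid_scales"] is None
            else np.array(doc["resid_scales"]),
            chosen_factors=int(doc["chosen_factors"]),
            pretreatment=doc["pretreatment"],
        )


@dataclass
class CVResult:
    """Grouped cross-validation summary for factor selection."""

    secv: np.ndarray            # (K,) SECV at 1..K factors
    chosen_factors: int
    cv_predictions: np.ndarray  # (n,) held-out predictions at chosen count
    groups: np.ndarray          # (n,) group index per sample


def fit_mpls(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int = DEFAULT_MAX_FACTORS,
    standardize_residuals: bool = True,
    pretreatment: str | None = None,
) -> MPLSModel:
    """Fit modified PLS1 of ``y`` on pretreated spectra ``X``.

    After each factor the spectral residual columns are divided by their
    SDs (floored at 1e-12) and the scale vector is stored so prediction
    replays it; with ``standardize_residuals=False`` this is plain
    NIPALS PLS1.  ``max_factors`` beyond the rank of the centered data
    is truncated with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ModelError(f"{n} spectra but {y.size} reference values")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ModelError("non-finite values in the training data")
    if n < max_factors + 2:
        max_factors = max(1, n - 2)
        log.warning("max_factors reduced to %d for n = %d", max_factors, n)
    if np.ptp(y) == 0:
        raise ModelError("zero-variance reference values")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean
    x_scale0 = float(np.linalg.norm(Xr)) or 1.0

    W, P, Q, S = [], [], [], []
    for f in range(max_factors):
        w = Xr.T @ yr
        nw = float(np.linalg.norm(w))
        if nw <= _RANK_TOL * x_scale0 * (np.abs(yr).max() + 1.0):
            log.warning(
                "rank exhausted after %d factors (requested %d)", f, max_factors
            )
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt <= (_RANK_TOL * x_scale0) ** 2:
            log.warning(
                "rank exhausted after %d factors (requested %d)", f, max_factors
            )
            break
        p_load = Xr.T @ t / tt
        q = float(yr @ t / tt)
        Xr = Xr - np.outer(t, p_load)
        yr = yr - q * t
        W.append(w)
        P.append(p_load)
        Q.append(q)
        if standardize_residuals:
            s = np.maximum(Xr.std(axis=0), _RESID_SD_FLOOR)
            Xr = Xr / s
            S.append(s)
    if not W:
        raise ModelError("no usable PLS factor (X has no variance?)")
    return MPLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=np.vstack(W),
        loadings=np.vstack(P),
        y_loadings=np.array(Q),
        resid_scales=np.vstack(S) if standardize_residuals else None,
        chosen_factors=len(W),
        pretreatment=pretreatment,
    )


def predict(
    m: MPLSModel, X: np.ndarray, k: int | None = None
) -> np.ndarray:
    """Predict by replaying centering, deflation and residual scaling.

    ``k`` defaults to the model's chosen factor count; ``k = 0`` returns
    the training mean for every row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.x_mean.size:
        raise ModelError(
            f"grid mismatch: model has {m.x_mean.size} wavelengths, "
            f"input has {X.shape[1]}"
        )
    k = m.chosen_factors if k is None else k
    if not 0 <= k <= m.n_factors:
        raise ModelError(f"k = {k} outside [0, {m.n_factors}]")
    Xr = X - m.x_mean
    yhat = np.full(X.shape[0], m.y_mean)
    for f in range(k):
        t = Xr @ m.weights[f]
        yhat += m.y_loadings[f] * t
        Xr = Xr - np.outer(t, m.loadings[f])
        if m.resid_scales is not None:
            Xr = Xr / m.resid_scales[f]
    return yhat


def predict_all_factors(m: MPLSModel, X: np.ndarray) -> np.ndarray:
    """(n, K) predictions at every factor count 1..K in one pass."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xr = X - m.x_mean
    out = np.empty((X.shape[0], m.n_factors))
    yhat = np.full(X.shape[0], m.y_mean)
    for f in range(m.n_factors):
        t = Xr @ m.weights[f]
        yhat = yhat + m.y_loadings[f] * t
        out[:, f] = yhat
        Xr = Xr - np.outer(t, m.loadings[f])
        if m.resid_scales is not None:
            Xr = Xr / m.resid_scales[f]
    return out


def assign_groups(n: int, groups: int, seed: int) -> np.ndarray:
    """Seeded shuffle then round-robin: sorted data do not confound folds
    with concentration."""
    perm = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm] = np.arange(n) % groups
    return assignment


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    groups: int = DEFAULT_CV_GROUPS,
    max_factors: int = DEFAULT_MAX_FACTORS,
    seed: int = 0,
    standardize_residuals: bool = True,
    secv_tolerance: float = DEFAULT_SECV_TOLERANCE,
) -> CVResult:
    """Grouped cross-validation; SECV(k) = sqrt(sum e_cv^2 / n).

    The chosen factor count is the smallest k whose SECV is within
    ``secv_tolerance`` (default 1.02, i.e. 2%) of the minimum — strict
    argmin overfits the count on small n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if groups < 2:
        raise ModelError("cross-validation needs at least 2 groups")
    if n < 2 * groups:
        raise ModelError(f"n = {n} too small for {groups} CV groups")
    assignment = assign_groups(n, groups, seed)
    k_max = max_factors
    preds = np.full((n, max_factors), np.nan)
    for g in range(groups):
        held = assignment == g
        model = fit_mpls(
            X[~held], y[~held], max_factors=max_factors,
            standardize_residuals=standardize_residuals,
        )
        k_max = min(k_max, model.n_factors)
        preds[held, : model.n_factors] = predict_all_factors(model, X[held])
    preds = preds[:, :k_max]
    secv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = int(np.argmax(secv <= secv_tolerance * secv.min())) + 1
    return CVResult(
        secv=secv,
        chosen_factors=chosen,
        cv_predictions=preds[:, chosen - 1].copy(),
        groups=assignment,
    )
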