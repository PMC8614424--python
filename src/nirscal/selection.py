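"""Rank-stratified calibration/validation splitting and the pretreatment
grid search.

The split sorts samples by reference value and sends one sample per
consecutive block of ``fold`` to validation, so the validation set spans
the calibration range; the default in-block position is the middle one,
keeping the extreme minimum and maximum inside the calibration set.

The grid search runs the full calibration protocol (pretreat,
compositional screen, fit, cross-validate) for every pretreatment and
ranks candidates by the cross-validated criteria: 1-VR descending, then
SECV ascending.  The in-sample SEC/RSQ_C are reported but do not rank —
they reward overfitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .dataset import ReferenceTable, SpectraSet
from .errors import NirscalError, SplitError
from .metrics import CalibrationStats, calibration_stats
from .mpls import (
    DEFAULT_CV_GROUPS,
    DEFAULT_MAX_FACTORS,
    DEFAULT_SECV_TOLERANCE,
    MPLSModel,
    predict,
)
from .outliers import (
    DEFAULT_MAX_PASSES,
    DEFAULT_SECV_MULTIPLIER,
    CompositionalScreenResult,
    compositional_screen,
)
from .preprocess import MathTreatment, Pretreatment, ScatterState, apply_pretreatment

log = logging.getLogger(__name__)

DEFAULT_FOLD = 5
_MAX_MISSING_FRACTION = 0.20

#: Default grid: 5 math treatments x 6 scatter corrections = 30.
DEFAULT_MATHS = (
    MathTreatment(0, 0, 1, 1),
    MathTreatment(1, 4, 4, 1),
    MathTreatment(2, 4, 4, 1),
    MathTreatment(1, 8, 8, 1),
    MathTreatment(2, 8, 8, 1),
)
DEFAULT_SCATTERS = (
    "none",
    "snv_only",
    "detrend_only",
    "msc_standard",
    "msc_weighted",
    "scale_linear",
)


@dataclass
class SplitPlan:
    """Disjoint, exhaustive calibration/validation id lists."""

    constituent: str
    calibration_ids: list[str]
    validation_ids: list[str]
    fold: int
    offset: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.calibration_ids + self.validation_ids,
                "subset": ["calibration"] * len(self.calibration_ids)
                + ["validation"] * len(self.validation_ids),
            }
        )


def rank_stratified_split(
    ref: ReferenceTable,
    constituent: str,
    fold: int = DEFAULT_FOLD,
    offset: int | None = None,
) -> SplitPlan:
    """Sort by reference value; one sample per block of ``fold`` (at
    in-block position ``offset``, default the middle) goes to validation.

    Ties are broken by sample id.  Samples missing the constituent are
    excluded (more than 20% missing is an error).
    """
    if fold < 2:
        raise SplitError("fold must be >= 2")
    offset = fold // 2 if offset is None else offset
    if not 0 <= offset < fold:
        raise SplitError(f"offset {offset} outside [0, {fold})")
    values = ref.values_for(constituent)
    n_missing = int(values.isna().sum())
    if n_missing > _MAX_MISSING_FRACTION * len(values):
        raise SplitError(
            f"{constituent!r} missing for {n_missing}/{len(values)} samples"
        )
    present = values.dropna()
    order = sorted(present.index, key=lambda sid: (present[sid], str(sid)))
    cal, val = [], []
    for start in range(0, len(order), fold):
        block = order[start : start + fold]
        for pos, sid in enumerate(block):
            (val if pos == offset else cal).append(str(sid))
    if not val:
        raise SplitError("validation set is empty; too few samples for the fold")
    return SplitPlan(
        constituent=constituent, calibration_ids=cal, validation_ids=val,
        fold=fold, offset=offset,
    )


def build_grid(
    maths=DEFAULT_MATHS, scatters=DEFAULT_SCATTERS
) -> list[Pretreatment]:
    """Deduplicated Cartesian product of math treatments and scatter labels."""
    if not maths or not scatters:
        raise ValueError("math-treatment and scatter lists must be non-empty")
    seen: set[str] = set()
    grid: list[Pretreatment] = []
    for m, sc in product(maths, scatters):
        p = Pretreatment(math=m, scatter=sc)
        if str(p) not in seen:
            seen.add(str(p))
            grid.append(p)
    return grid


@dataclass
class CandidateModel:
    """One grid-search entry: a pretreatment with its fitted model and stats."""

    pretreatment: Pretreatment
    status: str = "ok"                    # "ok" or "failed"
    error: str | None = None
    model: MPLSModel | None = None
    scatter_state: ScatterState | None = None
    stats: CalibrationStats | None = None
    screen: CompositionalScreenResult | None = None

    @property
    def rank_key(self):
        # primary: 1-VR descending; tie-break: SECV ascending
        return (-self.stats.one_minus_vr, self.stats.secv)


def evaluate_pretreatment(
    spectra_cal: SpectraSet,
    y: np.ndarray,
    p: Pretreatment,
    *,
    folds: int = DEFAULT_CV_GROUPS,
    max_factors: int = DEFAULT_MAX_FACTORS,
    multiplier: float = DEFAULT_SECV_MULTIPLIER,
    max_passes: int = DEFAULT_MAX_PASSES,
    seed: int = 0,
    standardize_residuals: bool = True,
    secv_tolerance: float = DEFAULT_SECV_TOLERANCE,
) -> CandidateModel:
    """Run the full calibration protocol for one pretreatment."""
    treated, state = apply_pretreatment(spectra_cal, p)
    screen = compositional_screen(
        treated.absorbance, y, folds=folds, multiplier=multiplier,
        max_passes=max_passes, max_factors=max_factors, seed=seed,
        standardize_residuals=standardize_residuals,
        secv_tolerance=secv_tolerance,
    )
    kept = np.flatnonzero(screen.keep)
    model = screen.model
    model.pretreatment = str(p)
    y_hat = predict(model, treated.absorbance[kept])
    stats = calibration_stats(
        y[kept], y_hat, screen.cv.cv_predictions, k=model.chosen_factors
    )
    return CandidateModel(
        pretreatment=p, model=model, scatter_state=state, stats=stats,
        screen=screen,
    )


def grid_search(
    spectra: SpectraSet,
    ref: ReferenceTable,
    constituent: str,
    grid: list[Pretreatment] | None = None,
    **protocol,
) -> list[CandidateModel]:
    """Evaluate every pretreatment on the calibration samples; return all
    candidates best first (1-VR descending, SECV ascending in ties).

    A pretreatment that fails (window too large for the grid, degenerate
    regression...) is recorded as a failed candidate, never fatal.
    """
    if grid is None:
        grid = build_grid()
    if not grid:
        raise ValueError("empty pretreatment grid")
    y = ref.values_for(constituent)
    mask = y.notna()
    if not mask.all():
        keep_ids = [sid for sid, ok in zip(ref.sample_ids, mask) if ok]
        spectra = spectra.select_ids(keep_ids)
        y = y[mask]
    yv = y.to_numpy(dtype=float)
    candidates: list[CandidateModel] = []
    for p in grid:
        try:
            candidates.append(
                evaluate_pretreatment(spectra, yv, p, **protocol)
            )
        except NirscalError as e:
            log.warning("pretreatment %s failed: %s", p, e)
            candidates.append(
                CandidateModel(pretreatment=p, status="failed", error=str(e))
            )
    ok = sorted((c for c in candidates if c.status == "ok"), key=lambda c: c.rank_key)
    failed = [c for c in candidates if c.status != "ok"]
    return ok + failed


def grid_report(candidates: list[CandidateModel]) -> pd.DataFrame:
    """One row per candidate, mirroring the calibration-table layout."""
    rows = []
    for c in candidates:
        if c.status == "ok":
            rows.append(
                {
                    "pretreatment": str(c.pretreatment),
                    "status": c.status,
                    "n": c.stats.n,
                    "factors": c.stats.k,
                    "rsq_c": round(c.stats.rsq_c, 4),
                    "sec": round(c.stats.sec, 4),
                    "secv": round(c.stats.secv, 4),
                    "one_minus_vr": round(c.stats.one_minus_vr, 4),
                }
            )
        else:
            rows.append(
                {
                    "pretreatment": str(c.pretreatment),
                    "status": f"failed: {c.error}",
                    "n": None, "factors": None, "rsq_c": None,
                    "sec": None, "secv": None, "one_minus_vr": None,
                }
            )
    return pd.DataFrame(rows)
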