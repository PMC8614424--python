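"""End-to-end calibration workflows: per-species and combined-set.

A run is driven by one serializable :class:`RunConfig`.  For each
species (simulated by default, or loaded from CSV paths) the workflow
is: GH spectral screen -> rank-stratified calibration/validation split
-> pretreatment grid search on the calibration set (with compositional
screening inside) -> external validation of the winning model -> quality
classification.  The combined workflow pools all species, reruns the
same protocol, and tabulates combined-vs-single RPDs — the comparison
that motivates pooling straws of several species into one calibration.

One global seed fans out into named substreams (simulation, CV, splits)
so stages are independently reproducible; rerunning from the config copy
written next to the outputs reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    CONSTITUENTS,
    ReferenceTable,
    SpectraSet,
    concat_spectra,
    read_reference,
    read_spectra,
)
from .errors import NirscalError
from .metrics import ValidationStats, classify_model, validation_stats
from .mpls import predict
from .outliers import GHReport, pca_gh_screen
from .preprocess import MathTreatment, Pretreatment, apply_pretreatment
from .selection import (
    DEFAULT_FOLD,
    DEFAULT_MATHS,
    DEFAULT_SCATTERS,
    CandidateModel,
    SplitPlan,
    build_grid,
    grid_report,
    grid_search,
    rank_stratified_split,
)
from .simulate import (
    DEFAULT_PROFILES,
    SimulationProfile,
    make_component_library,
    simulate_dataset,
)

log = logging.getLogger(__name__)

COMBINED_LABEL = "combined"


def derive_seed(seed: int, *tags: str | int) -> int:
    """Stable named substream seed (< 2^31) from one global seed."""
    words = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        words.append(zlib.crc32(str(t).encode()) if isinstance(t, str) else int(t))
    return int(np.random.SeedSequence(words).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a workflow run needs; JSON-serializable."""

    seed: int = 0
    species: tuple[str, ...] = ("corn_stover", "wheat_straw")
    n_samples: dict[str, int] = field(
        default_factory=lambda: {"corn_stover": 156, "wheat_straw": 135}
    )
    constituents: tuple[str, ...] = CONSTITUENTS
    # data source: CSV paths per species, else simulate from profiles
    spectra_paths: dict[str, str] = field(default_factory=dict)
    reference_paths: dict[str, str] = field(default_factory=dict)
    profiles: dict[str, SimulationProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    # grid search
    maths: tuple[str, ...] = tuple(str(m) for m in DEFAULT_MATHS)
    scatters: tuple[str, ...] = DEFAULT_SCATTERS
    # protocol parameters
    fold: int = DEFAULT_FOLD
    offset: int | None = None
    cv_groups: int = 4
    max_factors: int = 16
    gh_threshold: float = 3.0
    secv_multiplier: float = 3.0
    max_passes: int = 2
    secv_tolerance: float = 1.02
    standardize_residuals: bool = True
    output_dir: str | None = None

    def grid(self) -> list[Pretreatment]:
        return build_grid(
            [MathTreatment.parse(m) for m in self.maths], list(self.scatters)
        )

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        doc["profiles"] = {
            name: dataclasses.asdict(p) for name, p in self.profiles.items()
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        profiles = {}
        for name, p in doc.pop("profiles", {}).items():
            p["bounds"] = {k: tuple(v) for k, v in p["bounds"].items()}
            profiles[name] = SimulationProfile(**p)
        cfg = cls(**{**doc, "profiles": profiles})
        cfg.species = tuple(cfg.species)
        cfg.constituents = tuple(cfg.constituents)
        cfg.maths = tuple(cfg.maths)
        cfg.scatters = tuple(cfg.scatters)
        return cfg


@dataclass
class ConstituentResult:
    constituent: str
    status: str = "ok"
    error: str | None = None
    split: SplitPlan | None = None
    candidates: list[CandidateModel] | None = None
    winner: CandidateModel | None = None
    validation: ValidationStats | None = None
    model_class: str | None = None
    validation_pairs: pd.DataFrame | None = None  # reference vs predicted


@dataclass
class WorkflowBundle:
    label: str
    spectra: SpectraSet
    reference: ReferenceTable
    gh: GHReport
    results: dict[str, ConstituentResult]
    stats: pd.DataFrame


def load_species_data(
    cfg: RunConfig, species: str
) -> tuple[SpectraSet, ReferenceTable]:
    """Load the species' spectra/reference CSVs, or simulate them."""
    if species in cfg.spectra_paths:
        spectra = read_spectra(cfg.spectra_paths[species])
        ref = read_reference(cfg.reference_paths[species])
        return spectra, ref
    profile = cfg.profiles[species].with_seed(
        derive_seed(cfg.seed, "simulate", species)
    )
    n = cfg.n_samples.get(species, 150) if isinstance(cfg.n_samples, dict) else int(cfg.n_samples)
    return simulate_dataset(profile, n)


def _calibrate_constituent(
    cfg: RunConfig,
    label: str,
    spectra: SpectraSet,
    ref: ReferenceTable,
    constituent: str,
) -> ConstituentResult:
    split = rank_stratified_split(ref, constituent, fold=cfg.fold, offset=cfg.offset)
    cal_s = spectra.select_ids(split.calibration_ids)
    cal_r = ref.select_ids(split.calibration_ids)
    val_s = spectra.select_ids(split.validation_ids)
    val_r = ref.select_ids(split.validation_ids)
    candidates = grid_search(
        cal_s, cal_r, constituent, grid=cfg.grid(),
        folds=cfg.cv_groups, max_factors=cfg.max_factors,
        multiplier=cfg.secv_multiplier, max_passes=cfg.max_passes,
        seed=derive_seed(cfg.seed, "cv", label, constituent),
        standardize_residuals=cfg.standardize_residuals,
        secv_tolerance=cfg.secv_tolerance,
    )
    winner = next((c for c in candidates if c.status == "ok"), None)
    if winner is None:
        raise NirscalError("every pretreatment in the grid failed")
    treated_val, _ = apply_pretreatment(
        val_s, winner.pretreatment, state=winner.scatter_state
    )
    y_val = val_r.values_for(constituent).to_numpy(dtype=float)
    ok = np.isfinite(y_val)
    y_hat = predict(winner.model, treated_val.absorbance[ok])
    vstats = validation_stats(y_val[ok], y_hat)
    label_class = classify_model(winner.stats.rsq_c, vstats.rpd)
    pairs = pd.DataFrame(
        {
            "sample_id": [s for s, m in zip(split.validation_ids, ok) if m],
            "reference": y_val[ok],
            "predicted": np.round(y_hat, 6),
        }
    )
    log.info(
        "%s/%s: winner %s, factors %d, n %d, RSQ_C %.4f, 1-VR %.4f, RPD %.3f (%s)",
        label, constituent, winner.pretreatment, winner.stats.k,
        winner.stats.n, winner.stats.rsq_c, winner.stats.one_minus_vr,
        vstats.rpd, label_class,
    )
    return ConstituentResult(
        constituent=constituent, split=split, candidates=candidates,
        winner=winner, validation=vstats, model_class=label_class,
        validation_pairs=pairs,
    )


def _stats_frame(label: str, results: dict[str, ConstituentResult]) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        if r.status != "ok":
            rows.append({"constituent": name, "set": label, "status": r.status})
            continue
        w, v = r.winner, r.validation
        rows.append(
            {
                "constituent": name,
                "set": label,
                "status": "ok",
                "pretreatment": str(w.pretreatment),
                "n_cal": w.stats.n,
                "factors": w.stats.k,
                "rsq_c": round(w.stats.rsq_c, 4),
                "sec": round(w.stats.sec, 4),
                "secv": round(w.stats.secv, 4),
                "one_minus_vr": round(w.stats.one_minus_vr, 4),
                "n_val": v.n,
                "bias": round(v.bias, 4),
                "sep": round(v.sep, 4),
                "sep_c": round(v.sep_c, 4),
                "slope": round(v.slope, 4),
                "rsq_v": round(v.rsq_v, 4),
                "rpd": round(v.rpd, 3),
                "class": r.model_class,
            }
        )
    return pd.DataFrame(rows)


def _write_bundle(cfg: RunConfig, bundle: WorkflowBundle) -> None:
    if cfg.output_dir is None:
        return
    out = Path(cfg.output_dir) / bundle.label
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())
    pd.DataFrame(
        {
            "sample_id": bundle.gh.sample_ids,
            "gh": np.round(bundle.gh.gh, 4),
            "kept": bundle.gh.keep,
        }
    ).to_csv(out / "gh_report.csv", index=False)
    for name, r in bundle.results.items():
        if r.status != "ok":
            continue
        r.split.to_frame().to_csv(out / f"{name}_split.csv", index=False)
        grid_report(r.candidates).to_csv(out / f"{name}_grid.csv", index=False)
        (out / f"{name}_model.json").write_text(r.winner.model.to_json())
        r.validation_pairs.to_csv(out / f"{name}_predictions.csv", index=False)
    bundle.stats.to_csv(out / "stats.csv", index=False)


def run_workflow_on(
    cfg: RunConfig,
    label: str,
    spectra: SpectraSet,
    ref: ReferenceTable,
) -> WorkflowBundle:
    """GH screen + per-constituent calibration on an in-memory dataset."""
    gh = pca_gh_screen(spectra, threshold=cfg.gh_threshold)
    kept_ids = gh.kept_ids
    spectra_kept = spectra.select_ids(kept_ids)
    ref_kept = ref.select_ids(kept_ids)
    results: dict[str, ConstituentResult] = {}
    for constituent in cfg.constituents:
        try:
            results[constituent] = _calibrate_constituent(
                cfg, label, spectra_kept, ref_kept, constituent
            )
        except NirscalError as e:
            log.warning("%s/%s failed: %s", label, constituent, e)
            results[constituent] = ConstituentResult(
                constituent=constituent, status="failed", error=str(e)
            )
    bundle = WorkflowBundle(
        label=label, spectra=spectra, reference=ref, gh=gh,
        results=results, stats=_stats_frame(label, results),
    )
    _write_bundle(cfg, bundle)
    return bundle


def run_species_workflow(cfg: RunConfig, species: str) -> WorkflowBundle:
    """The full single-species workflow (simulate/load, screen, calibrate)."""
    spectra, ref = load_species_data(cfg, species)
    return run_workflow_on(cfg, species, spectra, ref)


def comparison_table(
    species_bundles: dict[str, WorkflowBundle], combined: WorkflowBundle
) -> pd.DataFrame:
    """Per constituent: single-species RPDs vs the combined RPD, plus the
    SD of each calibration set (pooling widens it when means differ)."""
    rows = []
    for constituent in combined.results:
        row: dict[str, object] = {"constituent": constituent}
        for name, b in species_bundles.items():
            r = b.results.get(constituent)
            ok = r is not None and r.status == "ok"
            row[f"rpd_{name}"] = round(r.validation.rpd, 3) if ok else None
            if ok:
                y = b.reference.select_ids(r.split.calibration_ids).values_for(constituent)
                row[f"sd_cal_{name}"] = round(float(y.std(ddof=1)), 4)
            else:
                row[f"sd_cal_{name}"] = None
        r = combined.results[constituent]
        ok = r.status == "ok"
        row["rpd_combined"] = round(r.validation.rpd, 3) if ok else None
        if ok:
            y = combined.reference.select_ids(r.split.calibration_ids).values_for(constituent)
            row["sd_cal_combined"] = round(float(y.std(ddof=1)), 4)
        else:
            row["sd_cal_combined"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def run_combined_workflow(
    cfg: RunConfig,
    species_bundles: dict[str, WorkflowBundle] | None = None,
) -> tuple[WorkflowBundle, pd.DataFrame]:
    """Pool all species, rerun the workflow, and emit the combined-vs-
    single comparison table.  Requires at least two species."""
    if len(cfg.species) < 2:
        raise NirscalError("combined workflow needs at least 2 species")
    if species_bundles is None:
        species_bundles = {
            sp: run_species_workflow(cfg, sp) for sp in cfg.species
        }
    spectra = concat_spectra([species_bundles[sp].spectra for sp in cfg.species])
    ref = species_bundles[cfg.species[0]].reference
    for sp in cfg.species[1:]:
        ref = ref.concat(species_bundles[sp].reference)
    combined = run_workflow_on(cfg, COMBINED_LABEL, spectra, ref)
    table = comparison_table(species_bundles, combined)
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir) / COMBINED_LABEL
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "comparison.csv", index=False)
    return combined, table
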