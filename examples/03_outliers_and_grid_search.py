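"""Screen outliers and rank pretreatments for one constituent.

The GH screen drops atypical spectra before any calibration; the grid
search then runs the whole protocol (pretreat, compositional 3xSECV
screen, fit, cross-validate) for each candidate pretreatment and ranks
them by cross-validated criteria.
"""

from nirscal import (
    WHEAT_STRAW,
    build_grid,
    grid_search,
    pca_gh_screen,
    rank_stratified_split,
    simulate_dataset,
)
from nirscal.preprocess import MathTreatment
from nirscal.selection import grid_report

spectra, reference = simulate_dataset(WHEAT_STRAW.with_seed(3), n=90)

gh = pca_gh_screen(spectra, threshold=3.0)
print(f"GH screen: {gh.n_components} PCA components, mean GH "
      f"{gh.gh.mean():.3f}, flagged {int((~gh.keep).sum())} of {len(gh.gh)}")
spectra, reference = (
    spectra.select_ids(gh.kept_ids), reference.select_ids(gh.kept_ids)
)

split = rank_stratified_split(reference, "cp", fold=5)
print(f"split: {len(split.calibration_ids)} calibration / "
      f"{len(split.validation_ids)} validation (rank-stratified)")

grid = build_grid(
    maths=[MathTreatment.parse(t) for t in ("0,0,1,1", "1,4,4,1")],
    scatters=["none", "snv_only", "msc_standard"],
)
candidates = grid_search(
    spectra.select_ids(split.calibration_ids),
    reference.select_ids(split.calibration_ids),
    "cp", grid=grid, seed=0,
)
print(grid_report(candidates).to_string(index=False))
# Candidates are sorted by 1-VR (cross-validated R^2) descending; n is
# the calibration count left after compositional outlier removal.
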