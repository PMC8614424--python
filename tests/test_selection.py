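"""Rank-stratified splitting and the pretreatment grid search."""

import numpy as np
import pytest

from nirscal.errors import SplitError
from nirscal.preprocess import MathTreatment, Pretreatment
from nirscal.selection import (
    build_grid,
    grid_search,
    rank_stratified_split,
)
from nirscal.simulate import SimulationProfile, simulate_dataset
from tests.conftest import make_reference


class TestRankStratifiedSplit:
    def test_forced_positions_small_example(self):
        ref = make_reference({"cp": list(np.arange(10.0, 20.0))})
        plan = rank_stratified_split(ref, "cp", fold=5, offset=2)
        # sorted positions 2 and 7 go to validation
        assert plan.validation_ids == ["s2", "s7"]
        assert len(plan.calibration_ids) == 8
        assert set(plan.calibration_ids) | set(plan.validation_ids) == {
            f"s{i}" for i in range(10)
        }

    def test_four_fifths_one_fifth_at_scale(self):
        rng = np.random.default_rng(0)
        ref = make_reference({"cp": rng.uniform(2, 10, 156).tolist()})
        plan = rank_stratified_split(ref, "cp", fold=5)
        assert len(plan.validation_ids) == 31
        assert len(plan.calibration_ids) == 125
        frac = len(plan.validation_ids) / 156
        assert 1 / 5 - 0.05 <= frac <= 1 / 5 + 0.05

    def test_middle_offset_keeps_extremes_in_calibration(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(2, 10, 60)
        ref = make_reference({"cp": vals.tolist()})
        plan = rank_stratified_split(ref, "cp", fold=5)
        cal_vals = ref.data.loc[plan.calibration_ids, "cp"]
        val_vals = ref.data.loc[plan.validation_ids, "cp"]
        assert val_vals.min() > cal_vals.min()
        assert val_vals.max() < cal_vals.max()

    def test_ties_broken_by_id_deterministically(self):
        ref = make_reference({"cp": [5.0] * 10})
        a = rank_stratified_split(ref, "cp", fold=5, offset=2)
        b = rank_stratified_split(ref, "cp", fold=5, offset=2)
        assert a.validation_ids == b.validation_ids
        assert set(a.validation_ids).isdisjoint(a.calibration_ids)

    def test_excessive_missingness_rejected(self):
        vals = [5.0] * 6 + [np.nan] * 4
        ref = make_reference({"cp": vals})
        with pytest.raises(SplitError, match="missing"):
            rank_stratified_split(ref, "cp")


class TestBuildGrid:
    def test_default_grid_has_thirty_members(self):
        grid = build_grid()
        assert len(grid) == 30
        strings = {str(p) for p in grid}
        assert len(strings) == 30
        # the treatments the workflow selects in practice are all present
        for s in ("1,4,4,1+SNV", "2,4,4,1+none", "0,0,1,1+SL",
                  "1,4,4,1+WMSC", "2,4,4,1+MSC", "1,4,4,1+DT"):
            assert s in strings

    def test_singleton_grid(self):
        grid = build_grid([MathTreatment(0, 0, 1, 1)], ["none"])
        assert len(grid) == 1

    def test_duplicates_deduplicated(self):
        m = MathTreatment(1, 4, 4, 1)
        grid = build_grid([m, m], ["snv_only", "snv_only"])
        assert len(grid) == 1


@pytest.fixture(scope="module")
def scattered_dataset():
    """Small synthetic set with strong multiplicative scatter."""
    profile = SimulationProfile(
        species="corn_stover",
        means=dict(moisture=5.35, cp=5.18, ndf=63.97, adf=36.28, adl=3.26,
                   hemicellulose=27.78),
        sds=dict(moisture=1.14, cp=1.34, ndf=6.21, adf=4.71, adl=1.61,
                 hemicellulose=3.58),
        bounds=dict(moisture=(3.01, 7.41), cp=(2.15, 10.15),
                    ndf=(43.73, 80.71), adf=(23.36, 66.57),
                    adl=(1.17, 10.70), hemicellulose=(13.53, 37.47)),
        slope_sd=0.35, offset_sd=0.0, tilt_sd=0.0, noise_sd=0.0005, seed=21,
    )
    return simulate_dataset(profile, 60)


class TestGridSearch:
    def test_single_identity_candidate_on_noiseless_data(self):
        """With no scatter and no noise the identity pretreatment fits the
        linear mixture essentially perfectly (1-VR ~ 1)."""
        profile = SimulationProfile(
            species="corn_stover",
            means=dict(moisture=5.35, cp=5.18, ndf=63.97, adf=36.28,
                       adl=3.26, hemicellulose=27.78),
            sds=dict(moisture=1.14, cp=1.34, ndf=6.21, adf=4.71, adl=1.61,
                     hemicellulose=3.58),
            bounds=dict(moisture=(3.01, 7.41), cp=(2.15, 10.15),
                        ndf=(43.73, 80.71), adf=(23.36, 66.57),
                        adl=(1.17, 10.70), hemicellulose=(13.53, 37.47)),
            slope_sd=0.0, offset_sd=0.0, tilt_sd=0.0, noise_sd=0.0, seed=31,
        )
        spectra, ref = simulate_dataset(profile, 60)
        grid = [Pretreatment(MathTreatment(0, 0, 1, 1), "none")]
        cands = grid_search(spectra, ref, "cp", grid=grid, seed=0,
                            max_factors=8)
        assert len(cands) == 1 and cands[0].status == "ok"
        assert cands[0].stats.one_minus_vr > 0.99

    def test_scatter_correction_outranks_raw_identity(self, scattered_dataset):
        """Under strong multiplicative scatter a scatter-corrected
        candidate beats the scatter-free identity pretreatment."""
        spectra, ref = scattered_dataset
        identity = Pretreatment(MathTreatment(0, 0, 1, 1), "none")
        grid = [identity] + [
            Pretreatment(MathTreatment(0, 0, 1, 1), sc)
            for sc in ("snv_only", "msc_standard", "detrend_only")
        ]
        cands = grid_search(spectra, ref, "cp", grid=grid, seed=0,
                            max_factors=4)
        ranked = [str(c.pretreatment) for c in cands if c.status == "ok"]
        assert ranked[0] != str(identity)

    def test_candidates_sorted_by_cv_criteria(self, scattered_dataset):
        spectra, ref = scattered_dataset
        cands = [
            c for c in grid_search(
                spectra, ref, "cp",
                grid=build_grid(
                    [MathTreatment(0, 0, 1, 1), MathTreatment(1, 4, 4, 1)],
                    ["none", "snv_only", "detrend_only"],
                ),
                seed=1, max_factors=6,
            )
            if c.status == "ok"
        ]
        vr = [c.stats.one_minus_vr for c in cands]
        assert all(a >= b - 1e-12 for a, b in zip(vr, vr[1:]))

    def test_winner_invariant_to_grid_order(self, scattered_dataset):
        spectra, ref = scattered_dataset
        grid = build_grid(
            [MathTreatment(0, 0, 1, 1), MathTreatment(1, 4, 4, 1)],
            ["none", "snv_only"],
        )
        a = grid_search(spectra, ref, "cp", grid=grid, seed=2, max_factors=4)
        b = grid_search(spectra, ref, "cp", grid=grid[::-1], seed=2,
                        max_factors=4)
        assert str(a[0].pretreatment) == str(b[0].pretreatment)
        assert np.isclose(a[0].stats.secv, b[0].stats.secv)

    def test_failing_pretreatment_recorded_not_fatal(self, scattered_dataset):
        spectra, ref = scattered_dataset
        huge_window = Pretreatment(MathTreatment(2, 5000, 1, 1), "none")
        cands = grid_search(
            spectra, ref, "cp",
            grid=[Pretreatment(MathTreatment(0, 0, 1, 1), "none"), huge_window],
            seed=0, max_factors=4,
        )
        status = {str(c.pretreatment): c.status for c in cands}
        assert status["0,0,1,1+none"] == "ok"
        assert status[str(huge_window)] == "failed"

    def test_reported_n_accounts_for_compositional_removals(
        self, scattered_dataset
    ):
        spectra, ref = scattered_dataset
        y = ref.data["cp"].copy()
        y.iloc[7] = min(y.iloc[7] + 5.0, 10.0)  # implausible chemistry
        ref2 = make_reference({"cp": y.tolist()}, ids=list(ref.sample_ids))
        spectra2 = spectra.select_ids(ref2.sample_ids)
        cands = grid_search(
            spectra2, ref2, "cp",
            grid=[Pretreatment(MathTreatment(0, 0, 1, 1), "snv_only")],
            seed=0, max_factors=6,
        )
        c = cands[0]
        removed = int((~c.screen.keep).sum())
        assert c.stats.n == spectra2.n_samples - removed
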