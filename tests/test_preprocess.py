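"""Scatter corrections and math treatments: algebraic contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirscal.dataset import SpectraSet
from nirscal.errors import DegenerateSpectrumError, WindowError
from nirscal.preprocess import (
    MathTreatment,
    Pretreatment,
    apply_math_treatment,
    apply_msc,
    apply_pretreatment,
    detrend,
    fit_msc,
    scale_polynomial,
    snv,
)


class TestSNV:
    def test_hand_computed_row(self):
        out = snv(np.array([1.0, 2.0, 3.0]))[0]
        expected = np.array([-1.22474487, 0.0, 1.22474487])
        assert np.allclose(out, expected, atol=1e-8)
        assert abs(out.mean()) < 1e-12 and abs(out.std() - 1) < 1e-12

    @given(
        a=st.floats(-5, 5), b=st.floats(0.01, 10),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        row = np.random.default_rng(seed).uniform(0.1, 1.0, size=20)
        if row.std() < 1e-6:
            return
        assert np.allclose(snv(a + b * row), snv(row), atol=1e-7)

    def test_constant_row_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            snv(np.full(10, 0.5))


class TestDetrend:
    wl = np.arange(850.0, 950.0, 1.0)

    def test_polynomial_annihilation(self):
        quad = 0.3 + 0.01 * self.wl + 2e-5 * self.wl**2
        assert np.abs(detrend(quad, self.wl, 2)).max() < 1e-9
        line = 1.0 - 0.002 * self.wl
        assert np.abs(detrend(line, self.wl, 1)).max() < 1e-9

    def test_projection_linearity(self):
        rng = np.random.default_rng(3)
        row = rng.uniform(size=self.wl.size)
        quad = 0.1 - 0.03 * self.wl + 1e-5 * self.wl**2
        assert np.allclose(
            detrend(row + quad, self.wl, 2), detrend(row, self.wl, 2), atol=1e-9
        )

    def test_residual_orthogonal_to_basis(self):
        rng = np.random.default_rng(4)
        row = rng.uniform(size=self.wl.size)
        resid = detrend(row, self.wl, 2)[0]
        x = (self.wl - self.wl.mean()) / (np.ptp(self.wl) / 2)
        for basis in (np.ones_like(x), x, x**2):
            proj = abs(resid @ basis) / (np.linalg.norm(row) * np.linalg.norm(basis))
            assert proj < 1e-8


class TestMSC:
    def make_set(self, rows, wl=None):
        wl = wl if wl is not None else np.arange(850.0, 850.0 + rows.shape[1])
        return SpectraSet(wl, rows, [f"s{i}" for i in range(rows.shape[0])])

    def test_identical_rows_mean_and_floored_weights(self):
        row = np.linspace(0.2, 0.8, 30)
        s = self.make_set(np.tile(row, (4, 1)))
        state = fit_msc(s, weighted=True)
        assert np.allclose(state.mean, row)
        assert np.allclose(state.weights, state.weights[0])  # all at the floor
        assert np.all(np.isfinite(state.weights)) and np.all(state.weights > 0)

    def test_symmetric_pair_stores_midpoint(self):
        m = np.linspace(0.3, 0.9, 25)
        d = 0.05 * np.sin(np.arange(25))
        state = fit_msc(self.make_set(np.vstack([m - d, m + d])))
        assert np.allclose(state.mean, m, atol=1e-12)

    def test_exact_inversion_of_affine_distortion(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0.2, 1.0, size=40)
        s = self.make_set(np.vstack([m, m + 0.1 * rng.uniform(size=40)]))
        state = fit_msc(s)
        out = apply_msc(2.0 * state.mean + 3.0, state)
        assert np.allclose(out[0], state.mean, atol=1e-10)
        assert np.allclose(apply_msc(state.mean, state)[0], state.mean, atol=1e-10)

    def test_single_sample_set_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            fit_msc(self.make_set(np.linspace(0, 1, 20)[None, :]))

    def test_msc_shrinks_multiplicative_scatter_variance(self):
        rng = np.random.default_rng(9)
        base = 0.5 + 0.3 * np.exp(
            -0.5 * ((np.arange(200) - 100) / 30.0) ** 2
        )
        rows = np.vstack(
            [(1 + 0.2 * rng.standard_normal()) * base
             + 0.05 * rng.standard_normal() for _ in range(30)]
        )
        s = self.make_set(rows, wl=np.arange(850.0, 1050.0))
        state = fit_msc(s)
        corrected = apply_msc(rows, state)
        assert corrected.var(axis=0).mean() < 0.05 * rows.var(axis=0).mean()


class TestScalePolynomial:
    wl = np.arange(850.0, 1000.0, 1.0)

    def test_constant_row_linear_degree_gives_zeros(self):
        out = scale_polynomial(np.full(self.wl.size, 0.7), self.wl, 1)
        assert np.abs(out).max() < 1e-12

    def test_scale_invariance(self):
        row = np.random.default_rng(5).uniform(0.2, 1.0, size=self.wl.size)
        assert np.allclose(
            scale_polynomial(3.7 * row, self.wl, 2),
            scale_polynomial(row, self.wl, 2),
            atol=1e-10,
        )

    def test_mean_times_line_is_annihilated(self):
        line = 1.0 + 0.001 * (self.wl - self.wl.mean())
        row = 0.6 * line
        assert np.abs(scale_polynomial(row, self.wl, 1)).max() < 1e-12


class TestMathTreatment:
    def make_set(self, rows, wl):
        rows = np.atleast_2d(rows)
        return SpectraSet(wl, rows, [f"s{i}" for i in range(rows.shape[0])])

    def test_identity_treatment_is_noop(self, tiny_spectra):
        out = apply_math_treatment(tiny_spectra, MathTreatment(0, 0, 1, 1))
        assert np.array_equal(out.absorbance, tiny_spectra.absorbance)
        assert np.array_equal(out.wavelengths, tiny_spectra.wavelengths)

    @pytest.mark.parametrize("t", ["1,4,4,1", "2,4,4,1", "1,8,8,1", "2,8,8,1"])
    def test_first_derivative_kills_constants_second_kills_lines(self, t):
        """A derivative of order d annihilates polynomials of degree < d."""
        wl = np.arange(850.0, 1000.0, 0.5)
        treatment = MathTreatment.parse(t)
        row = (
            np.full(wl.size, 0.37)
            if treatment.derivative == 1
            else 0.2 + 0.004 * wl
        )
        out = apply_math_treatment(self.make_set(row, wl), treatment)
        assert np.abs(out.absorbance).max() < 1e-9
        assert out.n_wavelengths < wl.size

    def test_second_difference_of_square_is_constant(self):
        idx = np.arange(60.0)
        s = self.make_set(idx**2 / 100.0, wl=850.0 + idx)
        out = apply_math_treatment(s, MathTreatment(2, 4, 1, 1))
        assert np.allclose(out.absorbance, 2 * 16 / 100.0)

    def test_trimming_accounts_for_all_windows(self):
        wl = np.arange(850.0, 900.0, 0.5)
        s = self.make_set(np.random.default_rng(0).uniform(size=wl.size), wl)
        out = apply_math_treatment(s, MathTreatment(1, 4, 4, 1))
        # boxcar 4 trims 3 points, first derivative with h=2 trims 4 more
        assert out.n_wavelengths == wl.size - 3 - 4
        step = np.diff(out.wavelengths)
        assert np.allclose(step, step[0])

    def test_too_short_spectrum_raises_window_error(self):
        wl = np.arange(850.0, 853.0, 0.5)
        s = self.make_set(np.ones(wl.size), wl)
        with pytest.raises(WindowError):
            apply_math_treatment(s, MathTreatment(2, 8, 1, 1))

    def test_parse_round_trip(self):
        for text in ("0,0,1,1", "1,4,4,1", "2, 4, 4, 1"):
            assert str(MathTreatment.parse(text)) == text.replace(" ", "")


class TestApplyPretreatment:
    def test_identity_pretreatment(self, tiny_spectra):
        p = Pretreatment(MathTreatment(0, 0, 1, 1), "none")
        out, _ = apply_pretreatment(tiny_spectra, p)
        assert np.array_equal(out.absorbance, tiny_spectra.absorbance)

    def test_snv_with_derivative_runs_end_to_end(self, corn_dataset):
        spectra, _ = corn_dataset
        p = Pretreatment.parse("1,4,4,1+SNV")
        out, _ = apply_pretreatment(spectra, p)
        assert out.n_wavelengths < spectra.n_wavelengths
        assert out.n_samples == spectra.n_samples

    def test_validation_uses_calibration_state(self, corn_dataset):
        spectra, _ = corn_dataset
        cal = spectra.take(np.arange(0, 80))
        val = spectra.take(np.arange(80, 100))
        p = Pretreatment.parse("1,4,4,1+WMSC")
        cal_out, state = apply_pretreatment(cal, p)
        val_out, _ = apply_pretreatment(val, p, state=state)
        # processing the same rows inside the calibration call matches
        joint, _ = apply_pretreatment(
            spectra.take(np.arange(0, 100)), p, state=state
        )
        assert np.allclose(val_out.absorbance, joint.absorbance[80:], atol=1e-12)

    def test_pretreatment_string_round_trip(self):
        for text in ("1,4,4,1+SNV", "0,0,1,1+none", "2,8,8,1+WMSC",
                     "1,4,4,1+SL", "0,0,1,1+SNV-DT"):
            assert str(Pretreatment.parse(text)) == text

    def test_snv_detrend_composes_both_corrections(self, tiny_spectra):
        from nirscal.preprocess import detrend

        p = Pretreatment(MathTreatment(0, 0, 1, 1), "snv_detrend")
        out, _ = apply_pretreatment(tiny_spectra, p)
        expected = detrend(
            snv(tiny_spectra.absorbance), tiny_spectra.wavelengths, 2
        )
        assert np.allclose(out.absorbance, expected, atol=1e-12)

    def test_operators_commute_with_sample_reordering(self, corn_dataset):
        spectra, _ = corn_dataset
        sub = spectra.take(np.arange(30))
        perm = np.random.default_rng(2).permutation(30)
        p = Pretreatment.parse("1,4,4,1+SNV")
        a, _ = apply_pretreatment(sub.take(perm), p)
        b, _ = apply_pretreatment(sub, p)
        assert np.allclose(a.absorbance, b.absorbance[perm], atol=1e-12)
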