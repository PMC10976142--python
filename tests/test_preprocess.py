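import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ephah.preprocess import (
    MSC,
    SNV,
    STANDARD_PIPELINES,
    SavitzkyGolay,
    apply_pipeline,
    msc,
    parse_pipeline_name,
    sg_filter,
    snv,
)
from ephah.spectra import SpectraSet, WavenumberGrid
from ephah.synthetic import default_profiles


def wrap(X, step=1.0):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grid = WavenumberGrid(4000.0, step, X.shape[1])
    return SpectraSet(grid, X, [f"s{i}" for i in range(X.shape[0])])


class TestSavitzkyGolay:
    def test_constant_spectrum_unchanged(self):
        s = wrap(np.full((1, 30), 3.3))
        out = sg_filter(s, window=7, polyorder=2, deriv_order=0)
        np.testing.assert_allclose(out.absorbance, 3.3)

    def test_linear_ramp_first_derivative_constant(self):
        g = WavenumberGrid(4000.0, 2.5, 40)
        a, b = 0.7, 0.03
        s = SpectraSet(g, (a + b * g.values)[None, :], ["s0"])
        out = sg_filter(s, window=11, polyorder=2, deriv_order=1)
        # derivative in physical units: d/dν = b everywhere (edges included,
        # polynomial interpolation is exact for degree ≤ polyorder)
        np.testing.assert_allclose(out.absorbance, b, rtol=1e-9)

    def test_quadratic_second_derivative_analytic(self):
        g = WavenumberGrid(4000.0, 3.0, 50)
        nu = g.values - 4050.0
        c2 = 4e-4
        s = SpectraSet(g, (1.0 + 0.01 * nu + c2 * nu**2)[None, :], ["s0"])
        out = sg_filter(s, window=9, polyorder=2, deriv_order=2)
        np.testing.assert_allclose(out.absorbance, 2 * c2, rtol=1e-8)

    def test_full_order_polynomial_reproduces_input(self, rng):
        X = rng.normal(size=(2, 25))
        s = wrap(X)
        out = sg_filter(s, window=5, polyorder=4, deriv_order=0)
        np.testing.assert_allclose(out.absorbance, X, atol=1e-10)

    @pytest.mark.parametrize("window,poly,deriv", [
        (8, 2, 0),      # even window
        (5, 5, 0),      # window ≤ polyorder
        (101, 2, 0),    # window > n_points
        (5, 2, 3),      # deriv > polyorder
    ])
    def test_invalid_parameters_rejected(self, window, poly, deriv):
        s = wrap(np.zeros((1, 30)))
        with pytest.raises(ValueError):
            sg_filter(s, window=window, polyorder=poly, deriv_order=deriv)


class TestSNV:
    def test_simple_row(self):
        out = snv(wrap([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    def test_output_rows_standardized(self, rng):
        out = snv(wrap(rng.normal(2.0, 3.0, size=(6, 40))))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1,
                                   rtol=1e-12)

    @given(a=st.floats(0.1, 50), b=st.floats(-20, 20))
    @settings(deadline=None, max_examples=25)
    def test_affine_invariance(self, a, b):
        x = np.linspace(0.0, 1.0, 17) ** 2
        base = snv(wrap(x[None, :])).absorbance
        scaled = snv(wrap((a * x + b)[None, :])).absorbance
        np.testing.assert_allclose(scaled, base, atol=1e-8)

    def test_idempotent(self, rng):
        s = wrap(rng.normal(size=(3, 20)))
        once = snv(s)
        twice = snv(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance,
                                   atol=1e-12)

    def test_constant_row_error_names_sample(self):
        s = wrap(np.vstack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ValueError, match="s0"):
            snv(s)


class TestMSC:
    def test_identical_rows_unchanged(self):
        row = np.sin(np.linspace(0, 3, 30)) + 2
        s = wrap(np.vstack([row, row, row]))
        out = msc(s)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-10)

    def test_affine_distortion_recovered_exactly(self):
        ref = np.sin(np.linspace(0, 3, 30)) + 2
        out = msc(wrap(np.vstack([ref, 2 * ref + 5])), reference=ref)
        np.testing.assert_allclose(out.absorbance[1], ref, atol=1e-10)

    def test_coefficients_match_normal_equations(self, rng):
        X = rng.normal(size=(4, 20)) + np.linspace(1, 2, 20)
        ref = X.mean(axis=0)
        t = MSC().fit(X)
        corrected = t.transform(X)
        A = np.column_stack([ref, np.ones_like(ref)])
        for i in range(4):
            ab = np.linalg.lstsq(A, X[i], rcond=None)[0]
            np.testing.assert_allclose(corrected[i], (X[i] - ab[1]) / ab[0],
                                       atol=1e-10)

    def test_mean_reference_leaves_mean_fixed(self, rng):
        X = rng.normal(size=(5, 25)) + 3
        out = MSC().fit(X).transform(X)
        # the mean spectrum regresses on itself with a=1, b=0
        np.testing.assert_allclose(
            MSC().fit(X).transform(X.mean(axis=0)[None, :])[0],
            X.mean(axis=0), atol=1e-10)
        assert out.shape == X.shape

    def test_single_spectrum_without_reference_rejected(self):
        with pytest.raises(ValueError):
            MSC().fit(np.ones((1, 10)))


class TestPipelineGrammar:
    def test_named_combination_parses_to_fused_derivative(self):
        p = parse_pipeline_name("SNV+SG-17+2D")
        assert [s.kind for s in p.steps] == ["snv", "sg-derivative"]
        step = p.steps[1]
        assert (step.window, step.polyorder, step.deriv_order) == (17, 2, 2)

    def test_single_token(self):
        p = parse_pipeline_name("SNV")
        assert [s.kind for s in p.steps] == ["snv"]

    @pytest.mark.parametrize("name", STANDARD_PIPELINES)
    def test_catalog_round_trips(self, name):
        # parse → format → parse is the identity on the parsed steps
        p = parse_pipeline_name(name)
        assert parse_pipeline_name(p.canonical_name()).steps == p.steps

    def test_catalog_variants_distinct(self):
        parsed = [parse_pipeline_name(n).steps for n in STANDARD_PIPELINES]
        assert len(parsed) == len(set(parsed)) == 15

    def test_fused_and_compact_forms_equivalent(self):
        assert (parse_pipeline_name("SG-21+2D").steps
                == parse_pipeline_name("2D-21").steps)

    @pytest.mark.parametrize("name", ["XYZ", "SG-16", "3D", "SNV+SG-4+1D"])
    def test_bad_tokens_rejected(self, name):
        with pytest.raises(ValueError):
            parse_pipeline_name(name)


class TestApplyPipeline:
    def test_empty_pipeline_is_identity(self, rng):
        from ephah.preprocess import Pipeline
        s = wrap(rng.normal(size=(2, 15)))
        out = apply_pipeline(Pipeline(steps=()), s)
        np.testing.assert_array_equal(out.absorbance, s.absorbance)

    def test_snv_pipeline_matches_direct(self):
        out = apply_pipeline("SNV", wrap([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    def test_fused_second_derivative_matches_analytic(self):
        # fine grid so the 17-point window spans ≪ one band width and the
        # local-quadratic estimate tracks the true curvature
        grid = WavenumberGrid(4000.0, 1.0, 1600)
        profile = default_profiles(2, separation=0.0, seed=4)[0]
        pure = profile.pure_spectrum(grid)
        s = SpectraSet(grid, pure[None, :], ["s0"])
        out = apply_pipeline("SG-17+2D", s)
        nu = grid.values
        d2 = np.zeros_like(nu)
        for band, pert in zip(profile.bands, profile.band_perturbation):
            amp = band.amplitude * (1 + pert)
            z = (nu - band.center) / band.width
            d2 += amp / band.width**2 * (z**2 - 1) * np.exp(-0.5 * z**2)
        interior = slice(20, -20)
        scale = np.abs(d2).max()
        # 17-point window over σ≈16 cm⁻¹ bands: a few percent attenuation
        np.testing.assert_allclose(out.absorbance[0][interior] / scale,
                                   d2[interior] / scale, atol=0.08)
        # narrower window tracks the analytic curvature much more closely
        tight = apply_pipeline("SG-9+2D", s)
        np.testing.assert_allclose(tight.absorbance[0][interior] / scale,
                                   d2[interior] / scale, atol=0.02)

    def test_msc_reference_frozen_from_fit_context(self, rng):
        train = wrap(rng.normal(size=(6, 20)) + 5)
        test = wrap(rng.normal(size=(2, 20)) + 5)
        out = apply_pipeline("MSC", test, fit_context=train)
        ref = train.absorbance.mean(axis=0)
        expected = MSC(reference=ref).fit(train.absorbance).transform(
            test.absorbance)
        np.testing.assert_allclose(out.absorbance, expected, atol=1e-12)

    def test_step_errors_carry_step_index(self):
        s = wrap(np.ones((2, 10)))  # constant rows break SNV (step 0)
        with pytest.raises(ValueError, match="step 0"):
            apply_pipeline("SNV+MSC", s)
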