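"""Scatter corrections and the four-digit derivative/smoothing codes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from teanirs.dataset import METAL_COLUMNS, SampleTable
from teanirs.pretreat import (
    PretreatmentCode,
    apply_pretreatment,
    derivative_gap_segment,
    detrend,
    msc,
    msc_fit_reference,
    parse_treatment_code,
    snv,
)

WL = 1100.0 + 2.0 * np.arange(50)


class TestParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Detrend (2,4,4,1)", ("DT", 2, 4, 4, 1)),
            ("(0,0,1,1)", ("none", 0, 0, 1, 1)),
            ("SNV-DT (1,4,4,1)", ("SNV_DT", 1, 4, 4, 1)),
            ("msc (1, 4, 4, 1)", ("MSC", 1, 4, 4, 1)),
            ("snv (2,8,6,2)", ("SNV", 2, 8, 6, 2)),
        ],
    )
    def test_valid_codes(self, text, expected):
        code = parse_treatment_code(text)
        assert (code.scatter, code.derivative_order, code.gap,
                code.smooth1, code.smooth2) == expected

    @pytest.mark.parametrize("text", ["Detrend", "(1,2,3)", "Foo (1,1,1,1)",
                                      "(4,4,4,1)", "(-1,1,1,1)", "(2,0,1,1)"])
    def test_malformed_codes_rejected(self, text):
        with pytest.raises(ValueError):
            parse_treatment_code(text)

    def test_roundtrip_through_str(self):
        code = parse_treatment_code("Detrend (2,4,4,1)")
        assert parse_treatment_code(str(code)) == code


class TestSNV:
    def test_three_point_example(self):
        np.testing.assert_allclose(snv(np.array([0.0, 1.0, 2.0])), [-1, 0, 1])

    def test_output_moments(self, rng):
        x = rng.normal(size=(5, 80))
        out = snv(x)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_idempotent(self, rng):
        x = rng.normal(size=60)
        np.testing.assert_allclose(snv(snv(x)), snv(x), atol=1e-12)

    def test_constant_spectrum_names_the_sample(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="sample bad_one"):
            snv(x, ids=np.array(["bad_one", "ok"]))

    @given(c=st.floats(0.1, 100), offset=st.floats(-5, 5))
    @settings(deadline=None, max_examples=30)
    def test_scale_and_offset_invariance(self, c, offset):
        x = np.sin(np.linspace(0, 3, 40))
        np.testing.assert_allclose(snv(c * x + offset), snv(x), atol=1e-9)


class TestMSC:
    def test_affine_distortion_recovered(self, rng):
        ref = rng.normal(size=70)
        x = 2.0 * ref + 0.5
        np.testing.assert_allclose(msc(x, ref), ref, atol=1e-10)

    def test_reference_itself_unchanged(self, rng):
        ref = rng.normal(size=70)
        np.testing.assert_allclose(msc(ref, ref), ref, atol=1e-10)

    def test_three_point_closed_form(self):
        # x = 1 + 2*ref exactly, so a=1, b=2 and the correction restores ref
        out = msc(np.array([3.0, 5.0, 7.0]), np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0], atol=1e-12)

    def test_degenerate_slope_rejected(self):
        ref = np.array([1.0, 2.0, 3.0])
        flat = np.array([1.0, 1.0 + 1e-12, 1.0])
        with pytest.raises(ValueError, match="slope"):
            msc(flat, ref)

    def test_mean_reference_needs_two_spectra(self):
        with pytest.raises(ValueError):
            msc_fit_reference(np.ones((1, 5)))


class TestDetrend:
    def test_quadratic_annihilated(self):
        x = 3.0 + 0.01 * WL + 2e-5 * WL ** 2
        assert np.max(np.abs(detrend(x, WL, degree=2))) < 1e-9

    def test_constant_annihilated(self):
        assert np.max(np.abs(detrend(np.full(50, 7.0), WL))) < 1e-12

    def test_residual_orthogonal_to_polynomial(self, rng):
        x = rng.normal(size=50)
        out = detrend(x, WL, degree=2)
        coef = np.polyfit((WL - WL.mean()) / 100, out, 2)
        assert np.max(np.abs(coef)) < 1e-9
        assert abs(out.mean()) < 1e-9

    def test_degree_too_high_rejected(self):
        with pytest.raises(ValueError):
            detrend(np.ones(5), WL[:5], degree=4)


class TestGapSegmentDerivative:
    def test_first_difference_of_line_is_constant(self):
        slope = 0.003
        x = slope * WL
        out, wl_eff = derivative_gap_segment(x, WL, PretreatmentCode("none", 1, 4, 1, 1))
        np.testing.assert_allclose(out, 4 * slope * 2.0, atol=1e-12)
        assert wl_eff.size == WL.size - 4

    def test_second_difference_annihilates_line(self):
        x = 1.0 + 0.02 * WL
        out, _ = derivative_gap_segment(x, WL, PretreatmentCode("none", 2, 4, 4, 1))
        assert np.max(np.abs(out)) < 1e-9

    def test_zeroth_derivative_is_identity(self, rng):
        x = rng.normal(size=50)
        out, wl_eff = derivative_gap_segment(x, WL, PretreatmentCode("none", 0, 3, 1, 1))
        np.testing.assert_array_equal(out, x)
        np.testing.assert_array_equal(wl_eff, WL)

    def test_stencil_wider_than_spectrum_rejected(self):
        with pytest.raises(ValueError):
            derivative_gap_segment(np.ones(6), WL[:6],
                                   PretreatmentCode("none", 3, 4, 1, 1))

    @given(
        a=st.floats(-3, 3),
        b=st.floats(-3, 3),
        x=arrays(float, 50, elements=st.floats(-10, 10)),
        y=arrays(float, 50, elements=st.floats(-10, 10)),
    )
    @settings(deadline=None, max_examples=30)
    def test_derivative_is_linear(self, a, b, x, y):
        code = PretreatmentCode("none", 2, 4, 4, 1)
        lhs, _ = derivative_gap_segment(a * x + b * y, WL, code)
        dx, _ = derivative_gap_segment(x, WL, code)
        dy, _ = derivative_gap_segment(y, WL, code)
        np.testing.assert_allclose(lhs, a * dx + b * dy, atol=1e-7)


def _table(spectra, wl):
    n = spectra.shape[0]
    meta = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)], "class": "black",
        "fraction_black": 1.0, "fraction_green": 0.0, "fraction_red": 0.0,
        **{c: 1.0 for c in METAL_COLUMNS.values()},
    })
    return SampleTable(meta, spectra, wl)


class TestApplyPretreatment:
    def test_identity_code_leaves_table_unchanged(self, rng):
        table = _table(rng.normal(size=(3, 50)), WL)
        out, _ = apply_pretreatment(table, "none (0,0,1,1)")
        np.testing.assert_array_equal(out.spectra, table.spectra)
        np.testing.assert_array_equal(out.wavelengths, table.wavelengths)

    def test_detrend_2441_trims_eleven_points(self, default_library):
        # smooth1=4 drops 3 points, two gap-4 differences drop 8: 700 -> 689
        out, _ = apply_pretreatment(default_library, "Detrend (2,4,4,1)")
        assert out.spectra.shape[1] == 689
        assert out.wavelengths.size == 689

    def test_fitted_state_reused_bitwise(self, rng):
        table = _table(rng.normal(size=(6, 50)) + 5.0, WL)
        out1, state = apply_pretreatment(table, "MSC (1,4,4,1)")
        out2, _ = apply_pretreatment(table, "MSC (1,4,4,1)", state)
        np.testing.assert_array_equal(out1.spectra, out2.spectra)

    def test_msc_state_transfers_to_new_data(self, rng):
        cal = _table(rng.normal(size=(6, 50)) + 5.0, WL)
        _, state = apply_pretreatment(cal, "MSC (0,0,1,1)")
        x = 3.0 * state["msc_reference"] - 1.0
        val = _table(x[None, :], WL)
        out, _ = apply_pretreatment(val, "MSC (0,0,1,1)", state)
        np.testing.assert_allclose(out.spectra[0], state["msc_reference"], atol=1e-9)

    @pytest.mark.parametrize("code", ["SNV (0,0,1,1)", "Detrend (0,0,1,1)",
                                      "none (1,4,1,1)", "SNV-DT (2,4,4,1)"])
    def test_additive_offset_removed(self, code, rng):
        x = rng.normal(size=(2, 50))
        a, _ = apply_pretreatment(_table(x, WL), code)
        b, _ = apply_pretreatment(_table(x + 42.0, WL), code)
        np.testing.assert_allclose(a.spectra, b.spectra, atol=1e-9)
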