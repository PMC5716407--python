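import numpy as np
import pytest
from hypothesis import given, strategies as st

from protondose.curves import (
    DepthCurve,
    IDENTITY_RESPONSE,
    ResponseModel,
    apply_response,
    build_sobp,
    calibrate_response,
    pristine_bragg,
    read_curve,
    sobp_curve,
    straggling_sigma,
    write_curve,
)


class TestDepthCurve:
    def test_rejects_non_monotone_depths(self):
        with pytest.raises(ValueError):
            DepthCurve(np.array([0.0, 10.0, 5.0]), np.array([1.0, 1.0, 1.0]))

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            DepthCurve(np.array([0.0, 1.0]), np.array([1.0, -0.1]))

    def test_lookup_at_knot(self):
        c = DepthCurve(np.array([0.0, 10.0, 20.0]), np.array([1.0, 2.0, 0.5]))
        assert c.lookup(10.0) == 2.0

    def test_lookup_midpoint_is_mean(self):
        c = DepthCurve(np.array([0.0, 10.0]), np.array([1.0, 3.0]))
        assert c.lookup(5.0) == pytest.approx(2.0)

    def test_lookup_beyond_table_is_zero(self):
        c = DepthCurve(np.array([0.0, 10.0]), np.array([1.0, 3.0]))
        assert c.lookup(11.0) == 0.0

    def test_lookup_before_table_is_first_value(self):
        c = DepthCurve(np.array([5.0, 10.0]), np.array([2.0, 3.0]))
        assert c.lookup(0.0) == 2.0

    def test_normalize_rescales_by_one_constant(self):
        c = DepthCurve(np.array([0.0, 5.0, 10.0]), np.array([2.0, 4.0, 1.0]))
        n = c.normalize()
        assert n.lookup(0.0) == pytest.approx(1.0)
        assert np.allclose(n.values * 2.0, c.values)


class TestPristineBragg:
    def test_argmax_location_239(self):
        c = pristine_bragg(239.0)
        assert 229.0 < c.peak_depth < 239.0

    def test_normalized_at_zero(self):
        c = pristine_bragg(239.0).normalize()
        assert c.lookup(0.0) == pytest.approx(1.0)

    def test_distal_falloff_to_zero(self):
        c = pristine_bragg(150.0)
        assert c.lookup(150.0 + 10.0 * straggling_sigma(150.0)) == 0.0

    @pytest.mark.parametrize("range_mm", [100.0, 180.0, 239.0, 320.0])
    def test_distal_80_within_1mm(self, range_mm):
        c = pristine_bragg(range_mm)
        peak = c.values.max()
        i = int(np.argmax(c.values))
        d80 = np.interp(-0.8 * peak, -c.values[i:], c.depths[i:])
        assert abs(d80 - range_mm) < 1.0

    def test_single_maximum(self):
        c = pristine_bragg(200.0)
        d = np.sign(np.diff(c.values[c.values > 1e-12]))
        # one sign change: rises then falls
        assert np.sum(np.diff(d) != 0) <= 1

    @pytest.mark.parametrize("range_mm", [5.0, 400.0, -10.0])
    def test_domain_errors(self, range_mm):
        with pytest.raises(ValueError):
            pristine_bragg(range_mm)


class TestSOBP:
    def test_width_zero_returns_deepest(self):
        c = build_sobp([200.0, 220.0], 0.0)
        ref = pristine_bragg(220.0).normalize()
        assert np.allclose(c.values, ref.values)

    def test_flatness_within_2pct(self):
        c = sobp_curve(239.0, 50.0)
        deepest_peak = pristine_bragg(239.0).peak_depth
        grid = np.arange(239.0 - 50.0, deepest_peak, 0.5)
        plateau = c.lookup(grid)
        mean = plateau.mean()
        assert plateau.max() / mean <= 1.02
        assert plateau.min() / mean >= 0.98

    def test_infeasible_spacing_raises_naming_flatness(self):
        ranges = [239.0, 214.0, 189.0]  # 25 mm spacing is far too coarse
        with pytest.raises(ValueError, match="flatness"):
            build_sobp(ranges, 50.0)

    def test_insufficient_proximal_coverage_raises(self):
        with pytest.raises(ValueError):
            build_sobp([239.0, 236.0], 50.0)

    def test_values_non_negative(self):
        c = sobp_curve(180.0, 30.0)
        assert np.all(c.values >= 0)


class TestResponseModel:
    def test_sensitivity_plateau(self):
        m = ResponseModel(r0=40.0, a=0.3, b=0.67)
        assert m.sensitivity(40.0) == 1.0
        assert m.sensitivity(100.0) == 1.0

    def test_sensitivity_monotone_toward_zero_range(self):
        m = ResponseModel(r0=40.0, a=0.3, b=0.67)
        rs = np.linspace(0, 50, 200)
        s = m.sensitivity(rs)
        assert np.all(np.diff(s) >= -1e-12)
        assert np.all((s > 0) & (s <= 1))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ResponseModel(r0=40.0, a=1.2, b=0.67)
        with pytest.raises(ValueError):
            ResponseModel(r0=-1.0, a=0.2, b=0.67)

    @given(st.floats(0.0, 200.0))
    def test_sensitivity_in_unit_interval(self, r):
        m = ResponseModel(r0=40.0, a=0.5, b=1.3)
        assert 0.0 < m.sensitivity(r) <= 1.0


class TestApplyResponse:
    def test_peak_ratio_073(self, dd190, do190):
        i = int(np.argmax(dd190.values))
        assert do190.values[i] / dd190.values[i] == pytest.approx(0.73, abs=1e-12)

    def test_plateau_ratio_unity(self, dd190, do190):
        assert do190.values[0] / dd190.values[0] == pytest.approx(1.0)

    def test_identity_model_is_identity(self, dd190):
        do = apply_response(dd190, IDENTITY_RESPONSE)
        assert np.allclose(do.values, dd190.values)
        assert do.kind == "output"

    def test_never_increases_values(self, dd190, do190):
        assert np.all(do190.values <= dd190.values + 1e-15)

    def test_ratio_monotone_non_increasing(self, dd190, do190):
        m = dd190.values > 1e-9
        ratio = do190.values[m] / dd190.values[m]
        assert np.all(np.diff(ratio) <= 1e-12)

    def test_requires_dose_kind(self, do190, response_model):
        with pytest.raises(ValueError):
            apply_response(do190, response_model)

    def test_calibration_solves_requested_ratio(self, dd190):
        m = calibrate_response(dd190, peak_ratio=0.85)
        do = apply_response(dd190, m)
        i = int(np.argmax(dd190.values))
        assert do.values[i] / dd190.values[i] == pytest.approx(0.85, abs=1e-12)


class TestCurveIO:
    def test_roundtrip_identical(self, tmp_path, dd190):
        p = tmp_path / "dd.csv"
        write_curve(dd190, p)
        back = read_curve(p)
        assert np.allclose(back.depths, dd190.depths, rtol=1e-12)
        assert np.allclose(back.values, dd190.values, rtol=1e-12)
        assert back.kind == dd190.kind
        assert back.range_mm == pytest.approx(dd190.range_mm, rel=1e-12)

    def test_non_monotone_depths_error_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# kind=dose normalization_depth=0 range_mm=none\n"
                     "depth_mm,value\n10,1.0\n5,1.0\n")
        with pytest.raises(ValueError, match="line 4"):
            read_curve(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError):
            read_curve(p)

    def test_negative_value_errors(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text("# kind=dose\ndepth_mm,value\n0,1.0\n1,-0.5\n")
        with pytest.raises(ValueError, match="line 4"):
            read_curve(p)

    def test_malformed_header_errors(self, tmp_path):
        p = tmp_path / "hdr.csv"
        p.write_text("depth_mm,value\n0,1\n1,2\n")
        with pytest.raises(ValueError, match="line 1"):
            read_curve(p)
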