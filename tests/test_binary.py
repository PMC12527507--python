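"""OR, RR, IRR, NNT formulas and cross-measure conversions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esconvert import binary, smd
from esconvert.estimate import InputError, UndefinedEffectError

APPROX = dict(abs=1e-4)


class TestLogOR:
    def test_worked_example(self):
        est = binary.logor_from_2x2(20, 80, 10, 90)
        assert est.value == pytest.approx(2.2500, **APPROX)
        assert math.log(est.value) == pytest.approx(0.81093, **APPROX)
        assert est.se == pytest.approx(0.416667, **APPROX)
        assert est.scale == "log"

    def test_cross_product_balance_gives_unity(self):
        assert binary.logor_from_2x2(10, 40, 20, 80).value == pytest.approx(1.0)

    def test_zero_cell_correction_applied_to_all_cells(self):
        est = binary.logor_from_2x2(0, 10, 5, 5)
        assert est.value == pytest.approx((0.5 * 5.5) / (10.5 * 5.5), **APPROX)

    def test_no_correction_without_zero_cell(self):
        est = binary.logor_from_2x2(20, 80, 10, 90)
        assert est.value == pytest.approx(2.25)  # exact, uncorrected

    def test_empty_margin_rejected(self):
        with pytest.raises(InputError):
            binary.logor_from_2x2(0, 0, 5, 5)

    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_group_swap_inverts_or(self, a, b, c, d):
        x = binary.logor_from_2x2(a, b, c, d)
        y = binary.logor_from_2x2(c, d, a, b)
        assert math.log(x.value) == pytest.approx(-math.log(y.value), abs=1e-9)

    def test_lnor_increasing_in_a(self):
        vals = [binary.logor_from_2x2(a, 100 - a, 10, 90).value
                for a in range(1, 100, 7)]
        assert all(x < y for x, y in zip(vals, vals[1:]))


class TestLogRR:
    def test_worked_example(self):
        est = binary.logrr_from_2x2(20, 80, 10, 90)
        assert est.value == pytest.approx(2.0000, **APPROX)
        assert est.se == pytest.approx(math.sqrt(0.13), **APPROX)

    def test_equal_risks_give_unity(self):
        assert binary.logrr_from_2x2(10, 90, 10, 90).value == pytest.approx(1.0)

    def test_proportions_reconstruction_matches_counts(self):
        a, b, c, d = 0.2 * 100, 0.8 * 100, 0.1 * 100, 0.9 * 100
        est = binary.logrr_from_2x2(a, b, c, d)
        ref = binary.logrr_from_2x2(20, 80, 10, 90)
        assert est.value == pytest.approx(ref.value, abs=1e-12)
        assert est.se == pytest.approx(ref.se, abs=1e-12)

    @given(
        a=st.integers(1, 99), c=st.integers(1, 99),
    )
    @settings(max_examples=100, deadline=None)
    def test_or_is_farther_from_unity_than_rr(self, a, c):
        orr = binary.logor_from_2x2(a, 100 - a, c, 100 - c)
        rr = binary.logrr_from_2x2(a, 100 - a, c, 100 - c)
        assert abs(math.log(orr.value)) >= abs(math.log(rr.value)) - 1e-12
        assert math.log(orr.value) * math.log(rr.value) >= -1e-12  # same side


class TestIRR:
    def test_worked_example(self):
        est = binary.logirr_from_rates(30, 100, 20, 100)
        assert est.value == pytest.approx(1.5000, **APPROX)
        assert est.se == pytest.approx(0.28868, **APPROX)

    def test_equal_rates_give_unity(self):
        assert binary.logirr_from_rates(10, 50, 20, 100).value == pytest.approx(1.0)

    def test_single_zero_count_corrected(self):
        est = binary.logirr_from_rates(0, 100, 20, 100)
        assert est.value == pytest.approx(0.025, **APPROX)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedEffectError):
            binary.logirr_from_rates(0, 100, 0, 100)


class TestReportedRatio:
    def test_or_with_ci(self):
        est = binary.ratio_from_reported(
            "OR", value=2.25, ci=(0.9937, 5.0945))
        assert est.se == pytest.approx(0.41665, abs=1e-3)
        assert est.route == "or_ci"

    def test_unity_or_symmetric_ci(self):
        est = binary.ratio_from_reported("OR", value=1.0, ci=(0.5, 2.0))
        assert est.se == pytest.approx(math.log(4) / 3.92, **APPROX)

    def test_ci_must_contain_point_estimate(self):
        with pytest.raises(InputError, match="contain"):
            binary.ratio_from_reported("OR", value=2.25, ci=(2.5, 5.0))

    def test_log_scale_input(self):
        est = binary.ratio_from_reported("IRR", log_value=0.4, log_se=0.1)
        assert est.value == pytest.approx(math.exp(0.4))


class TestDLnORConversion:
    def test_worked_example(self):
        d = smd.d_from_means(103, 100, 10, 10, 50, 50)
        orr = binary.logor_from_d(d)
        assert math.log(orr.value) == pytest.approx(0.54414, **APPROX)

    def test_zero_d_maps_to_unity_or(self):
        d = smd.d_from_means(5, 5, 1, 1, 20, 20)
        assert binary.logor_from_d(d).value == pytest.approx(1.0)

    @pytest.mark.parametrize("method", binary.D_TO_LNOR_METHODS)
    def test_round_trip_is_algebraic(self, method):
        d = smd.d_from_means(5, 3, 2, 4, 10, 10)
        back = binary.d_from_logor(binary.logor_from_d(d, method), method)
        assert back.value == pytest.approx(d.value, abs=1e-12)
        assert back.se == pytest.approx(d.se, abs=1e-12)


class TestORtoRR:
    def _or(self, value=2.25, se=0.4):
        return binary.ratio_from_reported(
            "OR", log_value=math.log(value), log_se=se)

    def test_registry_has_six_methods(self):
        assert len(binary.OR_TO_RR_METHODS) == 6

    def test_zhang_yu_worked_example(self):
        rr = binary.rr_from_or(self._or(2.25), baseline_risk=0.1)
        assert rr.value == pytest.approx(2.0000, **APPROX)
        assert rr.method == "zhang_yu"

    @pytest.mark.parametrize("method", sorted(binary.OR_TO_RR_METHODS))
    def test_unity_or_maps_to_unity_rr_all_methods(self, method):
        rr = binary.rr_from_or(
            self._or(1.0), baseline_risk=0.2, method=method, n1=100, n2=100)
        assert rr.value == pytest.approx(1.0, abs=1e-9)

    def test_rare_disease_is_identity(self):
        rr = binary.rr_from_or(self._or(2.25), method="rare_disease")
        assert rr.value == pytest.approx(2.25)

    def test_sqrt_or(self):
        rr = binary.rr_from_or(self._or(4.0), method="sqrt_or")
        assert rr.value == pytest.approx(2.0)

    def test_reconstructed_2x2_matches_zhang_yu_value(self):
        # with exact risks both approaches express the same identity
        rr = binary.rr_from_or(
            self._or(2.25), baseline_risk=0.1, method="reconstructed_2x2",
            n1=1000, n2=1000)
        assert rr.value == pytest.approx(2.0, abs=1e-6)

    def test_method_requiring_baseline_without_one_errors(self):
        with pytest.raises(InputError, match="baseline"):
            binary.rr_from_or(self._or(2.25), method="zhang_yu")

    def test_inverse_zhang_yu_round_trips(self):
        rr = binary.rr_from_or(self._or(2.25), baseline_risk=0.1)
        back = binary.or_from_rr(rr, 0.1)
        assert back.value == pytest.approx(2.25, abs=1e-10)


class TestNNT:
    def test_from_2x2_risks(self):
        est = binary.nnt_from_risks(0.2, 0.1, 100, 100)
        assert est.value == pytest.approx(10.0, **APPROX)
        assert est.scale == "risk_diff"

    def test_furukawa_from_d(self):
        d = smd.d_from_means(103, 100, 10, 10, 50, 50)
        est = binary.nnt_from_d(d, cer=0.2)
        assert est.value == pytest.approx(10.6338, abs=1e-3)
        assert est.method == "furukawa"

    def test_equal_risks_flagged_infinite(self):
        with pytest.raises(UndefinedEffectError, match="infinite"):
            binary.nnt_from_risks(0.2, 0.2, 100, 100)

    def test_via_or_route(self):
        orr = binary.ratio_from_reported(
            "OR", log_value=math.log(2.25), log_se=0.4)
        est = binary.nnt_from_or(orr, baseline_risk=0.1)
        # Zhang-Yu RR = 2.0 -> ARD = 0.1 -> NNT = 10
        assert est.value == pytest.approx(10.0, **APPROX)

    def test_nnt_reported_unrounded(self):
        est = binary.nnt_from_risks(0.35, 0.21, 80, 80)
        assert est.value == pytest.approx(1 / 0.14, **APPROX)


def test_lnor_se_shrinks_with_cell_size():
    ses = [binary.logor_from_2x2(2 * k, 8 * k, k, 9 * k).se
           for k in (1, 10, 100)]
    assert ses[0] > ses[1] > ses[2]
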