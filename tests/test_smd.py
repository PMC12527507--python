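"""Cohen's d, Hedges' g and MD formulas against hand-computed oracles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esconvert import smd
from esconvert.estimate import (
    DirectionRequiredError,
    InputError,
    UndefinedEffectError,
)

APPROX = dict(abs=1e-4)


class TestDFromMeans:
    @pytest.mark.parametrize(
        "args,d,se",
        [
            ((103, 100, 10, 10, 50, 50), 0.3000, 0.201122),
            ((5, 3, 2, 4, 10, 10), 0.632456, math.sqrt(0.21)),
        ],
    )
    def test_worked_examples(self, args, d, se):
        est = smd.d_from_means(*args)
        assert est.value == pytest.approx(d, **APPROX)
        assert est.se == pytest.approx(se, **APPROX)
        assert est.route == "means_sd"
        assert est.df_like == args[4] + args[5] - 2
        assert est.ci_lo == pytest.approx(est.value - 1.96 * est.se)

    def test_equal_means_give_zero(self):
        assert smd.d_from_means(7, 7, 2, 3, 20, 30).value == 0.0

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(InputError):
            smd.d_from_means(1, 0, 0, 0, 10, 10)

    @given(
        m1=st.floats(-50, 50), m2=st.floats(-50, 50),
        sd=st.floats(0.5, 20), n1=st.integers(2, 200),
        n2=st.integers(2, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_group_swap_negates_d(self, m1, m2, sd, n1, n2):
        a = smd.d_from_means(m1, m2, sd, sd, n1, n2)
        b = smd.d_from_means(m2, m1, sd, sd, n2, n1)
        assert a.value == pytest.approx(-b.value, abs=1e-10)
        assert a.se == pytest.approx(b.se, abs=1e-10)


class TestMomentsFromPrecision:
    def test_from_se(self):
        assert smd.moments_from_precision(10, 25, se=2) == (10, 10.0)

    def test_from_ci(self):
        mean, sd = smd.moments_from_precision(10, 25, ci=(6.08, 13.92))
        assert sd == pytest.approx(10.0, **APPROX)

    def test_zero_width_ci_rejected(self):
        with pytest.raises(InputError):
            smd.moments_from_precision(10, 25, ci=(5, 5))


class TestDFromTestStat:
    def test_from_t(self):
        est = smd.d_from_test_stat("t", 2.0, 50, 50)
        assert est.value == pytest.approx(0.4000, **APPROX)
        assert est.route == "t"

    def test_from_f_with_direction(self):
        est = smd.d_from_test_stat("F", 4.0, 50, 50, "positive")
        assert est.value == pytest.approx(0.4000, **APPROX)
        neg = smd.d_from_test_stat("F", 4.0, 50, 50, "negative")
        assert neg.value == pytest.approx(-0.4000, **APPROX)

    def test_from_p_two_tailed(self):
        est = smd.d_from_test_stat("p", 0.05, 50, 50, "positive")
        assert est.value == pytest.approx(0.396893, **APPROX)

    def test_from_eta_squared(self):
        # eta^2 = t^2/(t^2+df) at t=2, df=98 -> d = 2t/sqrt(df)
        eta = 4 / (4 + 98)
        est = smd.d_from_test_stat("eta2", eta, 50, 50, "positive")
        assert est.value == pytest.approx(4 / math.sqrt(98), **APPROX)

    @pytest.mark.parametrize("stat,value", [("F", 4.0), ("p", 0.05), ("eta2", 0.04)])
    def test_signless_stat_requires_direction(self, stat, value):
        with pytest.raises(DirectionRequiredError):
            smd.d_from_test_stat(stat, value, 50, 50, "unspecified")

    def test_t_and_p_routes_agree(self):
        t_est = smd.d_from_test_stat("t", 2.5, 40, 40)
        from scipy import stats

        p = 2 * stats.t.sf(2.5, 78)
        p_est = smd.d_from_test_stat("p", p, 40, 40, "positive")
        assert p_est.value == pytest.approx(t_est.value, abs=1e-10)


class TestMomentsFromQuantiles:
    def test_iqr_only_worked_example(self):
        mean, sd = smd.moments_from_quantiles(25, med=10, q1=8, q3=12)
        assert mean == pytest.approx(10.000, **APPROX)
        assert sd == pytest.approx(3.14447, **APPROX)

    def test_symmetric_quartiles_give_median_as_mean(self):
        mean, _ = smd.moments_from_quantiles(40, med=5, q1=3, q3=7)
        assert mean == pytest.approx(5.0, abs=1e-10)

    def test_degenerate_iqr_gives_zero_sd(self):
        _, sd = smd.moments_from_quantiles(25, med=10, q1=10, q3=10)
        assert sd == 0.0

    def test_ordering_violation_rejected(self):
        with pytest.raises(InputError, match="ordering"):
            smd.moments_from_quantiles(25, med=10, q1=12, q3=8)

    def test_all_three_scenarios_recover_planted_sd(self):
        # quantiles placed at the estimators' own plotting positions
        from scipy import stats

        n, m, sd = 60, 20.0, 4.0
        zr = stats.norm.ppf((n - 0.375) / (n + 0.25))
        zq = stats.norm.ppf((0.75 * n - 0.125) / (n + 0.25))
        kw = dict(med=m, q1=m - zq * sd, q3=m + zq * sd,
                  minimum=m - zr * sd, maximum=m + zr * sd)
        for scen in ("range_only", "iqr_only", "both"):
            mean, sd_hat = smd.moments_from_quantiles(n, scenario=scen, **kw)
            assert mean == pytest.approx(m, abs=1e-9)
            assert sd_hat == pytest.approx(sd, abs=1e-9)


class TestChangeAndAncova:
    def test_change_reduces_to_means_oracle(self):
        # sd_pre = sd_post = 10, r = .5 -> change SD 10 per group
        est = smd.d_from_change(13, 10, 10, 10, 10, 10, 10, 10, 0.5, 50, 50)
        ref = smd.d_from_means(3, 0, 10, 10, 50, 50)
        assert est.value == pytest.approx(ref.value, abs=1e-12)
        assert est.route == "change_scores"

    def test_r_zero_is_pythagorean(self):
        assert smd.change_score_sd(10, 10, 0.0) == pytest.approx(
            math.sqrt(200), **APPROX
        )

    def test_missing_r_prepost_instructive_error(self):
        with pytest.raises(InputError, match="pre-post correlation"):
            smd.change_score_sd(10, 10, None)

    def test_perfect_correlation_degenerate(self):
        with pytest.raises(UndefinedEffectError):
            smd.d_from_change(1, 0, 10, 10, 0, 0, 10, 10, 1 - 1e-16, 50, 50)

    def test_ancova_direct(self):
        est = smd.d_from_ancova(10.3, 10.0, 1.0, 50, 50)
        assert est.value == pytest.approx(0.3000, **APPROX)
        assert est.route == "ancova_means"

    def test_ancova_zero_sd_rejected(self):
        with pytest.raises(InputError):
            smd.d_from_ancova(1, 0, 0, 50, 50)


class TestHedges:
    def test_worked_example(self):
        d = smd.d_from_means(103, 100, 10, 10, 50, 50)
        g = smd.hedges_correction(d)
        assert g.measure == "G"
        assert g.value == pytest.approx(0.29770, **APPROX)
        assert g.route == d.route
        assert smd.j_factor(98) == pytest.approx(0.992327, **APPROX)

    def test_zero_d_maps_to_zero_g(self):
        g = smd.hedges_correction(smd.d_from_means(5, 5, 2, 2, 20, 20))
        assert g.value == 0.0

    def test_j_in_unit_interval_and_monotone(self):
        js = [smd.j_factor(df) for df in range(2, 500)]
        assert all(0 < j < 1 for j in js)
        assert all(a < b for a, b in zip(js, js[1:]))

    def test_g_approaches_d_for_large_df(self):
        d = smd.d_from_means(10.3, 10.0, 1.0, 1.0, 5000, 5000)
        g = smd.hedges_correction(d)
        assert abs(g.value - d.value) < 1e-3


class TestMD:
    def test_from_means(self):
        est = smd.md_from_means(103, 100, 10, 10, 50, 50)
        assert est.value == 3.0
        assert est.se == pytest.approx(2.0, **APPROX)

    def test_from_reported_ci(self):
        est = smd.md_from_reported(3, ci=(-0.92, 6.92))
        assert est.se == pytest.approx(2.0, **APPROX)
        assert est.route == "md_ci"

    def test_group_swap_negates(self):
        a = smd.md_from_means(7, 3, 2, 5, 12, 30)
        b = smd.md_from_means(3, 7, 5, 2, 30, 12)
        assert a.value == -b.value and a.se == b.se


def test_d_variance_shrinks_with_n():
    ses = [smd.d_from_means(1, 0, 2, 2, n, n).se for n in (10, 50, 250)]
    assert ses[0] > ses[1] > ses[2]
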