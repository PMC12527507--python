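"""Route detection, candidate enumeration, selection, convert_df."""

import math

import pandas as pd
import pytest

from esconvert import (
    Hierarchy,
    convert_df,
    enumerate_candidates,
    select_main,
)
from esconvert.estimate import InputError


def _means_row(make_row, **extra):
    return make_row(
        study_id="s1", n1=50, n2=50, m1=103.0, m2=100.0, sd1=10.0, sd2=10.0,
        **extra,
    )


class TestEnumerateCandidates:
    def test_one_candidate_per_applicable_route(self, make_row):
        # means+SD, t, and p (direction set) -> three G candidates
        row = _means_row(
            make_row, t_value=1.5, p_value=0.1366, es_direction="positive"
        )
        cs = enumerate_candidates(row, "G")
        assert cs.routes_available == ("means_sd", "t", "p")

    def test_empty_row_yields_note_not_error(self, make_row):
        cs = enumerate_candidates(make_row(study_id="s1"), "D")
        assert cs.candidates == ()
        assert any("no applicable input data" in m for _, m in cs.notes)

    def test_missing_direction_recorded_as_note(self, make_row):
        row = _means_row(make_row, f_value=4.0)  # direction unspecified
        cs = enumerate_candidates(row, "D")
        assert "f" not in cs.routes_available
        assert any(r == "f" and "direction" in m for r, m in cs.notes)

    def test_formula_error_never_aborts_row(self, make_row):
        # invalid quantile ordering errors in one route; means_sd survives
        row = _means_row(
            make_row, med1=10.0, q1_1=12.0, q3_1=8.0, med2=9.0, q1_2=8.0,
            q3_2=10.0,
        )
        cs = enumerate_candidates(row, "D")
        assert "means_sd" in cs.routes_available
        assert any(r == "med_iqr" for r, _ in cs.notes)

    def test_self_consistent_t_agrees_with_means(self, make_row):
        d = 0.3
        t = d / math.sqrt(1 / 50 + 1 / 50)
        cs = enumerate_candidates(_means_row(make_row, t_value=t), "D")
        by_route = {c.route: c for c in cs.candidates}
        assert by_route["t"].value == pytest.approx(
            by_route["means_sd"].value, abs=1e-12
        )


class TestSelectMain:
    def test_custom_hierarchy_prefers_earliest_route(self, make_row):
        cs = enumerate_candidates(_means_row(make_row, t_value=1.5), "G")
        sel = select_main(cs, "hierarchy", Hierarchy.parse("means_sd>t>p"))
        assert sel.route_used == "means_sd"

    def test_hierarchy_without_overlap_falls_back_to_auto(self, make_row, caplog):
        import logging

        cs = enumerate_candidates(_means_row(make_row), "G")
        with caplog.at_level(logging.WARNING, logger="esconvert"):
            sel = select_main(cs, "hierarchy", Hierarchy.parse("rates>irr_ci"))
        assert sel.route_used == "means_sd"
        assert "falling back" in caplog.text

    def test_smallest_largest_use_absolute_comparison_value(self, make_row):
        # means give d=+0.3; a discordant t gives d=-0.4
        row = _means_row(make_row, t_value=-2.0)
        cs = enumerate_candidates(row, "D")
        assert select_main(cs, "smallest").selected.value == pytest.approx(0.3)
        assert select_main(cs, "largest").selected.value == pytest.approx(-0.4)

    def test_single_candidate_selected_under_any_strategy(self, make_row):
        cs = enumerate_candidates(_means_row(make_row), "D")
        for strategy in ("auto", "smallest", "largest"):
            assert select_main(cs, strategy).route_used == "means_sd"

    def test_auto_follows_predefined_order(self, make_row):
        # reported MD+SE should outrank the t statistic for D
        row = make_row(study_id="s", n1=40, n2=40, md_value=3.0, md_se=2.0,
                       t_value=1.5)
        sel = select_main(enumerate_candidates(row, "D"), "auto")
        assert sel.route_used == "md_se"

    def test_selection_is_pure(self, make_row):
        cs = enumerate_candidates(_means_row(make_row, t_value=1.5), "D")
        a = select_main(cs, "auto")
        b = select_main(cs, "auto")
        assert a.route_used == b.route_used
        assert cs.selected is None  # input untouched

    def test_strategy_validation(self, make_row):
        cs = enumerate_candidates(_means_row(make_row), "D")
        with pytest.raises(InputError):
            select_main(cs, "bogus")
        with pytest.raises(InputError):
            select_main(cs, "hierarchy", None)


class TestConvertDf:
    def _frame(self):
        return pd.DataFrame(
            [
                {"study_id": "s1", "n1": 50, "n2": 50, "m1": 103.0,
                 "m2": 100.0, "sd1": 10.0, "sd2": 10.0},
                {"study_id": "s2", "n1": 40, "n2": 40, "m1": 5.0, "m2": 3.0,
                 "sd1": 2.0, "sd2": 2.0, "t_value": 2.0 / (2 * math.sqrt(2 / 40))},
                {"study_id": "s3", "r_value": 0.4, "n_r": 80},
            ]
        )

    def test_structure_one_output_row_per_input_row(self):
        out = convert_df(self._frame(), "D")
        assert list(out["study_id"]) == ["s1", "s2", "s3"]
        # only the two-route row carries consistency columns
        assert math.isnan(out.loc[0, "ci_overlap_pct"])
        assert out.loc[1, "ci_overlap_pct"] == pytest.approx(100.0, abs=0.5)
        assert math.isnan(out.loc[2, "es_sd"])

    def test_deterministic_bit_identical_output(self):
        a = convert_df(self._frame(), "G")
        b = convert_df(self._frame(), "G")
        pd.testing.assert_frame_equal(a, b)

    def test_or_from_own_2x2_and_ci_agree(self, make_row):
        """An OR+CI built from the same 2x2 yields matching candidates and
        a near-zero consistency diff."""
        import esconvert.binary as binary

        base = binary.logor_from_2x2(20, 80, 10, 90)
        frame = pd.DataFrame(
            [{
                "study_id": "s1", "a": 20, "b": 80, "c": 10, "d_cell": 90,
                "or_value": base.value, "or_ci_lo": base.ci_lo,
                "or_ci_up": base.ci_up,
            }]
        )
        out = convert_df(frame, "OR")
        assert out.loc[0, "n_candidates"] == 2
        assert out.loc[0, "es_diff"] == pytest.approx(0.0, abs=1e-6)
        assert out.loc[0, "ci_overlap_pct"] == pytest.approx(100.0, abs=1e-6)

    def test_row_without_routes_gets_note_and_blanks(self):
        out = convert_df(pd.DataFrame([{"study_id": "s1"}]), "D")
        assert out.loc[0, "route_used"] == ""
        assert "no applicable input data" in out.loc[0, "note"]

    def test_accepts_path_input(self, tmp_path):
        path = tmp_path / "d.csv"
        self._frame().to_csv(path, index=False)
        out = convert_df(path, "D")
        assert len(out) == 3

    def test_ratio_consistency_reported_on_log_scale(self):
        frame = pd.DataFrame(
            [{"study_id": "s1", "a": 20, "b": 80, "c": 10, "d_cell": 90,
              "n1": 100, "n2": 100, "p_event1": 0.2, "p_event2": 0.1}]
        )
        out = convert_df(frame, "OR")
        assert out.loc[0, "consistency_scale"] == "log"
        assert out.loc[0, "es_min"] == pytest.approx(math.log(2.25), abs=1e-6)
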