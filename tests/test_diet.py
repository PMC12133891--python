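"""Diet parsing, bound application, and composition-feature tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietwbm.diet as dm
from dietwbm import solver
from dietwbm import synthetic_data as sd
from dietwbm.model_core import ReactionKind


class TestParseDiet:
    def test_prefixed_identifier_normalized(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("Diet_EX_glc_D[d]\t100\n")
        spec = dm.parse_diet(p)
        assert spec.entries == {"glc_D": 100.0}

    def test_duplicate_rows_summed(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("Diet_EX_x[d]\t40\nDiet_EX_x[d]\t60\n")
        assert dm.parse_diet(p).entries == {"x": 100.0}

    def test_negative_amount_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("Diet_EX_x[d]\t-5\n")
        with pytest.raises(dm.DietError, match="negative"):
            dm.parse_diet(p)

    def test_bad_row_reports_line_number(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("rxn\tamount\nDiet_EX_x[d]\t1\nonly_one_column\n")
        with pytest.raises(dm.DietError, match=":3"):
            dm.parse_diet(p)

    def test_header_and_comments_skipped(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("rxn_or_nutrient_id\tamount_mmol_per_day\n"
                     "# note\nDiet_EX_x[d]\t2.5\n")
        assert dm.parse_diet(p).entries == {"x": 2.5}

    def test_round_trip(self, tmp_path, toy_diets):
        for d in toy_diets[:3]:
            path = tmp_path / f"{d.name}.tsv"
            dm.write_diet(d, path)
            back = dm.parse_diet(path)
            assert back.name == d.name
            assert back.entries == pytest.approx(d.entries)


class TestApplyDiet:
    def test_optional_uptake_bounds(self, male_model):
        model = dm.apply_diet(male_model[0], dm.DietSpec("x", {"glc_D": 100.0}))
        r = model.reaction("Diet_EX_glc_D[d]")
        assert (r.lb, r.ub) == (-100.0, 0.0)

    def test_forced_uptake_bounds(self, male_model, forced_policy):
        model = dm.apply_diet(male_model[0], dm.DietSpec("x", {"glc_D": 100.0}),
                              forced_policy)
        r = model.reaction("Diet_EX_glc_D[d]")
        assert (r.lb, r.ub) == (-100.0, -80.0)

    def test_close_unlisted_shuts_other_diet_exchanges(self, male_model):
        model = dm.apply_diet(male_model[0], dm.DietSpec("x", {"glc_D": 1.0}))
        for r in model.reactions:
            if r.kind is ReactionKind.DIET_EXCHANGE and r.id != "Diet_EX_glc_D[d]":
                assert r.lb == 0.0

    def test_non_diet_bounds_untouched(self, male_model, toy_diets, forced_policy):
        base, _ = male_model
        applied = dm.apply_diet(base, toy_diets[0], forced_policy)
        for a, b in zip(base.reactions, applied.reactions):
            if a.kind is not ReactionKind.DIET_EXCHANGE:
                assert (a.lb, a.ub) == (b.lb, b.ub), a.id

    def test_empty_diet_infeasible_under_pinned_maintenance(self):
        model, _ = sd.toy3()
        closed = dm.apply_diet(model, dm.DietSpec("empty", {}))
        assert solver.pfba(closed).status is solver.SolverStatus.INFEASIBLE

    def test_unmatched_nutrient_is_warning_not_error(self, male_model, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="dietwbm.diet"):
            dm.apply_diet(male_model[0], dm.DietSpec("x", {"glc_D": 1.0,
                                                           "unobtainium": 2.0}))
        assert any("unobtainium" in rec.message for rec in caplog.records)

    def test_uptake_monotonicity_enlarges_feasible_set(self):
        # raising an allowed intake keeps every previously feasible state
        model, _ = sd.toy3()
        small = dm.apply_diet(model, dm.DietSpec("s", {"glc_D": 1.0}))
        large = dm.apply_diet(model, dm.DietSpec("l", {"glc_D": 5.0}))
        tiny = dm.apply_diet(model, dm.DietSpec("t", {"glc_D": 0.5}))
        assert solver.pfba(small).status is solver.SolverStatus.OPTIMAL
        assert solver.pfba(large).status is solver.SolverStatus.OPTIMAL
        assert solver.pfba(tiny).status is solver.SolverStatus.INFEASIBLE


class TestComposition:
    def test_single_class_fraction_is_one(self):
        table = dm.NutrientTable({"c": dm.NutrientInfo("carbohydrate", 1.0, 4.0)})
        out = dm.macronutrient_breakdown(dm.DietSpec("d", {"c": 100.0}), table)
        assert out == {"carbohydrate": 1.0}

    def test_atwater_arithmetic(self):
        # 50 g carb, 10 g fat, 20 g protein at 4/9/4 -> fat 90/370
        table = dm.NutrientTable({
            "c": dm.NutrientInfo("carbohydrate", 1.0, 4.0),
            "f": dm.NutrientInfo("fat", 1.0, 9.0),
            "p": dm.NutrientInfo("protein", 1.0, 4.0)})
        out = dm.macronutrient_breakdown(
            dm.DietSpec("d", {"c": 50.0, "f": 10.0, "p": 20.0}), table)
        assert out["fat"] == pytest.approx(90.0 / 370.0)
        assert out["carbohydrate"] == pytest.approx(200.0 / 370.0)

    def test_keto_fat_fraction_exceeds_053(self, toy_diets, nutrient_table):
        keto = next(d for d in toy_diets if d.name == "toy-Keto")
        out = dm.macronutrient_breakdown(keto, nutrient_table)
        assert out["fat"] > 0.53

    def test_zero_energy_diet_raises(self, nutrient_table):
        with pytest.raises(dm.UndefinedCompositionError):
            dm.macronutrient_breakdown(dm.DietSpec("d", {"fiber": 5.0}),
                                       nutrient_table)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=50.0),
                    min_size=3, max_size=3))
    def test_fractions_nonneg_and_sum_to_one(self, amounts):
        table = dm.NutrientTable({
            "c": dm.NutrientInfo("carbohydrate", 0.18, 4.0),
            "f": dm.NutrientInfo("fat", 0.25, 9.0),
            "p": dm.NutrientInfo("protein", 0.11, 4.0)})
        diet = dm.DietSpec("d", dict(zip(("c", "f", "p"), amounts)))
        out = dm.macronutrient_breakdown(diet, table)
        assert all(v >= 0 for v in out.values())
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)

    def test_negative_amount_rejected_in_spec(self):
        with pytest.raises(dm.DietError):
            dm.DietSpec("d", {"x": -1.0})


class TestNutrientMatrix:
    def test_macro_matrix_shape(self, toy_diets, nutrient_table):
        M, feats, names = dm.nutrient_matrix(toy_diets, nutrient_table, "macro")
        assert M.shape == (12, len(feats))
        assert names == [d.name for d in toy_diets]

    def test_identical_diets_identical_rows(self, nutrient_table, toy_diets):
        d = toy_diets[0]
        twin = dm.DietSpec("twin", dict(d.entries))
        M, _, _ = dm.nutrient_matrix([d, twin], nutrient_table, "macro")
        np.testing.assert_array_equal(M[0], M[1])

    def test_unhealthy_vs_balanced_fat_fraction_differs(self, toy_diets,
                                                        nutrient_table):
        M, feats, names = dm.nutrient_matrix(toy_diets, nutrient_table, "macro")
        fat = feats.index("fat")
        assert (M[names.index("toy-Unhealthy"), fat]
                > M[names.index("toy-Balanced"), fat])

    def test_micro_scope_amounts(self, toy_diets, nutrient_table):
        M, feats, _ = dm.nutrient_matrix(toy_diets, nutrient_table, "micro")
        assert set(feats) == set(sd.MICRONUTRIENTS)
        assert np.all(M >= 0)

    def test_micro_scope_without_micronutrients_errors(self, toy_diets):
        table = dm.NutrientTable({"c": dm.NutrientInfo("carbohydrate", 1.0, 4.0)})
        with pytest.raises(dm.DietError, match="micronutrient"):
            dm.nutrient_matrix(toy_diets, table, "micro")

    def test_fewer_than_two_diets_rejected(self, toy_diets, nutrient_table):
        with pytest.raises(dm.DietError):
            dm.nutrient_matrix(toy_diets[:1], nutrient_table, "macro")
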