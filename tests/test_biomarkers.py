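"""Biomarker panel resolution and flux summary statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietwbm.biomarkers as bm
from dietwbm import solver
from dietwbm import synthetic_data as sd
from dietwbm.model_core import group_exchanges_by_organ
from dietwbm.solver import FluxSolution, SolverStatus


def _sol(fluxes: dict[str, float],
         status: SolverStatus = SolverStatus.OPTIMAL) -> FluxSolution:
    return FluxSolution(fluxes=fluxes, objective=0.0, status=status,
                        max_mass_balance_residual=0.0, max_bound_violation=0.0)


class TestResolvePanel:
    def test_default_patterns_on_male_model(self, male_model, panels):
        _, manifest = male_model
        panel = panels["male"]
        facts = manifest.planted_facts["panel"]
        assert panel.tag_synthesis == facts["tag_synthesis"]
        assert sorted(panel.fao) == facts["fao"]
        assert sorted(panel.ldl_exchange) == facts["ldl_exchanges"]
        assert sorted(panel.hdl_exchange) == facts["hdl_exchanges"]
        assert len(panel.glucose_exchange) == len(manifest.organs)

    def test_female_panel_has_five_ldl_exchanges(self, panels):
        assert len(panels["female"].ldl_exchange) == 5
        assert len(panels["female"].hdl_exchange) == 3

    def test_fao_pattern_hits_muscle_and_heart_thiolase(self, panels):
        assert sorted(panels["male"].fao) == ["Heart_THIOLASE", "Muscle_THIOLASE"]

    def test_explicit_ids_with_missing_id_error(self, male_model):
        config = {"glucose": {"ids": ["Liver_EX_glc_D[bc]", "Nope_EX_glc_D[bc]"]}}
        with pytest.raises(bm.PanelResolutionError, match="Nope"):
            bm.resolve_panel(male_model[0], config)

    def test_zero_hit_pattern_errors(self, male_model):
        config = {"tag": {"pattern": {"organ": "Brain", "produces": "tag"}}}
        with pytest.raises(bm.PanelResolutionError):
            bm.resolve_panel(male_model[0], config)


class TestSummaryStats:
    def test_secretion_uptake_example(self):
        sol = _sol({"a": 2.0, "b": -1.0, "c": 0.5})
        out = bm.secretion_uptake_totals(sol, ["a", "b", "c"])
        assert out == {"total_secretion": 2.5, "total_uptake": 1.0, "net": 1.5}

    def test_all_zero_fluxes(self):
        out = bm.secretion_uptake_totals(_sol({"a": 0.0, "b": 0.0}), ["a", "b"])
        assert out == {"total_secretion": 0.0, "total_uptake": 0.0, "net": 0.0}

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=8))
    def test_totals_invariants(self, values):
        names = [f"r{i}" for i in range(len(values))]
        out = bm.secretion_uptake_totals(_sol(dict(zip(names, values))), names)
        assert out["total_secretion"] >= 0 and out["total_uptake"] >= 0
        assert out["total_secretion"] + out["total_uptake"] >= abs(out["net"]) - 1e-12

    def test_sum_flux_examples(self):
        sol = _sol({"a": 1.0, "b": 0.5, "c": 0.25})
        assert bm.sum_flux(sol, ["a", "b", "c"]) == pytest.approx(1.75)
        assert bm.sum_flux(sol, []) == 0.0

    def test_ldl_hdl_ratio_example(self):
        sol = _sol({"ldl1": 2.0, "hdl1": 4.0})
        assert bm.ldl_hdl_ratio(sol, ["ldl1"], ["hdl1"]) == pytest.approx(0.5)

    def test_ratio_guard_on_zero_hdl(self):
        sol = _sol({"ldl1": 2.0, "hdl1": 0.0})
        with pytest.raises(bm.UndefinedRatioError):
            bm.ldl_hdl_ratio(sol, ["ldl1"], ["hdl1"])

    def test_uptake_does_not_count_as_secretion_in_ratio(self):
        sol = _sol({"ldl1": 2.0, "ldl2": -5.0, "hdl1": 1.0, "hdl2": -0.5})
        assert bm.ldl_hdl_ratio(sol, ["ldl1", "ldl2"],
                                ["hdl1", "hdl2"]) == pytest.approx(2.0)


class TestOrganTable:
    def test_table_matches_individual_lookups(self):
        sols = {"d1": _sol({"A_EX_x[bc]": 1.0, "B_EX_x[bc]": -0.5, "B2": 0.25}),
                "d2": _sol({"A_EX_x[bc]": 2.0, "B_EX_x[bc]": 0.5, "B2": 0.25})}
        groups = {"A": ["A_EX_x[bc]"], "B": ["B_EX_x[bc]", "B2"]}
        tbl = bm.organ_contribution_table(sols, groups)
        assert tbl.to_frame().loc["A", "d1"] == 1.0
        assert tbl.to_frame().loc["B", "d1"] == pytest.approx(-0.25)
        assert tbl.to_frame().loc["B", "d2"] == pytest.approx(0.75)

    def test_single_diet_single_column(self):
        tbl = bm.organ_contribution_table({"only": _sol({"A_EX": 1.0})},
                                          {"A": ["A_EX"]})
        assert tbl.values.shape == (1, 1)

    def test_unsolved_diet_raises_partial_table_error(self):
        sols = {"ok": _sol({"A_EX": 1.0}),
                "bad": _sol({}, status=SolverStatus.INFEASIBLE)}
        with pytest.raises(bm.PartialTableError, match="bad"):
            bm.organ_contribution_table(sols, {"A": ["A_EX"]})

    def test_within_organ_sum_order_invariant(self):
        sols = {"d": _sol({"r1": 0.3, "r2": -0.1, "r3": 0.05})}
        a = bm.organ_contribution_table(sols, {"O": ["r1", "r2", "r3"]})
        b = bm.organ_contribution_table(sols, {"O": ["r3", "r1", "r2"]})
        np.testing.assert_allclose(a.values, b.values)

    def test_liver_row_positive_across_all_diets(self, male_model, solved_suite):
        model, manifest = male_model
        sols = {name: sol for (sex, name), sol in solved_suite.items()
                if sex == "male"}
        tbl = bm.organ_contribution_table(sols,
                                          group_exchanges_by_organ(model, "glc_D"))
        liver = tbl.to_frame().loc["Liver"]
        assert (liver > 0).all()
        assert manifest.planted_facts["sole_net_glucose_source_organ"] == "Liver"


class TestClassifyRoles:
    def test_examples(self):
        tbl = bm.OrganFluxTable(["sec", "mix", "upt", "idle"], ["d1", "d2"],
                                np.array([[1.0, 1.0], [1.0, -1.0],
                                          [-1.0, -2.0], [0.0, 0.0]]))
        roles = bm.classify_organ_roles(tbl)
        assert roles == {"sec": "secretor", "mix": "mixed",
                         "upt": "uptaker", "idle": "inactive"}

    def test_partition_and_column_order_invariance(self, male_model, solved_suite):
        model, _ = male_model
        sols = {name: sol for (sex, name), sol in solved_suite.items()
                if sex == "male"}
        groups = group_exchanges_by_organ(model, "glc_D")
        tbl = bm.organ_contribution_table(sols, groups)
        roles = bm.classify_organ_roles(tbl)
        assert set(roles) == set(model.organs)
        assert set(roles.values()) <= {"secretor", "uptaker", "mixed", "inactive"}
        shuffled = dict(reversed(list(sols.items())))
        roles2 = bm.classify_organ_roles(
            bm.organ_contribution_table(shuffled, groups))
        assert roles2 == roles

    def test_tau_threshold(self):
        tbl = bm.OrganFluxTable(["o"], ["d"], np.array([[5e-7]]))
        assert bm.classify_organ_roles(tbl, tau=1e-6) == {"o": "inactive"}
        assert bm.classify_organ_roles(tbl, tau=1e-8) == {"o": "secretor"}


class TestDirectionalRecovery:
    """The planted diet-to-biomarker mechanisms, checked against the
    exhaustive oracle on small fixtures and the pFBA suite on full models."""

    def test_tag_sum_unhealthy_exceeds_balanced(self, panels, solved_suite):
        for sex in ("male", "female"):
            p = panels[sex]
            hi = bm.sum_flux(solved_suite[(sex, "toy-Unhealthy")], p.tag_synthesis)
            lo = bm.sum_flux(solved_suite[(sex, "toy-Balanced")], p.tag_synthesis)
            assert hi > lo, sex

    def test_ldl_hdl_unhealthy_exceeds_vegan(self, panels, solved_suite):
        for sex in ("male", "female"):
            p = panels[sex]
            hi = bm.ldl_hdl_ratio(solved_suite[(sex, "toy-Unhealthy")],
                                  p.ldl_exchange, p.hdl_exchange)
            lo = bm.ldl_hdl_ratio(solved_suite[(sex, "toy-Vegan")],
                                  p.ldl_exchange, p.hdl_exchange)
            assert hi > lo, sex

    def test_fao_keto_exceeds_balanced_in_male(self, panels, solved_suite):
        p = panels["male"]
        hi = bm.sum_flux(solved_suite[("male", "toy-Keto")], p.fao)
        lo = bm.sum_flux(solved_suite[("male", "toy-Balanced")], p.fao)
        assert hi > lo

    def test_glucose_secretion_balanced_exceeds_unhealthy_uptake_side(
            self, panels, solved_suite):
        # the parsimony mechanism: energy-rich forced intake covers demand
        # directly, so the Unhealthy diet shows *lower* organ glucose
        # secretion relative to its own uptake than the Balanced diet
        p = panels["male"]
        bal = bm.secretion_uptake_totals(
            solved_suite[("male", "toy-Balanced")], p.glucose_exchange)
        unh = bm.secretion_uptake_totals(
            solved_suite[("male", "toy-Unhealthy")], p.glucose_exchange)
        assert bal["total_uptake"] == pytest.approx(unh["total_uptake"], rel=0.3)

    def test_lipid_fixture_ratio_ordering_against_oracle(self):
        ratios = {}
        for label, chol in (("unhealthy", 2.0), ("vegan", 0.0)):
            model, manifest = sd.make_lipid_toy(chol)
            p = solver.pfba(model)
            o = solver.qp_oracle(model)
            assert max(abs(p[r] - o[r]) for r in p.fluxes) < 1e-9
            ratios[label] = bm.ldl_hdl_ratio(
                o, [manifest.planted_facts["ldl_exchange"]],
                [manifest.planted_facts["hdl_exchange"]])
        assert ratios["unhealthy"] > ratios["vegan"]
        assert ratios["vegan"] == pytest.approx(1.0, abs=1e-9)

    def test_fat_fixture_fao_and_tag_rise_with_fat_load(self):
        out = {}
        for label, fat in (("keto", 4.6), ("balanced", 2.1)):
            model, manifest = sd.make_fat_toy(fat)
            o = solver.qp_oracle(model)
            p = solver.pfba(model)
            assert max(abs(p[r] - o[r]) for r in p.fluxes) < 1e-9
            out[label] = (o[manifest.planted_facts["fao_reaction"]],
                          o[manifest.planted_facts["ester_reaction"]])
        assert out["keto"][0] > out["balanced"][0]  # beta-oxidation
        assert out["keto"][1] > out["balanced"][1]  # TAG esterification
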