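"""Model data-structure, classification, I/O round-trip and SBML tests."""

from __future__ import annotations

import json
import math

import pytest

import dietwbm.model_core as mc
from dietwbm import solver
from dietwbm import synthetic_data as sd


def _write_sbml(model: mc.WholeBodyModel, path) -> None:
    """Serialize a toy model to SBML L3+fbc (test helper; brackets escaped)."""
    import libsbml

    def sid(s: str) -> str:
        return s.replace("[", "__91__").replace("]", "__93__")

    doc = libsbml.SBMLDocument(3, 1)
    doc.enablePackage(libsbml.FbcExtension.getXmlnsL3V1V2(), "fbc", True)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.getPlugin("fbc").setStrict(False)
    sm.setId("toy")
    sm.setName(f"{model.sex} toy whole-body model")
    sm.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>organs: {';'.join(model.organs)}</p>"
                f"<p>maintenance: {model.maintenance_reaction_id}</p></body>")
    def comp_id(c: str) -> str:
        return "comp_" + c.strip("[]")

    comps = {m.compartment for m in model.metabolites}
    for c in comps:
        co = sm.createCompartment()
        co.setId(comp_id(c))
        co.setConstant(True)
    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(sid(m.id))
        sp.setCompartment(comp_id(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    for i, r in enumerate(model.reactions):
        for tag, val in (("lb", r.lb), ("ub", r.ub)):
            par = sm.createParameter()
            par.setId(f"{tag}_{i}")
            par.setValue(val)
            par.setConstant(True)
        rx = sm.createReaction()
        rx.setId(sid(r.id))
        rx.setFast(False)
        rx.setReversible(r.lb < 0)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(f"lb_{i}")
        rfbc.setUpperFluxBound(f"ub_{i}")
        for met, coef in r.stoich.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(sid(met))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
    assert libsbml.writeSBMLToFile(doc, str(path))


class TestParseAndRoundTrip:
    def test_toy3_counts(self, tmp_path):
        model, _ = sd.toy3()
        path = tmp_path / "toy3.json"
        mc.write_model(model, path)
        parsed = mc.parse_model(path)
        assert len(parsed.reactions) == 5
        assert len(parsed.metabolites) == 5
        assert parsed.organs == ["Liver"]

    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_round_trip_exact(self, tmp_path, sex):
        model, _ = sd.make_toy_wbm(sex)
        path = tmp_path / "m.json"
        mc.write_model(model, path)
        back = mc.parse_model(path)
        assert back.reaction_ids == model.reaction_ids
        assert back.metabolite_ids == model.metabolite_ids
        for a, b in zip(model.reactions, back.reactions):
            assert a.lb == b.lb and a.ub == b.ub  # exact
            assert a.stoich == b.stoich
            assert a.kind == b.kind

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(mc.ModelFormatError):
            mc.parse_model(tmp_path / "nope.json")

    def test_garbage_file_is_format_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("not json {")
        with pytest.raises(mc.ModelFormatError):
            mc.parse_model(p)

    def test_duplicate_reaction_ids_rejected(self):
        met = mc.Metabolite("x[c]", "x", None, "[c]")
        rxns = [mc.Reaction("r", {"x[c]": 1.0}, 0, 1, mc.ReactionKind.MAINTENANCE),
                mc.Reaction("r", {"x[c]": -1.0}, 0, 1)]
        with pytest.raises(mc.ModelIntegrityError):
            mc.WholeBodyModel("male", [met], rxns, "r", [])

    def test_two_maintenance_reactions_rejected(self):
        met = mc.Metabolite("x[c]", "x", None, "[c]")
        rxns = [mc.Reaction("r1", {"x[c]": 1.0}, 0, 1, mc.ReactionKind.MAINTENANCE),
                mc.Reaction("r2", {"x[c]": -1.0}, 0, 1, mc.ReactionKind.MAINTENANCE)]
        with pytest.raises(mc.ModelError):
            mc.WholeBodyModel("male", [met], rxns, "r1", [])

    def test_bound_order_rejected_at_construction(self):
        with pytest.raises(mc.ModelIntegrityError):
            mc.Reaction("r", {"x[c]": 1.0}, lb=2.0, ub=1.0)

    def test_exchange_reorientation_recorded(self, tmp_path):
        model, _ = sd.toy3()
        path = tmp_path / "m.json"
        mc.write_model(model, path)
        doc = json.loads(path.read_text())
        rec = next(r for r in doc["reactions"] if r["id"] == "Liver_EX_glc_D[bc]")
        rec["stoich"] = {m: -c for m, c in rec["stoich"].items()}
        rec["lb"], rec["ub"] = -rec["ub"], -rec["lb"]
        path.write_text(json.dumps(doc))
        back = mc.parse_model(path)
        orig = model.reaction("Liver_EX_glc_D[bc]")
        flipped = back.reaction("Liver_EX_glc_D[bc]")
        assert flipped.stoich == orig.stoich
        assert (flipped.lb, flipped.ub) == (orig.lb, orig.ub)
        assert any("flipped" in note for note in back.report)


class TestTsvDialect:
    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_triplet_tsv_round_trip(self, tmp_path, sex):
        model, _ = sd.make_toy_wbm(sex)
        mc.write_model_tsv(model, tmp_path / "m")
        back = mc.parse_model(tmp_path / "m")
        assert back.reaction_ids == model.reaction_ids
        assert back.organs == model.organs
        assert back.maintenance_reaction_id == model.maintenance_reaction_id
        for a, b in zip(model.reactions, back.reactions):
            assert (a.lb, a.ub, a.kind) == (b.lb, b.ub, b.kind)
            assert a.stoich == b.stoich

    def test_non_model_directory_rejected(self, tmp_path):
        with pytest.raises(mc.ModelFormatError):
            mc.parse_model(tmp_path)


class TestClassification:
    def test_every_reaction_gets_exactly_one_kind(self, male_model):
        model, _ = male_model
        kinds = [r.kind for r in model.reactions]
        assert all(isinstance(k, mc.ReactionKind) for k in kinds)
        assert sum(k is mc.ReactionKind.MAINTENANCE for k in kinds) == 1

    def test_identifier_classification_matches_stored_kinds(self, male_model):
        model, _ = male_model
        for r in model.reactions:
            derived = mc.classify_reaction(r.id, r.stoich, model.organs,
                                           model.maintenance_reaction_id,
                                           model.convention)
            assert derived is r.kind, r.id

    def test_organ_prefix_longest_match(self):
        assert mc.organ_of_identifier("Renalblood_EX_ldl[bc]",
                                      ["Renalblood", "Kidney"]) == "Renalblood"
        assert mc.organ_of_identifier("Absorption_glc_D", ["Liver"]) is None


class TestFindOrganExchanges:
    def test_toy3_single_hit(self):
        model, _ = sd.toy3()
        assert mc.find_organ_exchanges(model, "glc_D") == ["Liver_EX_glc_D[bc]"]

    def test_default_model_one_per_organ(self, male_model):
        model, manifest = male_model
        hits = mc.find_organ_exchanges(model, "glc_D")
        assert len(hits) == manifest.planted_facts["glucose_exchange_count"]
        organs = {model.reaction(r).organ for r in hits}
        assert organs == set(model.organs)

    def test_unknown_base_id_empty(self, male_model):
        assert mc.find_organ_exchanges(male_model[0], "nonexistent") == []

    def test_empty_base_id_raises(self, male_model):
        with pytest.raises(ValueError):
            mc.find_organ_exchanges(male_model[0], "")

    def test_results_are_blood_exchanges_with_one_blood_metabolite(self, female_model):
        model, _ = female_model
        for base in ("glc_D", "ldl", "hdl"):
            for rid in mc.find_organ_exchanges(model, base):
                r = model.reaction(rid)
                assert r.kind is mc.ReactionKind.ORGAN_BLOOD_EXCHANGE
                blood = [m for m in r.stoich if m.endswith("[bc]")]
                assert len(blood) == 1


class TestValidate:
    def test_clean_models_pass(self, male_model, female_model):
        assert mc.validate_model(male_model[0]) == []
        assert mc.validate_model(female_model[0]) == []

    def test_no_diet_exchange_reported(self):
        model, _ = sd.toy3()
        model.reactions = [r for r in model.reactions
                           if r.kind is not mc.ReactionKind.DIET_EXCHANGE]
        codes = [e.code for e in mc.validate_model(model)]
        assert codes == ["NO_DIET_EXCHANGE"]

    def test_bound_order_reported(self):
        model, _ = sd.toy3()
        model.reaction("Absorption_glc_D").lb = 5.0
        model.reaction("Absorption_glc_D").ub = 1.0
        codes = [e.code for e in mc.validate_model(model)]
        assert codes == ["BOUND_ORDER"]

    def test_nan_bound_reported(self):
        model, _ = sd.toy3()
        model.reaction("Absorption_glc_D").ub = math.nan
        codes = [e.code for e in mc.validate_model(model)]
        assert "NAN_BOUND" in codes


class TestSBML:
    def test_sbml_read_matches_json_dialect(self, tmp_path):
        model, _ = sd.toy3()
        path = tmp_path / "toy3.xml"
        _write_sbml(model, path)
        parsed = mc.parse_model(path)
        assert sorted(parsed.reaction_ids) == sorted(model.reaction_ids)
        for r in model.reactions:
            p = parsed.reaction(r.id)
            assert p.stoich == r.stoich
            assert p.lb == pytest.approx(r.lb) and p.ub == pytest.approx(r.ub)
            assert p.kind is r.kind

    def test_cobra_agrees_on_fba_optimum(self, tmp_path):
        """Independent LP cross-check: cobrapy on the same SBML file."""
        import cobra

        model, _ = sd.toy3()
        model.reaction("WholeBody_maintenance").ub = 10.0
        path = tmp_path / "toy3.xml"
        _write_sbml(model, path)
        ours = solver.fba(model, "WholeBody_maintenance", "max")
        cb = cobra.io.read_sbml_model(str(path))
        cb.objective = cb.reactions.get_by_id("WholeBody_maintenance")
        assert ours.objective == pytest.approx(1.0, abs=1e-8)
        assert cb.slim_optimize() == pytest.approx(ours.objective, abs=1e-6)
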