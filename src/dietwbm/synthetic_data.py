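"""Generators for toy whole-body models, diets and nutrient tables.

The toy models reproduce the *structure* of organ-resolved whole-body
models — organ-prefixed namespaces, a shared blood compartment, diet
exchange reactions on a gastrointestinal lumen, organ-blood exchanges for
glucose and lipoproteins, adipocyte TAG esterification, thiolase-step
butyryl-CoA breakdown in muscle and heart, and a single whole-body
maintenance reaction — at a deliberately lumped scale (one reaction per
pathway stage, tens of reactions rather than tens of thousands).

Planted mechanisms, recorded in each model's manifest so tests can recover
them:

* dietary glucose enters through the liver (portal circulation), so the
  liver is the sole net glucose secretor while every other organ takes
  glucose up for its maintenance ATP share;
* forced fat intake must be disposed of either by muscle/heart
  beta-oxidation (through the thiolase step) or by adipocyte TAG
  esterification, so fat-heavy diets raise both readouts;
* excess carbohydrate is routed to adipocyte lipogenesis and thence TAG;
* dietary cholesterol loads the liver, which exports it as LDL to
  peripheral storage or to bile, against a diet-independent HDL delivery
  baseline — so cholesterol-rich diets raise the LDL/HDL secretion ratio.

Generation is a pure function of its arguments; identical inputs produce
byte-identical serialized models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .diet import DietSpec, NutrientInfo, NutrientTable, write_diet
from .model_core import (
    INF_BOUND,
    Metabolite,
    NamingConvention,
    Reaction,
    ReactionKind,
    WholeBodyModel,
    write_model,
)
from .solver import SolverSettings

MAINTENANCE_ID = "WholeBody_maintenance"

DEFAULT_ORGANS = ["Liver", "Adipocyte", "Muscle", "Heart",
                  "Lung", "Kidney", "Pancreas", "Brain"]
FEMALE_EXTRA_ORGANS = ["Breast", "Uterus", "Renalblood"]

# stoichiometric yields of the lumped pathway stages
GLYCOLYSIS_ATP_PER_GLC = 2.0
GNG_GLC_PER_AA = 0.8
GNG_GLC_PER_FAT = 0.5
CHOL_PER_GLC = 0.2
FAT_PER_GLC_LIPOGENESIS = 0.5
MAINT_CHOL_DEMAND = 0.3  # membrane upkeep, muscle and adipocyte each

MALE_PHYSIOLOGY = {"body_weight_kg": 70.0, "height_cm": 170.0,
                   "heart_rate_bpm": 67.0, "stroke_volume_ml": 80.0,
                   "cardiac_output": 5360.0, "hematocrit": 0.400}
FEMALE_PHYSIOLOGY = {**MALE_PHYSIOLOGY, "body_weight_kg": 58.0, "height_cm": 160.0}


@dataclass
class ToyModelManifest:
    model_id: str
    seed: int
    organs: list[str]
    planted_facts: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"model_id": self.model_id, "seed": self.seed,
             "organs": self.organs, "planted_facts": self.planted_facts},
            indent=1) + "\n")


class ToyConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# nutrient table
# ---------------------------------------------------------------------------

#: base_id -> (class, g/mmol, kcal/g).  Molar masses are realistic
#: (glucose 180 g/mol, palmitate-like 256, oleate-like 282, ...); energy
#: uses Atwater factors 4/9/4 kcal/g.
_TOY_NUTRIENTS = {
    "glc_D":     ("carbohydrate", 0.180, 4.0),
    "fru":       ("carbohydrate", 0.180, 4.0),
    "fat_sat":   ("fat", 0.256, 9.0),
    "fat_unsat": ("fat", 0.282, 9.0),
    "fat_ess":   ("fat", 0.280, 9.0),
    "aa":        ("protein", 0.110, 4.0),
    "fiber":     ("fiber", 0.162, 0.0),
    "chol":      ("other", 0.387, 0.0),
    "vit_a":     ("micronutrient", 0.286, 0.0),
    "vit_b1":    ("micronutrient", 0.300, 0.0),
    "vit_c":     ("micronutrient", 0.176, 0.0),
    "vit_d":     ("micronutrient", 0.385, 0.0),
    "fe2":       ("micronutrient", 0.056, 0.0),
}

MICRONUTRIENTS = [n for n, (c, _, _) in _TOY_NUTRIENTS.items() if c == "micronutrient"]
FAT_NUTRIENTS = ["fat_sat", "fat_unsat", "fat_ess"]


def nutrient_table_fixture() -> NutrientTable:
    """Nutrient classification covering every nutrient the toy diets use."""
    return NutrientTable({n: NutrientInfo(cls, g, kcal)
                          for n, (cls, g, kcal) in _TOY_NUTRIENTS.items()})


# ---------------------------------------------------------------------------
# toy diets
# ---------------------------------------------------------------------------

#: name -> (kcal, frac_carb, frac_fat, frac_protein, fructose share of carb
#: energy, (sat, unsat, ess) shares of fat energy, fiber mmol, chol mmol,
#: micronutrient richness multiplier).  Energy fractions are the stated
#: macronutrient targets (toy-Keto fat fraction 0.65 > 0.53; toy-Unhealthy
#: energy = 1.5x toy-Balanced).
_DIET_DESIGNS: dict[str, tuple] = {
    "toy-Balanced":        (20.0, 0.50, 0.30, 0.20, 0.15, (0.35, 0.55, 0.10), 3.0, 0.20, 1.00),
    "toy-Unhealthy":       (30.0, 0.45, 0.40, 0.15, 0.45, (0.70, 0.22, 0.08), 0.4, 2.00, 0.30),
    "toy-Keto":            (20.0, 0.08, 0.65, 0.27, 0.05, (0.50, 0.40, 0.10), 1.0, 1.00, 0.45),
    "toy-Vegan":           (20.0, 0.55, 0.25, 0.20, 0.20, (0.15, 0.70, 0.15), 4.0, 0.00, 0.90),
    "toy-Vegetarian":      (20.0, 0.52, 0.28, 0.20, 0.20, (0.25, 0.62, 0.13), 3.2, 0.10, 0.90),
    "toy-Mediterranean":   (20.0, 0.46, 0.35, 0.19, 0.18, (0.20, 0.68, 0.12), 3.5, 0.15, 1.20),
    "toy-HighProtein":     (20.0, 0.33, 0.27, 0.40, 0.12, (0.45, 0.45, 0.10), 1.8, 0.80, 0.80),
    "toy-HighFiber":       (20.0, 0.50, 0.28, 0.22, 0.15, (0.30, 0.58, 0.12), 6.0, 0.30, 0.95),
    "toy-GlutenFree":      (22.0, 0.46, 0.36, 0.18, 0.30, (0.50, 0.40, 0.10), 1.2, 0.60, 0.60),
    "toy-AverageAmerican": (26.0, 0.48, 0.37, 0.15, 0.40, (0.60, 0.32, 0.08), 1.0, 1.20, 0.50),
    "toy-AverageEuropean": (22.0, 0.44, 0.38, 0.18, 0.25, (0.50, 0.40, 0.10), 1.4, 0.90, 0.70),
    "toy-DACH":            (20.0, 0.50, 0.30, 0.20, 0.15, (0.33, 0.55, 0.12), 3.0, 0.30, 1.05),
}

#: baseline micronutrient amounts (mmol/day) at richness 1.0
_MICRO_BASE = {"vit_a": 0.05, "vit_b1": 0.04, "vit_c": 0.50, "vit_d": 0.01, "fe2": 0.30}
#: diet-specific multiplicative accents so micronutrient profiles differ in
#: shape, not just scale
_MICRO_ACCENTS = {
    "toy-Mediterranean": {"vit_c": 2.0, "vit_d": 1.5},
    "toy-Vegan": {"vit_d": 0.3, "fe2": 0.7, "vit_c": 1.6},
    "toy-Vegetarian": {"vit_d": 0.6, "vit_c": 1.4},
    "toy-Balanced": {"vit_b1": 1.5, "vit_d": 1.4},
    "toy-Unhealthy": {"vit_c": 0.5},
    "toy-Keto": {"vit_c": 0.4, "vit_d": 1.6},
    "toy-HighFiber": {"fe2": 1.4},
    "toy-HighProtein": {"fe2": 1.6, "vit_b1": 1.3},
}


def _kcal_per_mmol(nut: str) -> float:
    _cls, g, kcal = _TOY_NUTRIENTS[nut]
    return g * kcal


def make_toy_diets() -> list[DietSpec]:
    """The 12 named toy diets over the toy nutrient namespace."""
    diets = []
    for name, (kcal, f_carb, f_fat, f_prot, fru_share,
               fat_split, fiber, chol, micro) in _DIET_DESIGNS.items():
        entries: dict[str, float] = {}
        carb_kcal = kcal * f_carb
        entries["fru"] = carb_kcal * fru_share / _kcal_per_mmol("fru")
        entries["glc_D"] = carb_kcal * (1 - fru_share) / _kcal_per_mmol("glc_D")
        fat_kcal = kcal * f_fat
        for nut, share in zip(FAT_NUTRIENTS, fat_split):
            entries[nut] = fat_kcal * share / _kcal_per_mmol(nut)
        entries["aa"] = kcal * f_prot / _kcal_per_mmol("aa")
        entries["fiber"] = fiber
        if chol > 0:
            entries["chol"] = chol
        accents = _MICRO_ACCENTS.get(name, {})
        for nut, base in _MICRO_BASE.items():
            entries[nut] = base * micro * accents.get(nut, 1.0)
        diets.append(DietSpec(name=name, entries=entries))
    return diets


def diet_design_targets() -> dict[str, dict[str, float]]:
    """Stated macronutrient energy targets per toy diet (the build manifest)."""
    return {name: {"kcal": d[0], "carbohydrate": d[1], "fat": d[2], "protein": d[3]}
            for name, d in _DIET_DESIGNS.items()}


# ---------------------------------------------------------------------------
# model assembly helpers
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, sex: str, organs: list[str]):
        self.sex = sex
        self.organs = organs
        self.mets: dict[str, Metabolite] = {}
        self.rxns: list[Reaction] = []
        self.conv = NamingConvention()

    def met(self, met_id: str, base_id: str, organ: str | None, comp: str) -> str:
        if met_id not in self.mets:
            self.mets[met_id] = Metabolite(met_id, base_id, organ, comp)
        return met_id

    def lumen(self, base: str) -> str:
        return self.met(f"{base}[d]", base, None, "[d]")

    def blood(self, base: str) -> str:
        return self.met(f"{base}[bc]", base, None, "[bc]")

    def organ_met(self, organ: str, base: str) -> str:
        return self.met(f"{organ}_{base}[c]", base, organ, "[c]")

    def rxn(self, rxn_id: str, stoich: dict[str, float], lb: float, ub: float,
            kind: ReactionKind, organ: str | None = None) -> None:
        self.rxns.append(Reaction(id=rxn_id, stoich=stoich, lb=lb, ub=ub,
                                  kind=kind, organ=organ))

    def diet_exchange(self, base: str) -> None:
        self.rxn(f"Diet_EX_{base}[d]", {self.lumen(base): -1.0},
                 -INF_BOUND, 0.0, ReactionKind.DIET_EXCHANGE)

    def organ_blood_exchange(self, organ: str, base: str,
                             lb: float = -INF_BOUND, ub: float = INF_BOUND) -> None:
        # positive flux = secretion into blood
        self.rxn(f"{organ}_EX_{base}[bc]",
                 {self.organ_met(organ, base): -1.0, self.blood(base): 1.0},
                 lb, ub, ReactionKind.ORGAN_BLOOD_EXCHANGE, organ)

    def build(self, physiology: dict[str, float],
              report: list[str] | None = None) -> WholeBodyModel:
        return WholeBodyModel(
            sex=self.sex, metabolites=list(self.mets.values()),
            reactions=self.rxns, maintenance_reaction_id=MAINTENANCE_ID,
            organs=self.organs, physiology=physiology, convention=self.conv,
        )


# ---------------------------------------------------------------------------
# toy whole-body model
# ---------------------------------------------------------------------------

def make_toy_wbm(sex: str = "male", organs: list[str] | None = None,
                 seed: int = 0, options: dict | None = None
                 ) -> tuple[WholeBodyModel, ToyModelManifest]:
    """Build a toy whole-body model and its manifest of planted facts.

    ``options`` keys:

    * ``topology``: ``"full"`` (default), or the single-organ solver
      fixtures ``"chain"`` (5-reaction forced chain), ``"parallel"``
      (two identical glycolysis paths, L2 splits 0.5/0.5) and ``"asym"``
      (1-step vs 2-step path, L2 splits 2/3 vs 1/3);
    * ``infeasible``: close every diet exchange so maintenance cannot be
      met (the planted deficit is recorded in the manifest);
    * ``organ_weights``: per-organ ATP coefficients of the maintenance
      reaction (default: equal shares of 1.0 for the metabolic organs,
      0.0 for the female secretory conduits Breast/Uterus/Renalblood).
    """
    options = dict(options or {})
    topology = options.pop("topology", "full")
    infeasible = bool(options.pop("infeasible", False))
    weights_override = options.pop("organ_weights", None)
    if options:
        raise ToyConfigurationError(f"unknown options: {sorted(options)}")
    if sex not in ("male", "female"):
        raise ToyConfigurationError(f"sex must be 'male' or 'female', got {sex!r}")

    if topology in ("chain", "parallel", "asym"):
        if infeasible:
            raise ToyConfigurationError(
                "solver fixtures do not support the infeasible option")
        return _make_solver_fixture(topology, organs or ["Liver"], seed)
    if topology != "full":
        raise ToyConfigurationError(f"unknown topology {topology!r}")

    if organs is None:
        organs = list(DEFAULT_ORGANS)
        if sex == "female":
            organs += FEMALE_EXTRA_ORGANS
    if not organs:
        raise ToyConfigurationError("at least one organ required")
    if "Liver" not in organs:
        raise ToyConfigurationError("the full topology requires a Liver")

    weights = {o: 0.0 if o in FEMALE_EXTRA_ORGANS else 1.0 for o in organs}
    if weights_override:
        weights.update(weights_override)

    b = _Builder(sex, organs)

    # diet boundary + handling of every toy nutrient
    for nut in _TOY_NUTRIENTS:
        b.diet_exchange(nut)
    # portal absorption: sugars, amino acids and cholesterol pass through
    # the liver; fats enter systemic blood (chylomicron route)
    b.rxn("Absorption_glc_D", {b.lumen("glc_D"): -1, b.organ_met("Liver", "glc_D"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL)
    b.rxn("Absorption_fru", {b.lumen("fru"): -1, b.organ_met("Liver", "glc_D"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL)
    b.rxn("Absorption_aa", {b.lumen("aa"): -1, b.organ_met("Liver", "aa"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL)
    b.rxn("Absorption_chol", {b.lumen("chol"): -1, b.organ_met("Liver", "chol"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL)
    for nut in FAT_NUTRIENTS:
        b.rxn(f"Absorption_{nut}", {b.lumen(nut): -1, b.blood(nut): 1},
              0, INF_BOUND, ReactionKind.INTERNAL)
    for nut in MICRONUTRIENTS:
        b.rxn(f"Absorption_{nut}", {b.lumen(nut): -1, b.blood(nut): 1},
              0, INF_BOUND, ReactionKind.INTERNAL)
        b.rxn(f"Excretion_{nut}", {b.blood(nut): -1},
              0, INF_BOUND, ReactionKind.SINK_DEMAND)
    b.rxn("Excretion_fiber", {b.lumen("fiber"): -1},
          0, INF_BOUND, ReactionKind.SINK_DEMAND)

    # every organ exchanges glucose with blood and burns it for its
    # maintenance ATP share (secretory conduits carry weight 0 and no
    # glycolysis of their own)
    for organ in organs:
        b.organ_blood_exchange(organ, "glc_D")
        if weights[organ] > 0:
            b.rxn(f"{organ}_GLYCOLYSIS",
                  {b.organ_met(organ, "glc_D"): -1,
                   b.organ_met(organ, "adp"): -GLYCOLYSIS_ATP_PER_GLC,
                   b.organ_met(organ, "atp"): GLYCOLYSIS_ATP_PER_GLC},
                  0, INF_BOUND, ReactionKind.INTERNAL, organ)

    # liver: gluconeogenesis, amino-acid distribution, cholesterol hub
    b.rxn("Liver_GNG_AA", {b.organ_met("Liver", "aa"): -1,
                           b.organ_met("Liver", "glc_D"): GNG_GLC_PER_AA},
          0, INF_BOUND, ReactionKind.INTERNAL, "Liver")
    b.rxn("Liver_GNG_FAT", {b.organ_met("Liver", "fat_sat"): -1,
                            b.organ_met("Liver", "glc_D"): GNG_GLC_PER_FAT},
          0, INF_BOUND, ReactionKind.INTERNAL, "Liver")
    b.organ_blood_exchange("Liver", "aa")
    b.organ_blood_exchange("Liver", "fat_sat")
    b.rxn("Liver_CHOL_SYNTHESIS", {b.organ_met("Liver", "glc_D"): -1,
                                   b.organ_met("Liver", "chol"): CHOL_PER_GLC},
          0, INF_BOUND, ReactionKind.INTERNAL, "Liver")
    b.rxn("Liver_BILE_chol", {b.organ_met("Liver", "chol"): -1},
          0, INF_BOUND, ReactionKind.SINK_DEMAND, "Liver")
    b.rxn("Liver_LDL_ASSEMBLY", {b.organ_met("Liver", "chol"): -1,
                                 b.organ_met("Liver", "ldl"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL, "Liver")
    b.rxn("Liver_HDL_ASSEMBLY", {b.organ_met("Liver", "chol"): -1,
                                 b.organ_met("Liver", "hdl"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL, "Liver")
    b.organ_blood_exchange("Liver", "ldl")
    b.organ_blood_exchange("Liver", "hdl")

    # muscle and heart: thiolase-terminated fatty-acid beta-oxidation
    for organ in ("Muscle", "Heart"):
        if organ not in organs:
            continue
        for nut in ("fat_sat", "fat_unsat"):
            b.organ_blood_exchange(organ, nut)
            b.rxn(f"{organ}_FACOA_{nut.removeprefix('fat_')}",
                  {b.organ_met(organ, nut): -1, b.organ_met(organ, "btcoa"): 1},
                  0, INF_BOUND, ReactionKind.INTERNAL, organ)
        b.rxn(f"{organ}_THIOLASE",
              {b.organ_met(organ, "btcoa"): -1, b.organ_met(organ, "accoa"): 1},
              0, INF_BOUND, ReactionKind.INTERNAL, organ)
        b.rxn(f"{organ}_OXIDATION_accoa", {b.organ_met(organ, "accoa"): -1},
              0, INF_BOUND, ReactionKind.SINK_DEMAND, organ)

    # muscle: protein turnover sink and HDL-mediated cholesterol delivery
    if "Muscle" in organs:
        b.organ_blood_exchange("Muscle", "aa")
        b.rxn("Muscle_PROTEIN_sink", {b.organ_met("Muscle", "aa"): -1},
              0, INF_BOUND, ReactionKind.SINK_DEMAND, "Muscle")
        b.organ_blood_exchange("Muscle", "hdl")
        b.rxn("Muscle_HDL_RECEPTOR", {b.organ_met("Muscle", "hdl"): -1,
                                      b.organ_met("Muscle", "chol"): 1},
              0, INF_BOUND, ReactionKind.INTERNAL, "Muscle")
        b.organ_blood_exchange("Muscle", "ldl")  # present; carries no flux

    # adipocytes: the three TAG esterification reactions (one per fatty-acid
    # type), de novo lipogenesis from excess glucose, LDL-mediated
    # cholesterol storage
    if "Adipocyte" in organs:
        for nut in FAT_NUTRIENTS:
            b.organ_blood_exchange("Adipocyte", nut)
            b.rxn(f"Adipocyte_ESTER_{nut.removeprefix('fat_')}",
                  {b.organ_met("Adipocyte", nut): -1,
                   b.organ_met("Adipocyte", "tag"): 1},
                  0, INF_BOUND, ReactionKind.INTERNAL, "Adipocyte")
        b.rxn("Adipocyte_TAG_storage", {b.organ_met("Adipocyte", "tag"): -1},
              0, INF_BOUND, ReactionKind.SINK_DEMAND, "Adipocyte")
        b.rxn("Adipocyte_LIPOGENESIS",
              {b.organ_met("Adipocyte", "glc_D"): -1,
               b.organ_met("Adipocyte", "fat_sat"): FAT_PER_GLC_LIPOGENESIS},
              0, INF_BOUND, ReactionKind.INTERNAL, "Adipocyte")
        b.organ_blood_exchange("Adipocyte", "ldl")
        b.rxn("Adipocyte_LDL_RECEPTOR", {b.organ_met("Adipocyte", "ldl"): -1,
                                         b.organ_met("Adipocyte", "chol"): 1},
              0, INF_BOUND, ReactionKind.INTERNAL, "Adipocyte")
        b.rxn("Adipocyte_CHOL_storage", {b.organ_met("Adipocyte", "chol"): -1},
              0, INF_BOUND, ReactionKind.SINK_DEMAND, "Adipocyte")
        b.organ_blood_exchange("Adipocyte", "hdl")  # present; carries no flux

    # female secretory conduits: gluconeogenic glucose secretors and, for
    # kidney/renal blood, the two extra LDL delivery targets
    for organ in ("Breast", "Uterus", "Renalblood"):
        if organ not in organs:
            continue
        b.organ_blood_exchange(organ, "aa")
        b.rxn(f"{organ}_GNG_AA", {b.organ_met(organ, "aa"): -1,
                                  b.organ_met(organ, "glc_D"): GNG_GLC_PER_AA},
              0, INF_BOUND, ReactionKind.INTERNAL, organ)
    for organ in ("Kidney", "Renalblood"):
        if organ not in organs or sex != "female":
            continue
        b.organ_blood_exchange(organ, "ldl")
        b.rxn(f"{organ}_LDL_RECEPTOR", {b.organ_met(organ, "ldl"): -1,
                                        b.organ_met(organ, "chol"): 1},
              0, INF_BOUND, ReactionKind.INTERNAL, organ)
        b.rxn(f"{organ}_CHOL_storage", {b.organ_met(organ, "chol"): -1},
              0, INF_BOUND, ReactionKind.SINK_DEMAND, organ)

    # whole-body maintenance: per-organ ATP shares plus small membrane
    # cholesterol demands in muscle and adipocytes
    maint: dict[str, float] = {}
    for organ in organs:
        if weights[organ] > 0:
            maint[b.organ_met(organ, "atp")] = -weights[organ]
            maint[b.organ_met(organ, "adp")] = weights[organ]
    if "Muscle" in organs:
        maint[b.organ_met("Muscle", "chol")] = -MAINT_CHOL_DEMAND
    if "Adipocyte" in organs:
        maint[b.organ_met("Adipocyte", "chol")] = -MAINT_CHOL_DEMAND
    b.rxn(MAINTENANCE_ID, maint, 0, INF_BOUND, ReactionKind.MAINTENANCE)

    model = b.build(MALE_PHYSIOLOGY if sex == "male" else FEMALE_PHYSIOLOGY)

    glc_demand = sum(weights[o] for o in organs) / GLYCOLYSIS_ATP_PER_GLC
    chol_demand = MAINT_CHOL_DEMAND * (("Muscle" in organs) + ("Adipocyte" in organs))
    facts: dict[str, Any] = {
        "maintenance_value": 1.0,
        "glucose_atp_demand_mmol": glc_demand,
        "maintenance_chol_demand_mmol": chol_demand,
        "sole_net_glucose_source_organ": "Liver" if sex == "male" else None,
        "glucose_secretor_organs": (["Liver"] if sex == "male" else
                                    ["Breast", "Liver", "Renalblood", "Uterus"]),
        "glucose_exchange_count": len(organs),
        "panel": {
            "tag_synthesis": sorted(f"Adipocyte_ESTER_{t}"
                                    for t in ("sat", "unsat", "ess")),
            "fao": [f"{o}_THIOLASE" for o in ("Heart", "Muscle") if o in organs],
            "ldl_exchanges": sorted(r.id for r in model.reactions
                                    if r.kind is ReactionKind.ORGAN_BLOOD_EXCHANGE
                                    and "_EX_ldl" in r.id),
            "hdl_exchanges": sorted(r.id for r in model.reactions
                                    if r.kind is ReactionKind.ORGAN_BLOOD_EXCHANGE
                                    and "_EX_hdl" in r.id),
        },
        "biomarker_orderings": {
            "tag_sum": ["toy-Unhealthy", ">", "toy-Balanced"],
            "ldl_hdl_ratio": ["toy-Unhealthy", ">", "toy-Vegan"],
            "fao_sum": ["toy-Keto", ">", "toy-Balanced"],
        },
    }

    if infeasible:
        for r in model.reactions:
            if r.kind is ReactionKind.DIET_EXCHANGE:
                r.lb = r.ub = 0.0
        facts["infeasible_min_slack"] = {
            "Diet_EX_glc_D[d]": glc_demand,
            "Diet_EX_chol[d]": chol_demand,
        }

    manifest = ToyModelManifest(model_id=f"toy-wbm-{sex}"
                                + ("-infeasible" if infeasible else ""),
                                seed=seed, organs=organs, planted_facts=facts)
    return model, manifest


# ---------------------------------------------------------------------------
# single-organ solver fixtures
# ---------------------------------------------------------------------------

def _make_solver_fixture(topology: str, organs: list[str], seed: int
                         ) -> tuple[WholeBodyModel, ToyModelManifest]:
    organ = organs[0]
    b = _Builder("male", [organ])
    b.rxn("Diet_EX_glc_D[d]", {b.lumen("glc_D"): -1.0}, -1.0, 0.0,
          ReactionKind.DIET_EXCHANGE)
    b.rxn("Absorption_glc_D", {b.lumen("glc_D"): -1, b.blood("glc_D"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL)
    b.organ_blood_exchange(organ, "glc_D")
    glc, atp, adp = (b.organ_met(organ, m) for m in ("glc_D", "atp", "adp"))
    facts: dict[str, Any]
    if topology == "chain":
        b.rxn(f"{organ}_GLYCOLYSIS", {glc: -1, adp: -1, atp: 1},
              0, INF_BOUND, ReactionKind.INTERNAL, organ)
        b.rxn(MAINTENANCE_ID, {atp: -1, adp: 1}, 0, INF_BOUND,
              ReactionKind.MAINTENANCE)
        facts = {"chain_fluxes": {
            "Diet_EX_glc_D[d]": -1.0, "Absorption_glc_D": 1.0,
            f"{organ}_EX_glc_D[bc]": -1.0, f"{organ}_GLYCOLYSIS": 1.0,
            MAINTENANCE_ID: 1.0},
            "empty_diet_min_slack": {"Diet_EX_glc_D[d]": 1.0}}
    elif topology == "parallel":
        for tag in ("A", "B"):
            b.rxn(f"{organ}_GLYCOLYSIS_{tag}", {glc: -1, adp: -1, atp: 1},
                  0, INF_BOUND, ReactionKind.INTERNAL, organ)
        b.rxn(MAINTENANCE_ID, {atp: -1, adp: 1}, 0, INF_BOUND,
              ReactionKind.MAINTENANCE)
        facts = {"symmetric_split": {f"{organ}_GLYCOLYSIS_A": 0.5,
                                     f"{organ}_GLYCOLYSIS_B": 0.5}}
    else:  # asym: 1-step path A vs 2-step path B; min a^2 + 2 b^2, a + b = 1
        g6p = b.organ_met(organ, "g6p")
        b.rxn(f"{organ}_PATH_A", {glc: -1, adp: -1, atp: 1},
              0, INF_BOUND, ReactionKind.INTERNAL, organ)
        b.rxn(f"{organ}_PATH_B1", {glc: -1, g6p: 1},
              0, INF_BOUND, ReactionKind.INTERNAL, organ)
        b.rxn(f"{organ}_PATH_B2", {g6p: -1, adp: -1, atp: 1},
              0, INF_BOUND, ReactionKind.INTERNAL, organ)
        b.rxn(MAINTENANCE_ID, {atp: -1, adp: 1}, 0, INF_BOUND,
              ReactionKind.MAINTENANCE)
        facts = {"asym_split": {f"{organ}_PATH_A": 2.0 / 3.0,
                                f"{organ}_PATH_B1": 1.0 / 3.0,
                                f"{organ}_PATH_B2": 1.0 / 3.0}}
    model = b.build({})
    manifest = ToyModelManifest(model_id=f"toy-{topology}", seed=seed,
                                organs=[organ], planted_facts=facts)
    return model, manifest


def toy3() -> tuple[WholeBodyModel, ToyModelManifest]:
    """The 5-reaction, 5-metabolite forced-chain fixture."""
    return make_toy_wbm(organs=["Liver"], options={"topology": "chain"})


def toy_parallel() -> tuple[WholeBodyModel, ToyModelManifest]:
    return make_toy_wbm(organs=["Liver"], options={"topology": "parallel"})


def toy_asym() -> tuple[WholeBodyModel, ToyModelManifest]:
    return make_toy_wbm(organs=["Liver"], options={"topology": "asym"})


# ---------------------------------------------------------------------------
# oracle-sized mechanism fixtures
# ---------------------------------------------------------------------------

def make_lipid_toy(chol_intake: float
                   ) -> tuple[WholeBodyModel, ToyModelManifest]:
    """12-reaction cholesterol-routing fixture for oracle cross-checks.

    Dietary cholesterol loads the liver; disposal routes are bile or LDL
    export to adipocyte storage, against a fixed HDL delivery to muscle —
    the mechanism that makes the LDL/HDL secretion ratio rise with
    cholesterol-rich diets.
    """
    b = _Builder("male", ["Liver", "Muscle", "Adipocyte"])
    b.rxn("Diet_EX_chol[d]", {b.lumen("chol"): -1.0},
          -chol_intake, -0.8 * chol_intake if chol_intake else 0.0,
          ReactionKind.DIET_EXCHANGE)
    b.rxn("Absorption_chol", {b.lumen("chol"): -1, b.organ_met("Liver", "chol"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL)
    b.rxn("Liver_CHOL_SYNTHESIS", {b.organ_met("Liver", "chol"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL, "Liver")
    b.rxn("Liver_BILE_chol", {b.organ_met("Liver", "chol"): -1},
          0, INF_BOUND, ReactionKind.SINK_DEMAND, "Liver")
    b.rxn("Liver_LDL_ASSEMBLY", {b.organ_met("Liver", "chol"): -1,
                                 b.organ_met("Liver", "ldl"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL, "Liver")
    b.rxn("Liver_HDL_ASSEMBLY", {b.organ_met("Liver", "chol"): -1,
                                 b.organ_met("Liver", "hdl"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL, "Liver")
    b.organ_blood_exchange("Liver", "ldl")
    b.organ_blood_exchange("Liver", "hdl")
    b.organ_blood_exchange("Adipocyte", "ldl")
    b.rxn("Adipocyte_CHOL_storage", {b.organ_met("Adipocyte", "ldl"): -1},
          0, INF_BOUND, ReactionKind.SINK_DEMAND, "Adipocyte")
    b.organ_blood_exchange("Muscle", "hdl")
    b.rxn(MAINTENANCE_ID, {b.organ_met("Muscle", "hdl"): -MAINT_CHOL_DEMAND,
                           b.organ_met("Adipocyte", "ldl"): -MAINT_CHOL_DEMAND},
          0, INF_BOUND, ReactionKind.MAINTENANCE)
    model = b.build({})
    manifest = ToyModelManifest(
        model_id="toy-lipid", seed=0, organs=model.organs,
        planted_facts={"hdl_secretion": MAINT_CHOL_DEMAND,
                       "ldl_exchange": "Liver_EX_ldl[bc]",
                       "hdl_exchange": "Liver_EX_hdl[bc]"})
    return model, manifest


def make_fat_toy(fat_intake: float) -> tuple[WholeBodyModel, ToyModelManifest]:
    """11-reaction fat-disposal fixture: beta-oxidation vs TAG storage.

    Forced fat intake splits between the muscle oxidation route and the
    adipocyte esterification route; both rise with the fat load.
    """
    b = _Builder("male", ["Muscle", "Adipocyte"])
    b.rxn("Diet_EX_fat_sat[d]", {b.lumen("fat_sat"): -1.0},
          -fat_intake, -0.8 * fat_intake, ReactionKind.DIET_EXCHANGE)
    b.rxn("Absorption_fat_sat", {b.lumen("fat_sat"): -1, b.blood("fat_sat"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL)
    b.organ_blood_exchange("Muscle", "fat_sat")
    b.rxn("Muscle_FAO", {b.organ_met("Muscle", "fat_sat"): -1},
          0, INF_BOUND, ReactionKind.INTERNAL, "Muscle")
    b.organ_blood_exchange("Adipocyte", "fat_sat")
    b.rxn("Adipocyte_ESTER_sat", {b.organ_met("Adipocyte", "fat_sat"): -1},
          0, INF_BOUND, ReactionKind.INTERNAL, "Adipocyte")
    b.rxn("Diet_EX_glc_D[d]", {b.lumen("glc_D"): -1.0}, -2.0, 0.0,
          ReactionKind.DIET_EXCHANGE)
    b.rxn("Absorption_glc_D", {b.lumen("glc_D"): -1, b.blood("glc_D"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL)
    b.organ_blood_exchange("Muscle", "glc_D")
    b.rxn("Muscle_GLYCOLYSIS", {b.organ_met("Muscle", "glc_D"): -1,
                                b.organ_met("Muscle", "atp"): 1},
          0, INF_BOUND, ReactionKind.INTERNAL, "Muscle")
    b.rxn(MAINTENANCE_ID, {b.organ_met("Muscle", "atp"): -1},
          0, INF_BOUND, ReactionKind.MAINTENANCE)
    model = b.build({})
    manifest = ToyModelManifest(
        model_id="toy-fat", seed=0, organs=model.organs,
        planted_facts={"fao_reaction": "Muscle_FAO",
                       "ester_reaction": "Adipocyte_ESTER_sat",
                       "forced_fat_uptake": 0.8 * fat_intake})
    return model, manifest


# ---------------------------------------------------------------------------
# random small models for oracle-equivalence sweeps
# ---------------------------------------------------------------------------

def make_random_small_model(seed: int
                            ) -> tuple[WholeBodyModel, SolverSettings]:
    """A random feasible model with <= 12 reactions for pfba-vs-oracle checks.

    A random sparse stoichiometry is drawn, a point in its null space is
    taken as a feasibility witness, and bounds are placed around it (a few
    of them tight) so the generated QP always admits a solution.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 13))
    m = int(rng.integers(2, max(3, n - 2)))
    for _ in range(100):
        S = np.zeros((m, n))
        mask = rng.random((m, n)) < 0.45
        S[mask] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=int(mask.sum()))
        from scipy.linalg import null_space
        N = null_space(S)
        if N.shape[1] >= 1:
            break
    z = rng.normal(size=N.shape[1])
    v0 = N @ z
    scale = max(1.0, float(np.max(np.abs(v0))))
    v0 = v0 / scale * 2.0
    lo = v0 - rng.uniform(0.05, 1.5, size=n)
    hi = v0 + rng.uniform(0.05, 1.5, size=n)
    for j in rng.choice(n, size=min(2, n), replace=False):
        if rng.random() < 0.5:
            lo[j] = v0[j]
        else:
            hi[j] = v0[j]

    mets = [Metabolite(f"m{i}[c]", f"m{i}", None, "[c]") for i in range(m)]
    rxns = []
    for j in range(n):
        stoich = {f"m{i}[c]": float(S[i, j]) for i in range(m) if S[i, j] != 0}
        if not stoich:  # keep the matrix shape honest
            stoich = {f"m{rng.integers(m)}[c]": 0.0}
        kind = ReactionKind.MAINTENANCE if j == 0 else ReactionKind.INTERNAL
        rxns.append(Reaction(id=f"r{j}", stoich=stoich, lb=float(lo[j]),
                             ub=float(hi[j]), kind=kind))
    model = WholeBodyModel(sex="male", metabolites=mets, reactions=rxns,
                           maintenance_reaction_id="r0", organs=[])
    settings = SolverSettings(maintenance_value=float(v0[0]))
    return model, settings


# ---------------------------------------------------------------------------
# writing a synthetic study to disk
# ---------------------------------------------------------------------------

def write_synthetic_study(out_dir: str | Path, sex: str = "male",
                          seed: int = 0) -> dict[str, Path]:
    """Write the model dialect file, 12 diet TSVs, nutrient table and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, manifest = make_toy_wbm(sex=sex, seed=seed)
    paths = {"model": out / f"wbm_{sex}.json",
             "manifest": out / f"manifest_{sex}.json",
             "nutrient_table": out / "nutrient_table.tsv",
             "diet_dir": out / "diets"}
    write_model(model, paths["model"])
    manifest.to_json(paths["manifest"])
    nutrient_table_fixture().to_tsv(paths["nutrient_table"])
    paths["diet_dir"].mkdir(exist_ok=True)
    for d in make_toy_diets():
        write_diet(d, paths["diet_dir"] / f"{d.name}.tsv")
    return paths
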