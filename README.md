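# dietwbm

**In silico dietary interventions on organ-resolved whole-body metabolic
models, with metabolic-syndrome flux readouts.**

Metabolic Syndrome (MetS) is a cluster of interrelated abnormalities —
hyperglycemia, hypertriglyceridemia, high LDL-C with low HDL-C, central
obesity — whose progression is strongly diet-dependent, yet dietary
intervention trials are slow and cannot resolve what each organ does.
Constraint-based whole-body models (WBMs) offer a computational
alternative: organ-resolved, sex-specific stoichiometric networks joined
through a shared blood compartment, on which a diet becomes a set of
nutrient-uptake bounds and the systemic response becomes a flux
distribution.

`dietwbm` implements that simulation protocol end to end for researchers
in computational physiology and systems nutrition: diet files in the
two-column VMH dialect are turned into uptake bounds, parsimonious FBA is
solved with the whole-body maintenance reaction pinned to one, and the
flux solution is distilled into MetS readouts — organ-resolved glucose
exchange with blood, summed adipocyte TAG esterification, the
LDL-C/HDL-C secretion-flux ratio, and thiolase-step fatty-acid
β-oxidation in muscle and heart — plus nutrient-composition PCA and
flux-space t-SNE embeddings. A fully synthetic study (toy multi-organ
models with planted, analytically known mechanisms, and 12 toy diets
spanning Unhealthy/Balanced/Keto/Vegan-like macronutrient mixes) makes
every pipeline stage testable without downloading any external model.

## The model

Fluxes `v` (mmol/day/person) over reactions of a stoichiometric matrix
`S` satisfy pseudo-steady-state mass balance and bounds:

```
min   Σᵢ vᵢ²
s.t.  S v = 0
      lbᵢ ≤ vᵢ ≤ ubᵢ
      v_maintenance = 1        (lower bound = upper bound = 1)
```

Diet intake `a` of a nutrient sets the bounds of its diet exchange
reaction to `[-a, 0]` (uptake allowed) or `[-a, -0.8a]` (uptake forced,
the convention used for the studies here); all other bounds are
untouched. The L2 objective is strictly convex, so the optimum is the
unique projection of the origin onto the feasible set — simulations are
deterministic and need no statistics. The solver reduces out pinned
variables, solves the convex QP, and polishes the result with an exact
KKT active-set iteration; an exhaustive active-set oracle (`qp_oracle`)
independently verifies it on models of ≤ 12 reactions.

For organ–blood exchange reactions, positive flux is secretion into
blood throughout the package.

## Worked example

```python
from dietwbm import synthetic_data as sd, solver, biomarkers as bm
from dietwbm.diet import DietApplicationPolicy, DietMode, apply_diet

model, manifest = sd.make_toy_wbm("male")        # 87 reactions, 8 organs
panel = bm.resolve_panel(model)                  # biomarker reaction sets
policy = DietApplicationPolicy(mode=DietMode.FORCED_UPTAKE)

for diet in sd.make_toy_diets():
    if diet.name not in ("toy-Balanced", "toy-Unhealthy"):
        continue
    sol = solver.pfba(apply_diet(model, diet, policy))
    print(diet.name,
          f"TAG={bm.sum_flux(sol, panel.tag_synthesis):.3f}",
          f"LDL/HDL={bm.ldl_hdl_ratio(sol, panel.ldl_exchange, panel.hdl_exchange):.3f}",
          f"FAO={bm.sum_flux(sol, panel.fao):.3f}")
```

prints

```
toy-Balanced TAG=1.273 LDL/HDL=1.057 FAO=1.350
toy-Unhealthy TAG=2.426 LDL/HDL=2.202 FAO=2.681
```

TAG is the summed flux (mmol/day/person) through the three adipocyte
esterification reactions — the energy-dense, cholesterol-rich Unhealthy
diet nearly doubles it relative to the Balanced diet, because forced
intake beyond oxidation capacity is routed to storage. The LDL/HDL
column is the ratio of total LDL-C to HDL-C secretion flux into blood,
driven up by dietary cholesterol load; FAO is the summed thiolase-step
butyryl-CoA → acetyl-CoA flux in muscle and heart.

The numbered drivers under `analysis/` run the full study narrative:

```sh
python analysis/01_generate_study.py      # models, diets, nutrient table
python analysis/02_diet_composition.py    # macronutrient table + PCA
python analysis/03_run_intervention.py    # 2 sexes x 12 diets, pFBA, readouts
python analysis/04_biomarker_findings.py  # diet rankings per readout
python analysis/05_solver_validation.py   # oracle sweep + closed forms
```

with tables written under `results/`. A `dietwbm` console command wraps
the same steps (`dietwbm synth`, `dietwbm validate`, `dietwbm run`,
`dietwbm embed`).

## Scope

The package simulates reaction fluxes only: no serum-concentration
predictions, no insulin or hormonal regulation, no dynamic FBA, and no
reconstruction or curation of real whole-body models. Real VMH-hosted
WBMs can be loaded through the SBML or JSON dialect readers with
explicit biomarker id lists in the panel config, but all bundled studies
run on the synthetic models. See `docs/methods.md` for modeling
assumptions and design decisions.
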