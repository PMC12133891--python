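# Methods

This note documents the modeling protocol, the numerical choices, the
synthetic study that serves as the package's test bed, and the design
decisions taken where the simulation recipe is genuinely open.

## 1. Simulation protocol

### 1.1 Constraint-based model

A whole-body model (WBM) is a stoichiometric network whose reactions are
partitioned into organ sub-networks (reaction ids are organ-prefixed,
`Liver_…`, `Muscle_…`) joined through shared compartments: a systemic
blood compartment (metabolite tag `[bc]`) and a gastrointestinal lumen
(`[d]`). Five reaction kinds are distinguished — internal,
organ–blood exchange, diet exchange, sink/demand, and a single whole-body
maintenance reaction — and classification is derivable from identifiers
alone under a configurable naming convention, so the same code path
serves both the synthetic models and externally supplied files (JSON
dialect or SBML L3/fbc).

Sign conventions, fixed package-wide:

* organ–blood exchange: **positive flux = secretion into blood**.
  Readers re-orient reactions stored the other way and record the flip
  in the model report.
* diet exchange: **uptake is negative flux**; an intake of `a` mmol/day
  becomes bounds `[-a, 0]` (optional uptake) or `[-a, -f·a]` (forced
  uptake, default `f = 0.8`).

Unbounded bounds are encoded as ±1e6 (finite big-M). The L2 objective is
strictly convex, so the optimum stays far from that box and its exact
value is immaterial; keeping it finite keeps the QP well posed.

### 1.2 Parsimonious FBA

Given bounds `lb ≤ v ≤ ub` and stoichiometry `S`, the protocol solves

    min Σ vᵢ²   s.t.   S v = 0,   lb ≤ v ≤ ub,   v_maint = 1,

with the maintenance flux pinned by setting both of its bounds to the
maintenance value (default 1.0 — a weight-stable upkeep state). The sum
of squares runs over *all* reactions, exchanges and maintenance included
(the pinned maintenance contributes a constant); this matters because
some parsimony variants exclude exchanges, and the two conventions give
different flux distributions.

Solver pipeline (`solver.pfba`):

1. feasibility probe by LP (HiGHS); infeasible models short-circuit to
   `status=infeasible`;
2. variables with `lb == ub` are eliminated exactly, and the equality
   system is projected onto an independent row basis by SVD (WBM-style
   networks carry many redundant mass balances);
3. the reduced strictly convex QP is solved by scipy's `trust-constr`
   (gtol 1e-12, xtol 1e-14) from the LP feasible point;
4. the approximate solution is polished to a KKT point by a primal
   active-set iteration: the working set only ever contains bounds
   active at the current (feasible) iterate, each equality-constrained
   min-norm subproblem is solved exactly by least squares, steps are
   line-searched to the first blocking bound, and bounds with wrong-sign
   multipliers are released. For a strictly convex QP any KKT point is
   the unique global optimum, so the polish terminates with a
   machine-precision solution.

Every reported solution carries diagnostics: `max |S v|` (accepted below
1e-6 relative to the largest flux) and the maximum bound violation
(accepted below 1e-8). An L1 mode (minimum total flux via
positive/negative splitting, solved as an LP) is available as a fallback
but is a *different* parsimony criterion and is never used by the
bundled studies.

`solver.qp_oracle` solves the same QP by exhaustive enumeration of
active-set assignments (free / at-lb / at-ub per reaction, smallest
active sets first, dense KKT solve per assignment) and refuses models
with more than 12 reactions. It shares no code path with the polish
beyond the KKT algebra and serves as the independent oracle in tests;
across 50+ random small models the two agree to ~1e-14.

### 1.3 Infeasibility diagnosis

When a diet starves the model, `diagnose_infeasibility` solves an LP
that adds non-negative slack to the bounds of diet exchanges and the
maintenance reaction and minimizes the weighted total. Maintenance slack
is charged 10× diet slack, so the diagnosis names the missing nutrients
rather than proposing to give up the physiological demand; maintenance
relaxation appears only when no diet could supply it. Reported
relaxations are the minimal extra intakes that restore feasibility.

## 2. Diets and composition features

Diet files are two-column text (`Diet_EX_<nutrient>[d]`, mmol/day);
identifiers are normalized to nutrient base ids and duplicate rows are
summed. Unmatched diet nutrients are warnings, not errors — real diet
formulations routinely contain compounds absent from a given model
version.

Energy accounting uses a nutrient table (base id → macronutrient class,
g/mmol, kcal/g) with Atwater factors 4/9/4 kcal/g (7 for alcohol) as
defaults. The macronutrient breakdown of a diet is the energy fraction
per class; micronutrient features stay in mmol/day since they are
essentially non-caloric. Fractions are exact by construction for the
synthetic diets, whose amounts are solved from stated energy targets.

## 3. The synthetic study

### 3.1 What the toy WBM emulates

The toy generator reproduces the *structure* of organ-resolved WBMs at a
lumped scale (87 reactions male, 102 female, vs ~8×10⁴ in real WBMs):
one reaction per pathway stage, 8 metabolic organs (liver, adipocytes,
muscle, heart, lung, kidney, pancreas, brain) plus, in the female
variant, breast, uterus and a renal-blood conduit. Planted mechanisms,
all recorded in a machine-checkable manifest:

* **Glucose.** Dietary sugars enter through the liver (portal
  circulation, fructose lumped into hepatic glucose); every weighted
  organ draws blood glucose for its maintenance ATP share (glycolysis
  yield 2 ATP/glucose against a per-organ ATP/ADP pair). The liver is
  therefore the sole net glucose secretor in the male model, all other
  organs consistent uptakers; the female secretory conduits run
  amino-acid gluconeogenesis (yield 0.8) and secrete glucose, mirroring
  breast/uterus/renal-blood secretion. Gluconeogenesis from amino acids
  and fat (yield 0.5) kicks in when carbohydrate is scarce (Keto).
* **TAG.** Three adipocyte esterification reactions (saturated,
  unsaturated, essential fatty acids) feed a storage sink; excess blood
  fat and de novo lipogenesis from excess glucose (yield 0.5) both end
  there. Essential fatty acids have no other consumer, so all diets show
  a nonzero TAG baseline.
* **β-oxidation.** Muscle and heart each take up saturated/unsaturated
  fat, activate it to butyryl-CoA and run a thiolase step
  (butyryl-CoA → acetyl-CoA) into a terminal oxidation sink. The FAO
  readout is the summed flux of exactly these two thiolase reactions.
* **Cholesterol.** Dietary cholesterol loads the liver, which disposes
  of it via bile or packages it as LDL-C for peripheral delivery
  (adipocyte storage; kidney and renal blood join in the female model,
  giving five LDL exchanges vs three in the male). HDL-C delivery to a
  fixed muscle membrane demand provides a diet-independent secretion
  baseline, so the LDL/HDL secretion ratio is always defined and rises
  with cholesterol-rich diets. With no dietary cholesterol the liver
  synthesizes it from glucose (yield 0.2). This "nascent lipoprotein
  delivery" picture is deliberately simplified — reverse cholesterol
  transport is not modeled.
* **Maintenance.** One whole-body reaction consumes each weighted
  organ's ATP (equal weights 1.0 by default, overridable) plus 0.3
  mmol cholesterol in muscle and adipocytes per unit flux — the
  composite-demand reading of whole-body upkeep.

Because disposal routes compete under a strictly convex objective, every
open route carries flux in the interior optimum, and route loads scale
with forced intake. That is what makes the planted directional facts
(TAG: Unhealthy > Balanced; LDL/HDL: Unhealthy > Vegan; FAO: Keto >
Balanced) consequences of the mechanism rather than hard-coded numbers.

### 3.2 Toy diets

Twelve diets span the macronutrient spectrum. Amounts are derived from
stated energy targets (toy-kcal scale ≈ 20 per diet; roughly 1% of a
human day, matching the maintenance-pinned demand scale): Balanced is
50/30/20% carbohydrate/fat/protein energy; Keto is 8/65/27 (fat share
0.65 > 0.53); Unhealthy carries 1.5× the Balanced energy, a high
saturated-fat and fructose share, 2.0 mmol/day cholesterol and little
fiber; Vegan has zero cholesterol and mostly unsaturated fat. Five
micronutrient proxies with per-diet accents give the micronutrient PCA
non-trivial structure. Molar masses are realistic (glucose 180 g/mol,
fatty acids 256–282 g/mol).

The bundled studies apply diets with the **forced-uptake** policy
(`[-a, -0.8a]`): the planted mechanisms describe what the body must do
with what it ate, which requires the eating to be mandatory. Under the
optional policy the parsimonious optimum would simply decline surplus
nutrients and diets with superset availability would collapse onto the
same solution. Both policies are exposed because the choice changes
fluxes materially.

### 3.3 What passing does not show

The toy study validates the protocol machinery — bound application,
QP solving, readout extraction — and the *directions* of the planted
mechanisms. It says nothing about flux magnitudes in real WBMs, about
pathway-level completeness (single-step lumps have no intermediate
regulation), or about any hormone-mediated effect; the models contain no
insulin. Real-model runs additionally require the biomarker reaction ids
to be supplied explicitly in the panel config.

## 4. Biomarker readouts

* Secretion/uptake totals over an exchange set are positive-part sums
  (`Σ max(v,0)`, `Σ max(-v,0)`): an organ taking lipoprotein up must not
  cancel another's secretion. Net flux is reported alongside.
* The LDL/HDL ratio divides total secretion fluxes and raises a guarded
  error when HDL secretion ≤ 1e-9 rather than returning infinity.
* Organ roles across diets use a consistency threshold τ = 1e-6
  mmol/day/person: secretor/uptaker only when every diet agrees in sign
  above τ, `mixed` otherwise, `inactive` below τ throughout.
* Panels resolve from explicit id lists (for real models) or structural
  patterns (exchange metabolite + blood tag; producing-organ +
  product for TAG; consumed/produced metabolite pair for the thiolase
  step), and resolution failures are loud errors naming the pattern.

## 5. Embeddings

PCA is computed by SVD of the centered (and by default unit-scaled)
matrix — composition features mix energy fractions and mmol/day scales,
so standardization is the default. Constant columns are dropped with a
warning; component signs are fixed (largest-|loading| entry positive) so
results are reproducible across runs and match a covariance
eigendecomposition to 1e-8. t-SNE delegates to scikit-learn (exact
gradient, PCA init, perplexity capped at (n−1)/3) with a mandatory seed;
its coordinates are treated as visualization output — the tested
contract is shape, finiteness and same-seed bitwise reproducibility,
never coordinate semantics, since manual cluster reading is not a
testable claim.

## 6. Numerical choices and degenerate inputs

* Tolerances: feasibility 1e-8, optimality 1e-8, mass-balance acceptance
  1e-6 (relative to the largest flux), maintenance pinning exact by
  variable elimination.
* No randomness anywhere in the default solve path; the only seeds are
  the t-SNE seed and the random-model generator used in solver
  validation.
* Empty diets, zero-energy diets, all-constant PCA inputs, < 4 t-SNE
  samples, zero-HDL ratios and oversized oracle calls all raise typed
  errors rather than returning garbage.
* Ties: the L2 optimum is unique, so no tie-breaking is needed in the
  solver; equal-cost disposal routes split symmetrically (tested:
  0.5/0.5 on identical parallel paths, (2/3, 1/3) on a 1-step vs 2-step
  pair from stationarity of a² + 2b² under a + b = 1).

## 7. Known limitations

* The toy stoichiometry is structural, not biochemical: yields are
  round numbers chosen for transparency, not measured ATP stoichiometry.
* Organ maintenance weights default to equal shares; real organ-weight
  parameterizations are out of scope.
* The L1 fallback changes the parsimony criterion and is flagged as
  non-protocol output.
* SBML support covers L3/fbc flux-bound models with organ lists in the
  model notes; exotic SBML variants are not handled.
* Alcohol is a recognized nutrient class (7 kcal/g) but no toy diet
  carries it; the alcohol energy fraction is structurally zero in the
  bundled composition tables.
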