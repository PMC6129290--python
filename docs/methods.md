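# Methods

## Scope and model

`flexcop` designs small synthetic microbial consortia *in silico*. A
consortium design problem has four ingredients:

1. **Stoichiometric models**, one per strain: metabolites, reactions with
   flux bounds, an objective (biomass) reaction, and optional *flux
   couplings* — exact linear equalities `v_target = k · v_source` appended
   to the LP. Fluxes are in mmol·gDW⁻¹·h⁻¹, the biomass reaction in h⁻¹;
   uptake is a negative exchange flux (BiGG sign convention); biomass is
   gDW/L, concentrations mM, time h. These units are fixed package-wide.
2. **A community layout**: initial biomass per strain, a shared medium of
   finite metabolite pools (anything not listed is unlimited — the
   minimal-medium convention), the Euler step Δt, the horizon, and a
   death rate δ.
3. **A discrete configuration space**: tunable parameters (strain ratios,
   cross-feeding rates, medium composition, per-strain uptake capacities,
   carbon partition fractions …), each with an ordered finite domain and
   a declarative *binding* saying what it sets. Physiological predicates
   mark parts of the grid inadmissible; those configurations are scored
   with a sentinel worst fitness (−10⁹) and never simulated, which keeps
   the search history totally ordered while honouring the constraint.
4. **A fitness function** from a small registry (terminal product titre,
   yield on the limiting carbon source, community growth rate, times to
   stationary/exhaustion/degradation, total biomass, maximin per-strain
   growth rate), or a weighted sum of normalised components.

## Flux balance analysis

`solve_fba` solves max/min c·v subject to S·v = 0, the coupling
equalities, and the box bounds, with SciPy's HiGHS backend. Infeasible
and unbounded problems are reported in the solution status, never raised:
inside the dynamic loop an infeasible step simply means the strain does
not grow that step. Objective values of an LP are unique; flux vectors at
degenerate optima are not, so `solve_fba` reports the solver's vertex and
offers an optional parsimonious second stage (minimise Σ|v| at the fixed
optimum) when a reproducible flux vector matters. A model may declare a
`secondary_objective` maximised lexicographically at the fixed primary
optimum; this is how nitrogen-starved product formation is modelled (grow
as fast as nitrogen allows, then push the product pathway with whatever
carbon uptake capacity is left).

Growth-coupled secretion ("k units of product per unit of growth rate")
is encoded as a hard equality row, not as a bound recomputed between
steps: a single solve then satisfies the coupling exactly, which makes
single-solve results reproducible and oracle-checkable. The carbon
partition operation ("fraction p of fixed carbon goes to the export
product") reduces to the same mechanism with
`k = p · c_fix / c_export`, where the `c` are carbon throughputs
(C-atoms per unit flux) computed from per-metabolite carbon annotations;
`p = 1` is rejected because it leaves no carbon for growth.

## Dynamic community simulation

The simulator advances the community on a fixed Euler grid. Per step:

1. the strain order is permuted with a seeded generator;
2. each strain in turn has its exchange lower bounds set to
   `−min(Vmax · c/(Km+c), c/(X·Δt))` against the *current* pools
   (Michaelis–Menten saturation only when a Km is given; the second term
   is the hard availability limit for the step), its LP is solved, and
   the pools are debited/credited immediately by `v · X · Δt`;
3. biomasses update as `X ← X · (1 + (μ − δ)Δt)` and pools are clamped
   at zero (clamping only absorbs float round-off, since uptake is
   availability-bounded).

This *sequential sharing* is the package's reading of why replicate runs
of the same configuration differ: replicates differ only in the order
strains draw on shared pools. A configuration's fitness is therefore the
mean over n seeded replicates (sd recorded with the population
convention, ddof = 0 — replicate counts are small and fixed). An
alternative *proportional* rule (all strains see start-of-step pools;
oversubscribed pools scale every claimant's whole flux vector down) is
available per layout; scaling the full vector preserves S·v = 0, so the
scaled solution remains feasible. The overflow-pair case bundle uses it
by default so that strains with identical phenotypes trace identically
for every seed and profile classes reflect the configuration rather than
execution-order luck.

Secreted products accumulate in the medium and are re-consumable by any
strain able to take them up — metabolite accumulation is part of the
dynamics, which is exactly what distinguishes this model class from
steady-state community methods that assume instantaneous transfer.

Defaults: Δt = 0.1 h, δ = 0, horizon per case (100 h for the
producer–consumer case); all three are recorded in every trace header.
Halving Δt changes toy final biomasses by O(Δt) (checked in the suite);
Δt = 0.5 h is used for some desk-scale sweeps where the extra Euler error
does not change the qualitative landscape — coarser steps can reorder
near-tied configurations and are avoided where an argmax matters.

## Configuration search

`run_exhaustive` scores every admissible configuration once
(deterministic enumeration order, ties broken by that order) and is the
oracle used throughout the suite. `run_smbo` is a sequential model-based
search in the SMAC family: a seeded random warm start; then per
iteration an ensemble of regression trees (scikit-learn random forest,
ordinal-encoded parameters, predictive sd from cross-tree spread) is
fitted to the (configuration, mean fitness) history, and a candidate set
is scored by closed-form expected improvement
`(m−b)Φ(z) + sφ(z)`, `z=(m−b)/s`. The candidate set is all
one-parameter neighbours of the incumbent (any other value of one
parameter, near values first) plus 1000 random configurations, plus —
on small spaces — every unevaluated configuration, so a budget covering
the space provably finds the optimum. Neighbours precede random
candidates so that EI ties, which are common while the surrogate is
flat, resolve into axis moves from the incumbent: the iterated-local-
search ingredient. With a noisy objective (replicates per evaluation
> 1), intensification is on: the incumbent accrues an extra fresh
replicate every other iteration (up to 4× the base replicate count) and
a challenger must match the incumbent's replicate count before it can
take over. The paired seeded experiment in the suite shows this reduces
incumbent-selection error versus a no-intensification baseline.

All optimizer knobs (budget, replicates, warm-start size, candidate
count, tree count, intensification) live in one `SearchBudget` block;
every run is bit-reproducible from its seed.

## Landscape mining

The history table (one row per evaluation, one column per parameter) is
mined three ways: Pearson correlations parameter↔fitness and pairwise
(constant columns are flagged undefined rather than emitting NaN);
the *top-fraction profile* — parameter values constant across the best
⌈fraction·N⌉ records, ties at the cutoff included; and decision rules —
for each parameter the single threshold (≤/≥) maximising balanced
accuracy for separating top from rest, found by exhaustive scan over
value midpoints, with one greedy two-condition conjunction attempted.
The exhaustive scan was chosen over a generic tree learner so results
are deterministic and directly checkable against a brute-force oracle.

Growth-curve *profiles* classify a multi-strain trace as `no_growth`
(no strain multiplied its inoculum by the growth factor, default 2×),
`single_survivor` (exactly one did), `ancestor_like` (several grew but
trajectories are pairwise within 5% relative tolerance —
phenotypically undifferentiated), or `coexistence` (several grew along
distinct trajectories). The categories are checked to be mutually
exclusive and exhaustive; both thresholds are explicit parameters
because the distinction is inherently a visual one made operational.

## Packaged case studies (what they emulate, and what they do not)

Three deterministic desk-scale bundles mirror the classic applications:

* **Producer–consumer** (`toy1`): a carbon fixer (0.5 C-mmol gDW⁻¹ h⁻¹
  fixation capacity, 10 C per gDW biomass) partitions a configured
  fraction of fixed carbon into sucrose; a consumer (sucrose uptake
  capped at 3.1 mmol gDW⁻¹ h⁻¹, 2 sucrose + 1 NH₄ per gDW) grows until
  the ammonium pool is gone, then converts remaining sucrose to a
  C8 storage product via the lexicographic objective. The search space
  is the published-style grid: secretion 10–80% (default 30), feeder
  inoculum 0.5–2 g/L (default 2), eater inoculum 0.02–0.2 g/L (default
  0.1), NH₄ 0.5–15 mM (default 7), with the feeder-≥-10×-eater
  admissibility predicate. Only ranges and defaults of such grids are
  ever published; the intermediate grid points here were chosen once to
  include every value the landscape discussion needs. Over the 100 h
  horizon the product-titre landscape has an *interior* optimum of the
  secretion fraction (30% in the sweep the acceptance script runs):
  secreting more starves the producer's own growth and ultimately
  lowers cumulative export — the qualitative trade-off the full-scale
  system exhibits. At short horizons (≲40 h) the optimum moves to the
  high boundary because producer growth has no time to pay off; tests
  that only need an informative landscape, not interiority, use those
  cheaper horizons.
* **Auxotroph ring** (`toy2`): n = 4 strains on unlimited glucose;
  strain i consumes amino acid i (1 mmol per gDW) and secretes amino
  acid i+1 growth-coupled at rate kᵢ ∈ {0, 0.5, 1, 1.5, 2}. Each pool
  starts with a 0.05 mM seed so growth can bootstrap; with k ≥ 1
  secretion outpaces demand and the ring sustains itself, with k = 0
  growth stalls at the seed (mutual starvation). Amino-acid pools pair
  producer to consumer uniquely and glucose is unlimited, so the
  symmetric configuration is exactly symmetric: all four strains grow
  at the same rate bit-for-bit, and the maximin-growth-rate fitness
  peaks at symmetric high coupling.
* **Overflow pair** (`toy3`): two strains starting at 0.01 g/L each on a
  10 mM glucose pulse, with per-strain glucose/acetate/oxygen uptake
  capacities as the configuration (O₂ domain {7, 20} — the lower value
  is the stress condition). Respiration (high yield, 6 O₂ per glucose),
  fermentation (low yield, 2 acetate out) and acetate respiration feed
  a common biomass precursor with exact carbon bookkeeping, so
  restricted oxygen forces overflow acetate secretion and
  glucose-specialist/acetate-specialist divisions of labour coexist in
  two growth phases. Five fitness variants (growth rate, biomass,
  yield, biomass-per-time, yield-per-time) run on the same space.

What the toys deliberately do not emulate: genome-scale network
redundancy (thousands of reactions, alternate optima), realistic
maintenance energies, pH/temperature effects, spatial structure, lag
phases, and regulation. Passing tests on them validates the machinery —
LP correctness, conservation, determinism, search and mining behaviour,
and the qualitative landscape shapes — not quantitative predictions for
real organisms. The genome-scale case studies require published models
(iJB785, iJN1411, iAF1260, iJO1366) that this package does not
redistribute; `real_case_recipe` documents the exact documented edits
(invertase addition, nitrate-assimilation removal, sucrose uptake 3.1,
PHA cap 1.83, glucose 10 / acetate 3.7 calibration, O₂ stress 7) as
executable recipes that refuse to run until the model files are present.
The methionine secretion rate for the auxotroph case is quoted as both
1.6 and 1.5 in its source; the recipe preserves the discrepancy instead
of silently resolving it.

## Numerical choices and degenerate inputs

* Mass balance of reported optima is asserted at 10⁻⁶; the FBA-vs-vertex
  -enumeration oracle agrees to well below 10⁻⁹ on all toy models.
* Pool clamping tolerance 10⁻¹²; carbon drift on death-free annotated
  toys stays below 10⁻¹⁵ relative.
* `uptake_bound` returns 0 on any degenerate input (empty pool, zero
  biomass, zero step).
* Effective growth rates are least-squares slopes of ln X; flat series
  return 0; series hitting zero are fitted on their positive prefix with
  a warning.
* Stationary phase: community biomass changing < 0.1% per step for 5
  consecutive steps; washout (stability goal): final biomass below 0.5×
  inoculum. Both are parameters of the metric spec.
* Ties everywhere (exhaustive search, rule thresholds, EI candidates)
  break deterministically by enumeration order.

## Problem sizes used by the test and acceptance runs

Desk-scale sweeps use the full 100 h producer–consumer horizon only
where the interior optimum itself is the claim (an 8-point sweep); the
optimizer-versus-oracle comparisons run on a planted 8×8 landscape
(budget 30, 100 seeds) and on a 96-configuration consortium sub-space
(budget 24, 20 seeds); robustness sweeps use 200 randomized communities
of 10–30 steps. These sizes were chosen so every claim is exercised by
an exact or statistical oracle while the whole suite stays comfortably
reproducible on one CPU.

## Known limitations

* Euler updates are first-order; Δt must be chosen against the fastest
  growth rate (μ·Δt ≲ 0.1 is safe on the toys).
* Sequential sharing makes replicate variability *order-driven* only;
  real COMETS-style simulators add further stochasticity this package
  does not model.
* The random-forest surrogate cannot extrapolate monotone trends beyond
  the evaluated region; the neighbour-first candidate ordering
  compensates but very tight budgets on large flat landscapes will
  degrade to local search.
* SBML import maps stoichiometry, FBC bounds and the FBC objective only
  (via cobrapy); kinetic laws and gene–protein–reaction rules are
  ignored with a logged warning.
* No FVA, gapfilling, thermodynamic constraints, Pareto multi-objective
  search, or spatial grids.
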