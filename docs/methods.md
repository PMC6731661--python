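# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `diauxlab`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The hybrid model

**Regulatory layer.** A two-slice dynamic Bayesian network over gene
activity states. Nodes are tagged `regulator` or `enzyme`; only regulators
may have children (enzymes are read-outs that gate metabolism). Each node's
conditional is linear-Gaussian, `x[t+1] = b + Σ w_p x_p[t] + N(0, σ²)`,
with an initial Gaussian state per node. Activities are nominally in
[0, 1] (clipped only where they scale flux bounds) but states are genuine
unbounded Gaussians. Discretization to active/inactive, where needed, uses
a 0.5 threshold.

**Metabolic layer.** A stoichiometric model: internal metabolites satisfy
S·v = 0; reactions carry default bounds in mmol·gDW⁻¹·h⁻¹; one reaction is
the biomass drain and its flux is the specific growth rate μ (h⁻¹).
Gene–reaction rules are AND/OR boolean expressions over enzyme genes;
their continuous evaluation (AND → min, OR → max over means clipped to
[0, 1]) scales the reaction's default bounds linearly. Linear scaling is
the minimal monotone coupling; it is isolated in
`dfba.gene_states_to_bounds` so alternative couplings can be swapped in.

**Bridges.** Metabolite→gene threshold rules overwrite a target gene's
state for the next slice when the comparison holds on the current culture
state (e.g. glucose < 0.25 mM sets the shift regulator to (1.0, 0.05)).
Conflicting rules are applied in file order, the last one winning.
Knockouts clamp a gene to (0, 0) at every slice *and* make it evaluate as
0 in gene–reaction rules, so a deletion severs both signal and mass flow.

## Simulation loop

Each step of `simulate_strain` performs (1) a regulatory forward step,
(2) a dynamic-FBA step using bounds scaled by the new gene means, and
(3) metabolite-rule application on the updated culture state. Mean-field
propagation is the default: means and variances propagate with a diagonal
(gene-independence) approximation,

    μ[t+1] = b + W μ[t]        var[t+1] = W² var[t] + σ²  (elementwise),

which matches the reporting of states as per-gene means and SDs.
Trajectory sampling (each state drawn from its Gaussian) is available with
a seed and is what the virtual laboratory uses for expression data.

**Dynamic FBA.** Static-optimization approach: at each step, the uptake
bound of every reaction consuming an external metabolite m is capped at
`min(Vmax·c/(Km+c), c/(X·dt)) / |stoichiometric coefficient|` (per-reaction
Michaelis–Menten plus pool availability; defaults Vmax = 10, Km = 0.5 mM,
overridable per metabolite in the model). A single LP maximizes
`v_biomass − 1e-7·Σ|v|`; the tiny parsimony penalty is the degeneracy
tie-break (it biases μ by ≤ ~1e-6 h⁻¹, far below all tolerances, and halves
the LP count relative to a two-phase solve). `solve_fba` proper uses the
exact two-phase parsimonious solve and is the operation checked against
brute-force LP vertex enumeration. Biomass integrates exponentially
(X' = X·e^{μ·dt}); pools update with interval-average biomass and clip at
zero; an infeasible LP produces a zero-growth fallback state, flagged.

## Backward inference

`dbn.backward_infer` conditions the exact joint linear-Gaussian process on
partial (gene, time) evidence — Kalman filtering plus Rauch–Tung–Striebel
smoothing over the full state vector, with pseudo-inverses wherever
zero-variance directions make innovation covariances singular. The forward
pass uses the diagonal approximation *only* when there is no evidence (the
posterior then equals the prior marginal-wise); with evidence, cross-gene
covariances are carried exactly, which the suite verifies against
brute-force joint-covariance conditioning on models of up to 5 genes and
4 slices.

## Inverse DFBA (growth evidence)

`dfba.bounds_from_growth` pins the biomass flux to an observed growth rate
(projected onto the feasible maximum with a warning if above it), finds the
parsimonious flux vector, and computes each rule-bearing reaction's flux
variability **under the parsimonious total-flux budget**. Plain flux
variability admits futile cycles (e.g. simultaneous secretion/uptake) that
would claim activity is "required" at zero growth; constraining total |v|
to the parsimonious optimum removes them. The admissible |flux| interval,
normalized by the reaction's largest default bound and clipped to [0, 1],
becomes a required-activity interval; each gene in the rule receives a
Gaussian with the interval midpoint as mean and a quarter of the width as
SD (floored at `sd_min` = 1e-3). Genes gating several reactions take the
intersection of their intervals (the binding requirement when empty). This
flux-range → activity-evidence construction is an explicit interpretation
and is isolated behind this one operation.

**Phase awareness.** When evidence is built from a fitted growth curve
(`design._growth_evidence`), pre-shift slices use the default bounds and
post-shift slices close every reaction consuming the glucose metabolite:
after depletion the observed respiratory rate must be explained by the
alternative carbon route, otherwise the LP would satisfy it with glucose
fermentation and the ethanol-route enzymes would receive vacuous evidence.

## Active design (forward/backward divergence)

`design.adactive_rank` compares two phenotype-constrained posteriors over
gene states: one conditioned on evidence derived from the growth curve the
model itself predicts, one conditioned on evidence from the observed
curve. The per-(gene, time) Kullback–Leibler divergence between them is
summed per gene (max per gene behind `mode="max"`); knocked-out genes and
rule-clamped (gene, time) pairs are excluded, and rule-clamped states are
pinned as evidence in both posteriors (they are known givens of the
simulation, not inferable quantities — without pinning, divergence leaks
through the shift regulator to its descendants).

The matched-posterior construction is deliberate: conditioning always
shrinks variances, so a raw comparison of the forward prior with a
conditioned posterior is bounded away from zero even when the model
explains the data perfectly. With matched geometry, self-generated
evidence gives *exactly* zero divergence, and any nonzero divergence is
attributable to the phenotype mismatch. Ranking ties (the all-zero case)
break on a phenotype-coupling information gain — the KL of the
observation-constrained posterior from the rule-aware forward trajectory —
so the designer still prefers the most phenotype-coupled genes when the
model already fits the reference curve; final ties are lexicographic.
KL inputs floor SDs at 1e-3; the direction is KL(predicted-constrained ‖
observed-constrained).

## ELSA structure inference

Each of K (default 200) components double-samples the data — a bootstrap
of `row_frac` = 0.8 of the transitions × a uniform subsample of
`node_frac` = 0.7 of the candidate parents — builds the lagged dependency
graph (edge weight = |Pearson r| between parent at t and child at t+1;
mutual information is a config alternative), attaches a virtual root to
every node with weight ε = 1e-6 (no biological root needs designating), and
keeps the Edmonds maximum spanning arborescence minus the root edges.
Edge frequency across components is the ranking score; prior-network edges
are floored at 0.5; the postfilter refits each edge's single-parent lagged
coefficient on the full data and drops |w| < 0.05. Ties break
lexicographically on (parent, child); the arborescence tie-break adds a
≤ 1e-9 total lexicographic bonus to the weights.

`forward_select` walks the ranking and accepts an edge only if it lowers
its child's exact leave-one-out one-step prediction error by ≥ 5%
(relative). The margin matters: measured on null candidates, chance LOO
improvements occur for ~1 in 5 candidates but stay below ~2.5%, while
genuinely predictive parents improve LOO by tens of percent. LOO is exact
via the ridge hat-matrix identity (equivalent to refitting every fold),
with deterministic fold order; node fits use ridge λ = 1e-2 on weights
(intercept unpenalized) and σ = residual RMS.

## Refinement (validated edge removal)

The error currency is the post-shift specific growth rate:
`postshift_error` simulates every observed deletant and takes
|predicted − observed| per strain. `score_candidate_removals` ranks edges
cheaply (no simulation): only the worst-predicted quartile of strains
contributes, and an edge scores |w| per such strain when it touches the
deleted genes' descendant cone or the ancestor cone of a phenotype-coupled
gene (metabolite-rule targets and gene–reaction-rule enzymes). `refine`
then validates greedily: tentative removal, full re-simulation of the
observation set, acceptance iff the mean absolute error drops by
≥ `min_gain` = 1e-4 h⁻¹ (float-noise guard), re-ranking after each
acceptance, a per-run tabu on rejected edges, and a hard cap of
`max_evals` tentative removals. Acceptance is purely error-driven; the
trace records every decision. Only removals are enacted; additions are
architecturally possible but disabled.

## Phenotyping

`preprocess_curve`: per replicate, blank subtraction, clipping at zero,
median smoothing (window 5 samples, nearest-edge padding — zero padding
would corrupt the curve ends), interpolation onto the first replicate's
grid, then averaging; fewer than `min_reps` = 8 replicates warns but
proceeds; normalization by starting OD is opt-in.

`growth_parameters`: on log OD, the shift time is the glucose-depletion
time (first sample < 0.1 mM) when a glucose series is present and
depletes, else the best two-segment breakpoint. The fermentative rate is
the slope before the shift; the respiratory rate is the slope from just
after the shift to growth cessation (OD reaching 95% of final), so a
stationary plateau does not dilute it; both clip at zero. Shift detection
is an F-test (α = 0.05) of the two-segment fit against a single line; when
undetected, both rates equal the single-line slope and the shift time is
NaN. Lag is the time to exceed 1.05× the initial OD; yield is the final
OD. The same estimator runs on simulated and observed curves — errors are
estimator-consistent by construction.

`compare_models`: ratio = (mean(A) − mean(B))/mean(A) (the relative error
reduction of B over A) and a two-sided Wilcoxon signed-rank test on the
paired per-strain errors, exact up to n = 25 (zero differences dropped;
normal approximation with continuity correction beyond, or when ties
preclude the exact distribution).

## The virtual laboratory

`generate_ground_truth` builds a diauxic core that is fixed by design and
a randomized periphery:

* metabolism (mmol, mM, h): glucose uptake (cap 10, HXT1) → fermentation
  (cap 12, PDC1; 1 glucose → 1.6 ethanol + 2.45 CO₂ + 0.035 biomass) with
  ethanol secretion, and ethanol uptake (cap 3, ADH2) → two respiratory
  steps (caps 3 and 2.8; CIT1, KGD1; 1 ethanol → 1.6 CO₂ + 0.04 biomass).
  The stoichiometry is carbon-balanced (glucose 6 C, ethanol/α-ketoacid
  pool 2 C, CO₂ 1 C, biomass 10 C per unit flux), which the suite checks
  to 1e-6 per step. Capacities make the gene-gated steps the binding
  constraints, so the post-shift rate responds linearly to enzyme
  activity. With the defaults this yields a wild type growing at
  ≈ 0.32 h⁻¹ pre-shift and ≈ 0.10 h⁻¹ post-shift — the fast-fermentation /
  slow-respiration pattern of a diauxic culture;
* regulation: constitutive repressor MIG1 (−0.4 onto the respiratory
  enzymes), rule-driven activator CAT8 (+0.9), and a random periphery of
  extra regulators (bias U[0.1, 0.9], at most one regulator parent) and
  enzymes (one or two regulator parents, |w| ∈ [0.4, 0.85], random signs,
  σ ∈ [0.05, 0.1]); total |w| into any regulator is rescaled below 0.95 so
  the regulator subsystem is stable;
* the three post-shift reactions get silent OR-isoenzyme partners (basal
  activity 0.05, no regulators) — formally redundant bypasses carrying
  almost no flux in the wild type. They are the substrate for
  *over-permissive* model defects: spuriously activating a bypass leaves
  the wild type untouched but predicts respiratory growth for deletants
  of the true enzyme;
* two metabolite rules on glucose (threshold 0.25 mM) switch CAT8.

Every generated model is validated and its wild-type simulation checked
for a genuine diauxic shift (detected shift, pre > post > 0.01 h⁻¹,
glucose below 0.1 mM before the shift time); failing draws are retried
deterministically, so a seed maps to exactly one model.

`run_virtual_experiment` adds i.i.d. Gaussian observation noise (OD SD
0.02, glucose SD 0.1 mM by default, clipped at zero) to the simulated
curves of 8 replicates; `observe_strain` routes them through the same
preprocessing/estimation path as any observed data.

`generate_expression_dataset` samples stochastic gene-state trajectories:
episode 1 is the wild-type diauxic time course; later episodes restart
from randomized initial gene states (uniform [0, 1]) and run a shorter
horizon (default 7.5 h, 30 episodes) — short perturbed cultures are the
desk-scale stand-in for the multi-condition compendium a real inference
run would use. Transitions are taken only within episodes (time-stamp
resets break the chain). Measurement noise is additive Gaussian
(SD 0.02).

**What the virtual lab does *not* emulate:** microarray probe effects and
normalization artifacts, plate/edge effects, lag-phase physiology,
oxygen/pH dynamics, regulator post-translational control, and the scale
of a genome-wide network (hundreds of nodes). Passing the planted-recovery
and repair suites therefore shows the algorithms are correct and
well-calibrated on data whose generating process matches the model class —
it does not certify performance on real compendia, where model mismatch
dominates.

## Problem sizes and defaults

Laboratory defaults mirror a 45 h assay sampled every 30 min (20 mM
glucose, 0.01 gDW/L inoculum, OD = 2·gDW/L, 8 replicates). The test and
acceptance runs use a scaled grid — 24 h horizon, 0.75 h steps, 8 mM
glucose — which preserves the full two-phase dynamics (shift at ~11 h)
at roughly a third of the LP count, and model sizes of 14–40 genes;
recovery experiments use a planted 18-node network (6 regulators, 12
enzymes), 300 expression transitions, 30 knockout observations, and
improvement cycles with a budget of k = 20 strains against 20 held-out
strains. Each reported quantity in `scripts/acceptance.py` records the
size actually used.

## Known limitations

* The activity→bounds coupling is linear and memoryless; enzyme kinetics,
  delays and saturation are not modelled.
* Backward inference is exact only for the linear-Gaussian regulatory
  layer; the metabolic layer enters through the activity-evidence
  construction, which discards flux-space correlations between genes.
* The removal scorer's relevance cone is a reachability heuristic; it
  bounds which edges are *considered*, while correctness rests entirely on
  the simulation-validated acceptance step.
* Refinement edits regulatory edges only — stoichiometry, gene–reaction
  rules and metabolite rules are fixed.
* With several defects, greedy validated removal can accept a compensating
  removal of a true edge when the observed strains cannot discriminate it;
  richer observation sets (more strains, full-curve errors via the config
  alternatives) reduce but do not eliminate this.
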