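# Methods

`fluxcohort` implements a personalized constraint-based analysis of
two-group (healthy vs disease) transcriptome cohorts on genome-scale
metabolic models: context-specific model extraction, per-individual flux
variability simulation, differential flux statistics, reaction-set
enrichment, metabolite-network component discovery, and GA-SVM selection
of exchange-flux markers. This note records the model, its assumptions,
the tunable parameters, and the design choices made where the design was
genuinely open.

## The constraint-based model

A metabolic network is a stoichiometric matrix **S** (metabolites ×
reactions) with flux bounds `lb ≤ v ≤ ub` (mmol·gDW⁻¹·h⁻¹). All
simulation happens on the steady-state flux polytope `{v : Sv = 0,
lb ≤ v ≤ ub}`. Exchange reactions follow the COBRA convention
`met_s ↔ ∅` with negative flux meaning uptake; compartments are
single-letter codes (c, m, l, g, r, x, n; s = extracellular). Each
reaction may carry a boolean gene–protein–reaction (GPR) rule — `AND`
joins subunits of one complex, `OR` joins isozymes — and a subsystem
(pathway) label. Linear programs are solved with HiGHS
(`scipy.optimize.linprog`); infinite bounds are capped at ±1000 before
solving.

### Dead-end pruning

A dead-end metabolite appears only as substrate or only as product
across the network (reversible reactions count both sides; exchange
reactions count as both producer and consumer, since the boundary can
absorb or supply). Pruning removes every reaction touching a dead end
and iterates to a fixed point, because removing a reaction can orphan
further metabolites. Detection is purely topological — deterministic and
fast — rather than LP-based flux-consistency testing; on the toy
fixtures the two coincide (tested). Pruning refuses to remove the
biomass or objective reaction.

### Metabolic task checking

A task asks whether the network can produce required extracellular
outputs from a stated set of inputs: all exchange uptakes are closed,
the allowed inputs opened to their maxima, and each required output's
exchange maximized by LP. Task lists are user configuration; the package
provides the mechanism only.

## Expression preprocessing

Raw counts are filtered (keep genes with ≥ `min_count` = 5 reads in
≥ `min_fraction` = 25% of samples), then normalized: median-of-ratios
size factors (geometric-mean reference over genes positive in every
sample), division by gene length in kb (counts-per-kilobase), and
log2(x+1). The filter wording is read as *keep genes that reach 5 counts
in at least 25% of samples*; length adjustment is applied after
size-factor division. One caveat worth recording: scaling one sample's
counts by *c* moves the geometric-mean reference by c^(1/m), so
median-of-ratios normalization is invariant only up to a single global
factor — the tests check that exact form.

## E-Flux personalization

For each sample (or a group's per-gene mean), every reaction's GPR is
evaluated on the normalized expression: `AND` = min of the children (a
complex is limited by its scarcest subunit), `OR` = sum (isozymes add
capacity). Genes missing from the data are dropped from their parent
node rather than zeroed, so annotation gaps never block reactions; a
rule whose genes are all missing leaves the reaction unconstrained.
Activities are divided by the sample's **maximum activity over
GPR-bearing, non-exchange reactions** — a per-sample normalization, so
cohort composition does not couple individuals — giving scale factors in
[0, 1] that multiply both bounds (reversible reactions shrink
symmetrically). Exchange reactions have no enzyme and are exempt; media
alone governs them: uptake bounds are −`default_uptake` (10) for media
metabolites and 0 otherwise, secretion untouched.

Context extraction runs this machinery on the healthy group mean,
removes reactions with zero activity, prunes dead ends, and then
**restores the template bounds** — the context model fixes the
structure, while personalization re-scales bounds per individual.

## Simulation and differential flux

The objective is a mitochondrial ATP demand; biomass is a viability
floor. The healthy group-average model's biomass optimum is the shared
reference; every individual's biomass flux is constrained to
≥ `biomass_fraction` (β = 0.8) of it. During FVA the objective is held
at `objective_fraction` (γ, default 1.0 — the COBRA convention) of the
individual's own optimum, and each reaction's minimum and maximum flux
is found by LP. Individuals whose constrained model is infeasible are
excluded and logged; a fully infeasible group aborts the run.

Per reaction, Welch's unequal-variance t-test compares the groups'
minimum fluxes and, separately, their maximum fluxes (groups are taken
in alphabetical label order, so t compares disease − healthy).
Benjamini–Hochberg correction is applied within the min family and the
max family separately, and a reaction is **perturbed** when either
adjusted p-value is below `alpha` = 0.1. Welch is used because "two
sample t-test" underdetermines the variance assumption and unequal
variances are the safer default; separate BH families with a union call
is likewise one of two defensible readings — both choices are single
switches in `diffflux.py`. Zero-variance degenerate cases use the
conventions t=0, p=1 (equal means) and p=0 (different means) to keep
cohort runs total.

## Enrichment and the metabolite network

Reaction sets are built from the context model: pathway sets from
subsystem labels, metabolite sets from stoichiometric participation
(substrate or product; reported both per compartmentalized id and
collapsed to the compartment-free "unique" id), compartment sets from
single-compartment reactions. Each set is scored two ways: the coverage
score `100·k/K` (percentage of the set that is perturbed) and the exact
one-sided hypergeometric tail `P(X ≥ k)` with universe N = all
annotated reactions of the context model, with BH correction within
each set kind. Currency metabolites are *not* excluded from enrichment
(cofactors can be genuinely informative there); they are excluded only
from the network below. The compartment summary reports raw counts and
percentages adjusted by compartment size, excluding transport reactions
from numerator and denominator.

The metabolite-centric network takes each perturbed internal reaction
(transport and exchange skipped), drops currency metabolites
(configurable list: H2O, H+, ATP, ADP, AMP, Pi, PPi, NAD(H), NADP(H),
FAD(H2), CoA, CO2, O2), and connects every remaining substrate–product
pair of unique metabolites with an undirected edge. Nodes whose
metabolite-enrichment q exceeds `network_q` = 0.05 are removed, and
connected components are reported sorted by size then lexicographically
smallest member. All substrate–product pairs are linked (not just "main"
pairs): after currency removal the toy reactions are essentially
one-substrate-one-product, so the choice is inert here.

## Marker selection

Candidate markers are exchange reactions whose flux range in the disease
group-average model is shifted against the healthy one: interval Jaccard
similarity `|intersection| / |union| < 1 − δ` with δ = 0.1 (point
intervals compared by endpoint distance). This is an explicit
interpretation of a "shifted flux range" and is the one assumption most
worth revisiting on real data.

Each candidate contributes two features — its per-individual FVA minimum
and maximum flux. The classifier is an SVM with polynomial kernel of
degree 2 (C = 1, coef0 = 1, per-fold z-score standardization fit on
training folds only), evaluated by stratified 10-fold cross-validation;
per repeat, test predictions are pooled into one confusion matrix and
accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP) with disease as the positive class (undefined ratios are
NaN, never 0).

The wrapper is a binary GA: chromosome length = feature count,
population 300, at most 100 generations, tournament selection (size 2),
uniform crossover (rate 0.8), per-bit mutation (rate 1/L), elitism 1,
early stop once the best fitness reaches 0.90. Fitness is the CV
accuracy of the SVM on the encoded subset (resubstitution accuracy would
reward overfitting); the all-zero chromosome scores 0 without touching
the SVM. The GA is repeated (100 by default; 20 in the scaled
experiments) and each feature's selection frequency across repeats is
computed; a reaction scores the maximum of its two features, and
reactions at ≥ 80% frequency form the top-ranked panel. Validation
evaluates the panel's features on an external cohort, optionally after
excluding a tagged confounder subgroup.

## The synthetic data generator

The generator defines the study conditions; its defaults are the
conditions the experiments run under.

**Models.** Two deterministic templates. `mini` (16 reactions, 3
compartments) routes glucose/alanine/pyruvate through glycolysis and
oxidative phosphorylation to a mitochondrial ATP demand and a biomass
drain — used for fast nulls and unit fixtures. `core` (100 reactions, 6
compartments, 61 genes) adds eight labeled pathways, each a
substrate-uptake → three conversion steps (two parallel isoform
reactions per step, each with its own gene; the first step carries an
AND complex) → exporter (own gene) → product exchange, homed in cytosol,
Golgi, lysosome, ER or mitochondria. Two structural choices matter and
are deliberate:

- the oxidative-phosphorylation rule is an OR-sum of three highly
  expressed subunits, so the per-sample E-Flux normalization denominator
  is always dominated by backbone genes and never couples null pathways
  to a planted knockdown;
- two parallel isoforms per step give every chain intermediate four
  incident reactions, which is what makes metabolite-level
  hypergeometric enrichment detectable at toy scale (a linear chain
  leaves each metabolite in only two reactions — hopeless after BH).
- each end product has a free overflow sink, so the product exchange
  flux is governed by the exporter gene alone; that makes the exporter a
  clean single-feature marker site for the selection experiments.

**Cohorts.** Counts are negative binomial with Var = μ + αμ²,
dispersion α = 0.1, gene means log-uniform on (50, 2000), gene lengths
uniform on 500–3000 bp; backbone genes draw from the top decile of the
mean range; 65 filler genes pad the matrix to realistic width and 10
"low" genes (mean 0.5) are planted below the count filter. Default group
sizes are 20+20. The disease effect multiplies the means of all genes of
the chosen pathways by `effect_size` (default 0.5; 1.0 gives an
exchangeable null) — the effect is planted at the *gene* level, so the
E-Flux → FVA → statistics chain is what must transduce it into flux
space. Note the transduction is logarithmic: a 0.5× count knockdown
lowers log2 activity by ~1 unit (~12% of a typical capacity), not by
half — recovering it is a genuine signal-to-noise test, not an identity.
An optional `separating_exchange` drives that pathway's exporter gene to
a strong (0.1×), low-noise (dispersion/20) knockdown, producing one
cleanly separating feature. External cohorts redraw everything from a
shifted seed; `shift_labels` relabels that fraction of disease-like
samples as healthy under a "confounder" subgroup tag.

**What the generator does not emulate:** genome-scale size (~8000
reactions), realistic GPR depth, correlated gene expression, library-size
variation between samples, batch effects, or any real muscle biology.
Passing tests therefore show that the pipeline transduces gene-level
effects into calibrated flux-level calls under NB noise at toy scale —
not that it reproduces any particular clinical result.

## Model file formats

SBML Level 3 with the fbc package is the interchange format (bounds as
fbc parameters, GPRs as gene-product associations, the model objective
as the active fbc objective and the biomass reaction as a second
objective named `biomass_obj`, subsystems in reaction notes). The JSON
dialect is a direct transcription of the in-memory model:

```json
{
  "id": "...", "compartments": {"c": "cytosol", ...},
  "biomass_id": "BIOMASS", "objective_id": "ATPM",
  "metabolites": [{"id": "glc_c", "name": "", "compartment": "c"}, ...],
  "reactions": [{"id": "GLYC",
                 "stoichiometry": {"glc_c": -1.0, "pyr_c": 2.0},
                 "lower_bound": 0.0, "upper_bound": 20.0,
                 "gene_reaction_rule": "g1 and g2",
                 "subsystem": "glycolysis", "kind": "internal"}, ...]
}
```

Round-tripping either format reproduces stoichiometry, bounds, GPR
strings and subsystems exactly (tested bit-for-bit via the dict form).

## Numerical choices

LP tolerance 1e-9; FVA clips solver jitter back into declared bounds and
treats `ub − lb ≤ tol` as a fixed reaction without solving. Interval
comparisons use absolute tolerance 1e-6. The vertex-enumeration oracle
used in tests is exact on bounded polytopes with ≤ 10 reactions;
cobrapy+GLPK serves as an independent second route for FBA/FVA. All
stochastic stages (cohort generation, CV fold assignment, GA) take
explicit integer seeds and are reproducible bit-for-bit; cohort FVA
results are independent of iteration order.

## Experiment sizes

The committed experiments use: planted recovery on `core` with 20+20
samples and effect 0.5; null control on `mini` with 8+8 samples over 200
repeats (tests) or 50 repeats (acceptance script); marker selection with
20 GA repetitions (scaled from the default 100) and 5× repeated 10-fold
CV for validation. These sizes were chosen to keep the full study
reproducible on a single CPU in minutes while leaving every statistical
margin wide (the planted effects sit 4–7 noise SDs from the null).

## Known limitations

- The shift rule (interval Jaccard, δ = 0.1) and the GA fitness choice
  (CV rather than resubstitution accuracy) are interpretations; both are
  exposed as parameters.
- Frequency ranking after an early-stopping GA concentrates on a planted
  marker only when exactly one feature can reach the stop threshold;
  with several redundant separating features the frequency mass splits
  between them. Real cohorts (weaker, correlated signals) push the GA
  past generation 1, where selection pressure matters more.
- BH control is proven under positive dependence; FVA min/max fluxes of
  coupled reactions are strongly dependent. The null experiment checks
  the realized false-discovery proportion empirically instead of relying
  on the theorem.
- Topological dead-end pruning does not remove flux-blocked-but-
  topologically-balanced cycles; an FVA-based consistency pass would,
  at LP cost.
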