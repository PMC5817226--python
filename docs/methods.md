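# Methods

This note documents the models, defaults, numerical choices and limitations
of `evodesign`. It is the reference for anyone auditing what the package
computes and why the design is the way it is.

## Design space and encoding

A factor is a physical quantity with a working range `[min, max]` and a
gene length `b` (default 5). Levels are evenly spaced:
`level(k) = min + k·(max − min)/(2^b − 1)`, `k = 0 … 2^b − 1`, so the grid
always contains both endpoints and decoding is affine in the gene's integer
value. Encoding a physical value picks the nearest level; exact midpoints
round toward the lower index so the mapping is deterministic.

Plain base-2 gene encoding is the default. Gray encoding is available
(`gray_code: true` in the configuration) and is recommended whenever
single-bit mutation is the dominant exploration operator on a coarse grid:
under plain binary, adjacent levels can differ in up to `b` bits (e.g.
`011 → 100`), which stalls bit-flip hill climbing at these "Hamming
cliffs"; under Gray, adjacent levels always differ by exactly one bit.

Chromosomes concatenate genes in declared factor order; the order is stored
in the state file so sessions are order-stable. Levels decode to continuous
reals; no rounding to "nice" lab values is applied (the experimenter rounds
when pipetting). Categorical factors and non-uniform (e.g. logarithmic)
level grids are out of scope.

The default population size is `2n − 2` for `n` factors — the upper part of
the `n … 2n` band conventionally recommended for GA populations (nine
factors → 16 individuals). It can be overridden in the configuration.

## Fitness

Raw replicate measurements are aggregated per (condition, objective) as the
median of the replicates; a single missing replicate is first replaced by
the arithmetic mean of the remaining ones. Two or more missing replicates
in one cell are a hard data error — the repair rule is only defined for a
single gap, and silently imputing more would fabricate data.

The fitness of a condition is the weighted sum of min-max-normalised
objective terms, with extremes taken **within the current generation only**;
minimised objectives contribute `1 − normalised`. Weights are normalised to
sum to one at load time, so scores always lie in [0, 1]. Per-generation
normalisation makes scores comparable only within a generation — this is
deliberate: the GA only ever compares contemporaries, and it keeps the
method usable when absolute assay calibration drifts between rounds.

If an objective is constant within a generation (max = min), its term is
set to 0.5 for every individual and a warning is logged: an uninformative
objective neither rewards nor punishes anyone.

## Selection, variation, turnover

"Selection probability 0.5" is implemented as a composite of truncation and
roulette: the better-scoring `selection_fraction` (default 0.5) of the
population forms the mating pool (ties broken by chromosome id, so replays
are stable), and within the pool each parent is drawn with probability
proportional to its score. If every pool score is zero the draw is uniform;
if the truncated pool would have fewer than two members it is expanded to
the top two with a warning. The two parents of a pair must be distinct
individuals; the second is redrawn, with a uniform fallback when only one
pool member carries any roulette weight.

Crossover is single-point: with the pair-level rate (default 0.9) a cut is
drawn uniformly from the `L − 1` internal boundaries and suffixes are
exchanged; children are always fresh copies. Mutation flips exactly one
uniformly chosen bit with the per-chromosome rate. The library default
mutation rate is 0.01; medium-optimisation campaigns typically run at 0.1,
and small toy problems benefit from considerably higher rates (see the
recovery study below). Generational replacement is total by default — no
elitism — matching the interactive workflow where every proposed condition
is a new experiment; optional elitism (`elitism: k`) copies the best k
unchanged. Duplicate chromosomes within a generation are permitted:
forbidding them would bias small populations.

All randomness derives from one session seed; each generation's operations
use a seed deterministically derived from (session seed, generation index),
recorded in the state, so a session replays bit-identically.

## Convergence diagnostics

* **Trajectories**: per generation, the mean score of all individuals, the
  mean of the better-performing fraction (default top half, membership by
  total score), and the best individual.
* **Improvement test**: one-sided Welch t-test that the better fraction of
  the next generation outscores that of the previous one. Welch is a
  pragmatic choice (the underlying score distributions are unknown and
  heteroscedastic); swap in a rank test if normality is a concern. When both
  groups have zero variance the statistic is undefined: equal means report
  p = 1.0 (with a warning), otherwise the continuity limit 0/1 by the sign
  of the shift. Termination is advisory — the tool reports p-values
  (practice: continue while p < 0.05, consider stopping once p > 0.1) and
  the experimenter decides.
* **RSD**: sample standard deviation (n − 1) divided by the mean. Its
  decline in the better fraction signals contraction onto an optimal
  sub-space. Note that it should be computed on *raw* aggregated responses
  (e.g. enzyme activities), not on the per-generation normalised scores:
  min-max renormalisation each round erases exactly the scale information
  whose shrinkage the RSD is meant to show.
* **Profiling / footprint**: absolute level-occupancy counts per factor and
  generation (sparse by default — only levels that occurred), and the
  percent occupancy within the better half of the final generation, from
  which optimal levels are read off.

## Multigene symbolic regression

A model is `ŷ = b₀ + Σ b_g · tree_g(x)` with up to `max_genes` (default 5)
expression trees over the factors, real constants (uniform in ±5) and the
four basic operations; division is protected — a denominator below 1e-12
returns the numerator, preserving continuity rather than jumping to a
constant, so finite inputs always produce finite predictions. Trees are
depth-capped (default 4 operator levels).

Gene weights are re-fit by ordinary least squares at every evaluation, so
evolution searches structure while coefficients come for free;
rank-deficient designs (duplicate genes) get the minimal-norm solution.
Fitness is training RMSE — no holdout: the surrogate models the campaign's
own dataset, and complexity is controlled by the depth/gene caps rather
than cross-validation. R² is `1 − SS_res/SS_tot` (a constant response
defines R² = 1 if the fit is exact, else 0, with a warning) and adjusted R²
uses `p` = number of genes for SR and `p` = number of factors for the MLR
baseline.

Evolution: ramped half-and-half initialisation (depths 2…max, grow/full
alternating, gene counts uniform 1…max), tournament selection (size 2),
subtree crossover within a random gene, high-level gene swap with
probability 0.2 when both parents carry ≥ 2 genes, subtree mutation, and
operator probabilities 0.85/0.10/0.05 (crossover/mutation/reproduction)
with one elite — typical multigene-GP practice; all exposed in `SRParams`.
Children violating the depth cap fall back to the parent's gene. Default
search size is population 500 × 500 generations; the bundled studies use
smaller budgets (see below). Inputs are *not* standardised: trees see raw
physical units, matching the decoded condition tables, and the least-squares
weighting absorbs scale.

Batches (`fit_batch`, default 10 models) run independently from seeds
spawned off the batch seed and are sorted by training R²; the batch is the
unit the sensitivity analysis consumes.

## Sensitivity analysis

For each (objective batch, factor): predictions at the determined optimum
and with that factor scaled by (1 ± δ) (δ = 0.10); the relative response is
`max(|ŷ₊ − ŷ₀|, |ŷ₋ − ŷ₀|)/|ŷ₀|`. Both shift signs are evaluated and the
larger taken. A factor is a **major contributor** when at least half the
batch's models respond by ≥ 10 % (`batch_rule` options: any / majority /
all; majority is the default because a single overfit model should neither
grant nor veto a flag). Near-zero baseline predictions yield an infinite
sentinel with a warning instead of a division error. Objective direction
plays no role — the raw model output is perturbed identically for minimised
objectives. Factors physically absent from a phase (e.g. inducer carbon
sources before induction) are excluded per objective and reported "n/a".

This is a local, one-at-a-time analysis around the optimum; variance-based
global indices (Sobol) are out of scope.

## The synthetic oracle

The oracle emulates a small-culture optimisation study for
methanol-inducible recombinant-protein production in yeast: nine factors
(eight medium components, g/l, plus pH) and four objectives — pre-induction
biomass `od_pre` (maximise), induction-phase biomass gain `od_gain`
(minimise), secreted enzyme activity (maximise) and specific productivity =
activity per unit harvest biomass (maximise), equally weighted.

Noiseless surfaces combine Monod saturation `x/(K + x)`, Gaussian bells
`exp(−(x − μ)²/2σ²)` and a ratio interaction:

* `od_pre = 2 + 16·sat(glycerol, 6)·sat(ammonium, 1.5)·bell(pH; 4.8, 1.2)`
  — growth saturates in carbon and nitrogen with a mildly acidic optimum.
* `od_gain = 0.4 + 0.12·glycerol + 0.05·sorbitol + 0.8·sat(methanol, 3)`
  — leftover carbon feeds unwanted post-induction growth.
* `enzyme_activity = 5 + 0.04·od_pre·glycerol²·bell(pH; 6.5, 0.9)·(0.75 +
  0.25·sat(methanol, 2))` — secreted activity scales with biomass and
  superlinearly with the carbon budget and needs near-neutral pH for
  stability.
* `specific_productivity = enzyme_activity / (od_pre + od_gain)`.

Potassium, magnesium and iron are null everywhere. Because growth and
product formation pull pH and glycerol in opposite directions, the
composite optimum sits on the *flanks* of the individual responses, not at
every objective's interior peak. This is deliberate, and it is what makes
the sensitivity pattern identifiable: a surrogate fitted to campaign data
reproduces a strong local slope far more reliably than pure curvature at an
interior stationary point, so ±10 % shifts at the optimum move the driving
objectives well above the 10 % flag threshold while null factors stay at
zero.

The measurement layer is multiplicative mean-one lognormal noise with CV
0.1 (biological measurements are positive and CV-stable; additive Gaussian
is available), 3 replicates, and per-cell missing values at probability
0.02 with the guarantee that at most one replicate per (condition,
objective) is ever blanked — every emitted file is repairable by the
single-missing-value rule and ingests cleanly.

Ground truth: per-objective extremes and the composite grid optimum are
found by exhaustive enumeration when the representable grid has ≤ 65 536
points (the two-factor oracle), and otherwise by deterministic multi-start
coordinate ascent over the level grid (fixed internal seed, centre +
5 random restarts, 50-sweep cap). Coordinate ascent is exact for the
separable product surfaces and is validated against enumeration on the
small grids; for the ratio objective it is a heuristic whose result is
checked to be a coordinate-wise local maximum.

What the oracle does *not* emulate: batch effects between generations,
heteroscedasticity beyond constant CV, assay detection limits and
censoring, time-course dynamics, or mechanistic fermentation behaviour.
Passing the recovery tests therefore demonstrates the machinery is sound on
data with the stated statistical structure — not that any particular wet
campaign will converge in a given number of rounds.

## Study sizes used by the bundled tests

Chosen so the whole suite runs in minutes on one core:

* GA-vs-brute-force: two factors × 3 bits (64-cell grid, fully enumerated),
  N = 6, 10 generations, 20 seeds, success = reaching a top-5 % grid cell.
  This study uses Gray encoding and a per-chromosome mutation rate of 0.3:
  on a 6-bit toy with a 6-individual population, single-bit mutation is the
  only effective exploration operator, and the binary encoding's Hamming
  cliffs sit directly between the near-optimal levels. (With the
  campaign-scale settings — binary, mutation 0.1 — the same search plateaus
  near, but not inside, the top 5 %.)
* Convergence diagnostics: nine-factor oracle at 3 bits, N = 16,
  8 generations, 20 seeds; RSD computed on raw better-half enzyme
  activities; modal-level recovery within 2 level-steps for pH and
  glycerol.
* Selection-pressure check: mean population score non-decreasing across
  adjacent generations, N = 16 at the default mutation 0.01 — the regime
  the property describes; at high mutation rates or deep into a converged
  plateau, mutation noise dominates the mean and the monotone fraction
  drops.
* SR recovery: `y = 3x₁ + 2x₁x₂ − x₃` on 64 rows, population 200 ×
  100 generations, best of 10 seeds.
* SR vs MLR: `y = x₁x₂` on a symmetric 8 × 8 grid (MLR R² = 0 by
  construction), batch 3 × population 100 × 30 generations, 10 repetitions.
* Sensitivity end-to-end: 4 GA generations of data (64 conditions), batch
  5 × population 120 × 40 generations per objective, 20 seeds.

## Known limitations

* The GA gives no global-optimality guarantee; results should be judged by
  the improvement achieved, and the found optimum can depend on the initial
  random population.
* Per-generation score normalisation means fitness values are not
  comparable across generations; cross-generation comparisons must use raw
  responses.
* The surrogate models are trained on search-biased data (the GA
  concentrates sampling near the optimum); their global R² overstates
  accuracy far from the sampled region, and the sensitivity analysis is
  only meaningful near the optimum.
* Protected division creates flat spots in model predictions near zero
  denominators; simplified expressions render it as plain division.
* Expression simplification (`GPModel.expression`) is cosmetic; the
  authoritative model is the tree + weights stored in the model JSON.
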