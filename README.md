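# evodesign

Genetic-algorithm experimental design for multi-factor, multi-objective
optimisation campaigns — with multigene symbolic-regression surrogates and
perturbation sensitivity analysis to explain what the search found.

## The problem

Optimising culture conditions for an engineered biological system (medium
composition, pH, inducer levels, ...) is a multiparametric problem: with nine
factors at 32 levels each, a full factorial design would require 32⁹ ≈ 3.5 ×
10¹³ experiments. `evodesign` instead runs a **human-in-the-loop genetic
algorithm**: each *generation* is a small batch of conditions (16 for nine
factors) that the lab actually tests; measured responses are scored by a
weighted multi-objective fitness; selection, crossover and mutation on the
bit-encoded conditions breed the next batch. After a handful of generations
the search contracts onto the optimal sub-space, and the accumulated data are
mined with symbolic regression to rank the factors driving each objective.

Typical users: experimental biologists and bioprocess engineers optimising
recombinant-protein production, fermentation media, or any bench protocol
with many interacting knobs and a few competing objectives.

## The method

**Encoding.** Each factor spans `[min, max]` on `2^b` evenly spaced levels
(`b` = 5 bits by default); a condition is the concatenation of one `b`-bit
gene per factor (nine 5-bit factors → 45-bit chromosomes).

**Fitness.** For generation *i* with measured responses *x_j* per objective
*j* (replicate medians; a single missing replicate is replaced by the mean
of the remaining ones):

    score = Σ_j w_j · t_j
    t_j = (x_j − min_i x_j) / (max_i x_j − min_i x_j)        (maximise)
    t_j = 1 − (x_j − min_i x_j) / (max_i x_j − min_i x_j)    (minimise)

with extremes taken over the current generation, so scores lie in [0, 1]
when Σ w_j = 1.

**Turnover.** The better-scoring half of the population forms the mating
pool; parents are drawn by roulette wheel (probability ∝ score); pairs
recombine by single-point crossover (rate 0.9) and offspring mutate by a
single uniformly chosen bit flip (per-chromosome rate, 0.01 default).

**Diagnostics.** Score trajectories (population mean, better-half mean,
best individual), a one-sided Welch t-test between the better halves of
adjacent generations (keep going while p < 0.05, consider stopping once
p > 0.1), the relative standard deviation (SD/mean) of the better half as
a search-contraction readout, and per-factor *population profiles* and
*occupancy footprints* from which the optimal levels are read off.

**Surrogate modelling.** Each objective is modelled as
`ŷ = b₀ + Σ_g b_g · tree_g(x)` — a multigene genetic program over
{+, −, ×, ÷ (protected)} whose gene weights are re-fit by ordinary least
squares at every fitness evaluation; batches of independently seeded models
are compared against a multiple-linear-regression baseline by R² and
adjusted R².

**Sensitivity.** Every factor is shifted ±10 % from the determined optimum
through the model batch; a factor is a *major contributor* to an objective
when at least half the models respond by ≥ 10 %.

A built-in synthetic oracle (nine factors, four objectives, triplicates
with lognormal noise and occasional missing values, known optimum) stands
in for the wet lab so the whole pipeline is testable offline.

## Worked example

`examples/02_simulated_campaign.py` runs five simulated generations of 16
conditions against the built-in oracle:

```
score trajectories (weighted multi-objective fitness, 0..1):
 generation  mean_all  mean_better_fraction  best
          1     0.282                 0.382 0.608
          2     0.415                 0.511 0.603
          3     0.494                 0.594 0.648
          4     0.609                 0.675 0.752
          5     0.478                 0.562 0.656

one-sided Welch p-value for improvement of the better half:
  generation 1 -> 2: p = 0.011  (clear improvement)
  generation 2 -> 3: p = 0.009  (clear improvement)
  generation 3 -> 4: p = 0.001  (clear improvement)
  generation 4 -> 5: p = 1.000
```

The mean fitness climbs for three rounds and then plateaus — the signal to
stop experimenting.  `examples/03_profiling_and_footprint.py` then shows the
population piling onto single glycerol/pH levels,
`examples/04_symbolic_regression.py` fits surrogate models (best SR R² 0.979
vs MLR 0.861 for enzyme activity), and `examples/05_sensitivity.py` flags
exactly the factors the oracle truly uses:

```
median model response to a +/-10% shift (enzyme activity):
  glycerol    0.209  <- major contributor
  ph          0.166  <- major contributor
  potassium   0.000
  ...
```

The same workflow is available from the shell for real campaigns:

```sh
evodesign --state run.json init --config design.yaml
evodesign --state run.json propose --out batch1.csv     # -> to the lab
evodesign --state run.json ingest --results batch1_results.csv
evodesign --state run.json step                         # breeds the next batch
evodesign --state run.json footprint                    # read off the optimum
evodesign --state run.json fit-sr --objective enzyme_activity --out models.json
evodesign sensitivity --models models.json --optimum optimum.csv
```

Configuration is a YAML file (factors with ranges/bits/units, objectives
with direction/weight, GA parameters, seed); it is locked after `init`, all
state lives in a versioned JSON file, ingest is atomic, and a session
replays bit-identically from its seed and input files.

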