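"""Run a simulated optimisation campaign against the built-in oracle.

The oracle stands in for the wet lab: it returns noisy triplicate
measurements (with occasional missing values) for any proposed set of
conditions.  Five GA generations of 16 conditions are run; the score
trajectories and the Welch improvement p-values show how the search
converges.
"""

from evodesign import case_study_oracle, run_ga, score_trajectories
from evodesign.diagnostics import better_fraction_scores, improvement_test

oracle = case_study_oracle(bits=3, seed=0)
history = run_ga(oracle, generations=5, seed=0)

print("score trajectories (weighted multi-objective fitness, 0..1):")
print(score_trajectories(history).to_string(index=False, float_format="%.3f"))
print()
print("one-sided Welch p-value for improvement of the better half:")
for prev, nxt in zip(history, history[1:]):
    p = improvement_test(
        better_fraction_scores(prev), better_fraction_scores(nxt)
    )
    print(
        f"  generation {prev.generation_index} -> {nxt.generation_index}: "
        f"p = {p:.3f}"
        + ("  (clear improvement)" if p < 0.05 else "")
    )
print()
print("practice: keep iterating while p < 0.05; consider stopping once p > 0.1")
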