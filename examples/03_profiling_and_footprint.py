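"""Read the optimum off a finished campaign by population profiling.

Profiling counts how often each encoded level of each factor appears per
generation: convergence shows up as the counts piling onto few levels.  The
occupancy footprint then gives, for the better-performing half of the final
generation, the percent share of each level — the basis for picking the
optimal setting of every factor.
"""

from evodesign import (
    case_study_oracle,
    occupancy_footprint,
    population_profile,
    run_ga,
)

oracle = case_study_oracle(bits=3, seed=0)
history = run_ga(oracle, generations=8, seed=0)

profile = population_profile(history, oracle.space)
print("glycerol level occupancy by generation (absolute frequency):")
gly = profile[profile.factor == "glycerol"].pivot_table(
    index="level_value", columns="generation", values="frequency", fill_value=0
)
print(gly.to_string(float_format="%.0f"))
print()

footprint = occupancy_footprint(history[-1], oracle.space, fraction=0.5)
print("occupancy footprint of the better half, final generation:")
for factor in ("glycerol", "ph"):
    rows = footprint[footprint.factor == factor]
    desc = ", ".join(
        f"{r.level_value:.2f} ({r.percent:.0f}%)" for r in rows.itertuples()
    )
    print(f"  {factor}: {desc}")

opt_cond, _ = oracle.true_optimum()
print()
print(
    "oracle ground truth: glycerol "
    f"{opt_cond['glycerol']:.2f} g/l, pH {opt_cond['ph']:.2f} "
    "-- the footprint mass should sit on/near these levels"
)
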