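"""Configure a design space and inspect its encoding arithmetic.

Nine cultivation factors on 5 bits each give 45-bit chromosomes addressing
a 32^9 grid — the combinatorial space a full factorial design would have to
test, and the reason a genetic algorithm is used instead.
"""

from evodesign import DesignSpace, FactorSpec, ObjectiveSpec, population_size_rule

factors = [
    FactorSpec("ammonium", 0.0, 10.0, bits=5, units="g/l"),
    FactorSpec("potassium", 0.0, 10.0, bits=5, units="g/l"),
    FactorSpec("magnesium", 0.0, 10.0, bits=5, units="g/l"),
    FactorSpec("iron", 0.0, 1.0, bits=5, units="g/l"),
    FactorSpec("calcium", 0.0, 5.0, bits=5, units="g/l"),
    FactorSpec("glycerol", 0.0, 20.0, bits=5, units="g/l"),
    FactorSpec("methanol", 0.0, 15.0, bits=5, units="g/l"),
    FactorSpec("sorbitol", 0.0, 30.0, bits=5, units="g/l"),
    FactorSpec("ph", 2.6, 7.0, bits=5, units="pH"),
]
objectives = [
    ObjectiveSpec("od_pre", "maximize", 0.25),
    ObjectiveSpec("od_gain", "minimize", 0.25),
    ObjectiveSpec("enzyme_activity", "maximize", 0.25),
    ObjectiveSpec("specific_productivity", "maximize", 0.25),
]
space = DesignSpace(factors, objectives)

print(f"factors:                  {len(space.factors)}")
print(f"chromosome length:        {space.chromosome_length} bits")
print(f"levels per factor:        {space.factors[0].n_levels}")
print(f"population size (2n-2):   {population_size_rule(len(space.factors))}")
print(f"full-factorial equivalent: {space.grid_size:.3g} combinations")
print()
print("pH grid: each 5-bit gene indexes one of 32 evenly spaced levels")
ph = space.factor("ph")
for k in (0, 1, 29, 31):
    print(f"  level {k:2d} -> pH {ph.level_value(k):.3f}")
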