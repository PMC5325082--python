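"""Double-mutant cycle energetics from four EC50 values.

The cycle compares wild type, the two single mutants (loop-D W55T and
loop-E R117M on the complementary face) and the double mutant.  A coupling
coefficient Omega far from 1 means the two positions do not act additively.
"""

from pentasite import EnergyParams, MutantCycleInput, coupling, format_cycle_report

# Published EC50s for the rat alpha9alpha10 W55T/R117M cycle, molar
cycle = MutantCycleInput(wr=18e-6, wm=31e-6, tr=36e-6, tm=768e-6)
result = coupling(cycle, EnergyParams(temperature=294.0))

print(format_cycle_report(result))
print()
print("Omega = 12.4 means the double mutant shifts the concentration-response")
print("curve ~12x further than the two single mutations predict additively;")
print("the -1.47 kcal/mol coupling energy quantifies that interaction.")
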