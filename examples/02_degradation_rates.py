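"""Degradation rates and fold-decreases from qPCR endpoint concentrations.

Uses the enzyme-supplementation endpoint table (500 ng/mL of genomic
HMW DNA incubated 2 h / 8 h in serum, with or without NE and MPO) and
attributes degradation with the subtraction scheme: nuclease activity =
serum minus EDTA plasma; enzyme activity = supplemented serum minus
control serum.
"""

from fragkin.kinetics import (
    TimeCourse,
    degradation_rate,
    enzyme_rate,
    fold_decrease,
    nuclease_rate,
    percent_degraded,
)

courses = {
    name: TimeCourse(name, times, concs)
    for name, times, concs in [
        ("serum", [0, 120, 480], [500.0, 207.0, 124.0]),
        ("serum+NE", [0, 120, 480], [500.0, 64.0, 23.0]),
        ("serum+MPO", [0, 120, 480], [500.0, 35.0, 16.0]),
        ("serum+NE+MPO", [0, 480], [500.0, 5.0]),
        ("plasma_EDTA", [0, 120, 480], [500.0, 475.0, 425.0]),
    ]
}

serum = courses["serum"]
print("fold decrease vs control serum at 8 h:")
for cond in ("serum+NE", "serum+MPO", "serum+NE+MPO"):
    fold = fold_decrease(serum.at(480), courses[cond].at(480), rounding="auto")
    print(f"  {cond.removeprefix('serum+'):8s} {fold:g}-fold")

print(f"NE at 2 h: {fold_decrease(serum.at(120), courses['serum+NE'].at(120), 'integer'):g}-fold")
print(f"NE+MPO degraded {percent_degraded(500.0, courses['serum+NE+MPO'].at(480)):.0f}% of input at 8 h")

r_overall = degradation_rate(serum, 0, 120)
r_nuclease = nuclease_rate(serum, courses["plasma_EDTA"], (0, 120))
r_ne = enzyme_rate(courses["serum+NE"], serum, (0, 120), attribution="NE")
print(f"overall serum rate (0-2 h):   {r_overall.rate:.2f} ng/mL/min")
print(f"nuclease-attributed rate:     {r_nuclease.rate:.2f} ng/mL/min")
print(f"NE-attributed extra rate:     {r_ne.rate:.2f} ng/mL/min")
# Rates are bulk concentration losses (ng DNA/mL/min), not enzyme
# activities; NE and MPO accelerate degradation beyond serum nucleases.
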