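"""Regimen-level decision outputs: probability table, target attainment,
dose-reduction effect, and the bleeding-management decision table.

The univariable GI-bleeding model is calibrated through the two Q3W cells
of the published probability table, then evaluated at the typical-value
exposures of the four regimens; trough-target attainment uses the full
population model with between-subject variability.
"""

import pandas as pd

from bleedrisk import (
    BleedingEvent,
    calibrate_univariable,
    dose_reduction_effect,
    management_action,
    regimen_probability_table,
    simulate_population,
    standard_regimens,
    target_attainment_table,
)
from bleedrisk.config import default_config, poppk_model_from_config
from bleedrisk.dose_eval import reference_patients
from bleedrisk.regimens import q3w

pk = poppk_model_from_config(default_config())
model = calibrate_univariable((136.0, 0.126), (273.0, 0.222))

table = regimen_probability_table(model, standard_regimens(), pk, n_sim=0)
print("predicted probability of any-grade GI bleeding:")
print(table[["regimen", "geomean_cavg_sd", "probability"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

effect = dose_reduction_effect(model, q3w(2400.0), q3w(1200.0), pk)
print(f"\n50% dose reduction 2400 -> 1200 mg Q3W: probability "
      f"{effect['p_from']:.3f} -> {effect['p_to']:.3f} "
      f"(absolute -{effect['absolute_reduction']:.3f}, "
      f"relative -{100 * effect['relative_reduction']:.0f}%)")

frames = []
for label, regimen in standard_regimens().items():
    sim = simulate_population(pk, reference_patients(2000, pk), regimen, seed=909)
    sim.insert(0, "regimen", label)
    frames.append(sim)
attainment = target_attainment_table(pd.concat(frames, ignore_index=True))
print("\ntrough-target attainment (% of 2000 simulated patients):")
print(attainment.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

print("\nmanagement actions for example bleeding events:")
for event in (BleedingEvent(2, resolved_to_grade_le1_by_cycle_end=True),
              BleedingEvent(2),
              BleedingEvent(3),
              BleedingEvent(3, tumoral=True)):
    action = management_action(event)
    print(f"  grade {event.grade}, tumoral={event.tumoral}, "
          f"resolved={event.resolved_to_grade_le1_by_cycle_end} -> {action.action}")
print("\nHalving the dose keeps PD-L1 occupancy (>= 11 ug/mL) in ~99-100% of "
      "patients while TGF-beta2 inhibition becomes intermittent -- the "
      "pharmacologic rationale for restarting at 50% dose after a grade 3 bleed.")
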