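"""Cohort-level aggregation of the 19-patient Freiburg benchmark table.

Loads the shipped per-patient results (sensitivity, false prediction
rate, mean prediction horizon and selection distance for the two-step
and one-step firing-power variants) and appends the unweighted means.
"""

from pesp import cohort_averages

table = cohort_averages()
print(table.to_string(float_format=lambda v: f"{v:.3f}"))

avg = table.loc["Avg."]
print(f"\ntwo-step: SS {avg['SS_two']:.1%}, FPR {avg['FPR_two']:.3f}/h, "
      f"SPH {avg['SPH_two']:.2f} min, distance {avg['dist_two']:.2f}")
print(f"one-step: SS {avg['SS_one']:.1%}, FPR {avg['FPR_one']:.3f}/h, "
      f"SPH {avg['SPH_one']:.2f} min, distance {avg['dist_one']:.2f}")
print("\nthe two-step variant halves the distance to the ideal operating point,")
print("mostly by cutting false predictions to below the 0.15/h chance level")
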