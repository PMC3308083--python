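"""Simulate a small two-group cohort and inspect its true T2 structure.

Draws 10 at-risk and 10 control subjects (no imaging), printing group means
of the true medial-femur T2 and the five-compartment average. The at-risk
group should sit ~0.8 ms higher in the medial femur by construction.
"""

from dataclasses import replace

from cartt2 import SimConfig, true_t2_cohort_table

config = replace(SimConfig(), n_incidence=10, n_control=10, seed=42)
table = true_t2_cohort_table(config)

print(table[["subject_id", "group", "age", "sex", "bmi",
             "mean_t2_medial_femur", "mean_t2_all"]].round(2).to_string(index=False))
print()
for group, sub in table.groupby("group"):
    print(f"{group:>9}: MF T2 = {sub.mean_t2_medial_femur.mean():.2f} ms, "
          f"all-compartment = {sub.mean_t2_all.mean():.2f} ms")
print("\nThe at-risk (incidence) group is configured with higher and more "
      "heterogeneous cartilage T2 than controls.")
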