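"""A small discounted-QALE risk table.

Mirrors the layout of standard 10-year risk tables: systolic blood pressure
down the rows, total/HDL cholesterol ratio across the columns, here for
60-year-old male smokers and non-smokers in the most deprived SIMD fifth.
Family history (0.26) and diabetes (0.15) enter as cohort expectations.
"""

from cvdpolicy import RunConfig, make_synthetic_params, risk_table

params, _ = make_synthetic_params(seed=1)
frame = risk_table(
    {"male": params, "female": params},
    RunConfig(horizon=100),
    ages=(60,),
    sexes=("male",),
    simd_fifths=(5,),
    age_anchored=True,
)

for cigs, block in frame.groupby("cigarettes_per_day"):
    label = "smoker (20/day)" if cigs else "non-smoker"
    print(f"\ndiscounted QALE as expected age at death - {label}:")
    table = block.pivot(index="sbp", columns="chol_ratio",
                        values="qale_disc_age_anchored")
    print(table.sort_index(ascending=False).round(1).to_string())
# Higher blood pressure, a worse cholesterol ratio and smoking each shave
# quality-adjusted years; the gradients echo printed risk-table layouts.
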