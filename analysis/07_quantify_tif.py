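"""Absolute quantification of fluid metabolites from external standards.

Standard curves fit over the 5 mM - 1 uM dilution series invert TIF-like
sample responses to concentrations; the cohort was generated at uridine
24.1 uM and uracil 90.2 uM, so the recovered medians show what unweighted
linear calibration delivers at that scale.
"""

import pandas as pd

from _common import RESULTS, RUN_DIR, ensure_campaign

ensure_campaign()

curves = pd.read_csv(RUN_DIR / "curves.csv")
summary = pd.read_csv(RUN_DIR / "fluid_summary.csv")
concs = pd.read_csv(RUN_DIR / "concentrations.csv")
summary.to_csv(RESULTS / "tif_summary.csv", index=False)

for _, c in curves.iterrows():
    print(f"{c['analyte']}: slope = {c['slope']:.3e}, r^2 = {c['r_squared']:.4f}, "
          f"calibrated {c['range_low']:.1f}-{c['range_high']:.0f} uM")
truth = {"uridine": 24.1, "uracil": 90.2}
for _, row in summary.iterrows():
    true = truth[row["analyte"]]
    print(f"TIF {row['analyte']}: median = {row['median']:.1f} uM "
          f"(generated at {true} uM; IQR {row['q1']:.1f}-{row['q3']:.1f}), "
          f"n = {int(row['n'])}, "
          f"{int(concs[concs['analyte'] == row['analyte']]['extrapolated'].sum())} "
          f"below the lowest standard")
print(f"wrote {RESULTS / 'tif_summary.csv'}")
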