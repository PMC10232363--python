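"""Stratify by the nominated gene and compare expression and survival.

Cell lines split at the median of the top correlate's expression feed a
Welch-t differential-expression comparison; the 145-sample synthetic
cohort splits by its score into high/low arms for Kaplan-Meier curves
and the log-rank test.
"""

import pandas as pd

from _common import RESULTS, RUN_DIR, ensure_campaign

ensure_campaign()

de = pd.read_csv(RUN_DIR / "de_results.csv")
lr = pd.read_csv(RUN_DIR / "logrank.csv").iloc[0]
km = pd.read_csv(RUN_DIR / "km_curves.csv")

de.head(15).to_csv(RESULTS / "de_top.csv", index=False)
lr.to_frame().T.to_csv(RESULTS / "logrank.csv", index=False)

top = de.iloc[0]
print(f"differential expression, high vs low (median split): {len(de)} genes")
print(f"top gene: {top['gene']} delta = {top['delta']:+.2f} log2, "
      f"q = {top['q_value']:.2e}")
print(f"survival cohort: {int(lr['n_high'])} high / {int(lr['n_low'])} low, "
      f"{int(lr['events'])} events")
print(f"log-rank chi2 = {lr['chi_square']:.2f}, p = {lr['p_value']:.3g}")
for g, sub in km.groupby("group"):
    print(f"  KM {g}: S at last event time = {sub['survival'].iloc[-1]:.2f}")
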