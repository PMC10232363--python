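"""Call high-confidence metabolites and check plate-level QC.

RMA = per-well maximum height minus the cell line's median blank signal;
a substrate is an HCM when its across-line RMA distribution differs from
pooled blanks (one-tailed Wilcoxon rank-sum in both directions, BH across
substrates at q <= 0.05).
"""

import pandas as pd

from _common import RESULTS, RUN_DIR, ensure_campaign

ensure_campaign()

calls = pd.read_csv(RUN_DIR / "hcm_calls.csv")
qc = pd.read_csv(RUN_DIR / "qc_flags.csv")
calls.to_csv(RESULTS / "hcm_calls.csv", index=False)

n_hcm = int(calls["is_hcm"].sum())
print(f"{n_hcm} HCMs of {len(calls)} substrates "
      f"({(calls['direction'] == 'above').sum()} tested above, "
      f"{(calls['direction'] == 'below').sum()} below)")
print(f"QC-flagged cell lines: {list(qc['cell_line']) or 'none'}")
print(f"wrote {RESULTS / 'hcm_calls.csv'}")
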