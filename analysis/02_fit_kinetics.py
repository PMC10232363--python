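"""How well do the nonparametric curve readouts recover the generating kinetics?

Compares fitted lambda/mu/A per well against the generator's truth table
for responsive wells (A >= 0.2 signal units, where the readouts are
well-defined against the noise floor) and writes the error summary.
"""

import pandas as pd

from _common import RESULTS, RUN_DIR, ensure_campaign

ensure_campaign()

params = pd.read_csv(RUN_DIR / "params.csv")
truth = pd.read_csv(RUN_DIR / "truth.csv")
merged = params.merge(truth, on=["plate_id", "well"], suffixes=("_fit", "_true"))
resp = merged[merged["A_true"] >= 0.2].copy()

resp["A_rel_err"] = (resp["A_fit"] - resp["baseline"] - resp["A_true"]).abs() / resp["A_true"]
resp["mu_rel_err"] = (resp["mu_fit"] - resp["mu_true"]).abs() / resp["mu_true"]
resp["lambda_abs_err_h"] = (resp["lambda_h_fit"] - resp["lambda_h_true"]).abs()

summary = (
    resp[["A_rel_err", "mu_rel_err", "lambda_abs_err_h"]]
    .describe(percentiles=[0.5, 0.9])
    .loc[["mean", "50%", "90%", "max"]]
)
summary.to_csv(RESULTS / "kinetics_recovery.csv")

print(f"{len(resp)} responsive wells of {len(merged)}")
print(f"median |A| relative error:      {resp['A_rel_err'].median():.3%}")
print(f"median |mu| relative error:     {resp['mu_rel_err'].median():.3%}")
print(f"median |lambda| absolute error: {resp['lambda_abs_err_h'].median():.2f} h")
print(f"wrote {RESULTS / 'kinetics_recovery.csv'}")
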