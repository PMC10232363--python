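"""Repeatable simulation experiments at the screen's own scale.

These drivers wire the generators to the analysis stages for the
recurring questions about the pipeline: does the planted metabolite-gene
pair surface from a full-scale screen, is the HCM caller calibrated on
null substrates, and does the survival machinery have the expected power?
They are used by the analysis scripts and the acceptance checks alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .correlation import correlate_screen, specificity_panel
from .kinetics import fit_table
from .screen import call_hcm, normalize_rma
from .stratify import logrank
from .synthetic import SyntheticConfig, simulate_expression, simulate_plates, simulate_survival

SCREEN_SCALE = dict(n_cell_lines=16, n_substrates=180, n_genes=100)


def planted_pair_trial(seed: int, effect: float = 0.85, **overrides) -> dict:
    """One full screen: plates -> kinetics -> RMA -> expression -> correlation.

    Returns the planted pair's global |rho| rank among all substrate x gene
    pairs, its rho, and whether the nucleoside specificity panel assigns
    q <= 0.05 to the planted substrate only.
    """
    params = {**SCREEN_SCALE, **overrides}
    cfg = SyntheticConfig(seed=seed, planted_pairs=(("uridine", "UPP1", effect),), **params)
    platemap, traces, truth = simulate_plates(cfg, return_truth=True)
    rma = normalize_rma(fit_table(traces), platemap)

    from .synthetic import true_rma

    expr = simulate_expression(cfg, true_rma(truth, platemap))
    res = correlate_screen(rma, expr)
    hit = res[(res["substrate"] == "uridine") & (res["gene"] == "UPP1")].iloc[0]

    panel = specificity_panel(rma, expr, "UPP1", list(cfg.substrate_names))
    significant = set(panel.loc[panel["q_value"] <= 0.05, "substrate"])
    return {
        "rank": int(hit["rank"]),
        "rho": float(hit["rho"]),
        "n_pairs": len(res),
        "specificity_only_planted": significant == {"uridine"},
    }


def null_screen(seed: int, n_substrates: int = 500, n_cell_lines: int = 16) -> pd.DataFrame:
    """HCM calls for a screen in which no substrate is utilized.

    Every test well is a blank (inert), so substrate wells and negative
    controls are exchangeable and p-values should be uniform.
    """
    cfg = SyntheticConfig(
        seed=seed,
        n_cell_lines=n_cell_lines,
        n_substrates=n_substrates,
        n_genes=4,
        inert_fraction=1.0,
        substrate_names=(),
        gene_names=(),
        planted_pairs=(),
    )
    platemap, traces = simulate_plates(cfg)
    rma = normalize_rma(fit_table(traces), platemap)
    return call_hcm(rma, fdr=False)


def mixed_screen(seed: int, n_substrates: int = 500, n_cell_lines: int = 16) -> dict:
    """Mixed true/null screen; counts of true and false HCMs under BH.

    ~90% of substrates are inert; the rest respond with screen-typical
    amplitudes.  Ground truth comes from the generator's truth table.
    """
    cfg = SyntheticConfig(
        seed=seed,
        n_cell_lines=n_cell_lines,
        n_substrates=n_substrates,
        n_genes=4,
        inert_fraction=0.9,
        substrate_names=(),
        gene_names=(),
        planted_pairs=(),
    )
    platemap, traces, truth = simulate_plates(cfg, return_truth=True)
    rma = normalize_rma(fit_table(traces), platemap)
    calls = call_hcm(rma, alpha=0.05, fdr=True).set_index("substrate")
    test = platemap[platemap["role"] == "test"].merge(truth, on=["plate_id", "well", "cell_line"])
    truly_active = test.groupby("substrate")["A"].max() > 0
    hcm = calls["is_hcm"]
    return {
        "n_true": int(truly_active.sum()),
        "true_hcms": int((hcm & truly_active.reindex(hcm.index)).sum()),
        "false_hcms": int((hcm & ~truly_active.reindex(hcm.index)).sum()),
    }


def logrank_null_pvalues(n_seeds: int = 500, n_samples: int = 60, base_seed: int = 0) -> np.ndarray:
    """Log-rank p-values under no group effect (hazard_ratio = 1)."""
    out = np.empty(n_seeds)
    for i in range(n_seeds):
        cfg = SyntheticConfig(seed=base_seed + i, hazard_ratio=1.0,
                              n_survival_samples=n_samples)
        rng = np.random.default_rng(base_seed + 900_000 + i)
        scores = pd.Series(rng.standard_normal(n_samples),
                           index=[f"T{j}" for j in range(n_samples)])
        surv = simulate_survival(cfg, scores)
        out[i] = logrank(surv["time"], surv["event"], surv["group"])[1]
    return out


def logrank_power(
    hazard_ratio: float = 3.0, n_per_arm: int = 150, n_seeds: int = 200, base_seed: int = 0
) -> float:
    """Fraction of simulated cohorts with log-rank p < 0.05."""
    hits = 0
    for i in range(n_seeds):
        cfg = SyntheticConfig(seed=base_seed + i, hazard_ratio=hazard_ratio,
                              n_survival_samples=2 * n_per_arm)
        rng = np.random.default_rng(base_seed + 700_000 + i)
        scores = pd.Series(rng.standard_normal(2 * n_per_arm),
                           index=[f"T{j}" for j in range(2 * n_per_arm)])
        surv = simulate_survival(cfg, scores)
        hits += logrank(surv["time"], surv["event"], surv["group"])[1] < 0.05
    return hits / n_seeds
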