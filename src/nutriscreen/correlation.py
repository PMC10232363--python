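"""Metabolite-gene correlation: the discovery engine of the screen.

Every (substrate, gene) pair is scored by the Spearman correlation of the
substrate's RMA against the gene's expression across the shared cell
lines, and pairs are ranked by |rho| so that both positive and negative
correlates surface.  This is the procedure that nominates a transporter
or catabolic enzyme for a utilized nutrient (uridine-UPP1 being the
canonical hit: r = 0.82 over 16 lines).

p-values use the t approximation t = rho * sqrt((n-2)/(1-rho^2)) with
n-2 df by default; exact permutation enumeration is available for n <= 9.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError, UndefinedCorrelationError
from .screen import RMATable, call_hcm

MIN_N = 4
EXACT_MAX_N = 9


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise UndefinedCorrelationError("zero variance in a rank vector")
    return float(np.clip((rx @ ry) / denom, -1.0, 1.0))


def _t_approx_p(rho: float, n: int) -> float:
    denom = max(1.0 - rho * rho, 1e-300)
    t = rho * np.sqrt((n - 2) / denom)
    p = 2.0 * t_dist.sf(abs(t), n - 2)
    return float(max(p, np.finfo(float).tiny))


def spearman(x, y, method: str = "approx") -> tuple[float, float]:
    """Spearman rho (midranks for ties) and two-sided p-value.

    Missing pairs are dropped (pairwise-complete).  ``method="exact"``
    enumerates all n! permutations of one rank vector (n <= 9); at
    rho = ±1 the exact p is the permutation atom 2/n!.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < MIN_N:
        raise DataError(f"need at least {MIN_N} complete pairs, got {n}")
    rx, ry = rankdata(x), rankdata(y)
    rho = _rank_rho(rx, ry)
    if method == "approx":
        return rho, _t_approx_p(rho, n)
    if method == "exact":
        if n > EXACT_MAX_N:
            raise ParameterError(f"exact permutation p limited to n <= {EXACT_MAX_N}")
        target = abs(rho) - 1e-12
        hits = sum(abs(_rank_rho(rx, np.array(perm))) >= target for perm in permutations(ry))
        return rho, hits / factorial(n)
    raise ValueError(f"unknown method {method!r}")


def _rank_zscore_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise midranks, centered and scaled to unit norm; NaN for constant rows."""
    r = rankdata(mat, axis=1).astype(float)
    r -= r.mean(axis=1, keepdims=True)
    norms = np.sqrt((r * r).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norms > 0, r / norms, np.nan)


def correlate_screen(
    rma: RMATable | pd.DataFrame,
    expr: pd.DataFrame,
    genes: list[str] | None = None,
    hcm_only: bool = False,
    hcm_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score all (substrate, gene) pairs and rank them by |rho|.

    With ``hcm_only`` the substrate set is restricted to called HCMs
    (``hcm_calls`` as produced by :func:`nutriscreen.screen.call_hcm`, or
    computed on the fly when a full RMATable is given).  Returns a table
    (substrate, gene, rho, n, p_value, q_value, rank), BH-corrected across
    all tested pairs and sorted by |rho| descending; rank ties are broken
    by (substrate, gene) lexicographic order.
    """
    rma_values = rma.values if isinstance(rma, RMATable) else rma
    if hcm_only:
        if hcm_calls is None:
            if not isinstance(rma, RMATable):
                raise DataError("hcm_only needs hcm_calls or a full RMATable")
            hcm_calls = call_hcm(rma)
        keep = hcm_calls.loc[hcm_calls["is_hcm"], "substrate"]
        rma_values = rma_values.loc[rma_values.index.intersection(keep, sort=False)]
        if rma_values.empty:
            raise DataError("no HCM substrates to correlate")

    shared = [c for c in rma_values.columns if c in set(expr.columns)]
    if len(shared) < MIN_N:
        raise DataError(f"need >= {MIN_N} shared samples, got {len(shared)}")
    if genes is not None:
        genes = [g for g in genes if g in set(expr.index)]
        if not genes:
            raise DataError("gene list does not intersect the expression matrix")
        expr = expr.loc[genes]

    sub_mat = rma_values[shared].to_numpy(float)
    gene_mat = expr[shared].to_numpy(float)
    n_shared = len(shared)

    if np.isfinite(sub_mat).all() and np.isfinite(gene_mat).all():
        zs = _rank_zscore_rows(sub_mat)
        zg = _rank_zscore_rows(gene_mat)
        rho = np.clip(zs @ zg.T, -1.0, 1.0)  # substrates x genes; NaN for constant rows
        subs = np.repeat(rma_values.index.to_numpy(), len(expr.index))
        gens = np.tile(expr.index.to_numpy(), len(rma_values.index))
        out = pd.DataFrame(
            {"substrate": subs, "gene": gens, "rho": rho.ravel(), "n": n_shared}
        )
    else:  # pairwise-complete deletion, per pair
        rows = []
        for substrate, xr in zip(rma_values.index, sub_mat):
            for gene, yr in zip(expr.index, gene_mat):
                keep = np.isfinite(xr) & np.isfinite(yr)
                if keep.sum() < MIN_N:
                    rows.append((substrate, gene, np.nan, int(keep.sum())))
                    continue
                try:
                    r, _ = spearman(xr[keep], yr[keep])
                except UndefinedCorrelationError:
                    r = np.nan
                rows.append((substrate, gene, r, int(keep.sum())))
        out = pd.DataFrame(rows, columns=["substrate", "gene", "rho", "n"])

    out = out.dropna(subset=["rho"]).reset_index(drop=True)
    if out.empty:
        raise DataError("no pair had a defined correlation")
    denom = np.maximum(1.0 - out["rho"] ** 2, 1e-300)
    t = out["rho"] * np.sqrt((out["n"] - 2) / denom)
    out["p_value"] = np.maximum(
        2.0 * t_dist.sf(np.abs(t), out["n"] - 2), np.finfo(float).tiny
    )
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values(
        by=["rho", "substrate", "gene"],
        key=lambda s: -s.abs() if s.name == "rho" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def specificity_panel(
    rma: RMATable | pd.DataFrame,
    expr: pd.DataFrame,
    gene: str,
    substrates: list[str],
) -> pd.DataFrame:
    """Correlate one gene against a panel of substrates (e.g. all nucleosides).

    Used to check that a nominated gene correlates with its substrate and
    not with chemically similar bystanders.  BH correction is applied
    within the panel.
    """
    rma_values = rma.values if isinstance(rma, RMATable) else rma
    if gene not in set(expr.index):
        raise DataError(f"gene {gene!r} not in expression matrix")
    if missing := [s for s in substrates if s not in set(rma_values.index)]:
        raise DataError(f"substrates not in RMA table: {missing}")
    shared = [c for c in rma_values.columns if c in set(expr.columns)]
    if len(shared) < MIN_N:
        raise DataError(f"need >= {MIN_N} shared samples, got {len(shared)}")
    g = expr.loc[gene, shared].to_numpy(float)
    rows = []
    for s in substrates:
        x = rma_values.loc[s, shared].to_numpy(float)
        keep = np.isfinite(x) & np.isfinite(g)
        rho, p = spearman(x[keep], g[keep])
        rows.append((s, rho, int(keep.sum()), p))
    panel = pd.DataFrame(rows, columns=["substrate", "rho", "n", "p_value"])
    panel["q_value"] = multipletests(panel["p_value"], method="fdr_bh")[1]
    return panel
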