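"""Relative metabolic activity (RMA) normalization and high-confidence metabolite calling.

The screen's readout for a (substrate, cell line) pair is the well's
maximum curve height A, normalized by subtracting the median of that cell
line's blank (negative-control) wells — the relative metabolic activity.
RMA may be negative: substrates utilized *below* the blank level are a
real signal class.  A substrate is called a high-confidence metabolite
(HCM) when its across-cell-line RMA distribution differs from the pooled
negative-control RMA distribution by a one-tailed Wilcoxon rank-sum test,
run in both directions, with Benjamini-Hochberg control across substrates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .errors import DataError

EXACT_MAX_N = 12  # combined sample size up to which full enumeration is used


@dataclass
class RMATable:
    """Substrate x cell-line RMA matrix plus the control context it came from."""

    values: pd.DataFrame  # substrates x cell lines, control-subtracted
    neg_controls: dict[str, np.ndarray]  # per cell line, negative-control RMAs
    raw_line_medians: pd.Series  # per cell line, median raw A across test wells

    @property
    def substrates(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns)

    def pooled_negative(self) -> np.ndarray:
        return np.concatenate([self.neg_controls[c] for c in self.cell_lines])


def normalize_rma(
    params: pd.DataFrame,
    platemap: pd.DataFrame,
    cell_counts: pd.Series | dict | None = None,
) -> RMATable:
    """Turn per-well A values into the RMA matrix.

    Parameters
    ----------
    params
        Output of :func:`nutriscreen.kinetics.fit_table` (needs plate_id, well, A).
    platemap
        Columns plate_id, well, cell_line, substrate, role, replicate.
    cell_counts
        Optional per-cell-line proliferation factor (CyQUANT-style); raw A
        is divided by it before control subtraction.
    """
    for frame, cols in ((params, {"plate_id", "well", "A"}),
                        (platemap, {"plate_id", "well", "cell_line", "substrate", "role"})):
        if missing := cols - set(frame.columns):
            raise DataError(f"missing columns: {sorted(missing)}")
    merged = platemap.merge(params, on=["plate_id", "well"], how="left", validate="1:1")
    if merged["A"].isna().any():
        bad = merged.loc[merged["A"].isna(), ["plate_id", "well"]].head()
        raise DataError(f"wells in plate map without fitted parameters, e.g.\n{bad}")

    merged = merged.copy()
    if cell_counts is not None:
        counts = pd.Series(cell_counts, dtype=float)
        lines = merged["cell_line"].unique()
        if missing_lines := set(lines) - set(counts.index):
            raise DataError(f"cell_counts missing lines: {sorted(missing_lines)}")
        merged["A"] = merged["A"] / merged["cell_line"].map(counts)

    neg = merged[merged["role"] == "negative_control"]
    lines = list(dict.fromkeys(merged["cell_line"]))
    neg_by_line = {line: g["A"].to_numpy(float) for line, g in neg.groupby("cell_line")}
    if missing_neg := [line for line in lines if len(neg_by_line.get(line, ())) == 0]:
        raise DataError(f"cell lines without negative controls: {missing_neg}")
    neg_median = {line: float(np.median(v)) for line, v in neg_by_line.items()}

    test = merged[merged["role"] == "test"].copy()
    test["rma"] = test["A"] - test["cell_line"].map(neg_median)
    values = test.pivot_table(index="substrate", columns="cell_line", values="rma", aggfunc="mean")
    values = values.reindex(index=list(dict.fromkeys(test["substrate"])), columns=lines)
    raw_medians = test.groupby("cell_line")["A"].median().reindex(lines)
    neg_rma = {line: neg_by_line[line] - neg_median[line] for line in lines}
    return RMATable(values=values, neg_controls=neg_rma, raw_line_medians=raw_medians)


def _exact_tail_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(p_greater, p_less) by full enumeration of rank assignments (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    total = comb(n, n1)
    ge = le = 0
    for idx in itertools.combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if w >= w_obs - 1e-9:
            ge += 1
        if w <= w_obs + 1e-9:
            le += 1
    return ge / total, le / total


def _approx_tail_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Normal approximation with midrank tie correction and continuity correction."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0, 1.0
    p_g = mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
    p_l = mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
    return float(p_g), float(p_l)


def wilcoxon_rank_sum(
    x, y, alternative: str = "greater", method: str = "auto"
) -> float:
    """One- or two-tailed Wilcoxon rank-sum p-value.

    Exact enumeration of all C(n1+n2, n1) rank assignments when the
    combined sample size is at most 12 (or on request); otherwise the
    normal approximation.  The two-sided value follows the doubled-
    smaller-tail convention, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    if method == "auto":
        method = "exact" if x.size + y.size <= EXACT_MAX_N else "normal_approx"
    if method == "exact":
        p_g, p_l = _exact_tail_p(x, y)
    elif method == "normal_approx":
        p_g, p_l = _approx_tail_p(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    if alternative == "greater":
        return p_g
    if alternative == "less":
        return p_l
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_g, p_l))
    raise ValueError(f"unknown alternative {alternative!r}")


def call_hcm(
    rma: RMATable,
    alpha: float = 0.05,
    method: str = "auto",
    fdr: bool = True,
) -> pd.DataFrame:
    """Call high-confidence metabolites against pooled negative-control RMAs.

    Per substrate both one-tailed tests are run; the direction is the tail
    with the smaller p, and the reported p doubles that tail (capped at 1).
    q-values are Benjamini-Hochberg across substrates; with ``fdr=False``
    the raw p is gated instead.
    """
    if len(rma.cell_lines) < 2:
        raise DataError("HCM calling needs at least 2 cell lines")
    pooled = rma.pooled_negative()
    if pooled.size == 0:
        raise DataError("empty pooled negative-control sample")

    rows = []
    for substrate in rma.substrates:
        x = rma.values.loc[substrate].dropna().to_numpy(float)
        use = method
        if use == "auto":
            use = "exact" if x.size + pooled.size <= EXACT_MAX_N else "normal_approx"
        if use == "exact":
            p_g, p_l = _exact_tail_p(x, pooled)
        else:
            p_g, p_l = _approx_tail_p(x, pooled)
        degenerate = bool(np.all(np.concatenate([x, pooled]) == pooled[0])) if pooled.size else False
        direction = "above" if p_g <= p_l else "below"
        p_two = min(1.0, 2.0 * min(p_g, p_l))
        rows.append((substrate, direction, p_two, degenerate))
    calls = pd.DataFrame(rows, columns=["substrate", "direction", "p_value", "degenerate"])
    calls["q_value"] = multipletests(calls["p_value"], method="fdr_bh")[1]
    gate = calls["q_value"] if fdr else calls["p_value"]
    calls["is_hcm"] = (gate <= alpha) & ~calls["degenerate"]
    return calls[["substrate", "direction", "p_value", "q_value", "is_hcm", "degenerate"]]


def qc_plates(rma: RMATable, z_cut: float = 3.5) -> list[str]:
    """Flag cell lines with atypically high signal across the plate.

    A line is flagged when the robust z-score (median/MAD across lines) of
    its median raw A exceeds ``z_cut``.  The test is one-sided high: the
    failure mode being screened for is a plate-wide additive shift.
    """
    x = rma.raw_line_medians.astype(float)
    if x.size < 3:
        raise DataError("plate QC needs at least 3 cell lines")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        warnings.warn("zero MAD across cell lines; falling back to rank-based flagging",
                      stacklevel=2)
        return list(x.index[x > med])
    z = (x - med) / (1.4826 * mad)
    return list(x.index[z > z_cut])
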