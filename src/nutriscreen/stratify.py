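"""High/low stratification, two-group differential expression, and survival comparison.

Samples (cell lines or tumours) are rank-split by a score — a substrate's
RMA or a gene's expression — into high and low groups.  Differential
expression between the groups uses a per-gene Welch two-sample t-test on
log2 values with Benjamini-Hochberg correction.  Survival comparison uses
the Kaplan-Meier product-limit estimator and the two-group log-rank test
(hypergeometric variance, chi-square with 1 df), both via lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DegenerateSplitError

P_FLOOR = np.finfo(float).tiny


def split_by_score(
    samples, scores, scheme: str = "median", tie: str = "low"
) -> pd.DataFrame:
    """Assign samples to high/low groups by score.

    ``median``: strictly above the median is high; samples exactly at the
    median go to ``tie`` ("low" by default).  ``halves``: the upper
    ceil(n/2) of the rank order is high, so an odd cohort splits with the
    extra (median) sample in the high group — a 145-sample cohort gives
    low n = 72, high n = 73.  Ties in the halves scheme are broken by
    sample identifier, making the split invariant to input order.
    """
    samples = list(samples)
    scores = np.asarray(scores, dtype=float)
    n = len(samples)
    if n < 4 or scores.size != n:
        raise DataError("need >= 4 samples with one score each")
    if np.all(scores == scores[0]):
        raise DegenerateSplitError("all scores identical; high/low split undefined")
    if scheme == "median":
        med = np.median(scores)
        high = scores > med if tie == "low" else scores >= med
    elif scheme == "halves":
        order = sorted(range(n), key=lambda i: (scores[i], str(samples[i])))
        high = np.zeros(n, dtype=bool)
        high[order[n - (n + 1) // 2 :]] = True
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return pd.DataFrame(
        {"sample": samples, "score": scores, "group": np.where(high, "high", "low")}
    )


def welch_t(a, b) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p with explicit degenerate rules.

    Zero variance in both groups: equal means give (0, 1); unequal means
    give a sign-correct infinite statistic with the p-value floored.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("Welch t needs >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    delta = a.mean() - b.mean()
    se2 = va / a.size + vb / b.size
    if se2 == 0.0:
        if delta == 0.0:
            return 0.0, 1.0
        return float(np.sign(delta) * np.inf), P_FLOOR
    t = delta / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return float(t), float(max(2.0 * t_dist.sf(abs(t), df), P_FLOOR))


def differential_expression(expr: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Welch t (high - low) with BH correction, sorted by p.

    Returns (gene, delta, t_stat, p_value, q_value, flagged); ``flagged``
    marks genes whose p was floored because both groups had zero variance
    with unequal means.
    """
    assign = groups.set_index("sample")["group"]
    hi_samples = [s for s in expr.columns if assign.get(s) == "high"]
    lo_samples = [s for s in expr.columns if assign.get(s) == "low"]
    if len(hi_samples) < 2 or len(lo_samples) < 2:
        raise DataError("need >= 2 samples per group")
    hi = expr[hi_samples].to_numpy(float)
    lo = expr[lo_samples].to_numpy(float)
    n1, n0 = hi.shape[1], lo.shape[1]
    m1, m0 = hi.mean(axis=1), lo.mean(axis=1)
    v1, v0 = hi.var(axis=1, ddof=1), lo.var(axis=1, ddof=1)
    delta = m1 - m0
    se2 = v1 / n1 + v0 / n0

    t = np.zeros_like(delta)
    p = np.ones_like(delta)
    flagged = np.zeros(delta.shape, dtype=bool)
    ok = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = delta[ok] / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (v1[ok] / n1) ** 2 / (n1 - 1) + (v0[ok] / n0) ** 2 / (n0 - 1)
        )
    p[ok] = np.maximum(2.0 * t_dist.sf(np.abs(t[ok]), df), P_FLOOR)
    degen = ~ok & (delta != 0)
    t[degen] = np.sign(delta[degen]) * np.inf
    p[degen] = P_FLOOR
    flagged[degen] = True

    out = pd.DataFrame(
        {
            "gene": expr.index,
            "delta": delta,
            "t_stat": t,
            "p_value": p,
            "flagged": flagged,
        }
    )
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return (
        out.sort_values(["p_value", "gene"], kind="mergesort")
        .reset_index(drop=True)[["gene", "delta", "t_stat", "p_value", "q_value", "flagged"]]
    )


@dataclass
class KMCurve:
    """Right-continuous Kaplan-Meier step function."""

    timeline: np.ndarray  # starts at 0
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        out = self.survival[np.clip(idx, 0, len(self.timeline) - 1)]
        out = np.where(idx < 0, 1.0, out)
        return float(out) if out.ndim == 0 else out

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.timeline, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(time, event) -> KMCurve:
    """Product-limit estimator; censoring never drops the curve."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise DataError("need at least one record")
    if np.any(time < 0):
        raise DataError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    timeline = sf.index.to_numpy(float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(float)
    return KMCurve(
        timeline=timeline,
        survival=sf.iloc[:, 0].to_numpy(float),
        at_risk=at_risk,
    )


def logrank(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test: (chi_square, p_value) on 1 df."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise DataError(f"log-rank needs exactly 2 groups, got {list(labels)}")
    a, b = (group == labels[0]), (group == labels[1])
    if a.sum() == 0 or b.sum() == 0:
        raise DataError("both groups must be non-empty")
    if event.sum() == 0:
        raise DataError("log-rank undefined with zero events")
    res = logrank_test(time[a], time[b], event_observed_A=event[a], event_observed_B=event[b])
    return float(res.test_statistic), float(res.p_value)
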