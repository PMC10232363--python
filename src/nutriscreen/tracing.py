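"""Mass isotopologue distributions with natural ¹³C abundance correction.

A metabolite with n carbons observed by LC-MS yields peak areas for its
M+0 ... M+n isotopologues.  Even a fully unlabelled compound shows M+1,
M+2, ... signal because each carbon is ¹³C with natural probability
p ≈ 1.07%.  The observed area vector is therefore a binomial convolution
of the underlying (tracer-derived) mass isotopologue distribution (MID):

    observed = M @ mid,   M[i, j] = C(n-j, i-j) · p^(i-j) · (1-p)^(n-i)

where column j describes how a molecule that already carries j heavy
carbons from the tracer distributes its remaining n-j natural carbons.
Correction inverts this lower-triangular, column-stochastic operator and
renormalizes, giving fractions that sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import nnls
from scipy.stats import binom

from .errors import DataError, ParameterError, UndefinedMIDError

#: terrestrial natural abundance of 13C
NATURAL_13C = 0.0107


@dataclass
class IsotopologueSpectrum:
    """Raw (uncorrected) peak areas M+0 ... M+n for one metabolite in one sample."""

    metabolite: str
    n_carbons: int
    areas: np.ndarray
    sample: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.n_carbons < 1:
            raise ParameterError("n_carbons must be >= 1")
        if self.areas.shape != (self.n_carbons + 1,):
            raise DataError(
                f"{self.metabolite}: expected {self.n_carbons + 1} areas "
                f"(M+0..M+{self.n_carbons}), got {self.areas.size}"
            )
        if np.any(self.areas < 0):
            raise DataError(f"{self.metabolite}: negative peak areas")


@dataclass
class CorrectionMatrix:
    """Lower-triangular natural-abundance operator for a given carbon count."""

    n_carbons: int
    p: float
    matrix: np.ndarray = field(repr=False)

    def convolve(self, fractions: np.ndarray) -> np.ndarray:
        """Forward model: corrected fractions -> expected observed fractions."""
        return self.matrix @ np.asarray(fractions, dtype=float)


@dataclass
class MID:
    """Normalized mass isotopologue distribution (fractions sum to 1)."""

    metabolite: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 1 or self.fractions.size < 2:
            raise DataError("MID needs fractions for M+0..M+n, n >= 1")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise DataError(f"{self.metabolite}: MID fractions outside [0, 1]")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise DataError(f"{self.metabolite}: MID fractions sum to {self.fractions.sum()}, not 1")

    @property
    def n_carbons(self) -> int:
        return self.fractions.size - 1

    @property
    def labelled_fraction(self) -> float:
        return float(1.0 - self.fractions[0])

    @property
    def m5_fraction(self) -> float:
        return float(self.fractions[5]) if self.n_carbons >= 5 else 0.0

    @property
    def others_fraction(self) -> float:
        # everything other than M+0 and M+5; only meaningful for a 5-carbon tracer
        if self.n_carbons < 5:
            return 0.0
        return float(max(0.0, 1.0 - self.fractions[0] - self.fractions[5]))


def build_correction_matrix(n_carbons: int, p: float = NATURAL_13C) -> CorrectionMatrix:
    """Binomial natural-abundance operator; every column sums to exactly one."""
    if not 0.0 <= p < 0.5:
        raise ParameterError(f"natural abundance p must be in [0, 0.5), got {p}")
    if n_carbons < 1:
        raise ParameterError("n_carbons must be >= 1")
    m = np.zeros((n_carbons + 1, n_carbons + 1))
    for j in range(n_carbons + 1):
        m[j:, j] = binom.pmf(np.arange(n_carbons - j + 1), n_carbons - j, p)
    return CorrectionMatrix(n_carbons=n_carbons, p=p, matrix=m)


def correct_natural_abundance(
    spectrum: IsotopologueSpectrum, p: float = NATURAL_13C
) -> MID:
    """Deconvolve natural ¹³C contribution from observed peak areas.

    The exact triangular solve is used when it yields a non-negative
    distribution; otherwise (noisy areas) non-negative least squares is
    used and a warning is emitted, since clamping is a real data event.
    """
    total = spectrum.areas.sum()
    if total <= 0:
        raise UndefinedMIDError(f"{spectrum.metabolite}: all-zero peak areas")
    cm = build_correction_matrix(spectrum.n_carbons, p)
    x = solve_triangular(cm.matrix, spectrum.areas, lower=True)
    if x.min() < -1e-12 * total:
        warnings.warn(
            f"{spectrum.metabolite} ({spectrum.sample}): negative isotopologue "
            "intensities after exact correction; clamped via non-negative least squares",
            stacklevel=2,
        )
        x, _ = nnls(cm.matrix, spectrum.areas)
    x = np.clip(x, 0.0, None)
    s = x.sum()
    if s <= 0:
        raise UndefinedMIDError(f"{spectrum.metabolite}: correction annihilated all signal")
    return MID(metabolite=spectrum.metabolite, fractions=x / s)


def enrichment_summary(mid: MID) -> tuple[float, float, float]:
    """(labelled_fraction, fractional_enrichment, others_fraction).

    Fractional enrichment is the average heavy-carbon content per carbon,
    Σ i·fᵢ / n; it equals 1 for a fully M+n species.
    """
    n = mid.n_carbons
    fe = float(np.dot(np.arange(n + 1), mid.fractions) / n)
    return mid.labelled_fraction, fe, mid.others_fraction


def batch_trace(
    spectra: pd.DataFrame, p: float = NATURAL_13C
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correct a long-form spectra table and summarize fractions per group.

    Parameters
    ----------
    spectra
        Long table with columns metabolite, n_carbons, iso_index, area,
        sample, group (one row per isotopologue peak).

    Returns
    -------
    mids
        (metabolite, sample, group, iso_index, fraction) per corrected MID.
    summary
        (metabolite, group, iso_index, mean_fraction, sd_fraction, n) —
        the numbers behind stacked-bar MID plots.
    """
    required = {"metabolite", "n_carbons", "iso_index", "area", "sample", "group"}
    missing = required - set(spectra.columns)
    if missing:
        raise DataError(f"spectra table missing columns: {sorted(missing)}")
    if spectra["group"].isna().any() or (spectra["group"].astype(str) == "").any():
        raise DataError("missing group label in spectra table")

    rows = []
    for met, met_df in spectra.groupby("metabolite", sort=False):
        ncs = met_df["n_carbons"].unique()
        if len(ncs) != 1:
            raise DataError(f"{met}: inconsistent n_carbons {sorted(ncs)}")
        n = int(ncs[0])
        for (sample, group), s_df in met_df.groupby(["sample", "group"], sort=False):
            areas = np.zeros(n + 1)
            idx = s_df["iso_index"].to_numpy(dtype=int)
            if np.any(idx < 0) or np.any(idx > n):
                raise DataError(f"{met}/{sample}: iso_index outside 0..{n}")
            areas[idx] = s_df["area"].to_numpy(dtype=float)
            mid = correct_natural_abundance(
                IsotopologueSpectrum(met, n, areas, sample=str(sample), group=str(group)), p
            )
            for i, f in enumerate(mid.fractions):
                rows.append((met, sample, group, i, f))
    mids = pd.DataFrame(rows, columns=["metabolite", "sample", "group", "iso_index", "fraction"])
    summary = (
        mids.groupby(["metabolite", "group", "iso_index"], sort=False)["fraction"]
        .agg(mean_fraction="mean", sd_fraction="std", n="size")
        .reset_index()
    )
    return mids, summary
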