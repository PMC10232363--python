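"""Synthetic data generators for every pipeline input.

The paper-scale raw data behind the screen (Biolog plate reads, CCLE-style
expression, isotopologue peak areas, survival cohorts, standard-curve
dilutions) are not deposited, so each generator here produces inputs with
the statistical structure the analysis assumes, at the study's own scale:
96-well plates read for 74.5 h at 15-min intervals with triplicate
glucose-positive and blank-negative controls, a 16-cell-line correlation
panel over >175 substrates, a 145-sample survival cohort, a 5 mM -> 1 μM
standard dilution series, and ¹³C isotopologue spectra convolved at the
natural-abundance fraction p = 0.0107.

Determinism: one independent random stream per generator, derived from
the master seed by stable sub-seeding, so adding or re-running one
generator never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tracing import MID, IsotopologueSpectrum, build_correction_matrix

_ROWS = "ABCDEFGH"
_STREAMS = {
    "plates": 0,
    "expression": 1,
    "spectra": 2,
    "survival": 3,
    "standards": 4,
    "cohort": 5,
}


def well_name(i: int) -> str:
    """0-based well index to 96-well plate coordinate (A01 ... H12)."""
    return f"{_ROWS[i // 12]}{i % 12 + 1:02d}"


def logistic_signal(t, lambda_h: float, mu: float, A: float, baseline: float = 0.0):
    """Three-parameter logistic trace with explicit lag, slope and height.

    s(t) = A / (1 + exp(4 mu / A * (lambda - t) + 2)) + baseline: the
    maximal slope is mu, attained at the inflection, and the tangent there
    crosses the baseline at t = lambda.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        return A / (1.0 + np.exp(4.0 * mu / A * (lambda_h - t) + 2.0)) + baseline


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic campaign.

    Defaults mirror the screen that the pipeline re-implements: 16 cell
    lines, 180 substrates across two 96-well panels, triplicate controls,
    74.5 h reads at 15-min intervals, one planted uridine-UPP1-like
    metabolite-gene pair at effect 0.85 (on the scale of the r = 0.82
    discovery correlation), a 145-sample survival cohort, and TIF-scale
    fluid concentrations.
    """

    seed: int = 0
    # plates
    n_cell_lines: int = 16
    n_substrates: int = 180
    n_neg_controls: int = 3
    n_pos_controls: int = 3
    duration_h: float = 74.5
    interval_h: float = 0.25
    growth_model: str = "logistic"
    noise_sd: float = 0.01
    baseline: float = 0.05
    amplitude_sd: float = 0.4
    consumer_fraction: float = 0.3
    consumer_boost: float = 1.8
    inert_fraction: float = 0.2
    inert_scale: float = 0.0
    outlier_cell_lines: tuple[str, ...] = ()
    outlier_shift: float = 0.5
    # expression
    n_genes: int = 100
    expression_noise_sd: float = 1.0
    expression_center: float = 8.0
    planted_pairs: tuple[tuple[str, str, float], ...] = (("uridine", "UPP1", 0.85),)
    substrate_names: tuple[str, ...] = ("uridine", "adenosine", "inosine", "thymidine")
    gene_names: tuple[str, ...] = ("UPP1",)
    # spectra
    natural_abundance_p: float = 0.0107
    spectra_total_intensity: float = 1e6
    spectra_noise_frac: float = 0.01
    # survival
    hazard_ratio: float = 2.0
    n_survival_samples: int = 145
    median_survival_low_hazard: float = 20.0  # months, for the low-hazard arm
    censor_max: float = 80.0  # months, uniform censoring horizon
    # standards
    standard_top_conc: float = 5000.0  # μM (5 mM)
    standard_n_levels: int = 13  # 2-fold series down to ~1 μM
    standard_slope: float = 2.0e-3  # response units per μM
    standard_intercept: float = 0.05
    response_noise_frac: float = 0.02

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.interval_h <= 0:
            raise ConfigError("duration_h and interval_h must be positive")
        steps = self.duration_h / self.interval_h
        if abs(steps - round(steps)) > 1e-9:
            raise ConfigError("duration_h must be an integer multiple of interval_h")
        if self.n_neg_controls < 3 or self.n_pos_controls < 3:
            raise ConfigError("need >= 3 negative and >= 3 positive control wells")
        if self.growth_model != "logistic":
            raise ConfigError(f"unknown growth model {self.growth_model!r}")
        capacity = 96 - self.n_neg_controls - self.n_pos_controls
        if capacity < 1:
            raise ConfigError("controls leave no room for test wells on a 96-well plate")
        subs, gens = set(self.substrates), set(self.genes)
        for substrate, gene, effect in self.planted_pairs:
            if not 0.0 <= effect <= 1.0:
                raise ConfigError(f"effect size {effect} outside [0, 1]")
            if substrate not in subs:
                raise ConfigError(f"planted substrate {substrate!r} not among substrates")
            if gene not in gens:
                raise ConfigError(f"planted gene {gene!r} not among the {self.n_genes} genes")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be positive")

    # -- derived vocabulary ------------------------------------------------
    @property
    def time_grid(self) -> np.ndarray:
        n = round(self.duration_h / self.interval_h) + 1
        return np.arange(n) * self.interval_h

    @property
    def cell_lines(self) -> list[str]:
        return [f"CL{i:02d}" for i in range(1, self.n_cell_lines + 1)]

    @property
    def substrates(self) -> list[str]:
        names = list(self.substrate_names[: self.n_substrates])
        names += [f"S{i:03d}" for i in range(len(names) + 1, self.n_substrates + 1)]
        return names

    @property
    def genes(self) -> list[str]:
        names = list(self.gene_names[: self.n_genes])
        names += [f"G{i:04d}" for i in range(len(names) + 1, self.n_genes + 1)]
        return names

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


# --------------------------------------------------------------------------
# plates
# --------------------------------------------------------------------------

def simulate_plates(
    config: SyntheticConfig, return_truth: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate plate maps and long-form kinetic traces for every cell line.

    Test wells follow the three-parameter logistic with per-(line,
    substrate) amplitude; a random "consumer" subset of substrates per
    line is boosted.  Negative controls are baseline-only plus noise;
    positive (glucose) controls are strong logistic responders.  Cell
    lines listed in ``outlier_cell_lines`` get a uniform additive shift
    across all their wells, emulating a plate-wide artefact.

    Returns (platemap, traces) and, with ``return_truth``, the generating
    per-well parameters for recovery checks.
    """
    rng = config.rng("plates")
    t = config.time_grid
    n_s, n_l = config.n_substrates, config.n_cell_lines
    substrates, lines = config.substrates, config.cell_lines

    # global per-substrate / per-(substrate, line) structure, drawn first so
    # plate layout never changes it
    a_base = rng.uniform(0.2, 1.2, n_s)
    lam_base = rng.uniform(5.0, 20.0, n_s)
    rate_base = rng.uniform(0.05, 0.15, n_s)  # mu / A, per hour
    # a fraction of substrates is simply not utilized (near-blank wells);
    # planted substrates are kept responsive so their signal is defined
    inert = rng.random(n_s) < config.inert_fraction
    planted_subs = {s for s, _, _ in config.planted_pairs}
    inert &= np.array([s not in planted_subs for s in substrates])
    a_base = np.where(inert, config.inert_scale * a_base, a_base)
    mult = np.exp(config.amplitude_sd * rng.standard_normal((n_s, n_l)))
    consumer = rng.random((n_s, n_l)) < config.consumer_fraction
    lam_jitter = rng.normal(0.0, 1.0, (n_s, n_l))

    a_mat = a_base[:, None] * mult * np.where(consumer, config.consumer_boost, 1.0)
    lam_mat = np.clip(lam_base[:, None] + lam_jitter, 0.5, config.duration_h)
    mu_mat = rate_base[:, None] * a_mat

    capacity = 96 - config.n_neg_controls - config.n_pos_controls
    n_plates = math.ceil(n_s / capacity)

    map_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    trace_plates: list[str] = []
    trace_wells: list[list[str]] = []
    trace_signals: list[np.ndarray] = []

    for li, line in enumerate(lines):
        shift = config.outlier_shift if line in config.outlier_cell_lines else 0.0
        for pi in range(n_plates):
            plate_id = f"{line}-P{pi + 1}"
            sub_idx = list(range(pi * capacity, min(n_s, (pi + 1) * capacity)))
            wells, lam_w, mu_w, a_w = [], [], [], []
            for k, si in enumerate(sub_idx):
                wells.append(well_name(k))
                map_rows.append((plate_id, well_name(k), line, substrates[si], "test", 1))
                lam_w.append(lam_mat[si, li])
                mu_w.append(mu_mat[si, li])
                a_w.append(a_mat[si, li])
            a_pos = 1.2 * np.exp(0.2 * rng.standard_normal(config.n_pos_controls))
            lam_pos = rng.uniform(3.0, 8.0, config.n_pos_controls)
            for r in range(config.n_pos_controls):
                w = well_name(len(wells))
                wells.append(w)
                map_rows.append((plate_id, w, line, "glucose", "positive_control", r + 1))
                lam_w.append(lam_pos[r])
                mu_w.append(0.12 * a_pos[r])
                a_w.append(a_pos[r])
            for r in range(config.n_neg_controls):
                w = well_name(len(wells))
                wells.append(w)
                map_rows.append((plate_id, w, line, "blank", "negative_control", r + 1))
                lam_w.append(0.0)
                mu_w.append(0.0)
                a_w.append(0.0)

            lam_w, mu_w, a_w = (np.asarray(v) for v in (lam_w, mu_w, a_w))
            active = a_w > 0
            signal = np.full((len(wells), t.size), config.baseline + shift)
            if active.any():
                with np.errstate(over="ignore"):
                    signal[active] += a_w[active, None] / (
                        1.0
                        + np.exp(
                            4.0
                            * (mu_w[active] / a_w[active])[:, None]
                            * (lam_w[active, None] - t[None, :])
                            + 2.0
                        )
                    )
            if config.noise_sd > 0:
                signal += config.noise_sd * rng.standard_normal(signal.shape)
            trace_plates.append(plate_id)
            trace_wells.append(wells)
            trace_signals.append(signal)
            for w, lam, mu, a in zip(wells, lam_w, mu_w, a_w):
                truth_rows.append((plate_id, w, line, lam, mu, a, config.baseline + shift))

    platemap = pd.DataFrame(
        map_rows, columns=["plate_id", "well", "cell_line", "substrate", "role", "replicate"]
    )
    n_t = t.size
    plate_per_well = np.array(
        [p for p, ws in zip(trace_plates, trace_wells) for _ in ws]
    )  # fixed-width numpy strings: cheap to repeat
    well_per_well = np.array([w for ws in trace_wells for w in ws])
    traces = pd.DataFrame(
        {
            "plate_id": np.repeat(plate_per_well, n_t),
            "well": np.repeat(well_per_well, n_t),
            "time_h": np.tile(t, well_per_well.size),
            "signal": np.concatenate([s.ravel() for s in trace_signals]),
        }
    )
    if not return_truth:
        return platemap, traces
    truth = pd.DataFrame(
        truth_rows,
        columns=["plate_id", "well", "cell_line", "lambda_h", "mu", "A", "baseline"],
    )
    return platemap, traces, truth


def true_rma(truth: pd.DataFrame, platemap: pd.DataFrame) -> pd.DataFrame:
    """Noise-free substrate x cell-line utilization matrix from the truth table.

    True RMA equals the generating amplitude A: blanks have A = 0, so the
    median negative-control signal is exactly the shared baseline.
    """
    merged = platemap.merge(truth, on=["plate_id", "well", "cell_line"], validate="1:1")
    test = merged[merged["role"] == "test"]
    mat = test.pivot_table(index="substrate", columns="cell_line", values="A", aggfunc="mean")
    cols = list(dict.fromkeys(platemap["cell_line"]))
    return mat.reindex(index=list(dict.fromkeys(test["substrate"])), columns=cols)


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def simulate_expression(config: SyntheticConfig, rma) -> pd.DataFrame:
    """Gene x sample log2-scale expression with planted metabolite-gene structure.

    For each planted (substrate, gene, effect): the gene's expression is
    effect * z(RMA of the substrate) + sqrt(1 - effect^2) * noise,
    affinely rescaled into a log2-like range (affine maps preserve the
    Spearman correlation, so effect is the target correlation strength).
    All other genes are i.i.d. noise.
    """
    mat = rma.values if hasattr(rma, "neg_controls") else rma
    missing = [c for c in config.cell_lines if c not in set(mat.columns)]
    if missing:
        raise ConfigError(f"RMA table does not cover cell lines: {missing}")
    rng = config.rng("expression")
    genes, samples = config.genes, config.cell_lines
    expr = config.expression_center + config.expression_noise_sd * rng.standard_normal(
        (config.n_genes, len(samples))
    )
    expr = pd.DataFrame(expr, index=genes, columns=samples)
    for substrate, gene, effect in config.planted_pairs:
        if substrate not in set(mat.index):
            raise ConfigError(f"planted substrate {substrate!r} absent from RMA table")
        x = mat.loc[substrate, samples].to_numpy(float)
        sd = x.std()
        if sd == 0:
            raise ConfigError(f"substrate {substrate!r} has constant RMA; cannot plant signal")
        z = (x - x.mean()) / sd
        g = effect * z + math.sqrt(1.0 - effect**2) * rng.standard_normal(len(samples))
        expr.loc[gene] = config.expression_center + config.expression_noise_sd * g
    return expr


# --------------------------------------------------------------------------
# isotopologue spectra
# --------------------------------------------------------------------------

def simulate_spectra(
    config: SyntheticConfig,
    true_mids: list[MID],
    n_replicates: int = 1,
    group: str = "all",
) -> list[IsotopologueSpectrum]:
    """Forward-convolve true MIDs with natural abundance and add truncated noise.

    The output is the *uncorrected* observable: areas proportional to
    CorrectionMatrix(n, p) @ mid, plus non-negative truncated Gaussian
    noise of sd ``spectra_noise_frac`` x total intensity.
    """
    rng = config.rng("spectra")
    p = config.natural_abundance_p
    total = config.spectra_total_intensity
    out = []
    for mid in true_mids:
        cm = build_correction_matrix(mid.n_carbons, p)
        expected = total * cm.convolve(mid.fractions)
        for r in range(n_replicates):
            areas = expected.copy()
            if config.spectra_noise_frac > 0:
                areas = np.clip(
                    areas
                    + config.spectra_noise_frac * total * rng.standard_normal(areas.shape),
                    0.0,
                    None,
                )
            out.append(
                IsotopologueSpectrum(
                    metabolite=mid.metabolite,
                    n_carbons=mid.n_carbons,
                    areas=areas,
                    sample=f"{mid.metabolite}_{group}_{r + 1}",
                    group=group,
                )
            )
    return out


def spectra_frame(spectra: list[IsotopologueSpectrum]) -> pd.DataFrame:
    """Long-form (metabolite, n_carbons, iso_index, area, sample, group) table."""
    rows = [
        (s.metabolite, s.n_carbons, i, a, s.sample, s.group)
        for s in spectra
        for i, a in enumerate(s.areas)
    ]
    return pd.DataFrame(
        rows, columns=["metabolite", "n_carbons", "iso_index", "area", "sample", "group"]
    )


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------

def simulate_survival(config: SyntheticConfig, scores: pd.Series) -> pd.DataFrame:
    """Exponential event times with hazard x hazard_ratio above the score median.

    Censoring is independent uniform on [0, censor_max].  Returns
    (sample, time, event, score, group).
    """
    rng = config.rng("survival")
    scores = pd.Series(scores, dtype=float)
    n = len(scores)
    high = scores.to_numpy() > np.median(scores.to_numpy())
    h0 = math.log(2.0) / config.median_survival_low_hazard
    hazard = h0 * np.where(high, config.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, config.censor_max, n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "sample": scores.index,
            "time": time,
            "event": event,
            "score": scores.to_numpy(),
            "group": np.where(high, "high", "low"),
        }
    )


# --------------------------------------------------------------------------
# standards
# --------------------------------------------------------------------------

def simulate_standards(
    config: SyntheticConfig,
    true_concs: np.ndarray | list[float],
    analyte: str = "uridine",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """External-standard dilution series plus sample responses of known truth.

    The standard series is a 2-fold dilution from ``standard_top_conc``
    (5 mM) over ``standard_n_levels`` levels (down to ~1 μM); responses
    are linear in concentration with proportional Gaussian noise.
    """
    rng = config.rng("standards")
    true_concs = np.asarray(true_concs, dtype=float)
    if np.any(true_concs < 0):
        raise ConfigError("sample concentrations must be non-negative")
    levels = config.standard_top_conc * 0.5 ** np.arange(config.standard_n_levels)

    def respond(conc: np.ndarray) -> np.ndarray:
        clean = config.standard_slope * conc + config.standard_intercept
        if config.response_noise_frac > 0:
            clean = clean * (1.0 + config.response_noise_frac * rng.standard_normal(conc.shape))
        return clean

    standards = pd.DataFrame(
        {"analyte": analyte, "conc": levels, "response": respond(levels)}
    )
    samples = pd.DataFrame(
        {
            "analyte": analyte,
            "sample": [f"{analyte}_s{i + 1}" for i in range(true_concs.size)],
            "true_conc": true_concs,
            "response": respond(true_concs),
        }
    )
    return standards, samples


# --------------------------------------------------------------------------
# whole campaign
# --------------------------------------------------------------------------

def default_true_mids() -> dict[str, MID]:
    """Per-group true 5-carbon MIDs emulating a [¹³C₅]uridine tracing design.

    The control arm carries most signal at M+5 (intact ribose transfer);
    the knockout-like arm is entirely unlabelled.
    """
    return {
        "ctrl": MID("uridine_ribose", np.array([0.30, 0.02, 0.03, 0.02, 0.03, 0.60])),
        "ko": MID("uridine_ribose", np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])),
    }


def simulate_campaign(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Run every generator once; returns the full set of pipeline inputs.

    Expression is planted against the TRUE (noise-free) utilization matrix,
    so the measured RMA recovered downstream carries realistic attenuation.
    """
    platemap, traces, truth = simulate_plates(config, return_truth=True)
    rma_true = true_rma(truth, platemap)
    expression = simulate_expression(config, rma_true)

    mids = default_true_mids()
    spectra = simulate_spectra(config, [mids["ctrl"]], n_replicates=3, group="ctrl")
    spectra += simulate_spectra(config, [mids["ko"]], n_replicates=3, group="ko")

    # scores come from their own stream: simulate_survival restarts the
    # "survival" stream, and sharing it would couple scores to event times
    cohort_rng = config.rng("cohort")
    cohort = pd.Series(
        cohort_rng.standard_normal(config.n_survival_samples),
        index=[f"T{i + 1:03d}" for i in range(config.n_survival_samples)],
        name="score",
    )
    survival = simulate_survival(config, cohort)

    uridine_std, uridine_samples = simulate_standards(
        config, np.full(8, 24.1), analyte="uridine"
    )
    uracil_std, uracil_samples = simulate_standards(
        config, np.full(8, 90.2), analyte="uracil"
    )
    fluid_samples = pd.concat([uridine_samples, uracil_samples], ignore_index=True)
    fluid_samples["group"] = "TIF"

    return {
        "platemap": platemap,
        "traces": traces,
        "truth": truth,
        "expression": expression,
        "spectra": spectra_frame(spectra),
        "survival": survival,
        "standards": pd.concat([uridine_std, uracil_std], ignore_index=True),
        "fluid_samples": fluid_samples,
    }


def write_campaign(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Write every generated table to ``outdir``; returns name -> path."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_campaign(config)
    paths = {}
    for name, frame in data.items():
        if name == "expression":
            path = outdir / "expression.tsv"
            frame.to_csv(path, sep="\t", index_label="gene")
        elif name == "survival":
            path = outdir / "survival.tsv"
            frame.to_csv(path, sep="\t", index=False)
        else:
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
        paths[name] = str(path)
    return paths


def config_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
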