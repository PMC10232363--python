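"""File-based pipeline orchestration with provenance capture.

Stages communicate only through CSV/TSV files, never in-memory state, so
any stage can be re-run standalone and intermediate deletion plus a
downstream re-run reproduces outputs exactly.  The manifest records the
configuration, seed and SHA-256 of every input and output (no
timestamps, so identical runs are byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import StageError
from .correlation import correlate_screen, specificity_panel
from .kinetics import fit_table
from .quantify import fit_standard_curve, interpolate_concentration, summarize_fluid
from .screen import RMATable, call_hcm, normalize_rma, qc_plates
from .stratify import differential_expression, km_estimate, logrank, split_by_score
from .synthetic import SyntheticConfig, write_campaign
from .tracing import batch_trace

STAGE_ORDER = ("simulate", "kinetics", "screen", "correlate", "stratify", "trace", "quantify")

#: files each stage reads / writes (relative to the run directory)
STAGE_IO: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "simulate": (
        (),
        ("platemap.csv", "traces.csv", "truth.csv", "expression.tsv", "spectra.csv",
         "survival.tsv", "standards.csv", "fluid_samples.csv"),
    ),
    "kinetics": (("traces.csv",), ("params.csv",)),
    "screen": (
        ("params.csv", "platemap.csv"),
        ("rma.tsv", "neg_rma.csv", "hcm_calls.csv", "qc_flags.csv"),
    ),
    "correlate": (
        ("rma.tsv", "neg_rma.csv", "expression.tsv", "hcm_calls.csv"),
        ("correlations.csv", "specificity_panel.csv"),
    ),
    "stratify": (
        ("expression.tsv", "survival.tsv", "correlations.csv"),
        ("groups.csv", "de_results.csv", "km_curves.csv", "logrank.csv"),
    ),
    "trace": (("spectra.csv",), ("mids.csv", "mid_summary.csv")),
    "quantify": (
        ("standards.csv", "fluid_samples.csv"),
        ("curves.csv", "concentrations.csv", "fluid_summary.csv"),
    ),
}


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "pipeline_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    window: int = 5
    alpha: float = 0.05
    fdr: bool = True
    hcm_only: bool = True
    split_scheme: str = "median"
    abundance_p: float = 0.0107
    synthetic: dict = dataclasses.field(default_factory=dict)
    paths: dict = dataclasses.field(default_factory=dict)  # filename -> override path

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise StageError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in STAGE_ORDER if s in self.stages)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def path(self, name: str) -> Path:
        return Path(self.paths.get(name, Path(self.outdir) / name))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _rows(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)


def _synth_config(cfg: PipelineConfig) -> SyntheticConfig:
    kwargs = dict(cfg.synthetic)
    kwargs.setdefault("seed", cfg.seed)
    for key in ("planted_pairs", "substrate_names", "gene_names", "outlier_cell_lines"):
        if key in kwargs:
            kwargs[key] = tuple(
                tuple(v) if isinstance(v, (list, tuple)) else v for v in kwargs[key]
            )
    return SyntheticConfig(**kwargs)


# --------------------------------------------------------------------------
# stage bodies (file -> file)
# --------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig) -> None:
    data_dir = Path(cfg.outdir)
    paths = write_campaign(_synth_config(cfg), data_dir)
    # fluid_samples is written as fluid_samples.csv by write_campaign already
    del paths


def _read_rma(cfg: PipelineConfig) -> RMATable:
    values = pd.read_csv(cfg.path("rma.tsv"), sep="\t", index_col=0)
    neg = pd.read_csv(cfg.path("neg_rma.csv"))
    neg_controls = {
        line: g["rma"].to_numpy(float) for line, g in neg.groupby("cell_line", sort=False)
    }
    meds = neg.drop_duplicates("cell_line").set_index("cell_line")["raw_line_median"]
    return RMATable(values=values, neg_controls=neg_controls,
                    raw_line_medians=meds.reindex(values.columns))


def _stage_kinetics(cfg: PipelineConfig) -> None:
    traces = pd.read_csv(cfg.path("traces.csv"))
    fit_table(traces, window=cfg.window).to_csv(cfg.path("params.csv"), index=False)


def _stage_screen(cfg: PipelineConfig) -> None:
    params = pd.read_csv(cfg.path("params.csv"))
    platemap = pd.read_csv(cfg.path("platemap.csv"))
    rma = normalize_rma(params, platemap)
    rma.values.to_csv(cfg.path("rma.tsv"), sep="\t", index_label="substrate")
    neg_rows = [
        {"cell_line": line, "replicate": i + 1, "rma": v,
         "raw_line_median": rma.raw_line_medians[line]}
        for line in rma.cell_lines
        for i, v in enumerate(rma.neg_controls[line])
    ]
    pd.DataFrame(neg_rows).to_csv(cfg.path("neg_rma.csv"), index=False)
    call_hcm(rma, alpha=cfg.alpha, fdr=cfg.fdr).to_csv(cfg.path("hcm_calls.csv"), index=False)
    pd.DataFrame({"cell_line": qc_plates(rma)}).to_csv(cfg.path("qc_flags.csv"), index=False)


def _stage_correlate(cfg: PipelineConfig) -> None:
    rma = _read_rma(cfg)
    expr = pd.read_csv(cfg.path("expression.tsv"), sep="\t", index_col=0)
    hcm = pd.read_csv(cfg.path("hcm_calls.csv"))
    res = correlate_screen(rma, expr, hcm_only=cfg.hcm_only, hcm_calls=hcm)
    res.to_csv(cfg.path("correlations.csv"), index=False)
    # specificity panel for the top-ranked pair's gene over the named substrates
    synth = _synth_config(cfg)
    panel_subs = [s for s in synth.substrate_names if s in set(rma.values.index)]
    top_gene = res.iloc[0]["gene"]
    if len(panel_subs) >= 2:
        specificity_panel(rma, expr, top_gene, panel_subs).to_csv(
            cfg.path("specificity_panel.csv"), index=False
        )
    else:
        pd.DataFrame(columns=["substrate", "rho", "n", "p_value", "q_value"]).to_csv(
            cfg.path("specificity_panel.csv"), index=False
        )


def _stage_stratify(cfg: PipelineConfig) -> None:
    expr = pd.read_csv(cfg.path("expression.tsv"), sep="\t", index_col=0)
    res = pd.read_csv(cfg.path("correlations.csv"))
    score_gene = res.iloc[0]["gene"]
    scores = expr.loc[score_gene]
    groups = split_by_score(scores.index, scores.to_numpy(), scheme=cfg.split_scheme)
    groups.insert(1, "score_gene", score_gene)
    groups.to_csv(cfg.path("groups.csv"), index=False)
    differential_expression(expr, groups).to_csv(cfg.path("de_results.csv"), index=False)

    surv = pd.read_csv(cfg.path("survival.tsv"), sep="\t")
    sgroups = split_by_score(surv["sample"], surv["score"].to_numpy(), scheme=cfg.split_scheme)
    surv = surv.drop(columns=["group"], errors="ignore").merge(
        sgroups[["sample", "group"]], on="sample"
    )
    curves = []
    for label, sub in surv.groupby("group", sort=False):
        km = km_estimate(sub["time"], sub["event"]).as_frame()
        km.insert(0, "group", label)
        curves.append(km)
    pd.concat(curves, ignore_index=True).to_csv(cfg.path("km_curves.csv"), index=False)
    chi2, p = logrank(surv["time"], surv["event"], surv["group"])
    pd.DataFrame(
        [{
            "chi_square": chi2,
            "p_value": p,
            "n_high": int((surv["group"] == "high").sum()),
            "n_low": int((surv["group"] == "low").sum()),
            "events": int(surv["event"].sum()),
        }]
    ).to_csv(cfg.path("logrank.csv"), index=False)


def _stage_trace(cfg: PipelineConfig) -> None:
    spectra = pd.read_csv(cfg.path("spectra.csv"))
    mids, summary = batch_trace(spectra, p=cfg.abundance_p)
    mids.to_csv(cfg.path("mids.csv"), index=False)
    summary.to_csv(cfg.path("mid_summary.csv"), index=False)


def _stage_quantify(cfg: PipelineConfig) -> None:
    standards = pd.read_csv(cfg.path("standards.csv"))
    samples = pd.read_csv(cfg.path("fluid_samples.csv"))
    curve_rows, conc_frames = [], []
    for analyte, std in standards.groupby("analyte", sort=False):
        curve = fit_standard_curve(std["conc"], std["response"], analyte=analyte)
        curve_rows.append(
            {
                "analyte": analyte,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r_squared": curve.r_squared,
                "range_low": curve.calibrated_range[0],
                "range_high": curve.calibrated_range[1],
            }
        )
        sub = samples[samples["analyte"] == analyte].copy()
        conc, flag = interpolate_concentration(curve, sub["response"].to_numpy(float))
        sub["conc"], sub["extrapolated"] = conc, flag
        conc_frames.append(sub)
    pd.DataFrame(curve_rows).to_csv(cfg.path("curves.csv"), index=False)
    concs = pd.concat(conc_frames, ignore_index=True)
    concs.to_csv(cfg.path("concentrations.csv"), index=False)
    summaries = []
    for analyte, sub in concs.groupby("analyte", sort=False):
        s = summarize_fluid(sub)
        s.insert(0, "analyte", analyte)
        summaries.append(s)
    pd.concat(summaries, ignore_index=True).to_csv(cfg.path("fluid_summary.csv"), index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "kinetics": _stage_kinetics,
    "screen": _stage_screen,
    "correlate": _stage_correlate,
    "stratify": _stage_stratify,
    "trace": _stage_trace,
    "quantify": _stage_quantify,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in order; returns (and writes) the run manifest.

    Pre-flight: every input of every enabled stage must already exist on
    disk or be produced by an earlier enabled stage — checked before any
    stage runs, so a bad configuration touches nothing.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    produced: set[str] = set()
    for stage in config.stages:
        inputs, outputs = STAGE_IO[stage]
        for name in inputs:
            if name not in produced and not config.path(name).exists():
                raise StageError(
                    f"pre-flight: stage '{stage}' needs {config.path(name)}, "
                    "which no earlier enabled stage produces"
                )
        produced.update(outputs)

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    for stage in config.stages:
        inputs, outputs = STAGE_IO[stage]
        record = {"inputs": {}, "outputs": {}}
        for name in inputs:
            record["inputs"][name] = _sha256(config.path(name))
        try:
            _STAGE_FUNCS[stage](config)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        for name in outputs:
            path = config.path(name)
            record["outputs"][name] = {"sha256": _sha256(path), "rows": _rows(path)}
        manifest["stages"][stage] = record

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
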