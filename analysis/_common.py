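"""Shared locations and the campaign bootstrap for the analysis scripts.

The screen-scale synthetic campaign (16 cell lines, 180 substrates,
74.5 h reads) lives under scratch/ — it is bulky, regenerable
intermediate data.  Each numbered script ensures the campaign exists,
reads the stage outputs it needs, and writes only small summary tables
under results/.
"""

from pathlib import Path

from nutriscreen import PipelineConfig, run_pipeline

REPO = Path(__file__).resolve().parents[1]
RUN_DIR = REPO / "scratch" / "analysis_run"
RESULTS = REPO / "results"

SEED = 1


def ensure_campaign() -> Path:
    """Run the full pipeline once (idempotent via the manifest)."""
    if not (RUN_DIR / "manifest.json").exists():
        run_pipeline(PipelineConfig(outdir=str(RUN_DIR), seed=SEED))
    RESULTS.mkdir(exist_ok=True)
    return RUN_DIR
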