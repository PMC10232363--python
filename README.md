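# nutriscreen

Analytics for nutrient-utilization screening: from phenotype-microarray
kinetic traces to metabolite–gene correlation nominations, with the
downstream survival stratification, stable-isotope-tracing summaries and
standard-curve absolute quantification that follow a hit.

The motivating workflow is the discovery of a nutrient–enzyme pair in
cancer cell lines: panels of cells are starved of glucose and offered
~180 candidate substrates in 96-well plates whose dye-reduction kinetics
are read for ~3 days; each well's curve is reduced to its maximum height
A, normalized against blank wells into a **relative metabolic activity
(RMA)**; substrates utilized above or below blanks become
**high-confidence metabolites (HCMs)**; and each HCM's RMA profile
across cell lines is Spearman-correlated against gene expression to
nominate the transporter or catabolic enzyme behind it (the canonical
hit being uridine and uridine phosphorylase 1, UPP1, r ≈ 0.8 over 16
lines). The package implements every computational stage of that
pipeline, plus a synthetic-data module that generates all inputs with
the statistical structure the analysis assumes, so the whole chain is
testable without any external download.

## The statistics at the core

- **Kinetics** — per-well readouts λ (lag, tangent-intercept), μ
  (maximal sliding-regression slope, floored at 0), A (max smoothed
  height) and AUC; nonparametric, exactly scale/shift-equivariant.
- **Screen** — RMA = A − median(blank A) per cell line; HCM calls by
  one-tailed Wilcoxon rank-sum against pooled blanks in both directions
  (exact enumeration for combined n ≤ 12, normal approximation with tie
  and continuity corrections otherwise), BH across substrates; robust
  z-score plate QC.
- **Correlation** — Spearman ρ via midrank Pearson, p from
  t = ρ√((n−2)/(1−ρ²)), exact permutation for n ≤ 9; all substrate ×
  gene pairs ranked by |ρ|; nucleoside specificity panels.
- **Stratify** — median or halves rank-split (a 145-sample cohort
  splits 72 low / 73 high), per-gene Welch t + BH differential
  expression, Kaplan–Meier and two-group log-rank via lifelines.
- **Tracing** — natural-abundance correction of mass isotopologue
  distributions by inverting the binomial operator
  M[i,j] = C(n−j, i−j)·p^(i−j)(1−p)^(n−i) at p = 0.0107, with
  non-negative least squares for noisy spectra; labelled-fraction and
  fractional-enrichment summaries.
- **Quantify** — external-standard linear calibration over a
  5 mM → 1 μM dilution series, flagged extrapolation, per-group medians
  and Welch comparison.

See `docs/methods.md` for conventions, noise models and limitations.

## Worked example

The numbered scripts under `analysis/` run the campaign end to end and
write small summary tables under `results/` (bulky intermediates go to
`scratch/`). `python analysis/01_simulate_campaign.py` simulates and
runs the full pipeline; subsequent scripts narrate each stage:

```text
$ python analysis/03_screen_hcms.py
142 HCMs of 180 substrates (163 tested above, 17 below)
QC-flagged cell lines: none

$ python analysis/04_correlate_expression.py
14200 substrate x gene pairs scored over n = 16 cell lines
top pair: S070-G0086 rho = -0.81, p = 1.21e-04
planted uridine-UPP1: rho = 0.62, p = 1.08e-02, rank 189 ...
UPP1 nucleoside specificity panel (q <= 0.05 marks the specific substrate):
substrate     rho  n  p_value  q_value
  uridine  0.6176 16   0.0108   0.0432
adenosine  0.4824 16   0.0585   0.0779
  inosine -0.0294 16   0.9139   0.9139
thymidine -0.5324 16   0.0338   0.0675
```

142 of 180 substrates separate from blanks; the planted uridine–UPP1
pair correlates at ρ = 0.62 in this seed and only uridine passes the
specificity panel at q ≤ 0.05 — the single-gene panel, not the global
ranking, is the robust readout at n = 16 (measured recovery rates are in
`docs/methods.md`). Downstream:

```text
$ python analysis/05_stratify_survival.py
survival cohort: 72 high / 73 low, 103 events
log-rank chi2 = 24.70, p = 6.71e-07

$ python analysis/06_trace_isotopes.py
uridine_ribose [ctrl]: M+0 = 0.308, M+5 = 0.593, others = 0.099, labelled = 0.692, ...
uridine_ribose [ko]:   M+0 = 0.977, M+5 = 0.005, others = 0.018, labelled = 0.023, ...

$ python analysis/07_quantify_tif.py
uridine: slope = 1.967e-03, r^2 = 0.9998, calibrated 1.2-5000 uM
TIF uridine: median = 18.4 uM (generated at 24.1 uM; IQR 17.7-18.9), n = 8, ...
```

The high-hazard arm of the survival cohort is clearly separated; the
tracing stage recovers the generating M+5-dominant distribution in the
control arm and near-zero labelling in the knockout-like arm; and the
fluid quantification recovers TIF-scale concentrations with the
low-concentration uncertainty that unweighted calibration carries
(`docs/methods.md`).

Everything is also scriptable through the CLI
(`nutriscreen simulate|kinetics|screen|correlate|stratify|trace|quantify|run`),
e.g. `nutriscreen run --config pipeline.yaml`; each stage reads and
writes plain CSV/TSV so stages can be re-run in isolation, and each run
directory carries its `config.yaml` and a `manifest.json` with SHA-256
hashes of every input and output.

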