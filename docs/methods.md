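# Methods

This note documents the models, conventions and numerical choices behind
`nutriscreen`, and what the synthetic campaign does and does not emulate.

## Kinetic readouts (λ, μ, A, AUC)

Each well of a phenotype-microarray plate yields a dye-reduction trace
s(t) (absorbance difference A590−A750, read every 15 min for 74.5 h by
default). The four readouts are nonparametric — no sigmoid is fitted:

- **smoothing**: centered moving median followed by centered moving mean,
  both over `window` points (default 5, i.e. 75 min), with symmetrically
  shrunken windows at the ends. `window = 1` disables smoothing. The
  median pass removes single-read spikes; the mean pass removes the
  staircase the median leaves.
- **A** (maximum height): max of the smoothed trace — the screen's main
  readout, carrying the well's maximum catabolic signal.
- **μ** (maximal slope): the largest OLS slope over all sliding windows
  of `window` points, floored at 0. Declining traces (dye bleaching)
  report μ = 0 rather than a negative uptake rate, because the screen's
  readout is utilization, not decay. With `window = 1`, slopes fall back
  to two-point secants.
- **λ** (lag): the tangent-intercept convention, λ = t\* − (s(t\*) − s₀)/μ
  evaluated at the center t\* of the max-slope window, clamped to the
  observation window; λ = t_last when μ = 0 (no growth means the lag
  never ended). On a noise-free logistic this recovers the generating
  lag to a few percent; on a straight line through the origin it is 0.
- **AUC**: trapezoidal integral of the smoothed trace.

All four are exactly equivariant: scaling the signal by c > 0 scales A,
μ, AUC by c and leaves λ fixed; adding b shifts A by b and AUC by b·T.
No baseline subtraction happens here — control-relative normalization is
deferred to the screen stage so the subtraction is exactly the
median-blank convention.

## RMA and HCM calling

RMA(substrate, line) = A(substrate, line) − median A of that line's
blank wells (after optional division by a per-line proliferation factor,
CyQUANT-style). RMA is kept signed: utilization *below* blank level is a
real class of calls. By construction, each line's blank RMAs have median
exactly 0 — with triplicate blanks one blank per line sits at exactly 0,
which makes the pooled-control reference slightly discrete and the HCM
test mildly conservative (measured null type-I ≈ 0.03–0.05 at nominal
0.05; see `scripts/acceptance.py`).

A substrate is a high-confidence metabolite (HCM) when its across-line
RMA vector differs from the pooled blank RMAs by a Wilcoxon rank-sum
test, run one-tailed in both directions; the direction is the smaller
tail and the reported p doubles it (capped at 1). Exact enumeration of
all C(n₁+n₂, n₁) midrank assignments is used when the combined sample is
≤ 12; otherwise the normal approximation with midrank tie correction and
continuity correction (the enumeration-wide gap between the two is
≤ 0.019 when both groups have ≥ 3 observations). Benjamini–Hochberg
across substrates at q ≤ 0.05 by default; `fdr=False` gates raw p.

Plate QC flags cell lines whose median raw A across substrates has a
one-sided robust z-score ((x − median)/(1.4826·MAD) across lines) above
3.5 — the plate-wide-shift failure mode. Zero MAD falls back to flagging
lines above the median, with a warning.

## Metabolite–gene correlation

Spearman ρ is the Pearson correlation of midranks; two-sided p from
t = ρ√((n−2)/(1−ρ²)) on n−2 df, with exact permutation enumeration
offered for n ≤ 9 (at ρ = ±1 the exact p is the permutation atom 2/n!).
Pairs are ranked by |ρ| so negative correlates surface; ties break
lexicographically. Pairwise-complete deletion handles missing values,
with n recorded per pair. The screen-scale path ranks and z-scores whole
matrices and takes one matrix product, which is what makes 100-seed
18,000-pair experiments affordable; it is verified pair-by-pair against
the scalar routine.

**Recovery at discovery scale.** With 16 cell lines and an 18,000-pair
search space, a planted pair at target correlation 0.85 (the scale of a
real discovery correlation, r ≈ 0.8) tops the ranking in only ~25% of
screens and lands in the top 3 in ~40% — the sampling noise of ρ at
n = 16 (≈ 0.29 on the Fisher-z scale) is comparable to the gap between
the effect and the extreme-value threshold of the null pairs (|ρ| ≈ 0.8).
This is a property of the discovery design itself, not of the
implementation; the substrate-specificity panel (one gene against the
nucleoside panel, BH within panel) is the robust readout, isolating the
planted substrate in ~85% of screens. Both rates are recomputed by
`scripts/acceptance.py`.

## Stratification, differential expression, survival

Median split sends strictly-above-median samples to "high" (ties low by
default, flippable). The halves split ranks by (score, sample-id) — so
it is invariant to input order — and sends the top ⌈n/2⌉ to "high"; a
145-sample cohort splits 72 low / 73 high, matching the reference cohort
sizes.

Differential expression is a per-gene Welch t on log2 values with BH
correction, replacing a moderated-t package: with tens of samples per
arm the empirical-Bayes variance shrinkage changes little, and the Welch
test keeps the stage free of any R dependency; the cost is some power at
very small n. Zero-variance degeneracies are explicit: equal means give
p = 1, unequal means give a sign-correct infinite statistic with p
floored at the smallest positive double and a flag.

Kaplan–Meier estimation and the two-group log-rank test (hypergeometric
variance, χ² on 1 df) are delegated to lifelines and cross-checked in
the tests against hand-computed product-limit and O−E tables.

## Isotope tracing

For an n-carbon metabolite the observed isotopologue areas are modelled
as M·x, where x is the tracer-derived MID and M is lower-triangular with
M[i,j] = C(n−j, i−j)·p^(i−j)·(1−p)^(n−i), p = 0.0107 (terrestrial ¹³C
abundance). Columns of M are binomial distributions and sum to 1 exactly,
so correction conserves total signal. The exact triangular solve is used
when it returns a non-negative vector; noisy spectra that go negative are
re-solved by non-negative least squares with a warning — clamping is a
data event worth seeing, not a silent fix. Corrected fractions are
renormalized to sum to 1. Only carbon is corrected: the tracer design
([¹³C₅] on a ribose ring) assumes ²H/¹⁵N/adduct envelopes are handled
upstream of the peak-area table. Summaries report labelled fraction
(1 − f₀), fractional enrichment (Σ i·fᵢ/n), and the "others" class
(1 − f₀ − f₅) used for 5-carbon tracers.

## Absolute quantification

External standard curves are unweighted OLS of normalized peak area on
concentration over a 2-fold dilution series from 5 mM to ~1 μM (13
levels); r² < 0.98 warns. Interpolation inverts the line; values outside
the calibrated range are flagged as extrapolated, never refused or
clipped, since interstitial-fluid levels can sit below the lowest
standard. **Low-end caveat:** with constant-CV (proportional) response
noise, unweighted OLS is dominated by the top standards, so the
intercept uncertainty translates into roughly ±10–25% error at the tens-
of-μM scale while mid-range points (≳50 μM) recover within a few
percent. A `--log` style weighted fit would cure this but the linear
convention is kept as the stage's defining contract; the TIF-scale
recovery actually achieved is reported by the acceptance script.

## Synthetic campaign: what it emulates, and what it does not

Generators (all `numpy` Generator-based, one independent stream per
generator derived from the master seed by stable sub-seeding, so outputs
are byte-reproducible and adding a generator never perturbs another):

- **Plates**: 96-well plates, one well per test substrate plus
  triplicate glucose (positive) and blank (negative) controls per plate;
  74.5 h at 15-min intervals. Test wells follow the three-parameter
  logistic s(t) = A/(1 + exp(4μ/A·(λ−t) + 2)) + baseline with additive
  Gaussian noise (sd 0.01 signal units); the logistic is the simplest
  generative model exposing all three readouts. Per-(line, substrate)
  amplitudes are lognormal around a per-substrate base (sd 0.4 log
  units) with a random 30% "consumer" boost ×1.8 per line; 20% of
  substrates are inert (true blanks). Declared outlier lines receive a
  uniform +0.5 plate shift, the QC target. Defaults: 16 cell lines, 180
  substrates (two plates per line), matching the discovery screen scale.
- **Expression**: planted genes are effect·z(true RMA) + √(1−effect²)·
  noise, affinely mapped to a log2-like range (mean 8, sd 1); the affine
  map preserves Spearman ρ so `effect` is the target correlation
  strength. Other genes are i.i.d. noise. The default planted pair is
  uridine–UPP1 at 0.85, the scale of the motivating discovery. Planting
  uses the *true* utilization matrix so measured RMA contributes
  realistic attenuation.
- **Spectra**: forward-convolution of true MIDs with the correction
  matrix, total intensity 10⁶, truncated Gaussian noise (sd 1% of total).
  Default design: a control arm with M+5-dominant labelling and an
  unlabelled knockout-like arm, 3 replicates each.
- **Survival**: exponential event times, hazard ln2/20 months⁻¹ for the
  low arm, ×hazard_ratio (default 2) above the score median; independent
  uniform censoring on [0, 80] months; 145 samples by default.
- **Standards**: linear responses (slope 2×10⁻³ per μM, intercept 0.05)
  with 2% proportional noise; TIF-like cohorts at uridine 24.1 μM and
  uracil 90.2 μM.

Not emulated: within-plate spatial covariance (wells are independent,
a modelling choice the real instrument does not guarantee), raw LC–MS
chromatograms, edge effects, batch drift, or non-exponential survival.
Passing tests therefore demonstrate correctness of the computations and
calibration under the stated noise model, not robustness to structured
real-world artefacts.

## Problem sizes and reproducibility

The test-suite and acceptance-script experiments run at the study's own
scale where that is what is being claimed (16 lines × 180 substrates ×
100 genes for recovery; 500 null substrates for calibration; 150/arm for
survival power; 145 for the cohort split) and at reduced plate reads
(30 h at 30-min intervals) for shared fixtures where only structure, not
power, matters. `scripts/acceptance.py --seed N --out f.json` recomputes
every headline number from scratch; identical seeds give byte-identical
pipeline outputs, hashed into each run's `manifest.json`.
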