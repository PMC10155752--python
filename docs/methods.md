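# Methods

spgkit analyzes barcode-count data from segmented spatial profiling
experiments that measure whole-transcriptome RNA and a high-plex protein
panel simultaneously in each area of interest (AOI). This note records the
statistical model behind each stage, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical choices
made where the design was open.

## Background model and normalization

Each analyte carries its own control probes: negative ISH probes for RNA and
three IgG isotype antibodies for protein. Their counts estimate the
AOI-specific background. Because probe counts are ratio-scale and
right-skewed, all background summaries are geometric: for AOI *i* with
negative-probe counts x₁…xₘ,

    geomean_i = exp(mean(log x)),   geosd_i = exp(sd(log x))     (sample SD, n−1)

The limit of quantification is

    LoQ_i = geomean_i · geosd_i^n_sd,    n_sd = 2 (default), floored at 2.

A gene is *detected* in an AOI when its raw count is strictly above LoQ_i.
Signal-to-noise normalization divides every count by the per-AOI geometric
mean of the analyte's control class:

    SNR_gi = count_gi / geomean_i(controls)

SNR detection thresholds are inclusive: protein SNR ≥ 3, whole-transcriptome
RNA SNR ≥ 4. Protein uses no LoQ; its detection runs on SNR alone.

Geometric statistics are undefined at zero, so counts are floored at 1
(`shift_counts`) exactly once before any geometric summary. Consequences
that the tests pin down: the control rows' SNR has per-AOI geometric mean
exactly 1; SNR is invariant to any per-AOI global scaling; LoQ scales
linearly when the negative probes are scaled (geometric SD is
scale-invariant).

## Detection filters

Filters run segment-first, then gene-level:

* **Segment filter** — an AOI is removed when less than 5% of the endogenous
  genes are above its LoQ (kept iff fraction ≥ 0.05).
* **Gene inclusion** (profile `general`) — a gene is kept iff detected in
  strictly more than 15% of surviving AOIs.
* **Gene exclusion** (profile `gbm`) — a gene is removed iff below LoQ in at
  least 10% of AOIs (inclusive).

The two gene rules differ in direction and strictness in the source
workflow; both are implemented as explicit modes rather than silently
reconciled, selected by profile. Boundary semantics (strict vs inclusive)
are asserted at exact boundary counts in the tests. The non-detection rate
for the exclusion rule is computed directly from the boolean matrix, not as
1 − detection rate, so boundaries are exact in floating point.

Replicate AOIs are averaged with the geometric mean by default because all
downstream concordance operates on log2 SNR and geometric averaging commutes
with the log transform; arithmetic averaging is available.

## Assay-performance metrics

* **Concordance** — Pearson r between unit profiles (cell lines, ROIs or
  targets) of log2 SNR, optionally restricted per pair to targets passing
  the detection threshold in the reference assay. Pairs with fewer than 3
  shared targets or a zero-variance profile are recorded as missing.
* **Identity matching** — each test unit is assigned the reference unit with
  maximal r; ties break by first column index and are reported. Accuracy is
  scored against the known identity.
* **Detection TPR/FPR** — against a truth set of expressed targets
  (reference expression > 1 on a TPM-like scale):
  TPR = |detected ∩ expressed| / |expressed ∩ assessed|,
  FPR = |detected \ expressed| / |assessed \ expressed|.
* **Sensitivity slope** — per unit, the OLS slope (with intercept) of
  log2(test SNR) on log2(reference SNR); slopes are averaged over units and
  the percent sensitivity change is (1 − mean slope) × 100. OLS with
  intercept, fit per cell line and then averaged, is the simplest reading of
  a "regression line slope" summary; the direction is fixed so a slope
  below 1 reads as a sensitivity loss in the test assay. Note that this
  metric carries the classical errors-in-variables (regression-dilution)
  offset: noise in the reference profile biases the slope below 1 even at
  attenuation 1, so recovery is judged against a Monte-Carlo oracle that
  shares the generative law, not against the nominal attenuation factor.
* **CV table** — per-target SD/mean (sample SD) of normalized expression,
  ranked descending; CV is scale-invariant, which the tests assert.
* **Clustering** — agglomerative clustering under correlation distance
  d = 1 − r after per-feature z-scaling, complete linkage by default
  (average available), deterministic leaf order.

## Differential expression

Both inference routes operate on log2 SNR, which makes fold changes additive
and directly comparable between routes; the estimate reported as log2FC is
the group-mean difference (t-test) or the segment fixed-effect coefficient
(mixed model).

* **Welch t-test** — two-sided, unequal variance, per target, with
  Benjamini–Hochberg adjustment applied within each analyte (the analyte
  families are reported separately; pooled adjustment is a flag).
* **Linear mixed model** — log2 SNR ~ intercept + segment, with a random
  intercept per tissue, fitted by REML (statsmodels MixedLM). This absorbs
  the repeated sampling of several ROI/AOI segments per tissue core. The
  segment contrast uses a t statistic with Satterthwaite degrees of
  freedom: df = 2g²/(∇g′A∇g) where g(θ) is the contrast variance as a
  function of the variance components θ = (σ²_tissue, σ²_resid), the
  gradient is numerical, and A is the inverse observed information of the
  REML criterion (finite differences; the REML profile for a random
  intercept factors in closed form per tissue). The df is clipped to
  [1, n − p]. A normal-approximation z-test is available via
  `df_method="normal"`. No Python package exposes Satterthwaite df for
  mixed models, hence the in-package implementation.
* **Degenerate fits** — when the tissue variance collapses to zero the
  model falls back to the fixed-effects-only OLS t-test for that target
  (flag `fixed_only`); non-convergence yields a missing p (flag
  `no_convergence`). Estimated variance components are reported per target
  (`re_var`, `resid_var`).
* **Tiers** — a pure function of (p, FDR): `fdr001` (FDR < 0.001), else
  `fdr05` (FDR < 0.05), else `p05` (p < 0.05), else `ns`. Headline target
  lists use FDR < 0.001 and fold change strictly > 2.
* The combined volcano table concatenates the RNA and protein tables with
  an analyte flag and −log10 p, erroring on duplicated (target, analyte)
  pairs.

In a balanced design the mixed model's fixed-effect estimate equals the
group-mean difference exactly, so the zero-random-variance limit reproduces
the t-test log2FC to machine precision — a property the tests assert.

## Synthetic data generator

No public dataset accompanies this assay family, so the generator is
first-class: it produces the two study designs with a complete planted-truth
manifest (reference expression, attenuation factors, planted effects,
random-intercept draws, config echo, seed) sufficient to regenerate any
dataset bit for bit.

**Count law.** Negative binomial in the mean/size parameterization
(variance = m + m²/k). The platform publishes no generative model; the NB is
the standard overdispersed choice for probe counts and is documented here as
a stand-in, not a validated noise law. Endogenous targets have mean

    m = background_mean + capture_scale · attenuation · reference

and control probes have mean `background_mean` independent of expression.
The background enters additively (nonspecific binding adds to, rather than
replaces, specific signal). Reference expression is TPM-like: an expressed
fraction drawn as 1 + lognormal(μ, σ) (strictly above 1), the rest a point
mass at 0.1, so the expressed/not-expressed partition at reference > 1 is
clean by construction.

**Cell-pellet-array design** (`simulate_cpa`): 45 cell lines with 2
replicate 200-µm AOIs per line by default, three paired conditions — an
RNA-only control, a protein-only control, and the dual-analyte condition
whose endogenous means are attenuated by analyte-specific factors. The
default attenuations (0.85 RNA, 0.89 protein) encode the observed 15% and
11% sensitivity losses of dual-analyte profiling relative to single-analyte
controls. Defaults use 500 genes, 30 negative probes, 56 proteins and 3 IgG
controls — a desk-scale panel preserving the panel-composition ratios.

**Segmented-tissue design** (`simulate_tissue`): tissues × ROIs × segments
(default 6 × 4 × {CD45, GFAP}); per-target log2 signal = baseline + planted
segment effect (on the second segment label, for a `de_fraction` of
targets) + a per-(tissue, target) Gaussian random intercept with SD
`tissue_re_sd`. The intercepts are drawn per target, not shared across
targets: a single shared per-tissue scalar would make per-target p-values
perfectly dependent (and would cancel in SNR entirely if applied to control
probes too), defeating calibration testing. The manifest records the full
tissue × target intercept table.

**Randomness.** One master seed; every component draws from its own
`numpy` PCG64 stream derived via fixed `SeedSequence` spawn keys, so
identical configs reproduce identical datasets across runs and platforms.

**What the generator does not emulate.** No spatial coordinates or imagery,
no staining chemistry beyond the attenuation scalar, no probe-specific
efficiency differences (uniform capture scale), no between-slide batch
effects, no sequencing-depth variation beyond NB noise. Passing tests
therefore demonstrate correctness of the statistics under a clean
overdispersed-count law, not robustness to every artifact of real tissue
data.

## Calibration experiments and problem sizes

The inference checks run on configurations chosen so the quantity under
test is identifiable rather than confounded by the normalizer:

* The SNR denominator is itself estimated from control probes; its sampling
  noise is shared by all targets of an AOI and acts as an unmodeled
  AOI-level random effect. Calibration experiments therefore use 120
  negative probes with background mean 50 — the scale of a real
  whole-transcriptome panel's negative-probe set — which makes the
  denominator noise negligible. With few negative probes the t-test null
  distribution is visibly distorted; this is a property of SNR
  normalization worth knowing when interpreting real data.
* Effect-recovery experiments use expressed-only targets with signal well
  above background (capture 200 vs background 50), because the additive
  background compresses fold changes of background-dominated targets
  toward zero — again a real phenomenon, not an implementation artifact.
* Null-calibration: 2000 targets for the t-test uniformity check (KS at the
  1% critical value), 1000 targets for the mixed model's rejection rate at
  the nominal 5% level (exact binomial band), using an 8-tissue × 6-ROI
  design so the Satterthwaite approximation operates with adequate degrees
  of freedom.
* Sensitivity-slope recovery: 40 lines × 100 proteins × 2 replicates, 20
  implementation seeds against 30 oracle seeds, compared through a
  two-sample 95% band.
* Identity matching: 20 lines × 100 proteins at capture 10, where the
  matched line's correlation strictly dominates every mismatched line
  (asserted directly before scoring).

These sizes keep the full suite around 1–2 minutes while leaving the
Monte-Carlo bands well inside the asserted tolerances.

## Known limitations

* The LoQ exponent (2) and floor (2) follow the convention of the standard
  platform analysis workflow; the assay vendor's exact constants may vary by
  panel.
* The Satterthwaite information matrix is numerical; for pathological fits
  it falls back to the residual df rather than failing.
* The mixed model supports exactly two segment levels (the designs analyzed
  here); multi-level contrasts would need a small extension.
* TPR/FPR require both truth classes present among assessed targets;
  degenerate truth sets raise rather than returning 0/0.
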