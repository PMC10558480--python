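# Methods

## Scope and observation model

`seasonfc` analyzes seasonal variation in derived measures of
resting-state brain activity. Its inputs are region-averaged BOLD time
series (timepoints × regions, with a GM/WM tissue class and a
functional-network label per GM region), a subject table (sex, acquisition
season, year), and optionally a season-year environment table. Subjects
are grouped into the four acquisition quarters — spring Feb 1–Apr 30,
summer May 1–Jul 31, autumn Aug 1–Oct 31, winter Nov 1–Jan 31 — with a
winter attributed to the year in which it starts (January scans carry the
preceding year). Everything upstream of region-averaged signals (scanner
preprocessing, physiological nuisance regression, atlas geometry) is out
of scope; region membership is configuration, not shipped atlases.

## Signal preparation

- **Bandpass filter**: 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`) so it is zero-phase; phase-shifting filters would distort
  inter-regional correlation. Default band 0.01–0.1 Hz. The filter family
  and order are package choices (no canonical choice exists for this step)
  and are recorded in the pipeline configuration hash.
- **Normalization**: each region is demeaned and scaled to unit sample
  variance (ddof = 1). Demeaning is harmless for variance normalization
  and required by Pearson correlation anyway.
- **Wiring rule**: connectivity and graph measures use filtered +
  normalized signals; spectral measures use normalized but *unfiltered*
  signals, because fALFF's denominator spans all frequencies above
  0.01 Hz and would be emptied by the filter. This rule is enforced by the
  pipeline and covered by wiring tests.
- **Nuisance control**: sex is regressed out of every *derived* measure
  (not the raw series) by OLS on [sex, intercept], residuals + grand mean.
  The operation is idempotent and leaves measures orthogonal to the
  centered covariate.

## Spectra and fALFF

Welch's method with 8 segments, 50% overlap, Hamming taper (the common
pwelch defaults; configurable), no detrending, density scaling. The
segment length is ⌊N/(k(1−v)+v)⌋ for k segments at overlap v, i.e.
⌊N/4.5⌋ = 266 samples for N = 1200 — a frequency resolution of
1/(266·0.72 s) ≈ 0.0052 Hz.

fALFF is defined as **band-total** power in 0.01 ≤ f ≤ 0.08 Hz divided by
band-total power at f > 0.01 Hz (strict lower edge, up to Nyquist). The
totals-based ratio is the fraction of supra-0.01 Hz power that is
low-frequency: it is scale-invariant, lies in [0, 1], equals the
bin-count ratio ≈ (0.08 − 0.01)/(Nyquist − 0.01) ≈ 0.106 for a flat
spectrum at TR = 0.72 s, and matches the field's standard usage. A ratio
of per-bin *means* was considered and rejected: it would be 1 for any
flat spectrum and could exceed 1, losing the power-fraction
interpretation. The numerator edge is inclusive and the denominator edge
exclusive; on the Welch grid no bin falls exactly on 0.01 Hz, so the two
bands differ only above 0.08 Hz.

## Connectivity summaries

Pearson correlation between all region pairs of the two sets; Fisher
Z = artanh(r) element-wise with |r| clipped at 1 − 1e−7 (clipping events
are logged) so duplicate or self regions cannot produce infinities.
Summaries are means of |Z|:

- cross-tissue (WM × GM): all elements;
- within-tissue (GM–GM, WM–WM): upper triangle only, diagonal excluded —
  including the unit diagonal would add a constant inflation; the choice
  is configurable (`exclude_diagonal`);
- per network: all WM rows × that network's GM columns;
- per GM region: mean |Z| over WM rows (a tabular connectivity map).

The network summaries exactly recombine to the global mean when weighted
by column counts, which the tests exploit as a partition identity.

## Graph topology

Square correlation matrices (GM–GM, WM–WM, GM ∪ WM) are thresholded at
r = 0.2 and binarized. Thresholding acts on correlations, not Z values,
and by default keeps only r > τ (negative correlations give no edge); an
absolute-value mode exists because the treatment of negative correlations
is a genuinely open choice. Metrics: density 2m/(N(N−1)); transitivity by
the trace formula tr(X³)/(Σᵢⱼ(X²)ᵢⱼ − tr(X²)); global efficiency as the
mean inverse shortest-path over ordered pairs with 1/∞ = 0;
characteristic path length as the mean shortest-path over mutually
*reachable* unordered pairs. Shortest paths come from
`scipy.sparse.csgraph` (unweighted mode, BFS-equivalent). A graph with no
connected triplet has undefined transitivity: the default is an error so
degenerate configurations surface loudly, with an opt-in 0 convention;
an edgeless graph makes characteristic path length an error always. All
four metrics are validated against exact rational-arithmetic oracles
(triplet enumeration, integer Floyd–Warshall) and against networkx.

## Seasonal inference

Quarter coding t = 0..3, period mathematically set to 4, ω = 2π/4.
Subjects are the observation unit throughout; group means are used only
for plotting. The cosinor is OLS of the adjusted measure on
[1, sin ωt, cos ωt]; amplitude A = √(a²+b²) and phase ϑ = atan2(−a, b)
(so b = A cos ϑ, a = −A sin ϑ, ϑ ∈ (−π, π]); periodicity is the joint
F-test of the two harmonic terms, df (2, n−3). The 95% band is the
standard OLS pointwise band for the mean response over continuous
t ∈ [0, 4). Effect sizes: Cohen's f = √(η²/(1−η²)) for ANOVA and
√(R²/(1−R²)) for regression F-tests — the conventional
explained-variance forms; pairwise contrasts use pooled-variance
Student's t with pooled-SD Cohen's d and no multiplicity correction by
default (a correction can be applied downstream). Environmental
regression replaces the harmonic regressors with season-year mean
temperature and daylength; a rank and condition-number guard (cond >
1e10) rejects collinear designs, and an optional whole-quarter lag shifts
the covariate lookup backwards for exploration.

## The synthetic cohort generator

No accepted generative model of seasonal BOLD modulation exists, so the
simulator is deliberately minimal and every choice is its own, not a claim
about real physiology:

- Each subject's region matrix is X = g(s)·(latents·loadingsᵀ) + noise:
  `n_latents` (default 3) white-noise signals bandpass-filtered to
  0.01–0.08 Hz and standardized, coupled through N(0, loading_scale²)
  loadings drawn **once per cohort** so the connectivity backbone is
  shared, plus i.i.d. N(0, noise_sd²) noise.
- The seasonal gain g(s) = 1 + A·cos(2πs/4 + φ), A ∈ [0, 1), multiplies
  the latent component only, so a single parameter jointly raises
  low-frequency power (fALFF) and inter-regional correlation — the joint
  modulation the analysis is designed to detect — without asserting a
  mechanism.
- Defaults reproduce the reference cohort structure: 127/99/91/93
  subjects over winter/spring/summer/autumn (two acquisition years,
  winters spanning the year boundary), ~60% female, 90 GM regions in 14
  networks plus 48 WM bundles, 1200 volumes at TR = 0.72 s, and A = 0
  (no injected effect) unless an experiment sets one.
- Sex enters only as an additive offset on derived measures (a
  simulation-only hook the pipeline applies when ground truth is
  present), which is exactly what is needed to exercise residualization.
- Environmental series follow mean + amplitude·cos(2π(t − peak)/4) over
  season-years (defaults plausible for a mid-latitude continental site:
  13.5 ± 12.5 °C, 12.2 ± 2.6 h, summer peak) plus small seeded per-year
  deviations (1 °C, 0.1 h). Without those deviations temperature and
  daylength would be *exactly* collinear over four season values and no
  two-covariate regression could run; real weather varies between years,
  so the jitter also improves realism. Setting the jitter and amplitude
  to zero still produces the rank-deficiency error a degenerate design
  should raise.

What the simulator does **not** emulate: hemodynamic response shape,
spatial autocorrelation and atlas geometry, physiological noise, motion,
scanner drift, subject-level heterogeneity of the connectivity backbone,
and any asymmetric (non-sinusoidal) seasonal shape. Passing tests
therefore demonstrate that the analysis recovers effects *of the assumed
form* at realistic sizes — not that real seasonal physiology has this
form.

## Validation experiments and problem sizes

All experiments run through the package's own code path and are seeded.

- Graph oracles: 200 Erdős–Rényi graphs, N ≤ 12, p ∈ {0.2, 0.5, 0.8},
  compared to rational-arithmetic enumeration at 1e−12 (float summation
  order is the only source of discrepancy).
- White-noise fALFF: 50 realizations of 1200 samples at TR = 0.72 s
  against the analytic flat-spectrum bin ratio.
- Cosinor exact recovery: the four-point design y = (3, 2, 1, 2) has the
  closed-form solution a = 0, b = 1, c = 2, A = 1, ϑ = 0 (zero residual).
- Cosinor Monte-Carlo recovery: 200 replicates of n = 100/season with
  A = 0.1 on unit-noise measures, autumn-peak phase. Note the statistical
  ceiling at this signal-to-noise: the F(2, 397) noncentrality is
  n·A²/(2σ²) = 2, which caps power near 0.23, and the amplitude estimator
  √(â²+b̂²) is Rice-distributed with a substantial upward bias
  (E[Â] ≈ 0.13) because the coefficient standard error √(2/n) ≈ 0.071 is
  comparable to A itself. The harness reports the honest measured values;
  tight amplitude recovery and 0.8 power at this n would require roughly
  A ≈ 0.22 or σ ≈ 0.46.
- Type-I error: 2000 null cohorts (A = 0, no sex effect), 10
  subjects/season, 4 GM + 2 WM regions, 256 timepoints — small cohorts
  because null rejection rates do not depend on cohort scale; both the
  ANOVA and the cosinor F-test are checked against the nominal 5%.
- Directional reproduction: 100 replicates of n = 100/season with a 30%
  autumn-peaking gain, 6 GM + 4 WM regions, 1200 timepoints, run through
  the pipeline (connectivity battery); checks that the fitted curve of
  global GM–WM mean |Z| peaks in autumn and that autumn > summer is
  significant. Region counts are scaled down from the full parcellation
  to keep replicated runs cheap; the injected contrast acts at the
  subject level, so the operating characteristics are governed by n and
  the timepoint count, which are kept at full scale.
- Determinism: two complete pipeline runs with identical configuration
  and seed must produce byte-identical output tables; the config hash
  excludes only the output directory.

## Numerical choices and degenerate inputs

- Constant region signals are rejected by name in normalization and
  correlation (detected by exact zero range, robust to float summation).
- Perfect cosinor fits (zero residual) report F = ∞, p = 0; constant
  inputs report A = 0, F = 0, p = 1.
- Very short series reduce the forward–backward filter's reflection
  padding rather than erroring; Welch requires a segment length of at
  least 8 samples.
- Cohort serialization is plain CSV/JSON; floats round-trip exactly
  (shortest-repr writing, `float_precision="round_trip"` reading).

## Known limitations

- The gain model conflates amplitude and connectivity modulation by
  construction; it cannot distinguish which the analysis is detecting.
- Season is a four-level factor: the cosinor has only one harmonic and
  cannot represent asymmetric seasonal shapes (nor can any model on four
  points beyond three free parameters).
- Environmental covariates are near-collinear by nature; inference on
  their separate coefficients is fragile even with the condition guard.
- Graph metrics are computed on binary graphs at a single threshold;
  no proportional-threshold sweeps or weighted variants are provided.
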