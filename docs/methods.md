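# Methods

This note documents the models, defaults, and numerical choices behind
`symbiotherm`, and what the synthetic-data tests do and do not establish
about real data.

## Thermal dose

Loggers record seawater temperature at 15–120 s cadence per container.
Daily summaries are calendar-day means in the logger's local clock;
partial first/last days are included with their observation count
recorded. Bath-vs-container bias is corrected by subtracting the pooled
mean difference of paired spot measurements (one pooled offset per
treatment, matching a protocol of repeated spot checks over the
experiment).

Experimental degree heating weeks accumulate |daily mean − MMM| over days
whose mean strictly exceeds MMM + 1 °C, divided by 7 to convert °C-days
to °C-weeks (the standard degree-heating-week convention; the divisor is
exposed as a parameter). MMM defaults to 25 °C, the pre-experiment
holding temperature. Ramp days are treated by the same rule as hold days.
Accumulation is sequential in day order, so the result is bit-identical
to a literal day-by-day loop. eDHW is monotone under appended days,
invariant to reading cadence given identical daily means, and zero
exactly when no day crossed the threshold.

## Respirometry

**Slope extraction.** The published protocol subsets the linear portion
of each O₂ trace by eye; we replace this with a reproducible rule: among
all windows of 5–10 min starting ≥30 s after the light transition, take
the OLS slope of the window maximizing R², breaking ties toward the
earliest start and then the longest window. The search is exhaustive over
admissible (start, end) index pairs. An all-constant trace reports slope
0 with R² = 1 by convention (a perfect fit to a flat line). Note one
consequence: on near-flat traces (blanks, below-LOD animals) maximizing
R² selects the most trended window, which inflates the spread of
estimated blank slopes relative to naive full-trace regression; the
limit-of-detection band (below) inherits that spread on both sides, so
the comparison remains fair.

**Blank correction and LOD.** Mean blank slope per (temperature, light)
is subtracted from each animal's slope. Animals whose uncorrected dark
slope falls within ±1 SE of the dark-blank mean are below the limit of
detection and excluded from metabolic summaries; the SE requires ≥2 dark
blanks (4 per treatment by default).

**Units.** Slopes (µmol l⁻¹ min⁻¹) × vial volume (0.004 l) → µmol min⁻¹,
divided by host protein (µg) → µmol min⁻¹ µg⁻¹.

**Smooths.** Both the per-animal photosynthesis–irradiance fit and the
across-animal thermal-performance fit use a penalized cubic B-spline with
a second-order difference penalty, penalty weight selected by generalized
cross-validation on a log grid (10⁻⁸…10⁸, 81 points); the effective
degrees of freedom is the hat-matrix trace. The basis dimension is
min(n−1, 5) — only 6–7 light levels and 4 treatment temperatures exist —
and with fewer than 5 distinct covariate values the fit falls back to an
ordinary quadratic (so the 4-temperature thermal fit is a quadratic,
which is also the generating form of the synthetic truth). Predictions
are evaluated on 512-point grids restricted to the observed covariate
range; the smooth is never extrapolated, and P_max is the maximum of the
prediction over the observed light range (a deliberate choice — the
alternative of extrapolating beyond 270 µmol m⁻² s⁻¹ has no data
support).

**T_opt.** The optimum is the location where the finite-differenced
first derivative of the thermal smooth crosses zero from + to −
(linearly interpolated between grid points; if several crossings exist
the one with the highest predicted value wins), or the boundary maximum
when no interior crossing exists. LEDR is stored as the signed dark
slope; its thermal optimum is fitted on the consumption magnitude, so
"maximum LEDR" means strongest respiration. The SE comes from a
nonparametric bootstrap over individuals (200 resamples by default,
seeded generator; resamples with <3 distinct temperatures or degenerate
values are skipped and the realized count reported). The original report
prints an optimum ± error without stating the method; the bootstrap is
our choice and is labeled as such in outputs.

## Intracellular pH

The two-channel SNARF-1 ratio uses per-channel scalar background
subtraction — the simplest reading of "normalized to background
fluorescence"; division-based normalization is a known alternative in
the protocol lineage and this assumption is flagged here. Ratio
orientation is 585/640 by default (the calibration handles either
orientation automatically since only monotonicity is required).

Calibration fits a four-parameter logistic in pH (asymptotes, midpoint,
slope) by least squares; exactly three standards fall back to a straight
line. Standards must span ≥1 pH unit, and a trend reversal (|Pearson r| <
0.9 with non-monotone differences) or a non-monotone fitted curve is an
error. Conversion inverts the fitted map by bisection (xtol 10⁻¹²;
round-trip error <10⁻⁶ within range); ratios outside the calibrated
range (±1% of its width) are excluded rather than extrapolated, with the
reason logged. Cells are the unit of observation and animals the unit of
replication: each animal is summarized by the median pH of its cells per
class, and groups with zero usable cells are omitted, never reported as
NaN.

## Isotopes

δ¹³C ↔ atom-% uses the VPDB ratio 0.0111802 — a standards convention,
not a value fitted here; both input pathways (facility-reported atom-%
or δ) are accepted. The pulse-validation contrast fits a one-way model
over three groups (symbiont fraction, symbiotic host, aposymbiotic host)
and declares the pulse successful when both orderings symbiont > host
and host > aposymbiotic are Tukey-significant with the correct sign.
Missing groups produce a partial report with warnings rather than an
error.

## Statistics

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with all candidates fitted by maximum
likelihood so fixed-effect structures are comparable; k counts
coefficients plus variance components plus the residual variance. Mixed
models use a single container random intercept (statsmodels MixedLM;
optimizers tried in order bfgs → lbfgs → cg, as the default optimizer
occasionally returns a singular Hessian on small balanced designs).
Ranking ties break toward fewer parameters. Spline candidates use the
smoother above with k = ⌈edf⌉ + 1, a pragmatic approximation.

Tukey HSD contrasts use the studentized range with k = number of group
means and the model's residual df (for mixed models, a containment-style
n − k approximation, documented as approximate); with two groups this
reduces exactly to the pooled t-test. The compact letter display assigns
letters to maximal cliques of the non-significance graph — exact for the
factor sizes here (≤8 levels), rather than the insert-absorb heuristic.

PERMANOVA partitions the squared Euclidean distance matrix of z-scored
variables: F = (SS_among/(g−1))/(SS_within/(n−g)), with free (fully
unrestricted) permutation of row labels from a seeded generator and
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) (999 permutations by default).
Ties at F_obs are counted with a 10⁻¹² absolute guard so permutations
reproducing the observed partition are never lost to rounding;
consequently the minimum attainable p is governed by the number of
distinct partitions, as in any permutation test. Container structure is
not respected in the permutations (the original analysis does not state
that it was). PCA is the SVD of the centered, unit-variance matrix
(scaling is on by default and configurable, since the original report
does not state whether variables were scaled).

## Synthetic experiment

The generator mirrors the study design: two cohorts — high symbiont
density (HD, 1.05×10⁶ cells animal⁻¹) and low (LD, 2.69×10⁵) — × four
nominal temperatures (25/27/29/31 °C) × two symbiotic states × four
containers × 3–4 animals, over an 18-day calendar (days 0–2 acclimation,
then 1 °C day⁻¹ ramp and hold). Defaults: logger noise σ = 0.15 °C
(within the stated logger accuracy), 120 s cadence, container offsets
~N(0.15, 0.05) °C.

Metabolic truth is parameterized on the measurable envelopes: the net
saturated photosynthetic rate is `net·(1 − ((T − 26.4)/6)²)` and dark
respiration magnitude `resp·(1 − ((T − 27.2)/6)²)` (net = 1.2, resp =
0.4 µmol l⁻¹ min⁻¹ at vial scale), combined through a hyperbolic-tangent
irradiance law saturating at 60 µmol photons m⁻² s⁻¹ — so the named
optima are the optima of exactly the quantities the pipeline recovers.
The quadratic-about-the-optimum form is the simplest peaked thermal
performance curve; tanh is the standard saturating P–I form. Traces get
AR(1) measurement noise (σ = 0.02 µmol l⁻¹, ρ = 0.3); blanks have
near-zero slopes (σ = 0.003), and two aposymbiotic animals per treatment
are constructed with dark slopes at the blank mean (σ = 0.0003) to
exercise LOD flagging — because the flag is a band-membership test on
noisy estimates, the number actually flagged varies by seed, as it would
in a real experiment.

pH truth declines linearly by 0.30 units from 25 to 31 °C (symbiocytes
7.35 → 7.05, non-symbiocytes 7.45 → 7.15), with animal-level σ = 0.05
and cell-level σ = 0.10; cell counts are drawn uniformly from the
protocol ranges (9–22 symbiocytes, 7–38 non-symbiocytes). Intensities
are back-computed through a decreasing logistic calibration
(asymptotes 2.2/0.6, midpoint pH 7.2, slope 0.4) with 1% multiplicative
channel noise. Isotope truth places symbiont excess above host excess
above aposymbiotic ≈ natural abundance, with the HD host excess
declining toward the top temperature and LD flat (lognormal σ = 0.15 on
the excess); the pulse itself (31.22 µmol l⁻¹ NaH¹³CO₃, 7 h pulse, 12 h
chase) is design metadata. Phenotype truth: HD loses symbionts
dose-dependently to 50% at 31 °C, LD is flat, aposymbiotic counts are
near zero (2×10⁴), LD animals carry more protein (1500 vs 800 µg), and
containers carry lognormal random intercepts (σ = 0.1 log-units) so
mixed-model selection has signal to find.

One master seed spawns independent child streams; the same seed yields a
byte-identical experiment, and the truth is serialized beside the data.

**What passing recovery tests does not show.** The generator's noise is
well-specified (Gaussian/lognormal, known autocorrelation), its thermal
curves are exactly the family the fits can represent, and its blanks are
unbiased. Real optode drift, non-stationary mixing artifacts, dye-loading
heterogeneity, ROI-selection bias, and container confounding beyond a
random intercept are not emulated, so recovery here bounds estimator
correctness, not field robustness.

## Problem sizes

Simulation-based checks use 100 traces for slope recovery, 50
experiments (8 animals × 7 temperatures) for T_opt recovery, 20
experiments for pH recovery and for the integration pattern check, and
500–1000 null runs at 199 permutations for PERMANOVA calibration —
sizes chosen to keep Monte-Carlo error well below the tolerance each
check asserts.

## Known limitations

* Mixed-model Tukey df uses the containment approximation, not
  Kenward–Roger/Satterthwaite.
* The GAM candidate in model selection supports a single smooth covariate
  without factor interactions.
* The P–I smooth's edf for 6–7 points rarely exceeds 3–4; subtle
  photoinhibition shapes would need more light levels.
* Only Euclidean PERMANOVA distances are implemented.
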