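# Methods

## The measurement problem

Immersive 360° VR can induce simulator sickness (SS) — dizziness, difficulty
focusing, eye strain — and the practical question for medical education is
whether that sickness degrades skill acquisition, and through what
physiological route. The package models one candidate route: sickness
severity (measured by the 16-item Simulator Sickness Questionnaire, SSQ)
drives a late-session autonomic response visible as very-low-frequency (VLF)
power of heart-rate variability, which in turn predicts the
physical-examination component of a Mini-CEX assessment, with the NASA-TLX
frustration subscale modulating the transmitted effect.

## HRV spectral estimation

RR intervals come either from supplied tachograms or from R-peak detection
on single-lead ECG (band-pass 5–30 Hz, squared derivative smoothed over
150 ms, refractory period 250 ms, peak refinement on the raw trace). The
detector is validated against generator ground truth: noiseless synthetic
ECG is recovered to within two samples at 1024 Hz, and ≥ 99 % of beats are
recovered at a noise SD of 5 % of the R-wave amplitude.

Artifact handling flags, and never deletes, intervals outside 300–2000 ms or
differing from the previous valid interval by more than 20 %. Both bounds
are package conventions (common Holter practice); the cleaning rule is
idempotent, and a flagged fraction above 20 % raises a warning so the epoch
can be rejected downstream. Flagged beats are bridged by the interpolating
spline rather than concatenated out, keeping the time base intact.

Each epoch (consecutive 5-minute windows; half-open [start, end), an
interval belongs to the epoch of its terminating beat) is analysed as:
cubic-spline interpolation of valid intervals to an even 4 Hz grid, linear
detrend, Hann window with power normalisation, one-sided periodogram, and
rectangular integration of the PSD over VLF [0.003, 0.04), LF [0.04, 0.15),
HF [0.15, 0.4) and TP (0, 0.4] Hz. Half-open band edges avoid
double-counting shared boundaries; the DC bin is excluded from total power.
Epochs need ≥ 60 valid beats spanning ≥ 240 s. The 4 Hz / cubic-spline
choice follows common short-term-HRV practice and makes 0.4 Hz comfortably
resolvable; a plain Hann periodogram (not Welch) is used because epochs are
exactly five minutes and variance preservation matters for the Parseval
check: integrated TP equals the windowed, detrended tachogram variance
within 2 % (property-tested over 100 seeds). Time-domain and nonlinear HRV
indices, and ultra-short (< 5 min) analysis, are deliberately out of scope.

## Instruments

* **SSQ**: 16 symptoms rated 0–3; total = (Σ ratings) × 3.74; categories
  none (0), mild (0 < total ≤ 20), significant (> 20). Subscale *membership*
  (nausea / oculomotor / disorientation) uses the standard Kennedy
  symptom-to-subscale mapping; weighted subscale scores are intentionally
  not computed because the simplified ×3.74 total is the instrument's rule
  here. Temporal severity is the most-representative-symptom rating at
  minutes 0, 2, 4, 6, 8, 10.
* **NASA-TLX**: six raw subscales on a 0–20 visual-analogue scale, no
  pairwise weighting; analysed per subscale and against the scale midpoint
  10 as reference.
* **Mini-CEX**: seven competencies each 1–9 (total 7–63) plus teacher and
  learner satisfaction 1–9. All scorers validate ranges strictly and name
  the offending item; nothing is clamped on input.
* **Motion profile**: the learning video's per-timestamp motion degree
  (0 sitting still / 1 slightly / 2 moderately fast-moving); the
  motion–sickness association is the Spearman correlation of pooled
  (degree, severity) pairs across participants and timepoints, reported as
  degenerate when either pooled variable has zero variance.

## Statistical screen

Each sample is routed by the D'Agostino–Pearson omnibus test (normal iff
p ≥ .05; samples below n = 8, where the test is undefined, and
zero-variance samples are forced to the skewed route, and a `route=`
override exists for pre-specified analyses). Normal data use t tests and
mean ± SD summaries; skewed data use Mann–Whitney U / Wilcoxon signed-rank
and median [IQR] (25th–75th percentiles, linear interpolation). Mann–Whitney
p-values are exact (no ties, min(m, n) ≤ 10) or normal-approximated with
tie and continuity correction; Fisher's exact two-sided p sums
hypergeometric tables no more probable than the observed one. Correlations
are Spearman (average ranks, t-approximate p) or point-biserial when exactly
one variable is dichotomous. All p-values are two-sided; the screen records
significance at p < .01 — a deliberately strict threshold in place of a
formal multiplicity correction — while the multilevel stage uses .05. The
gated comparison pipeline holds its type-I error near nominal under null
simulation (2000 replicates at the study's 10/18 split).

## Multilevel moderated mediation

All legs are Gaussian linear mixed models estimated by **maximum
likelihood** (not REML) so deviance differences between nested fits form
valid likelihood-ratio statistics: total Y ~ X; mediator M ~ X; outcome
Y ~ X + M (the X coefficient is the direct effect c′); moderated
Y ~ X + M + W + M×W, dropping the interaction if inestimable. Clustering is
a caller-supplied column; for a one-row-per-participant table the default
two-level framing groups by sickness status, and repeated-measures tables
can group by participant instead. Optimisation goes through statsmodels'
MixedLM with several optimisers; the marginal log-likelihood and the
fixed-effect covariance (X′V⁻¹X)⁻¹ are then re-evaluated in closed form at
the fitted variance components, which stays finite where the optimiser's
Hessian is singular on the variance boundary (e.g. two clusters with
σ²_between → 0). When the likelihood is flat across candidate fits — one
observation per cluster identifies only the variance total — the tie breaks
to the boundary σ²_between = 0, where fixed effects coincide with ordinary
least squares. Deviance self-consistency (−2 × direct log-likelihood at the
returned parameters, to 1e-4) is asserted in the test suite, and ML variance
components were cross-checked against lme4 on identical data during
development.

ICC(1,1) = σ²_between / (σ²_between + σ²_within). Likelihood-ratio tests
report the deviance difference against χ²(df) with the conventional χ²(1)
5 % point 3.84; for a variance component on the boundary a 50:50 χ² mixture
is the modern recommendation, but the plain χ²(1) reference is the default
convention here. Mediation is concluded by joint significance of the a and
b paths at two-sided p < .05 (the primary rule); a cluster-resampling
bootstrap CI for the indirect effect a·b is available but off by default.
Negative LR statistics (numerically worse larger model) are clamped to zero
and flagged. Normalisation is the z-score with the n−1 SD; zero-variance
columns raise rather than silently passing through — an all-sickness-negative
cohort therefore surfaces as a degenerate mediation stage, not a result.

## Synthetic cohort generator

The generator is the package's test bed and default input. Its defaults
emulate the study conditions: 28 participants, 10 sickness-positive (36 %),
ages 23–26 with median 24, 8 of 28 female, and three 5-minute epochs
(baseline, minutes 0–5, minutes 6–10 of the video).

**Physiology.** An RR tachogram is a mean interval plus one sinusoid per
band at the band's geometric-centre frequency (≈ 0.011, 0.077, 0.245 Hz),
with amplitude √(2·power) so each sinusoid contributes the closed-form A²/2
to its band — the oracle for all spectral tests; round-trip recovery is
within 15 % averaged over 20 seeds, and a single epoch within 10 %. An
optional broadband white term adds `noise_fraction` × (VLF+LF+HF) of extra
variance spread over the whole spectrum (default 0.1 in cohort profiles, 0
for oracle profiles), so implied total power exceeds the band sum by about
a fifth of that fraction inside the TP band. Synthetic ECG places a
stylised unit QRS template at the beat times; morphology beyond a
detectable QRS (P/T waves, respiration, circadian structure) is
deliberately not modelled.

**Dependence.** Five latent variables — sickness severity, late-epoch VLF
shift, physical demand, frustration, physical-examination skill — follow a
Gaussian copula whose pairwise rank correlations are configuration
(defaults: severity–VLF 0.56, severity–physical-demand 0.54,
severity–frustration 0.58, severity–exam −0.50, VLF–exam −0.48; the five
unspecified pairs are filled with moderate values that keep the matrix
positive definite, which is validated at construction with the offending
pair named on failure). The n_ss_positive highest severities become the
sickness-positive group; negatives have all 16 SSQ ratings identically
zero. Positive totals come from thresholding the within-positive severity
quantile so the marginal reproduces a median symptom-sum of 4 (total 14.96)
with quartiles at sums 2 and 4; ratings are spread over symptoms with the
observed population weights (dizziness with eyes open, difficulty focusing
and concentrating most frequent). Band powers are the per-status epoch
medians scaled log-normally; the 6–10 min VLF uses a within-group log-SD of
0.8 — the order implied by the printed within-group IQR ratios — with half
of that dispersion carried by the VLF latent. Jointly with the status-median
separation this realises the configured severity–VLF rank correlation of
0.56 at large n (the observed correlation of a grouped-marginal design is
not the copula parameter alone, so these two constants were fixed together
at design time; reconfiguring effect sizes far from the defaults would need
the same one-time calibration). TLX and Mini-CEX values are latent normals
mapped through the per-status means/medians of this population and rounded
to instrument granularity, always inside their documented ranges
(property-tested over random configurations). One global seed fans out via
`SeedSequence.spawn` to per-participant substreams, so enlarging a cohort
leaves existing participants' draws untouched (their sickness *status* may
shift, since status is a cohort-level ranking).

**What passing tests do not show.** The generator matches marginal
summaries, one configured rank correlation and the sign structure of the
screen — not item-level response processes, measurement error of oral SSQ
administration, real ECG morphology or artifact physiology. Because group
marginals are fixed to this population's values, instrument correlations
other than the severity–VLF link come out stronger than their real-data
counterparts; with sickness-status clustering the mediation paths of a
28-participant cohort are mostly between-group and correspondingly weak
within-cluster. Results on synthetic cohorts validate the machinery, not
clinical conclusions.

## Problem sizes used in the test and acceptance suites

Chosen as the package's own verification scale: spectral oracle and
Parseval over 100 seeded 5-minute epochs; exact-test oracles exhaustively
over all 2×2 tables with N ≤ 12 and Mann–Whitney enumerations up to
8 + 8; mixed-model recovery on 200 clusters × 5 (three-seed mean, since a
single seed's MLE has sampling SD ≈ 0.12 for the between variance);
mediation recovery at 100 clusters × 5; null rates over 100–2000
replicates; large-sample copula checks at n = 2000 without RR synthesis
(band-power targets stand in for analysed powers, which is rank-equivalent).

## Known limitations

* The likelihood-ratio convention for boundary variance components is
  anti-conservative (see above); it is kept as the default reporting
  convention with this note.
* Exact Mann–Whitney p-values are only used for tie-free samples; tied
  small samples fall back to the corrected normal approximation.
* The mediation bootstrap refits legs by OLS within resamples for speed;
  with strongly unbalanced clusters its CI can differ from a full
  mixed-model bootstrap.
* `fit_mixed` supports one grouping level with a random intercept and at
  most one random slope — the two-level designs this analysis needs, not
  general crossed or deeply nested structures.
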