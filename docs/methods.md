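# Methods

`cardiorelax` implements a complete myocardial T1/T2 mapping analysis for
3 T cardiac MR: a digital short-axis phantom that emulates the acquisition,
pixel-wise relaxometry, AHA 16-segment quantification with rule-based
quality control, and mixed-model reference statistics on the log scale.
This note records the models, the parameter choices that matter, and the
limits of what the synthetic experiments demonstrate.

## Signal models

**T2 (T2-prepared SSFP).** Three magnitude images at preparation times
TE = 0, 24, 55 ms follow the two-parameter mono-exponential
S(TE) = S0·exp(−TE/T2). The fit is least squares over (S0, T2); for a
fixed T2 the amplitude is linear and solved in closed form, so the
optimisation reduces to a one-dimensional search over log T2 (coarse grid,
two zoom stages, parabolic refinement of the residual minimum). The
two-point log-linear solution seeds the pixel-level API. No noise-floor
(three-parameter) T2 model is fitted.

**T1 (MOLLI, 3-3-5).** Eleven magnitude images sample an effective
inversion-recovery curve S(TI) = A − B·exp(−TI/T1*), with the Look-Locker
correction T1 = T1*·(B/A − 1). Inversion times follow a 3-3-5 pattern:
three Look-Locker groups with base TIs 100/180/260 ms (minimum TI above
the protocol's 91 ms floor), each group contributing base + k·RR. Because
magnitude data discard polarity, all 12 monotone sign-restoration
candidates (negate the k lowest-TI samples, k = 0..11) are fitted and the
lowest-residual candidate wins; for inversion recovery the true sign
pattern is always of this prefix form, so the enumeration is exhaustive.
Amplitudes are again profiled out, leaving a 1-D search over log T1*.
B ≤ A at the optimum is an unphysical recovery and flags the pixel
non-converged. Physiologic ranges (T2 1–300 ms, T1 1–5000 ms) flag rather
than truncate. Pixels whose peak signal is below 5× the corner-estimated
Rician noise floor are skipped; this assumes the image corners are
signal-free background, which holds for the phantom and for typical
short-axis framing.

Numerical accuracy of the staged search: the profiled residual is smooth
in log τ, and the final parabolic vertex recovers noiseless ground truth
to ~1e-4 ms, far below the 0.01/0.1 ms round-trip tolerances asserted in
the tests. Map fitting is vectorised across pixels (shared-regressor
closed forms), so a 96×96 slice fits in tens of milliseconds.

## Phantom

Each simulated volunteer has three short-axis slices modelled as annuli
(base endo/epi 22/32 mm, middle 19/29 mm, apex 14/23 mm; 96×96 grid at
1.5 mm isotropic spacing). Myocardial pixels carry per-segment ground
truth; the blood pool uses fixed values (T2 250 ms, T1 1900 ms
pre-contrast, 300 ms post-contrast — above myocardium before contrast,
below it after); background has zero proton density; tissue S0 is a
uniform 100 arbitrary units. Angles are measured counter-clockwise from
+x with +y up; the anterior RV insertion (default 120°) anchors the AHA
sectors, with segment numbering anterior → anteroseptal → inferoseptal →
inferior → inferolateral → anterolateral on the basal/mid rings and four
90° sectors apically. There is no segment 17 (apical cap).

**Cohort.** Six sex × age-band strata (20–39, 40–59, 60–80 years), filled
equally (`n_per_stratum`) or round-robin for an arbitrary `n_total`.
Heart rate is truncated normal 70 ± 6 min⁻¹ within 47–102; blood pressure
132 ± 12 / 72 ± 11 mmHg. Ground-truth relaxation times are log-normal
around per-slice geometric means (packaged: T2 44.1/45.1/46.9 ms, T1 pre
1157.1/1158.7/1180.6 ms, T1 post 427.3/411.2/399.7 ms) with a single
subject-level factor per map type whose geometric SD is the scatter
factor (1.08/1.05/1.11). The factor is shared by all segments of a
subject: the scatter is inter-subject variability, which is what the
mixed model's subject variance component estimates. Covariate effects are
multiplicative (log-additive): the optional heart-rate effect scales T2
and post-contrast T1 for subjects above the drawn cohort's median heart
rate by the ratio of the configured group means (e.g. basal T2
42.8/45.8); the optional age effect scales pre-contrast T1 by 0.95 in the
oldest band (the magnitude is a configuration choice — the direction is
established, the size is not published).

**Noise and artifacts.** Magnitude images carry Rician noise (magnitude
of a complex Gaussian perturbation, default σ = 1% of tissue S0); a
Gaussian-free noiseless mode supports closed-form tests. Susceptibility
artifacts are modelled as a 60° inferolateral wall sector whose signal is
multiplied by an independent per-frame dropout factor in [0.3, 0.9] —
frame-varying modulation, like SSFP banding, breaks both signal models
and is detectable by residual, whereas a frame-constant factor would be
absorbed by the amplitudes (both fits are scale-equivariant). The default
occurrence probability is 0.08 per subject-slice, chosen so that roughly
a fifth of subjects have at least one affected slice. Inter-frame motion
is translational with per-frame Gaussian shifts (default SD 0.5 px).

The phantom does **not** emulate: partial-volume blending at contours
(except in a dedicated test), through-plane motion, non-rigid deformation,
B0/B1 field structure, inversion-efficiency loss, contrast-agent
pharmacokinetics (post-contrast is simply a distinct T1 regime), or ECG
waveform variability. Passing recovery tests therefore demonstrates
internal consistency of the analysis chain under the stated statistical
structure, not robustness to everything real data can do.

## Registration

Motion is corrected with a translational model per series: the reference
frame is the one with the highest mean signal in the myocardial mask; each
other frame's (row, col) shift is estimated by FFT normalised
cross-correlation and refined sub-pixel by a descending three-point grid
search on the interpolated correlation (three halvings from 0.5 px, cubic
resampling), then undone by linear resampling. A provided mask is dilated
and smoothed into a soft apodisation window before weighting the
correlation — a hard mask boundary would itself be a static feature and
anchor the correlation at zero shift. Estimated shifts beyond a quarter
of the grid are flagged as failures, left unapplied, and propagate to QC.
Measured recovery error on phantom series is ≤ 0.13 px. The cited
clinical pipelines use non-rigid registration; the translational model is
a transparent, testable stand-in adequate for the synthetic motion
generated here, and the module boundary admits a non-rigid drop-in.

## Segmentation and quantification

Analysis contours erode the annulus by 15% of wall thickness from each
border (configurable), operationalising conservative mid-wall contouring
that avoids trabeculae, blood and epicardial fat. Segment values are pixel
means (medians reported alongside; the choice between them is not
standardised); per-slice values are pixel-count-weighted means of segment
means, identical to direct ROI averaging.

## Quality control

Visual consensus reading is replaced by deterministic rules. Pixels are
flagged if non-converged, clamp-violating, or with residual RMSE above 3×
the slice median. Segments are excluded if flagged pixels exceed 10% of
their area (reason *susceptibility*), if any frame of the series failed
registration (*motion*), or if the frame timing is inconsistent with the
recorded RR interval beyond 10 ms (*mistrigger*). Precedence where causes
coexist: mistrigger > motion > susceptibility. Excluded segments never
enter any downstream statistic.

## Statistics

The reference model is a linear mixed model on log values fitted by REML
(`statsmodels` MixedLM): slice (or segment) fixed effects, a subject
random intercept, and candidate cofactors — age band, sex, heart rate
dichotomised at the cohort median, systolic and diastolic blood pressure.
Cofactors are eliminated backwards while the least significant has Wald
p ≥ 0.05; joint F statistics use conservative between-subject denominator
degrees of freedom (subjects minus between-subject parameters). LS means
average the design row over the observed levels of retained categorical
cofactors with continuous cofactors at their subject-level mean, then
exponentiate. Reported with each level: a 95% normal CI and a
95%-confidence/90%-coverage tolerance interval computed on the log scale
with Howe's k-factor approximation (accurate to a fraction of a percent
for n ≥ 10) and back-transformed, hence multiplicatively symmetric. The
scatter factor is exp(√(σ²_subject + σ²_residual)) — the back-transformed
total SD, interpretable like a coefficient of variation — with a
subject-only mode available. Observer agreement uses Bland-Altman bias ±
SD of paired differences with Pearson r; cofactor inter-correlations use
Spearman rank correlation. An OLS sanity check guards the REML fit
against a silent optimizer failure observed with near-zero variance
components; a gradient-free refit is used when it trips.

**Known statistical limitations.** (i) With the printed group means
(basal T2 42.8 vs 45.8 ms) and inter-subject scatter 1.08, the power to
retain the heart-rate term at n = 40 is only ~0.65 (analytically z ≈ 2.4
between subjects); retention is therefore seed-dependent, and the
corresponding property test documents this honestly rather than inflating
the effect. (ii) Backward elimination mildly inflates the false-retention
rate of null cofactors above the nominal 0.05 (measured ~0.05–0.1).
(iii) Printed tolerance-interval conventions vary; the implementation
follows the stated 95%/90% normal convention rather than reverse-
engineering any particular table.

## Problem sizes

The packaged reference experiment simulates 40 subjects at 96×96 (three
slices, one T2-prepared and two MOLLI series each) and runs end-to-end in
roughly 90 seconds on one CPU; Monte-Carlo property checks use 10⁴
replicates (tolerance-interval coverage) and 40 seeded cohorts
(elimination power and false retention). These sizes give sampling error
comfortably inside the 3%/±0.03 recovery tolerances for the quantities
reported.
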