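# Methods

## The statistic

The package quantifies how much each brain region reconfigures its
functional-connectivity pattern over the course of a resting-state scan.
Given a conditioned T × R matrix of regional BOLD signals, the series is cut
into n = ⌊T / l⌋ nonoverlapping windows of length l volumes (trailing
T mod l volumes dropped, keeping windows aligned to scan start).  Within
window i the R × R Pearson network F_i is computed; region k's
*connectivity profile* F_{i,k} is its row of F_i.  The temporal variability
of region k at window length l is

    V_k(l) = 1 − (2 / n(n−1)) Σ_{i<j} corr(F_{i,k}, F_{j,k}),

one minus the mean pairwise Pearson correlation of the region's profiles
across windows.  Because correlations lie in [−1, 1], V_k ∈ [0, 2]: 0 for a
region whose network affiliation never changes, values above 1 for a region
whose profiles anticorrelate across windows.  To avoid an arbitrary window
choice V_k(l) is computed for l = 10, 11, …, 20 volumes (20–40 s at
TR = 2 s) and averaged with equal weight; the per-length values are kept in
the result for inspection.

Numerical and policy choices:

* **Self-entry.**  The self-correlation entry of a profile is constantly 1
  and inflates inter-window profile similarity, so the default profile is
  the (R−1)-vector excluding it.  `include_self=True` keeps the full
  R-vector for literal replication of the textbook definition; both routes
  are tested against a brute-force double-loop oracle to 1e−12.
* **Unordered pairs.**  Pearson correlation is symmetric, so averaging over
  unordered pairs i < j equals the ordered average; the implementation uses
  the strict upper triangle of the n × n profile-correlation matrix, and a
  tested identity guarantees 1 − V_k equals the mean off-diagonal entry.
* **No Fisher z-transform** anywhere: the statistic is defined on raw
  correlations.
* **Degenerate regions.**  A region with zero variance inside any window
  (or an all-NaN column from a missing atlas label) cannot produce a
  correlation; such regions are excluded from every profile, reported in
  `VariabilityResult.excluded_regions`, and never imputed.
* Window spans are 0-based half-open internally.
* The batched implementation (one einsum per window length, one batched
  mat-mul for all profile-correlation matrices) is exact — equality with
  the naive path is asserted to 1e−12 in the suite, and in practice agrees
  to ~2e−16.

## Signal conditioning

The pipeline ingests spatially registered data — volume-level registration
(slice timing, realignment, normalisation) is out of scope — and applies,
in a fixed order that the series' conditioning log enforces:

1. optional hemisphere flip (see below),
2. discard of the first 5 volumes (signal equilibration; 205 → 200 at the
   default scan length),
3. per-region linear detrend (least squares),
4. ideal discrete-Fourier band-pass, 0.01–0.08 Hz (out-of-band bins zeroed,
   in-band bins kept exactly; DC always removed for a nonzero low edge),
5. nuisance regression: OLS residual against an intercept plus the supplied
   regressors (6 motion parameters, white-matter / CSF / global means);
   residuals are orthogonal to every regressor and rank-deficient designs
   are rejected with the collinear regressor names.

The band-pass is an ideal frequency-domain filter for reproducibility and
exact passband semantics rather than a Butterworth IIR; the passband check
(unit gain on an in-band sinusoid, >95% rejection out of band) is in the
suite.  Filtering precedes nuisance regression, matching the stated
conditioning order of the analysis this pipeline follows.

**Hemisphere flipping.**  In a mixed-lesion-side cohort, images of patients
with right-hemisphere lesions are conventionally mirrored so the left
hemisphere is always ipsilesional.  At the parcel level of a symmetric
atlas this is exactly a swap of homologous (left, right) region columns,
which is how `flip_hemispheres` implements it, under a declared
`HomologousPairing` (AAL-style `_L`/`_R` pairs; vermis/midline regions
unpaired).  The flip is an involution and commutes with every per-column
conditioning step (tested).  Residual anatomical asymmetry of real brains
is not modelled — a limitation of the parcel-level approach.

## Synthetic cohorts

No public data exist for the target study design, so the generator is a
first-class module.  It emulates the one property the statistic needs:
nonstationary connectivity.  The model is piecewise-stationary Gaussian —
no hemodynamic convolution, spatial noise fields, head motion or lesions.

* **Global-state engine** (`simulate_series`): one hidden state path for
  all regions; dwell lengths are geometric (memoryless) with configurable
  mean; within a dwell, samples are i.i.d. multivariate normal with the
  active state's correlation matrix (states are random two-block
  correlation matrices, within-block correlation 0.64) plus independent
  observation noise (default sd 0.2).  The empirical correlation of a long
  single-state run converges to the specified matrix (tested at T = 5000
  within ±0.05).
* **Per-region engine** (`simulate_region_switching`, used by
  `simulate_cohort`): K shared latent standard-normal factors (default 3);
  region r follows its own geometric dwell process and loads on one factor
  at a time with loading λ = 0.8, x_r = λf + √(1−λ²)ε.  Two regions on the
  same factor correlate at λ² = 0.64; a region that switches factors more
  often reconfigures its profile more.  The *mean dwell length* is the
  single switching-intensity knob: expected V decreases monotonically in
  mean dwell (tested by rank over dwell 5/20/80 and by a 100-replicate
  fast-vs-slow ordering check).  A global state path cannot express
  region-specific switching rates, which is why the cohort generator uses
  this engine while `simulate_series` keeps the simpler global-path
  semantics.

**Cohort layout.**  Defaults mirror the study conditions: 19 patients
scanned at three poststroke stages (acute / subacute / early chronic), 19
controls scanned once at baseline (configurable to repeated sessions for
within-subject null tests), 200 analysed volumes at TR = 2 s, 10 AAL-style
regions (homologous L/R pairs).  An `effect_map` multiplies the base
switching intensity per (group, stage, region); mean dwell = base dwell /
multiplier.

**Behavioral coupling.**  Each patient's score change from first to last
stage is

    Δscore = recovery_gain + slope · ΔV + N(0, σ_ε²),

where ΔV is the *realized* stage-1→stage-2 change of the designated
region's temporal variability, measured by the generator on its own output
(per-patient heterogeneity enters through a log-normal jitter, sd 0.35, of
that region's stage-2 switching intensity).  Coupling to the realized
change makes the downstream change–change correlation a designed property:
its population value, slope·σ_ΔV / √(slope²σ_ΔV² + σ_ε²), is computed per
cohort from the realized ΔV spread and stored in the ground truth, so
recovery tests compare measured against designed correlation without an
intractable analytic map from dwell length to expected V.  Scores follow
the upper-limb Fugl-Meyer scale: baseline 33.6 ± 14.5, total gain 21.5
(42% accrued by stage 2), clamped to [0, 66].  The clamp is deliberate
realism — ceiling effects attenuate correlations, and recovery tests use a
low-ceiling configuration (base 30, sd 6, gain 10) so the designed
correlation is identifiable.

Determinism: every subject × stage gets its own RNG stream derived by
stable hashing of (seed, subject, stage), so outputs are byte-identical
across runs and independent of generation order.

**What passing tests show.**  The generator produces stationary-variance
Gaussian series with exactly switching correlation structure; real BOLD has
hemodynamic autocorrelation, motion artefacts, physiological noise and
inter-subject anatomical variability.  Passing recovery and calibration
tests therefore demonstrates correctness of the pipeline's computations and
honest statistical behaviour under the model's assumptions — not robustness
of the statistic on real patient data.

## Group statistics

All tests run on the long cohort table of per-(subject, stage, region)
V values.  Thresholds are the analysis defaults: 0.005 (two-sample t,
uncorrected), 0.01 (RM-ANOVA), 0.05 (Tukey).  No multiple-testing
correction anywhere; every p is two-sided and labelled uncorrected.

* **Two-sample t** (patients vs controls per stage): pooled-variance
  Student t (Welch by flag); negative t means patients below controls.
* **Repeated-measures ANOVA** across patient stages:
  F = MS_stage / MS_(stage×subject) on (s−1, (s−1)(n−1)) df, closed form,
  no sphericity correction (Greenhouse–Geisser available nowhere because
  the reference analysis reports plain F); controls never enter.  With two
  stages F equals the squared paired t (tested to 1e−10), and the
  implementation matches statsmodels' AnovaRM to 1e−10.
* **Tukey HSD** stage pairs: mean difference oriented later − earlier;
  q = |diff| / √(MS_error/n) referred to the studentized-range distribution
  on (s, (s−1)(n−1)) — the repeated-measures error term, the only one
  consistent with the ANOVA above.  Implemented directly because installed
  libraries only offer Tukey with a between-subject error term.
* **Change–change correlation**: per-patient ΔV (stage pair) against
  Δscore (possibly a different stage pair, default acute→early-chronic
  score change vs acute→subacute variability change), Pearson r with its
  two-sided p; fewer than 3 complete cases is an error.

Type-I calibration is verified on null synthetic cohorts (all multipliers
1, slope 0, no subject jitter, n = 19 per group, 200 volumes): empirical
rejection rates at each stage's threshold must fall within binomial 95%
bounds of nominal over 500 replicate cohorts, pooling the three per-stage
t-tests the analysis performs.  On exactly normal data the Tukey
family-wise rate is nominal; on cohort V values it runs slightly
conservative (~0.043 for nominal 0.05) because the V distribution is
mildly light-tailed — a property of the statistic, not of the test
implementation.

## Problem sizes in the replicated checks

Replicated simulation checks scale the problem down to keep the suite
fast while preserving the study's structure: calibration cohorts use 6
regions at the full 200-volume scan length; ordering and recovery checks
use the full 10-region, 200-volume layout; oracle-agreement instances are
R ≤ 8 with ≤ 6 windows, where the brute-force double loop is cheap.  The
methods are size-agnostic; the 116-region case is exercised for shape and
windowing arithmetic.

## Known limitations

* Parcel-level flipping ignores anatomical L/R asymmetry.
* The ideal band-pass has sharp spectral edges (ringing on strong
  out-of-band transients); a Butterworth option would trade passband
  exactness for smoother edges.
* The generator's factor model induces correlated variability across
  regions within a cohort; rejection-rate estimates pool over regions, so
  their effective sample size is slightly below the trial count.
* Geometric dwell times are memoryless; real state durations are likely
  heavier-tailed.
* Windows shorter than ~10 volumes at TR = 2 s estimate 116-dimensional
  correlation rows from very few samples; the statistic remains defined
  but noisy, which is why the default length set starts at 10.
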