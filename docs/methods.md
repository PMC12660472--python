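# Methods

This note documents the models, numerical choices and known limitations of
the `mednf` pipeline. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Synthetic data model

**NF runs.** One run lasts 600 s at TR = 0.8 s (750 volumes) and interleaves
three 51-s rest blocks with six 26-s focused-attention meditation blocks in
the order rest – (cue, meditation, feedback) ×3 – rest – (cue, meditation,
feedback) ×3 – rest. Cue and feedback durations are not constrained by the
design and default to 3 s and 10 s; the remaining run time (213 s at
defaults) is split into six equal unmodelled gaps after the feedback blocks,
so the final rest block ends exactly at the end of the run. A run shorter
than the mandated blocks raises a sizing error naming the deficit.

Voxel intensities follow a multiplicative BOLD-like model around a per-voxel
baseline b_v ~ U(900, 1100) a.u.:

    y_v(t) = b_v · (1 + a_v s(t) + drift_v(t) + l_v p(t) + ε_v(t))

- s(t): the meditation boxcar convolved with a double-gamma HRF (peak 6 s,
  undershoot 16 s, peak/undershoot ratio 6) normalised to unit integral, so
  sustained blocks plateau at 1 and amplitudes read directly in percent
  signal change. A 26-s block reaches ≈ 0.98 of plateau.
- a_v: the deactivation amplitude (default −0.5% ÷ 100) carried by a
  configurable fraction of target voxels (default 0.5, so dynamic voxel
  selection is non-trivial), with per-voxel gains U(0.7, 1.3) renormalised to
  mean exactly 1 — the carrier mean equals the nominal amplitude.
- drift_v(t): a random linear trend plus one slow cosine, peak amplitude
  `drift_amplitude` percent (default 0.5).
- p(t): a unit-variance low-frequency component shared between the target
  and confound ROIs, built from three sinusoids with run-specific frequencies
  drawn from drift (0.005–0.02 Hz), respiratory-volume (0.05–0.12 Hz) and
  residual-respiration (0.2–0.35 Hz) bands. Frequencies are sampled per run
  because breathing rates differ across individuals; fixing them would give
  all simulated participants identical nuisance structure, which is both
  unrealistic and confounds independence checks between participants. Voxel
  loadings l_v are U(0.5, 1.5) × `physio_sd`/100 (default 0.3%).
- ε_v(t): white thermal noise, default SD 0.5%.

This emulates the statistical structure real-time scoring must cope with —
task-locked deactivation, drift, ROI-shared physiological noise — but not
anatomy, motion, spike artefacts, k-space physics or true respiratory
waveforms; passing tests therefore validate the algorithms, not robustness
to every real-scanner failure mode.

**Behavioural cohorts.** Per group (default 19 subjects/group): age
U(19, 50), balanced binary sex, sleepiness (SSS) ratings N(3, 0.8) clipped to
[1, 8]. SMS subscales are simulated on the per-item mean 1–5 scale. The
post-meditation SMS score at session day d_t ∈ {0, 3, 4, 5, 6, 7} is

    post = 1.2 + 0.5·trait + (−0.08)·SSS̄ + slope_i · d_t + ε,

with trait ~ N(3.3, 0.4) also generating the pre-meditation scores,
subject slopes N(group mean, 0.06) and noise SD 0.25; values are clipped to
[1, 5] after noise and clip events logged. Group mean slopes default to
+0.05/day (experimental) and −0.05/day (control) for SMS-Mind and 0/0 for
SMS-Body (a true-null endpoint). DASS-21 difference scores are
N(−4.8, 5.0) experimental vs N(−1.6, 3.6) control; in the experimental group
the DASS change and the simulated seed-coupling beta (N(−0.07, 0.11) vs
N(+0.08, 0.11) control) are drawn bivariate with r = 0.71, and independently
in the control group. BCT task accuracy changes target a group-difference
d = 0.39 with SD 10%; probe accuracy is binomial counts out of 5 probes
(baseline success 0.85) with the experimental success probability shifted to
target d = 0.56 — the realized d is approximate because of the discreteness,
which is exactly why this endpoint uses a rank-sum test. The configured
slope separation implies a much larger standardized group effect than a
small behavioural study would show; the generator's purpose is recoverable
ground truth, not effect-size realism.

## Real-time engine

The "incremental GLM" contract is cumulative ordinary least squares: the
engine stores X'X, X'Y and Y'Y and its coefficients at volume t equal a full
refit on volumes 1..t (property-tested to 1e−8 against `numpy.linalg.lstsq`
at every volume). Design columns are intercept, linear trend and the
convolved meditation regressor; fits are refused (flagged, not fitted) until
volumes > columns. Non-finite volumes are rejected with a warning and leave
the state unchanged.

Per-volume PSC is 100·(y − baseline)/baseline against the cumulative
intercept+trend prediction — the model's estimate of the rest trajectory.
Voxel selection takes the max(1, ⌊0.33·V⌋) voxels with the most negative
meditation t statistic, ties broken by ascending voxel id. "Peak" scoring is
interpreted as the per-volume PSC of the dynamically selected most-responsive
voxels, block-averaged; a per-block extremum alternative is exposed as
`NfConfig(block_statistic="peak")`. Scoring windows are shifted by 4 s
(haemodynamic lag; configurable) and a score is only computable once its
shifted window has fully elapsed (intermittency contract). Online
physiological control regresses the cumulative target-PSC series on the
confound-ROI PSC series (intercept + slope, refit every score); residuals
are orthogonal to the confound over the fitted window. The thermometer maps
residual PSC linearly from [0%, −1%] onto levels 1–20, clipped, rounded half
away from zero; the map is monotone non-increasing so deeper deactivation
always raises the bar. The whole chain is invariant to rescaling raw
intensities by any positive constant.

A consequence of cumulative baselining worth knowing: the *residualized*
block score contains a small deterministic within-run component, because the
cumulative mean PSC that the confound regression's intercept absorbs evolves
with the rising meditation duty cycle. The raw block PSC does not have this
component (noiseless runs score a flat −0.49 for a −0.5% amplitude). The
yoked-sham blinding check therefore correlates the donor's displayed scores
with the recipient's *raw* block PSC, matching the notion of the recipient's
actual activity.

Sham mode replays a donor's stored scores verbatim (count and order are
validated), donors being matched by nearest meditation-experience hours with
ties broken by donor id.

## Offline inference

The block GLM converts each voxel to PSC around its mean and regresses on
intercept, trend and the convolved condition regressors (meditation, rest,
cue, feedback); the meditation−rest contrast is in PSC units (noiseless
recovery of an injected −0.5% verified). Rank-deficient designs raise an
error naming the collinear columns.

gPPI includes, per voxel: intercept, trend, condition regressors, the
mean-centred seed time course, and seed × (mean-centred condition regressor)
products for meditation and rest; γ is the meditation−rest difference of the
interaction coefficients. No deconvolution is applied — for long blocks the
convolved-psychological product is standard practice — and a
`convolve_psych=False` flag switches to raw centred boxcars. Centring makes
γ invariant to adding constants to the seed (tested). A condition-number
guard (1e8 on the column-normalised design) rejects collinear PPI designs.

The group permutation test residualizes subject maps on covariates (plus
intercept) before permuting group labels — a pragmatic simplification of
covariate-aware permutation schemes (Freedman–Lane is out of scope); the
cluster-forming threshold's degrees of freedom are reduced accordingly.
Clusters form at one-tailed p < 0.005 on the pooled-variance two-sample
t-map with 6-neighbour connectivity. The cluster statistic defaults to
**mass** (sum of supra-threshold |t|): on unsmoothed synthetic grids the
max-extent null is concentrated on 1–2 voxels, so extent-based FWE p-values
are so discrete they cannot reject at any conventional level; mass has a
continuous null and calibrates (empirical FWE 0.04–0.07 against a nominal
0.05 over 200 null datasets at 500 permutations). Extent remains available
via `cluster_statistic="extent"` and is the natural choice for smoothed
data. FWE p-values use the (1 + exceedances)/(1 + permutations) convention,
which keeps them valid at finite permutation counts. Desk-scale defaults are
1000 permutations on a 20×20×10 grid; optional Gaussian smoothing is off by
default for synthetic grids.

## Behavioural endpoints

The repeated-measures slope procedure is operationalized as pooled covariate
residualization (post-SMS on pre-SMS, SSS, age, sex across all
subject-timepoints, covariates standardized) followed by one OLS slope per
subject on days since baseline — the reading that yields one slope per
participant; per-subject covariate adjustment would leave too few
within-subject degrees of freedom at six timepoints. Slopes need ≥ 3
timepoints (subjects excluded and logged otherwise). Group comparison is a
one-way ANOVA with d = sign(Δ)·√F·√(1/n₁ + 1/n₂). Difference-score ANCOVAs
(diff ~ group + age + sex) report the group t and the same d transform;
with zero-effect covariates they converge to the two-sample t-test (tested
at large n). The rank-sum uses midranks with full enumeration of all
C(n₁+n₂, n₁) label assignments for combined n ≤ 12 (two-sided p =
probability of a rank sum at least as far from its null mean as observed)
and scipy's tie-corrected normal approximation above that. BH-FDR uses the
statsmodels step-up implementation behind a validating wrapper; the family
can be widened beyond the supplied p-values (extra members assumed
non-significant). Note the step-up adjustment is permutation-equivariant
and monotone but not idempotent — re-adjusting adjusted values can only
raise them. Partial correlations use the residual method with
df = n − 2 − k and the t transform r·√(df/(1−r²)). p-values are reported in
full precision in machine output and to 3 decimals in printed tables.

## Problem sizes and determinism

Simulation studies run at desk scale chosen for a single CPU: 200 null
datasets × 500 permutations for FWE calibration, 100 replicates for gPPI
recovery and sham blinding, 200 cohorts at 19/group plus 20 cohorts at
2000/group for endpoint recovery. Every stochastic stage takes its seed
from `numpy.random.SeedSequence(global_seed).spawn(...)`, one child per
stage in a fixed order, reduced to 31 bits; identical config + seed yields
byte-identical CSV outputs (tested). File writes are atomic
(write-temporary-then-rename).

## Limitations

- No anatomy, registration, motion or smoothing: the engine assumes
  upstream preprocessing, and the synthetic ROI-collapsed grids do not test
  spatial failure modes.
- The permutation test's covariate handling (pre-residualization) is not
  exact under strong covariate-group dependence.
- The behavioural generator produces cleaner, more separable effects than
  small behavioural studies typically show; power numbers obtained on it do
  not transfer to real cohorts.
- The published one-sample t statistics for difference scores are not
  reproducible from their rounded summary statistics and are not targets of
  any check here.
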