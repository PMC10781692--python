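# Methods

This note documents the models, numerical choices and limitations of
`tmsdcm`. The package re-implements, as tested reusable code, the analysis
chain of an individualized-target accelerated-iTBS (SAINT-protocol)
resting-state fMRI study: seed-based target selection against the
subgenual cingulate, signed functional-connectivity profiling, spectral
dynamic causal modelling (spDCM) of directed connectivity, hierarchical
parametric empirical Bayes (PEB) with Bayesian model reduction and
averaging, and the clinical outcome layer. Because no raw data from such
studies are deposited, a synthetic-data module generates cohorts with the
statistical structure the analysis assumes, so every downstream stage is
testable without any download.

## Generative model

### Neuronal dynamics

Latent neuronal states of n regions follow a linear stochastic
differential equation

    dx/dt = A x(t) + v(t)

where A (Hz) is the effective-connectivity matrix — entry (i, j) is the
directed influence of region j on region i — and v(t) are endogenous
fluctuations with a power-law spectral density G_v(f) = α f^(−β)
(two-sided, per Hz, f in Hz). Self-connections are parameterized as
−0.5·exp(θ_ii) so they are always negative; all realized matrices must
have eigenvalues with strictly negative real part, and every generator
draw enforces this by rejection.

Integration is Euler–Maruyama at dt = 0.05 s with a 60 s burn-in. The
power-law noise is realized by FFT spectral shaping of white noise, which
makes the target spectrum exact on the simulation grid (the DC component
is zeroed; the power law is clamped below the first resolvable
frequency). With white noise (β = 0) the stationary variance matches the
continuous Lyapunov solution, which the test suite checks to 5%.

### Hemodynamics

Neuronal activity drives the balloon–Windkessel model per region
(vasodilatory signal, inflow, venous volume, deoxyhemoglobin), with
defaults κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2.0 s, α = 0.32, ρ = 0.4,
V0 = 0.04 and the classic BOLD coefficients k1 = 7ρ, k2 = 2,
k3 = 2ρ − 0.2. Flow, volume and deoxyhemoglobin are integrated in log
space and clamped to |log state| ≤ 2; the clamp only engages under
extreme fluctuation draws and keeps the integrator finite. The impulse
response peaks at ~4.5 s.

The default endogenous fluctuation amplitude (α_state = 2·10⁻⁵, β = 1)
yields neuronal states of a few-percent amplitude and BOLD fluctuations of
~1% signal change — the small-signal regime in which the balloon model is
approximately linear. Observation noise (white, α_obs = 8·10⁻⁶) gives an
in-band amplitude SNR of roughly 5; no published SNR exists for the ROI
series this emulates, so the default was chosen once as a realistic value
at which parameter recovery is attainable.

### Cohorts

The default cohort configuration encodes the emulated study conditions:
28 scanned subjects (2 carry a planted motion spike and are excluded
downstream, leaving 26 analyzable), two sessions (pre/post treatment),
TR = 2 s, 360 acquired volumes of which the first 10 are discarded, and a
5- or 7-region network around the stimulation target (DLPFC, PCUN, HIP,
INS, sgACC, optionally CAU and mPFC). The population coupling matrix is
chosen so the stationary correlation structure shows the expected
signed-profile: PCUN/HIP/INS/sgACC anticorrelated with the target
(r ≈ −0.2 … −0.3), CAU/mPFC positively correlated (r ≈ +0.15 … +0.25).
Per-subject matrices vary around the population mean (off-diagonal
sd 0.1 Hz, self-connection log-sd 0.05), and the post session adds a
treatment shift per connection (default: HIP→INS +0.2 ± 0.1 Hz,
HIP→sgACC −0.2 ± 0.1 Hz), with rejection sampling keeping both sessions
stable (a mild truncation of both distributions).

Clinical scales are generated on the published cohort magnitudes
(e.g. BSI-CV baseline 17.63 ± 7.06, HAMD-17 27.91 ± 4.31) with
timepoint-specific mean fractional reductions matching the published
trajectory. The planted connectivity–outcome link adds
w·(shift − mean shift) to each subject's reduction (default w = −1 for
BSI-CV on the HIP→INS shift, −0.8 for HAMD-17/MADRS) plus N(0, 0.12²)
noise; scores are floored at zero, which caps realized reductions at 100%
as in real bounded scales. One subject's week-4 visit is missing by
default, exercising the mean-imputation path.

What the generator does *not* emulate: scanner artifacts, spatial
inhomogeneity, susceptibility dropout, realistic motion-BOLD coupling,
physiological (cardiac/respiratory) noise, or spatially structured
hemodynamic variability. Passing tests therefore demonstrate the
correctness and calibration of the inference chain under its own
assumptions, not robustness to every property of real data.

## Preprocessing

Stages acting on aligned data only: discard the first 10 volumes,
Gaussian smoothing (FWHM 6 mm, σ = FWHM/(2√(2 ln 2)) in voxels, reflective
boundaries conserving the image sum), linear detrending, nuisance
regression (Friston-24 motion expansion — the 6 parameters, their
one-volume lags, and both sets squared — plus WM/CSF and optional global
signal), and a zero-phase order-4 Butterworth bandpass (0.01–0.1 Hz)
applied last. Motion exclusion drops a subject when any |translation|
exceeds 3.5 mm or any |rotation| exceeds 3.5° — strictly "larger than",
so boundary values are retained. Rotations are treated in degrees
throughout. The global signal is the mean over labelled (in-brain)
voxels, since synthetic data has no separate brain mask. Slice timing,
realignment and MNI normalization are out of scope: synthetic volumes are
born aligned.

The exact interleaving of detrending and nuisance regression is not
uniquely fixed by common practice; this package fixes
detrend → confounds → GSR → bandpass and logs the applied order.

## Functional connectivity and target selection

The stimulation target is the DLPFC voxel whose series is most negatively
correlated with the subgenual-cingulate reference (mean series over atlas
labels 187+188, unweighted), computed on the pre-treatment session only
(targets are fixed before treatment). Ties break at the smallest flat
voxel index, deterministically. Target-based connectivity is a Pearson r
map against a 6 mm spherical seed at the target; r maps are Fisher-z
transformed and entered into voxelwise one-sample t-tests, and the signed
maps threshold at two-sided p < 0.05 uncorrected. Pre-vs-post profile
comparisons use a paired-t map with Benjamini–Hochberg FDR control. ROI
masks are atlas labels intersected with the matching signed map; CAU,
PCUN, HIP and INS are restricted to the left hemisphere (voxel centers
with MNI x < 0), mPFC and sgACC keep both hemispheres. In the
orchestrated pipeline an ROI whose signed-map intersection is empty falls
back to its anatomical label with a warning; the library-level operation
raises instead.

## Spectral DCM

### Data features

The complex cross-spectral density (CSD) of the ROI series is estimated
from a least-squares multivariate autoregressive model (default order 8),
evaluated on a default grid of 32 frequencies from 1/(N·TR) to 0.25/TR:

    S(f) = TR · A(f)⁻¹ Σ A(f)⁻ᴴ,   A(f) = I − Σ_l A_l e^(−i2πfl·TR)

Spectral features are computed on detrended, confound-regressed but
*unfiltered* series (the bandpass is only for the correlation analyses).
Finite-sample AR fits carry spurious single-frequency coherence of order
√(p/T) between independent channels; the grid-averaged coherence stays
below 0.2 at 350 frames, which is what the suite asserts.

### Generative prediction

The predicted CSD is

    G_y(f) = H(f) G_v(f) H(f)ᴴ + G_e(f),  H(f) = B(f)·(i2πf·I − A)⁻¹

with B(f) the per-region first-order hemodynamic transfer function
obtained by analytically linearizing the balloon model around its fixed
point, and G_v, G_e diagonal power laws. Using the linearized kernel in
the likelihood while the generator integrates the full nonlinear model
means inversion is tested against data it did not generate from its own
equations; in the 0.01–0.1 Hz band the two agree to within 15%
band-averaged relative error at small signal amplitude.

### Parameterization and priors

Flat parameter vector: n(n−1) off-diagonal couplings (Hz), n
self-connection log-deviations (A_ii = −0.5·exp θ), 4 fluctuation
parameters (log-amplitude and exponent deviation for the neuronal and
observation spectra), and 2n hemodynamic log-deviations (transit time,
signal decay). Shrinkage priors: couplings N(0, 1/64), self-connections
N(0, 1/256), fluctuation and hemodynamic log-parameters N(0, 1/64). The
reference fluctuation amplitudes are calibrated from the data CSD (signal
power from the in-band diagonal, noise floor from the top frequency
quartile) so the log-deviations stay in the prior's range — the same role
data scaling plays in standard spectral-DCM practice.

### Variational Laplace

The observation vector stacks the real upper-triangular and imaginary
strict-upper-triangular CSD entries over frequencies; noise precision is
estimated per frequency band (4 bands) with Gaussian priors N(0, 16) on
the log-precisions. Optimization is damped Gauss–Newton on the free
energy with central finite-difference derivatives (step 1e−4); a
candidate step is accepted only if the freshly evaluated free energy
increases (so accepted-step free energies are non-decreasing by
construction), the damping adapts by factors of 8/4, and convergence is
declared when the improvement stays below 0.01 nats for three consecutive
iterations (cap 64). With a linear predictor and fixed noise precision
the scheme lands exactly on the conjugate Bayesian linear-regression
posterior, which the suite checks to 1e−6. Sessions are inverted
separately, both entering the group level.

## PEB, BMR, BMA

The second level is θ_i = X θ⁽²⁾ + ε with each subject/session posterior
entering as a Gaussian likelihood (mean and covariance). The design has
four columns: a constant (commonalities), session coded −0.5/+0.5,
and suicidal-ideation and depression responder flags effect-coded and
mean-centered; a no-variance covariate is flagged non-estimable. The
between-subject covariance is exp(−γ)·(1/16)·diag(prior variances) with
scalar γ optimized by type-II maximum likelihood (Brent) under a N(0, 1)
prior, plus a Laplace correction for its uncertainty. Given γ the model
is linear-Gaussian, so the group posterior and marginal likelihood are
exact.

Bayesian model reduction computes the evidence and posterior of any model
with tightened priors analytically from the full fit (a switched-off
parameter has prior variance 1e−8). Exhaustive search over all 2^p
reduced models is infeasible; the search greedily prunes every parameter
whose removal raises the evidence (up to 8 passes) and then scores the
full 2^k neighborhood of the k ≤ 8 parameters with the weakest evidence
either way. Commonalities stay outside the searched set in the pipeline.
Bayesian model averaging weights models by softmax of their free
energies, moment-matches the Gaussian mixture, and reports each
parameter's posterior probability as the summed weight of models where it
is on; parameters with probability > 0.95 are labelled significant in
reports.

## Clinical layer

Response is a reduction ≥ 50% (boundary inclusive: a printed reduction of
exactly 0.50 counts as response). Remission: BSI-CV requires reduction
≥ 50% *and* score < 6; HAMD-17 < 8; MADRS < 11; HAMD-6 < 5; BDI < 13.
Percentages are rounded half-up to 2 decimals at the reporting layer
only. A missing visit is mean-imputed from the observed values at that
timepoint, with an audit log; observed values are never modified.
Longitudinal change uses repeated-measures ANOVA (Greenhouse–Geisser
corrected degrees of freedom) with Bonferroni-corrected pairwise paired
t-tests, or a paired t-test for two-timepoint scales (where F = t²
exactly). Connectivity–outcome associations are Pearson correlations,
optionally partial (residualizing both variables on covariates such as
baseline severity); no multiple-testing correction is applied by default.

Two printing inconsistencies of the emulated study's tables are preserved
verbatim in the bundled reference data and deliberately not used as
computed targets: the 4-week suicidal-ideation response rate appears both
as 90.63% and 93.33%, and the immediate HAMD-17 mean reduction is printed
as 66.39% while the rounded summary means give 66.46% (the suite encodes
the latter as a documented-discrepancy test).

## Problem sizes in the validation experiments

The recovery experiments run at the package's standard conditions:
parameter recovery uses 10 subjects × 4 ROIs × 350 frames (TR 2 s);
hierarchical recovery uses 10 replicate cohorts of 12 subjects × 2
sessions with a −0.2 Hz planted session effect on one connection, 4-ROI
networks. The orchestrated end-to-end pipeline example runs a reduced
cohort (6–8 subjects, small volume grids) as a smoke of the full chain;
all stages scale to the full 28-subject configuration through the same
code path.

## Known limitations

- The spectral likelihood is linear in the neuronal states and uses the
  linearized hemodynamic kernel; strong fluctuations leave this regime.
- The AR-based CSD estimate is biased at the lowest grid frequencies
  (below ~1/(p·TR)); the per-band noise precisions absorb most but not
  all of this.
- Greedy-plus-neighborhood search can miss reduced models whose support
  only appears jointly; this mirrors the standard practice it replaces.
- The synthetic atlas is a block parcellation on a coarse grid; real-atlas
  use (e.g. a Brainnetome label volume) is a user-supplied path, and no
  atlas is redistributed.
- With few subjects the signed group maps can miss weakly coupled ROIs;
  the pipeline's atlas fallback trades specificity for robustness there.
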