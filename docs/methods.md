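# Methods

This note documents the models, parameter choices and limitations behind
`izbench`.  It is written for a reader who wants to know what the package
actually computes and what passing its tests does — and does not — show
about real MEG data.

## Forward model

The head is a homogeneous conducting sphere centred at the origin
(default radius 90 mm; +x right, +y anterior, +z superior).  The magnetic
field of a current dipole inside a spherically symmetric conductor has a
closed form (Sarvas); two of its properties anchor the test suite:

* the field outside the conductor is independent of the conductivity
  profile, which is why a sphere is an acceptable stand-in for a
  single-shell realistic conductor in MEG;
* dipole moments parallel to the radius produce no external field, so
  only the two tangential moment components are observable and every
  per-point gain matrix has rank 2.

Units are mm, nAm and fT (fT/cm for gradiometers).  The implementation is
verified against an independent closed form — the radial field component
outside any spherically symmetric conductor equals that of the primary
dipole in free space — plus silent-source, linearity and
rotation-covariance properties.

Sensors default to a helmet-like cap of 102 sites at 110 mm covering
`z/r >= -0.35`, two orthogonal planar gradiometers per site (204
channels) with radial pickup orientation and a 16.8 mm baseline,
mirroring the gradiometer-only selection of whole-head MEG practice.
Gradiometer outputs are two-point finite differences of the oriented
field divided by the baseline (fT/cm).

Source spaces are either regular volume grids (default 10 mm spacing for
the simulations here; clinical practice uses 5 mm) or cortical-like
quasi-uniform point sets on nested shells.  The volume grid stops at an
inner margin of 12 mm below the head surface, emulating the skull and
scalp: a "brain" point 5 mm under the scalp would couple unrealistically
strongly and distort data-driven hyperparameter heuristics.

## Inverse solvers

All solvers consume a single-time-sample topography `y` (the spike peak)
and the grid leadfield; grid argmax ties break toward the lowest index.

**ECD fitting.**  The location is optimised continuously: coarse scan of
the per-point least-squares residual (pseudo-inverse of the rank-2 normal
matrix), then Nelder–Mead refinement from the best five grid points
(starts in an already-covered basin, or with a coarse residual more than
twice the best, are pruned).  The moment is always the linear
least-squares solution at the current location.  The confidence volume is
the 95% ellipsoid of the location obtained from the finite-difference
Hessian of `residual/(2σ²)` at the optimum (0.5 mm steps); when the
caller supplies no noise level, σ is estimated from the residual with
n − 5 degrees of freedom.  A fit is *accepted* when GOF ≥ 80%, confidence
volume < 1000 mm³ and 50 ≤ |q| ≤ 500 nAm — the standard clinical rule.
The confidence-volume formula of commercial fitting software is not
public; ours is documented above and only enters through the accept
threshold.

**Bayesian single-dipole mapping.**  With priors `q ~ N(0, σ_q² I₃)` and
noise `ε ~ N(0, σ_e² I)`, the marginal likelihood of each candidate
location is Gaussian, `y ~ N(0, σ_q² L_r L_rᵀ + σ_e² I)`, evaluated per
point via the Woodbury identity (3×3 solves).  The posterior over the
grid is the normalised likelihood (uniform location prior).  The map is
invariant under joint rescaling of `y`, `σ_q`, `σ_e`.

Hyperparameter defaults: `BayesPrior.from_data` implements the
conventional data-driven choices `σ_q = max|y| / max|L|` and
`σ_e = 0.2·max|y|`.  The σ_q ratio heuristic is calibrated for leadfields
whose largest entries are representative of the source space as a whole
(cortical shells).  On volume grids the most superficial points dominate
`max|L|`, the heuristic lands one order of magnitude below the
physiological IED moment scale, and the over-shrunk prior biases the
posterior toward superficial low-moment points.  The synthetic pipeline
therefore sets the moment prior to the physiological scale
(`moment_prior_nAm = 250`, the middle of the 50–500 nAm range clinical
acceptance assumes); with it, the posterior peak is grid-exact at
power SNR 10 in 100/100 seeded trials.  Both choices are exposed.

**Sequential Monte Carlo sampler.**  The same posterior is approximated
by particles on grid indices: adaptive tempering (each inverse-temperature
increment chosen by bisection so the effective sample size halves),
systematic resampling below ESS = n/2, Metropolis moves mixing local
jumps (6 nearest neighbours) with global jumps, and 30 decorrelating
sweeps at the target.  The exact enumeration above is its oracle in the
tests.  Two facts govern the achievable accuracy: at the cohort's default
spike SNR the posterior is a near-delta and the sampler is trivially
exact; for a diffuse posterior with K effective support points even an
ideal iid sampler has expected total-variation error ≈ sqrt(K/(2πn)), so
a 0.05 TV budget at n = 2000 particles implies K ≲ 30.  The equivalence
test therefore runs at a deliberately low-SNR condition (power SNR 2,
σ_e = 0.3·max|y|) where the posterior spreads over a handful of points.

**Single-dipole MUSIC.**  The signal subspace is the span of the
topography (or the top singular vectors of a window); the scanned
quantity is the largest canonical correlation with each point's gain
column space (orthonormalised per point, rank handled by SVD).  With one
dipole and recursion depth one, RAP-MUSIC reduces to MUSIC; deeper
recursion is out of scope.

**Depth-weighted minimum-norm estimate.**  Free orientation; diagonal
source covariance with per-point weight `(trace L_rᵀ L_r)^(−γ)`
replicated over the three components, γ = 0.8 by default.  Weights are
capped at `10² ×` the minimum weight, the standard guard that keeps
weakly coupled deep points from being amplified without bound (the grid
interior would otherwise dominate the map).  The weighted Gram matrix is
normalised to `trace(L R Lᵀ)/n = 1` and the Tikhonov parameter is
`λ² = 1/SNR²` with SNR = 3 by default — the usual minimum-norm
regularisation convention.  The map value is the Euclidean norm of the
3-component moment estimate.

γ = 0.8 was checked on noiseless simulations against 0.6/1.0/1.2: it is
the value that cancels the mean radial (depth) bias of the peak (+10.1,
+0.3, −7.6, −10.4 mm respectively).  What no γ removes is a residual
*tangential* peak displacement of ~1–1.5 cm — the intrinsic point-spread
behaviour of minimum-norm maps for rank-2 spherical gains.  This is the
same order as the published map-method discrepancies the benchmark
reports, and it is why the package's solver-agreement guarantee holds for
the two dipolar scanners but not for the minimum-norm peak at 10 mm grid
resolution.

## Evaluation metrics

`MLD = sqrt( Σ (d_j |S_j|)² / Σ |S_j|² )` with `d_j` the voxel-to-ECD
distance; `SD` uses the distance to the map's own peak voxel.  Both are
invariant to positive rescaling of the map.  The ROC/AUC construction
follows the asymmetric convention of the benchmark exactly: positives are
the patient's ECDs (each scored by the map value of its nearest voxel),
negatives are the ECD-free voxels; "active" means strictly above the
threshold; thresholds sweep all unique map values plus sentinels and the
area is trapezoidal, which coincides with the rank-statistic AUC
(`P(pos > neg) + ½P(pos = neg)`) and with scikit-learn's `roc_auc_score`
— both used as oracles in the tests.  A constant map scores 0.5 under
this convention.  Patient summaries use the sample standard deviation
(ddof = 1); a single spike yields std 0.

## Clinical chain

The 10-region atlas is a geometric surrogate: hemisphere from the sign of
x (midline points go left), five contiguous sectors of the sagittal angle
`beta = atan2(z, y)` per hemisphere — F [−30°, 55°), C [55°, 100°),
P [100°, 150°), O [150°, 210°), T [−150°, −30°), i.e. anterior,
superior-central, posterior-superior, posterior-inferior and
inferior-lateral, with the temporal sector widest.  Real lobar anatomy is
of course not sectorial; the surrogate only needs to partition the sphere
reproducibly.

Lobar percentages: fraction of dipoles per region for point-estimate
methods, share of map mass (posterior probability, or current intensity)
for map methods.  The > 10% rule is a display filter only; concordance
always uses the unfiltered argmax, and a patient is concordant when *any*
region attaining the maximal percentage lies in the set of treated lobes.
The any-match tie rule and the membership rule for multi-lobe plans are
the unique natural reading that reproduces all 16 published
confusion-matrix cells, including the tied rows.  Engel class I is
"good"; classes II–IV, including the ambiguous "2/3", are "poor", which
makes that ambiguity inert.  Non-operated patients are kept in the metric
tables and excluded from the classification.  TPR, TNR, PPV, NPV are the
usual ratios and F1 the harmonic mean of PPV and TPR; zero denominators
yield NaN plus an `undefined` flag rather than an error.

## Cohort statistics

Mann–Whitney U is reported in the first-sample convention
`U = #{x_i > y_j} + ½·#ties` — the only convention consistent with the
published values (both U = 0 under complete separation and U > n₁n₂/2
occur).  p-values use the exact null for tie-free problems with
n₁n₂ ≤ 400 and the tie-corrected normal approximation otherwise (SciPy
throughout; the benchmark's own statistics were SciPy-based).  Published
U statistics, not p-values, are asserted, and the conventional
significance threshold is 0.01.

## Synthetic cohorts: what they emulate, what they do not

Each synthetic patient has one true IZ region; spike generators are grid
points of that region within `jitter_mm` (default 10 mm) of a
patient-specific centre drawn at cortical depths (0.45–0.92 of the head
radius); moments are tangential with magnitudes uniform in 50–500 nAm;
sensor noise is white with the noise power set from the requested
signal-to-noise power ratio (default 5, a typical single-spike figure;
the law-of-large-numbers check in the tests confirms the realized ratio
to 5%).  Plans and outcomes follow configurable probabilities whose
defaults mirror the published cohort's observed rates (12/20 concordant,
good outcome for 8/12 concordant and 5/8 discordant patients); IED counts
span the published 8–100 range.  All randomness descends from one root
seed through a `SeedSequence` spawn tree, so any patient can be
regenerated independently.

Not emulated: spike waveform morphology and propagation (every published
computation uses the single peak sample, so records reduce to the peak
topography), correlated or structured sensor noise, multi-focal
generators, channel-selection behaviour of a human expert, and head-model
mismatch (the same leadfield generates and inverts the data — an
"inverse crime" that makes the synthetic recovery rates *upper bounds*;
they validate the computational chain, not clinical performance).
Fixture-based reproduction of the published tables, by contrast, involves
no simulation at all.

## Problem sizes and determinism

The default simulation grid is 10 mm / margin 12 (≈ 1 900 points) rather
than the clinical 5 mm (≈ 20 000), keeping a full 22-patient × 10-spike
end-to-end run with ECD benchmarking around a minute on one CPU; the
particle-sampler oracle test runs on a 100-point shell space.  Scaling the
grid changes the absolute DLD quantisation floor but none of the chain's
logic.  Pipelines are byte-deterministic given a configuration and seed.

## Known limitations

* The sphere forward model cannot represent conductivity inhomogeneities
  or realistic cortical geometry; all localization accuracies are
  sphere-world figures.
* The Bayesian solver implements the single-dipole posterior only; the
  trans-dimensional case (unknown dipole count) is out of scope, matching
  the single-dipole regime the benchmark operates in.
* The confidence-volume definition is package-specific (see above), so
  acceptance rates are comparable within this package, not across fitting
  software.
* The minimum-norm peak carries an intrinsic ~1–1.5 cm displacement at
  these grid resolutions (see above); map-level metrics (MLD, SD, AUC),
  which are the quantities the benchmark actually compares, are
  unaffected as definitions.
* The lobar atlas is angular, not anatomical; percentages are comparable
  across methods within a simulation but not with real parcellations.
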