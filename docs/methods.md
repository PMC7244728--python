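# Methods

## Problem

Wavefront aberrometry measures the eye's optical error as a height map
W(x, y) over the pupil, usually expanded in Zernike polynomials Z_n^m.
Clinicians, however, prescribe a sphero-cylinder — equivalently a power
vector (M, J0, J45) in diopters — obtained by subjective refraction.  The
two disagree systematically: the subjective endpoint is not the paraxial
refraction of the measured wavefront because higher-order aberrations
(spherical aberration above all) shift the perceived best focus.
`refractml` implements, and makes testable end to end, a pipeline that
predicts the subjective power vector from wavefront coefficients expressed
in an LD/HD ("low degree / high degree") polynomial basis, comparing
gradient-boosted-tree regression against paraxial curvature matching.

## The LD/HD basis

A Zernike mode of radial order n >= 3 can contain monomials of total degree
<= 2 (e.g. Z_4^0 = sqrt5 (6 rho^4 - 6 rho^2 + 1) carries defocus-like rho^2
content).  Those low-degree terms are exactly what curvature at the pupil
center sees, so Zernike high-order coefficients contaminate the paraxial
sphero-cylinder.  The LD/HD basis removes the ambiguity:

* modes with n <= 2 are the Zernike modes themselves;
* for each mode with n >= 3, the Zernike polynomial is expanded in
  monomials, every term of total degree <= 2 is deleted, and the truncated
  set is orthonormalized by classical Gram–Schmidt (one re-orthogonalization
  pass) in ascending (n, m) order under the disk-average inner product
  ⟨f, g⟩ = (1/π)∫∫ f·g over the unit disk.  Signs are fixed so each mode
  has positive overlap with its truncated parent.

All polynomials are held as exact monomial coefficient tables; inner
products use the closed form of ∫∫ x^a y^b over the disk, so the
construction carries no quadrature error.  Both bases span the same
28-dimensional space (order <= 6), and the coefficient transform
G = Mg⁻¹ Mz c preserves the reconstructed wavefront identically: the
deleted low-degree content reappears in the low-order coefficients (a unit
of Zernike c(4,0) contributes exactly −√15 µm of LD/HD defocus G(2,0)).

Consequences used throughout:

* every high-order LD/HD mode has value, gradient and curvature zero at the
  pupil center, so the low-order coefficients alone carry the paraxial
  refraction;
* paraxial matching becomes three closed-form expressions,
  M = −4√3 G(2,0)/r², J0 = −2√6 G(2,2)/r², J45 = −2√6 G(2,−2)/r²
  (G in µm, pupil radius r in mm, result in diopters), and these are
  verified in tests to equal the analytic curvature of the reconstructed
  Zernike wavefront at the origin to 1e−6 D on random wavefronts.

Normalization is ANSI/OSA (Z_2^0 = √3(2ρ²−1), Z_2^2 = √6 ρ² cos 2θ), which
is what produces the 4√3 and 2√6 factors above.

## Synthetic cohort

No clinical dataset ships with the package; a seeded generator emulates a
refractive-surgery screening population so every stage can be validated at
desk scale.  Defaults (all configurable in `CohortParams`):

| quantity | default | note |
|---|---|---|
| spherical equivalent | N(−1.89, 2.54²) D, winsorized to [−6.75, 6.13] | myopic adult population |
| cylinder | N(−0.81, 0.90²) D, winsorized to [−6, 0] | negative-cylinder convention |
| age | N(36.0, 11.2²) y, winsorized to [18, 72] | patient-level |
| inter-eye correlation | ρ = 0.9 | shared patient component |
| axis | von Mises (κ=2) doubled-angle, mirror-symmetric between eyes | with-the-rule bias |
| HOA per-mode SD | 0.05 / 0.03 / 0.015 / 0.015 µm (orders 3/4/5/6) | 4 mm pupil |
| spherical aberration mean | +0.02 µm | c(4,0) |
| corr(c(4,±2), c(2,±2)) | 0.4 | secondary tracks primary astigmatism |
| corr(c(4,0), SE) | 0.2 | SA tracks refractive error |
| measured pupil | N(5.0, 0.8) mm | eyes < 4 mm excluded |

Winsorizing (clipping) rather than rejection-sampling the bounded normals
is deliberate: at these bound positions rejection truncation would shift
the SE mean by ≈ +0.16 D away from its nominal value, while clipping keeps
mean and SD within Monte-Carlo tolerance of the configured moments.

The LD/HD–LO correlations reflect real ocular optics, where higher-order
aberrations are not independent of the sphero-cylinder; they also matter
structurally: they are what gives a low-order-only predictor any systematic
signal beyond paraxial matching for the astigmatic vectors.

### Ground-truth subjective refraction

The subjective endpoint departs from the paraxial power vector linearly in
the rotationally matched 4th/6th-order LD/HD coefficients:

    M_subj   = M_par  + (k_m4 G(4,0) + k_m6 G(6,0)) / r²
    J0_subj  = J0_par + k_j G(4,2) / r²
    J45_subj = J45_par + k_j G(4,−2) / r²

with dimensionless defaults k_m4 = +2.0, k_m6 = −0.5, k_j = +1.5.  Setting
all weights to zero reduces the generator exactly to paraxial matching — a
closed-loop identity asserted in tests.  This is the minimal mechanism that
makes spherical aberration shift the spherical endpoint and secondary
astigmatism shift the astigmatic endpoints; it is a modeling device, not a
visual-performance model: it ignores pupil-size dependence of the shift,
neural adaptation, and any nonlinearity in how image quality maps to the
chosen endpoint.

### Measurement model

* Examiner noise: Gaussian on the subjective power vector, SD 0.12 D on M
  and 0.08 D on J0/J45.
* Prescription grid: the noisy endpoint is converted to sphere/cylinder/axis
  and snapped to 0.25 D under a maximum-plus rule (exact midpoints resolve
  toward the more positive sphere and the smaller-magnitude cylinder; axis
  to the nearest degree).
* Instrument noise: Gaussian, SD 0.01 µm per *measured LD/HD mode*.  The
  injection basis matters: the Zernike→LD/HD rows have norms up to ~17, so
  i.i.d. noise per Zernike mode would be amplified into ~0.17 D of spurious
  paraxial error — an artifact of the injection point.  The aberrometer
  reports G coefficients, so that is where noise belongs.

What passing tests on this generator do **not** show: performance on real
eyes, whose HOA structure, accommodation behavior and examiner variability
are all richer than this model; the replica validates the pipeline's
machinery and the qualitative method ordering, not clinical error
magnitudes.

## Predictors

* **Paraxial matching** — the closed-form low-order expressions above,
  applied to the measured coefficients.  No training.
* **Gradient-boosted trees** — one XGBoost regressor per power-vector
  component, squared-error objective, on either the three low-order LD/HD
  coefficients or all 25 modes of order 2–6 (piston and tilts are never
  features).  Hyperparameters (trees 50–400, depth 2–6, learning rate
  0.02–0.3 log-uniform, row/column subsampling 0.6–1.0, min child weight
  1–10) are tuned by randomized search under 5-fold cross-validation whose
  folds never split a patient, then refit on all training rows.  An i.i.d.
  standard-normal control column joins the full feature set so importances
  can be benchmarked against pure noise.

Numerical choices that matter:

* `tree_method="hist"` with `max_bin=1024`: defocus spans ~15 D across the
  cohort, and the default 256 bins would quantize the dominant feature to
  ~0.06 D — measured as ~0.023 D of pure approximation error on a noise-free
  linear target; 1024 bins halve it.
* Search budget: 50 candidates by default.  The study replica uses 16
  candidates for the low-order models and 6 for the full models: the
  low-order-vs-paraxial contrast is near-tied by construction, so its
  (cheap, 3-feature) models need a stable search, while the full models'
  advantage is insensitive to tuning and they dominate runtime.
* Bagged refit: the selected configuration is refit five times with
  distinct seeds and the member mean is the final predictor.  Row/column
  subsampling makes a single boosted fit stochastic; averaging removes that
  variance without changing the hypothesis class, which matters for the
  near-tied low-order-vs-paraxial contrast.
* Determinism: single-threaded XGBoost with fixed seeds; identical inputs
  reproduce identical hyperparameters and predictions bit for bit.

Feature attribution uses XGBoost's exact tree-path additive (SHAP)
contributions; base value plus row-sum reproduces each prediction to float32
accumulation accuracy (~1e−5 D).

## Evaluation

Per method and vector, on per-eye signed errors (predicted − subjective):
MAE; accuracy = mean error; precision = 2 × sample SD (ddof = 1).  Pairwise
contrasts: Wilcoxon signed-rank (two-sided, Pratt zero handling) on absolute
and signed errors, Levene (mean-centered) on spread, all
Bonferroni-multiplied by the family of 3 method pairs within one (vector,
metric) cell and flagged at adjusted α = 0.05.  Agreement: Bland–Altman bias
± 1.96 SD with a one-sample t-test of the differences; joint astigmatic
error summarized by the covariance confidence ellipse (semi-axes
√(eigenvalue · χ²₂(0.95))); error densities by Gaussian KDE with Scott's
bandwidth.  Train/test comparability: Welch t-tests for continuous
variables, two-sample proportion z-tests for binary shares.

Degenerate inputs are defined away rather than guessed at: identical error
series report p = 1; zero-variance Bland–Altman differences report p = 1
(bias 0) or 0; a singular (J0, J45) covariance yields a flagged degenerate
ellipse.

## Study replica and problem sizes

`RunConfig` defaults mirror the target study geometry: 2280 patients × 2
eyes, ~10.6% pupil exclusions, a 350-eye held-out test set assigned by whole
patients (the greedy assignment may overshoot by one eye at a paired-eye
boundary), leaving ≈ 3729 training eyes.  One master seed fans out to every
stage through `numpy.random.SeedSequence` spawning, so a single integer
reproduces cohort, split, control column and all six models; test eyes are
touched only at prediction time.

The expected qualitative outcome, checked over five independent replicas,
is MAE(full-feature GBT) < MAE(low-order GBT) < MAE(paraxial) for each
vector, with the full-vs-paraxial Wilcoxon contrast significant after
Bonferroni correction.  The outer contrasts are decisive in every replica.
The middle leg deserves a candid caveat: for the astigmatic vectors the
low-order model's true advantage over paraxial matching under these
defaults is ~+0.002 D of MAE, the same order as the sampling noise of a
350-eye test set (standard error ~0.0016 D), so its per-replica sign is
close to a fair coin weighted toward success.  A reference low-order model
trained on ~18,000 independent eyes — removing estimator error entirely —
still gets that leg wrong in 2 of 10 replicas, which bounds what any
estimator can achieve at this test size; at the study's own 3,729 training
eyes the bagged, tuned models recover roughly half that ceiling.  The same
contrast was marginal in clinical reports of this comparison, so the
narrowness is a feature of the problem, not an artifact of the simulation.
For the spherical equivalent the ordering is robust (positive in every
replica examined).

## Known limitations

* The generator's HOA magnitudes and LD/HD–LO correlations are plausible
  but not fitted to any published cohort; absolute error magnitudes from the
  replica are not clinical estimates.
* The mechanism is linear and pupil-static; real subjective endpoints are
  neither.
* One analysis pupil (4 mm diameter) per run; chromatic effects, vertex
  distance and accommodation dynamics are out of scope.
* Tree-path attributions are exact for the fitted ensemble but inherit the
  usual caveats of correlated features when read causally.
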