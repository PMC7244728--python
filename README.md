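# refractml

Predicting subjective sphero-cylindrical refraction from ocular wavefront
aberrometry, for vision scientists and ophthalmic-optics researchers who
want an objective, reproducible route from a measured wavefront to a
spectacle prescription.

Subjective refraction — the clinician-guided endpoint expressed as sphere,
cylinder and axis — remains the gold standard, but it is slow and noisy.
An aberrometer measures the full wavefront error W(x, y) of the eye, yet
its paraxial refraction disagrees systematically with the subjective one
because higher-order aberrations (spherical aberration above all) shift the
perceived best focus.  `refractml` implements:

* **the LD/HD polynomial basis**: a re-decomposition of the Zernike
  expansion (order ≤ 6) in which every high-order mode is stripped of its
  degree-≤2 monomial content and re-orthonormalized, so that the low-order
  coefficients alone carry the paraxial power vector

      M = −4√3·G₂⁰ / r²,  J0 = −2√6·G₂² / r²,  J45 = −2√6·G₂⁻² / r²

  (coefficients in µm, pupil radius r in mm, result in diopters) — built
  from exact monomial tables and verified against curvature at the pupil
  center;
* **power-vector algebra**: sphere/cylinder/axis ↔ (M, J0, J45), with
  maximum-plus rounding to the 0.25 D prescription grid;
* **a seeded synthetic eye-cohort generator** (two correlated eyes per
  patient, realistic refractive demographics and higher-order aberrations,
  a ground-truth mechanism by which HOA shift the subjective endpoint,
  examiner noise and grid quantization);
* **predictors**: paraxial curvature matching, and per-vector XGBoost
  models on LD/HD coefficients (low-order-only or all 25 modes), tuned by
  patient-grouped randomized-search cross-validation, with exact tree-path
  additive (SHAP) feature attributions;
* **evaluation**: MAE / accuracy (mean error) / precision (2·SD), Wilcoxon
  and Levene pairwise tests with Bonferroni correction, Bland–Altman
  agreement, confidence ellipses, KDE error densities and train/test
  comparability tables.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
from refractml import (
    CohortParams, CVSpec, RunConfig, run_study,
)

config = RunConfig(
    cohort=CohortParams(n_patients=600),
    n_test_eyes=200,
    cv=CVSpec(n_candidates=6),
    seed=7,
)
result = run_study(config)
print(result.report.metrics.pivot(index="method", columns="vector", values="mae").round(3))
print(result.attributions["M"].ranking.head(3).round(4))
```

prints

```
vector       J0    J45      M
method
paraxial  0.088  0.081  0.181
xgb_all   0.077  0.066  0.138
xgb_low   0.097  0.081  0.195
```

— the per-eye mean absolute prediction error (D) on the 200 held-out test
eyes for each method and power-vector component: the full-feature model
beats paraxial matching by ~0.04 D on the spherical equivalent M because it
learns how spherical aberration shifts the subjective endpoint, while the
low-order-only model needs more training eyes than this small example
provides before its slender edge over paraxial matching emerges — and

```
G2_0    1.9448
G4_0    0.1084
G2_2    0.0096
```

— the global feature importances (mean |additive contribution|, D) of the
M model: defocus dominates, spherical aberration is the runner-up.

At the full study scale (2280 patients → ≈3729 training / 350 test eyes,
deeper tuning) the full-feature model beats both alternatives decisively on
every vector; the low-only-vs-paraxial contrast is positive on average but
genuinely narrow — fractions of 0.01 D against a 350-eye test set — so its
sign can flip between replicas, exactly as in clinical reports of this
comparison.  See the acceptance script below.

The same pipeline is scriptable from the shell:

```bash
refractml run-all --seed 7 --out results/run7          # full replica
refractml simulate --seed 3 --out results/sim          # cohort + coefficients CSV
refractml decompose --coefficients results/sim/coefficients.csv \
    --out results/sim/ldhd.csv                         # Zernike -> LD/HD
refractml evaluate --predictions results/run7/predictions_xgb_all.csv \
    --subjective results/run7/test_cohort.csv --out results/eval
```

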