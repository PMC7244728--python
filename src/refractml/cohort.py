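"""Seeded synthetic eye cohorts for desk-scale refraction studies.

The generator emulates a refractive-surgery screening population: two eyes
per patient with strongly correlated refractive error, a winsorized-normal
spherical-equivalent and cylinder distribution, a with-the-rule axis bias
with inter-eye mirror symmetry, realistic higher-order aberration magnitudes
at a 4 mm analysis pupil, and a ground-truth subjective refraction that the
higher-order aberrations shift away from the paraxial value.  Subjective
endpoints are then blurred (examiner variability) and snapped to the 0.25 D
prescription grid under the maximum-plus rule, and wavefront coefficients
receive instrument noise — so no predictor can be exactly right, as in a real
refraction lane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import (
    LDHD,
    ZERNIKE,
    BasisTransform,
    ModeIndex,
    WavefrontCoefficients,
    build_ldhd_transform,
    modes_up_to,
    paraxial_curvature_refraction,
    zernike_to_ldhd,
)
from .power_vectors import (
    PowerVector,
    Refraction,
    power_vector_to_refraction,
    quantize_max_plus,
    refraction_to_power_vector,
)

__all__ = [
    "MechanismWeights",
    "NoiseParams",
    "CohortParams",
    "EyeRecord",
    "Cohort",
    "generate_cohort",
    "true_subjective_refraction",
    "add_noise_and_quantize",
    "apply_exclusions",
    "split_cohort",
    "low_order_zernike_from_power_vector",
]

_SQ3 = np.sqrt(3.0)
_SQ6 = np.sqrt(6.0)


@dataclass(frozen=True)
class MechanismWeights:
    """Dimensionless weights of the HOA shift of the subjective endpoint.

    The subjective power vector departs from the paraxial one linearly in the
    rotationally matched high-order LD/HD coefficients (um) scaled by the
    squared pupil radius (mm^2), so each term is in diopters:

        M_subj   = M_par  + k_m4 * G(4,0)/r^2 + k_m6 * G(6,0)/r^2
        J0_subj  = J0_par + k_j  * G(4,2)/r^2
        J45_subj = J45_par + k_j * G(4,-2)/r^2

    All weights zero reduces exactly to paraxial matching.
    """

    k_m4: float = 2.0
    k_m6: float = -0.5
    k_j: float = 1.5

    def is_null(self) -> bool:
        return self.k_m4 == self.k_m6 == self.k_j == 0.0


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model (all SDs >= 0)."""

    subjective_sd_m: float = 0.12  # D, examiner noise on M
    subjective_sd_j: float = 0.08  # D, on J0 and J45
    coeff_sd_um: float = 0.01  # instrument noise per measured (LD/HD) mode
    quantize_step: float = 0.25  # D; <= 0 disables grid snapping

    def __post_init__(self) -> None:
        if min(self.subjective_sd_m, self.subjective_sd_j, self.coeff_sd_um) < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class CohortParams:
    """Population parameters of the simulated cohort.

    Refractive demographics default to a myopic adult refractive-surgery
    population (SE mean -1.89 D, SD 2.54 D; cylinder mean -0.81 D, SD 0.90 D;
    age mean 36, SD 11).  Bounds are applied by winsorizing (clipping), which
    preserves the stated mean/SD far better than rejection truncation at
    these bound positions.  Higher-order aberration magnitudes are plausible
    4 mm-pupil values; secondary astigmatism partially tracks primary
    astigmatism and spherical aberration tracks spherical equivalent, as in
    real eyes (both correlations configurable, set to 0 for fully independent
    HOA draws).
    """

    n_patients: int = 2000
    se_mean: float = -1.89
    se_sd: float = 2.54
    se_bounds: tuple[float, float] = (-6.75, 6.13)
    cyl_mean: float = -0.81
    cyl_sd: float = 0.90
    cyl_bounds: tuple[float, float] = (-6.0, 0.0)
    age_mean: float = 36.03
    age_sd: float = 11.24
    age_bounds: tuple[float, float] = (18.0, 72.0)
    fraction_female: float = 0.571
    inter_eye_rho: float = 0.9
    axis_kappa: float = 2.0  # von Mises concentration of the doubled axis
    pupil_mean_mm: float = 5.0
    pupil_sd_mm: float = 0.8
    analysis_pupil_mm: float = 4.0  # coefficient pupil diameter
    max_order: int = 6
    hoa_sd_by_order: tuple[float, ...] = (0.05, 0.03, 0.015, 0.015)  # orders 3..6
    sa_mean_um: float = 0.02  # primary spherical aberration c(4,0)
    corr_secondary_astigmatism: float = 0.4  # c(4,+-2) vs c(2,+-2)
    corr_sa_se: float = 0.2  # c(4,0) vs spherical equivalent
    mechanism: MechanismWeights = field(default_factory=MechanismWeights)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for lo, hi in (self.se_bounds, self.cyl_bounds, self.age_bounds):
            if lo > hi:
                raise ValueError("bounds must be ordered (low <= high)")
        if min(self.se_sd, self.cyl_sd, self.age_sd, self.pupil_sd_mm) < 0:
            raise ValueError("SDs must be >= 0")
        if len(self.hoa_sd_by_order) != self.max_order - 2:
            raise ValueError("hoa_sd_by_order must cover orders 3..max_order")


@dataclass
class EyeRecord:
    patient_id: int
    eye_id: str
    side: str  # OD | OS
    age: float
    sex: str  # F | M
    pupil_mm: float  # measured pupil during acquisition (gates exclusion)
    true_coeffs: WavefrontCoefficients  # zernike, noise-free
    measured_coeffs: WavefrontCoefficients  # ldhd, after instrument noise
    true_subjective_pv: PowerVector  # mechanism output, noise-free
    subjective: Refraction  # after noise + maximum-plus quantization
    subjective_pv: PowerVector
    drawn_se: float  # the sampled spherical equivalent (pre-mechanism)
    drawn_cyl: float


@dataclass
class Cohort:
    eyes: list[EyeRecord]
    params: CohortParams

    def __len__(self) -> int:
        return len(self.eyes)

    @property
    def patient_ids(self) -> list[int]:
        return sorted({e.patient_id for e in self.eyes})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.eyes:
            rows.append(
                {
                    "patient_id": e.patient_id,
                    "eye_id": e.eye_id,
                    "side": e.side,
                    "age": e.age,
                    "sex": e.sex,
                    "pupil_mm": e.pupil_mm,
                    "sphere_D": e.subjective.sphere,
                    "cylinder_D": e.subjective.cylinder,
                    "axis_deg": e.subjective.axis,
                    "M": e.subjective_pv.M,
                    "J0": e.subjective_pv.J0,
                    "J45": e.subjective_pv.J45,
                    "drawn_se": e.drawn_se,
                    "drawn_cyl": e.drawn_cyl,
                }
            )
        return pd.DataFrame(rows)


def low_order_zernike_from_power_vector(
    pv: PowerVector, pupil_radius_mm: float
) -> dict[tuple[int, int], float]:
    """Invert paraxial matching: low-order coefficients (um) from (M, J0, J45)."""
    r2 = pupil_radius_mm**2
    return {
        (2, 0): -pv.M * r2 / (4.0 * _SQ3),
        (2, 2): -pv.J0 * r2 / (2.0 * _SQ6),
        (2, -2): -pv.J45 * r2 / (2.0 * _SQ6),
    }


def true_subjective_refraction(
    eye: EyeRecord,
    weights: MechanismWeights | None = None,
    transform: BasisTransform | None = None,
) -> PowerVector:
    """Noise-free subjective endpoint implied by the eye's true wavefront."""
    w = eye.true_coeffs
    return _mechanism_pv(w, weights or MechanismWeights(), transform)


def _mechanism_pv(
    w: WavefrontCoefficients,
    weights: MechanismWeights,
    transform: BasisTransform | None = None,
) -> PowerVector:
    par = paraxial_curvature_refraction(w)
    if weights.is_null():
        return par
    g = zernike_to_ldhd(w, transform)
    r2 = w.pupil_radius_mm**2
    return PowerVector(
        M=par.M + (weights.k_m4 * g[(4, 0)] + weights.k_m6 * g[(6, 0)]) / r2,
        J0=par.J0 + weights.k_j * g[(4, 2)] / r2,
        J45=par.J45 + weights.k_j * g[(4, -2)] / r2,
    )


def add_noise_and_quantize(
    eye: EyeRecord, noise: NoiseParams, rng: np.random.Generator
) -> EyeRecord:
    """Apply examiner noise + prescription-grid snapping and instrument noise."""
    pv = eye.true_subjective_pv
    noisy = PowerVector(
        M=pv.M + rng.normal(0.0, noise.subjective_sd_m),
        J0=pv.J0 + rng.normal(0.0, noise.subjective_sd_j),
        J45=pv.J45 + rng.normal(0.0, noise.subjective_sd_j),
    )
    subjective = power_vector_to_refraction(noisy)
    if noise.quantize_step > 0:
        subjective = quantize_max_plus(subjective, noise.quantize_step)
    # The aberrometer reports LD/HD coefficients, so instrument noise acts on
    # the G modes it measures; adding i.i.d. noise per Zernike mode instead
    # would be amplified (up to ~17x) by the ill-conditioned change of basis.
    g_true = zernike_to_ldhd(eye.true_coeffs)
    measured = WavefrontCoefficients(
        basis=LDHD,
        values=g_true.values
        + rng.normal(0.0, noise.coeff_sd_um, size=g_true.values.shape),
        pupil_radius_mm=eye.true_coeffs.pupil_radius_mm,
        max_order=eye.true_coeffs.max_order,
    )
    return replace(
        eye,
        subjective=subjective,
        subjective_pv=refraction_to_power_vector(subjective),
        measured_coeffs=measured,
    )


def _winsorized_normal(
    rng: np.random.Generator, mean, sd, bounds, size
) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=size), bounds[0], bounds[1])


def generate_cohort(params: CohortParams, seed: int | None = None) -> Cohort:
    """Draw a full synthetic cohort (two eyes per patient), deterministically.

    ``seed`` overrides ``params.seed`` when given.  Inter-eye correlation uses
    a shared-patient-component construction: for correlation rho, each eye's
    standardized deviate is sqrt(rho)*z_patient + sqrt(1-rho)*z_eye, which
    preserves the marginal distribution.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n = params.n_patients
    transform = build_ldhd_transform(params.max_order)
    modes = modes_up_to(params.max_order)
    r = params.analysis_pupil_mm / 2.0

    if n == 0:
        return Cohort(eyes=[], params=params)

    rho = params.inter_eye_rho
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)

    def eye_pair_deviates() -> np.ndarray:  # (n, 2) standardized, corr rho
        z_pat = rng.normal(size=(n, 1))
        z_eye = rng.normal(size=(n, 2))
        return a * z_pat + b * z_eye

    age = _winsorized_normal(rng, params.age_mean, params.age_sd, params.age_bounds, n)
    sex = np.where(rng.random(n) < params.fraction_female, "F", "M")
    se = np.clip(
        params.se_mean + params.se_sd * eye_pair_deviates(), *params.se_bounds
    )
    cyl = np.clip(
        params.cyl_mean + params.cyl_sd * eye_pair_deviates(), *params.cyl_bounds
    )
    # doubled-axis von Mises around 0 (with-the-rule in minus-cyl convention),
    # mirror-symmetric between fellow eyes
    axis_od = np.degrees(rng.vonmises(0.0, params.axis_kappa, size=n) / 2.0) % 180.0
    axis = np.column_stack([axis_od, (180.0 - axis_od) % 180.0])
    pupil = rng.normal(params.pupil_mean_mm, params.pupil_sd_mm, size=(n, 2))

    # higher-order Zernike draws, flattened over eyes
    n_eyes = 2 * n
    se_flat = se.reshape(-1)
    cyl_flat = cyl.reshape(-1)
    axis_flat = axis.reshape(-1)
    hoa = np.zeros((n_eyes, len(modes)))
    sd_of = {o: s for o, s in zip(range(3, params.max_order + 1), params.hoa_sd_by_order)}
    # standardized low-order drivers for the HOA correlations
    se_std = _standardize(se_flat)
    for i, mode in enumerate(modes):
        if mode.n < 3:
            continue
        sd = sd_of[mode.n]
        z = rng.normal(size=n_eyes)
        if mode.n == 4 and mode.m in (2, -2) and params.corr_secondary_astigmatism:
            c = params.corr_secondary_astigmatism
            driver = _standardize(_c2_component(cyl_flat, axis_flat, mode.m, r))
            hoa[:, i] = sd * (c * driver + np.sqrt(1 - c**2) * z)
        elif mode == ModeIndex(4, 0):
            c = params.corr_sa_se
            hoa[:, i] = params.sa_mean_um + sd * (c * se_std + np.sqrt(1 - c**2) * z)
        else:
            hoa[:, i] = sd * z

    pos = {(m.n, m.m): i for i, m in enumerate(modes)}
    eyes: list[EyeRecord] = []
    for p in range(n):
        for k, side in enumerate(("OD", "OS")):
            j = 2 * p + k
            cylinder = min(cyl_flat[j], 0.0)
            ax = axis_flat[j] if cylinder < 0 else 0.0
            sphere = se_flat[j] - cylinder / 2.0
            pv = refraction_to_power_vector(
                Refraction(sphere=sphere, cylinder=cylinder, axis=ax)
            )
            values = hoa[j].copy()
            for nm, v in low_order_zernike_from_power_vector(pv, r).items():
                values[pos[nm]] = v
            true_w = WavefrontCoefficients(
                basis=ZERNIKE, values=values, pupil_radius_mm=r,
                max_order=params.max_order,
            )
            eye = EyeRecord(
                patient_id=p,
                eye_id=f"P{p:05d}-{side}",
                side=side,
                age=float(age[p]),
                sex=str(sex[p]),
                pupil_mm=float(pupil[p, k]),
                true_coeffs=true_w,
                measured_coeffs=true_w,  # replaced by add_noise_and_quantize
                true_subjective_pv=PowerVector(0.0, 0.0, 0.0),
                subjective=Refraction(0.0, 0.0, 0.0),
                subjective_pv=PowerVector(0.0, 0.0, 0.0),
                drawn_se=float(se_flat[j]),
                drawn_cyl=float(cylinder),
            )
            eye.true_subjective_pv = _mechanism_pv(true_w, params.mechanism, transform)
            eyes.append(add_noise_and_quantize(eye, params.noise, rng))
    return Cohort(eyes=eyes, params=params)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def _c2_component(cyl, axis, m, pupil_radius_mm) -> np.ndarray:
    """Low-order astigmatic Zernike coefficient c(2, +-2) implied by (C, axis)."""
    half_c = np.asarray(cyl) / 2.0
    a = np.radians(np.asarray(axis))
    if m == 2:
        j = -half_c * np.cos(2 * a)  # J0
    else:
        j = -half_c * np.sin(2 * a)  # J45
    return -j * pupil_radius_mm**2 / (2.0 * _SQ6)


def apply_exclusions(cohort: Cohort, min_pupil_mm: float = 4.0) -> Cohort:
    """Drop eyes whose acquisition pupil is below the analysis diameter."""
    kept = [e for e in cohort.eyes if e.pupil_mm >= min_pupil_mm]
    return Cohort(eyes=kept, params=cohort.params)


def split_cohort(
    cohort: Cohort, n_test_eyes: int = 350, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Patient-level train/test split with no patient on both sides.

    Patients are shuffled with the given seed and assigned whole to the test
    side until its eye count first reaches ``n_test_eyes`` (so the test side
    may overshoot by one eye at a paired-eye boundary).
    """
    if len(cohort) <= n_test_eyes:
        raise ValueError(
            f"cohort has {len(cohort)} eyes; need more than n_test_eyes={n_test_eyes}"
        )
    by_patient: dict[int, list[EyeRecord]] = {}
    for e in cohort.eyes:
        by_patient.setdefault(e.patient_id, []).append(e)
    patients = sorted(by_patient)
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    test_patients: set[int] = set()
    count = 0
    for p in patients:
        if count >= n_test_eyes:
            break
        test_patients.add(p)
        count += len(by_patient[p])
    test = [e for e in cohort.eyes if e.patient_id in test_patients]
    train = [e for e in cohort.eyes if e.patient_id not in test_patients]
    return Cohort(train, cohort.params), Cohort(test, cohort.params)
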