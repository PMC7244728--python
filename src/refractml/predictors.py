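"""Refraction predictors: paraxial matching and gradient-boosted trees.

Paraxial matching reads the refraction directly off the low-order LD/HD
coefficients,

    M = -G(2,0) * 4*sqrt(3) / r^2,   J0 = -G(2,2) * 2*sqrt(6) / r^2,
    J45 = -G(2,-2) * 2*sqrt(6) / r^2,

with r the pupil radius in mm and G in um.  The machine-learning route
trains one XGBoost regressor per power-vector component on the LD/HD
coefficients (either the three low-order modes or all 25 modes of radial
order 2..6), tuned by randomized search with patient-grouped 5-fold
cross-validation under squared-error loss, and explains its predictions with
exact tree-path additive (SHAP) attributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import loguniform, randint, uniform
from sklearn.model_selection import GroupKFold, RandomizedSearchCV

from .basis import (
    LDHD,
    BasisTransform,
    WavefrontCoefficients,
    build_ldhd_transform,
    modes_up_to,
    zernike_to_ldhd,
)
from .cohort import Cohort
from .power_vectors import PowerVector

__all__ = [
    "LOW_ONLY",
    "ALL_FEATURES",
    "RANDOM_CONTROL",
    "CVSpec",
    "FeatureTable",
    "PredictorModel",
    "FeatureAttribution",
    "paraxial_predict",
    "paraxial_predict_cohort",
    "feature_names",
    "make_feature_table",
    "tune_and_train",
    "predict",
    "feature_attribution",
]

LOW_ONLY = "low_only"
ALL_FEATURES = "all"
RANDOM_CONTROL = "random_control"
TARGETS = ("M", "J0", "J45")

_SQ3 = math.sqrt(3.0)
_SQ6 = math.sqrt(6.0)


def paraxial_predict(g: WavefrontCoefficients) -> PowerVector:
    """Paraxial-matching refraction from LD/HD coefficients (um, mm -> D)."""
    if g.basis != LDHD:
        raise ValueError("paraxial_predict expects ldhd-basis coefficients")
    r2 = g.pupil_radius_mm**2
    return PowerVector(
        M=-g[(2, 0)] * 4.0 * _SQ3 / r2,
        J0=-g[(2, 2)] * 2.0 * _SQ6 / r2,
        J45=-g[(2, -2)] * 2.0 * _SQ6 / r2,
    )


def feature_names(feature_set: str, max_order: int = 6) -> list[str]:
    """Fixed, ordered LD/HD feature columns for a feature set."""
    if feature_set == LOW_ONLY:
        return ["G2_0", "G2_2", "G2_-2"]
    if feature_set == ALL_FEATURES:
        return [
            f"G{m.n}_{m.m}" for m in modes_up_to(max_order) if 2 <= m.n <= max_order
        ]
    raise ValueError(f"unknown feature set {feature_set!r}")


@dataclass(frozen=True)
class CVSpec:
    """Randomized-search cross-validation settings."""

    n_splits: int = 5
    n_candidates: int = 50
    seed: int = 0


@dataclass
class FeatureTable:
    """Per-eye LD/HD features plus power-vector targets.

    ``data`` holds eye_id, patient_id, the feature columns (in ``features``
    order) and the targets M, J0, J45.
    """

    data: pd.DataFrame
    features: list[str]
    feature_set: str
    pupil_radius_mm: float

    def __post_init__(self) -> None:
        missing = [c for c in self.features + list(TARGETS) if c not in self.data]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if self.data[self.features + list(TARGETS)].isna().any().any():
            raise ValueError("feature table contains missing values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.features]

    def y(self, target: str) -> np.ndarray:
        return self.data[target].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.data["patient_id"].to_numpy()


def _ldhd_matrix(cohort: Cohort, transform: BasisTransform) -> np.ndarray:
    coeffs = np.stack([e.measured_coeffs.values for e in cohort.eyes])
    bases = {e.measured_coeffs.basis for e in cohort.eyes}
    if bases == {LDHD}:
        return coeffs
    if bases != {"zernike"}:
        raise ValueError(f"mixed or unknown coefficient bases in cohort: {bases}")
    return coeffs @ transform.to_ldhd.T


def make_feature_table(
    cohort: Cohort,
    feature_set: str = ALL_FEATURES,
    add_random_control: bool = False,
    seed: int = 0,
    transform: BasisTransform | None = None,
) -> FeatureTable:
    """Build the per-eye design matrix from measured wavefront coefficients.

    Piston and the two tilts are never features.  ``add_random_control``
    appends an i.i.d. standard-normal column used to benchmark feature
    importances against pure noise.
    """
    if len(cohort) == 0:
        cols = feature_names(feature_set, cohort.params.max_order)
        features = cols + ([RANDOM_CONTROL] if add_random_control else [])
        empty = pd.DataFrame(
            {c: pd.Series(dtype=float) for c in ["patient_id", *features, *TARGETS]}
        )
        empty.insert(0, "eye_id", pd.Series(dtype=str))
        return FeatureTable(
            data=empty,
            features=features,
            feature_set=feature_set,
            pupil_radius_mm=cohort.params.analysis_pupil_mm / 2.0,
        )
    max_order = cohort.eyes[0].measured_coeffs.max_order
    transform = transform or build_ldhd_transform(max_order)
    g = _ldhd_matrix(cohort, transform)
    modes = modes_up_to(max_order)
    colmap = {f"G{m.n}_{m.m}": i for i, m in enumerate(modes)}
    cols = feature_names(feature_set, max_order)
    data = pd.DataFrame({name: g[:, colmap[name]] for name in cols})
    data.insert(0, "patient_id", [e.patient_id for e in cohort.eyes])
    data.insert(0, "eye_id", [e.eye_id for e in cohort.eyes])
    features = list(cols)
    if add_random_control:
        rng = np.random.default_rng(seed)
        data[RANDOM_CONTROL] = rng.standard_normal(len(cohort))
        features.append(RANDOM_CONTROL)
    for tgt in TARGETS:
        data[tgt] = [getattr(e.subjective_pv, tgt) for e in cohort.eyes]
    return FeatureTable(
        data=data,
        features=features,
        feature_set=feature_set,
        pupil_radius_mm=cohort.eyes[0].measured_coeffs.pupil_radius_mm,
    )


class BaggedGBT:
    """Small bag of identically configured XGBoost regressors.

    Row/column subsampling makes a single boosted ensemble stochastic;
    averaging a few seeds removes that variance from the final predictor
    without changing the hypothesis class.  Predictions (and per-feature
    attributions) are the member means, so attribution additivity is
    preserved exactly.
    """

    def __init__(self, members: list[xgb.XGBRegressor]):
        if not members:
            raise ValueError("need at least one member")
        self.members = members

    def predict(self, X) -> np.ndarray:
        return np.mean([m.predict(X) for m in self.members], axis=0).astype(float)

    def pred_contribs(self, X, feature_names: list[str]) -> np.ndarray:
        dm = xgb.DMatrix(X, feature_names=feature_names)
        return np.mean(
            [m.get_booster().predict(dm, pred_contribs=True) for m in self.members],
            axis=0,
        )


@dataclass
class PredictorModel:
    target: str
    feature_set: str
    features: list[str]
    model: BaggedGBT
    best_params: dict
    cv_best_mse: float
    seed: int


def save_model(model: PredictorModel, path) -> None:
    """Persist a fitted model as one self-describing JSON file."""
    import json as _json

    payload = {
        "target": model.target,
        "feature_set": model.feature_set,
        "features": list(model.features),
        "best_params": model.best_params,
        "cv_best_mse": model.cv_best_mse,
        "seed": model.seed,
        "boosters": [
            _json.loads(bytes(m.get_booster().save_raw("json")).decode("utf-8"))
            for m in model.model.members
        ],
    }
    with open(path, "w") as fh:
        _json.dump(payload, fh)


def load_model(path) -> PredictorModel:
    import json as _json

    with open(path) as fh:
        payload = _json.load(fh)
    members = []
    for raw in payload["boosters"]:
        reg = xgb.XGBRegressor()
        reg.load_model(bytearray(_json.dumps(raw), "utf-8"))
        members.append(reg)
    return PredictorModel(
        target=payload["target"],
        feature_set=payload["feature_set"],
        features=list(payload["features"]),
        model=BaggedGBT(members),
        best_params=payload["best_params"],
        cv_best_mse=payload["cv_best_mse"],
        seed=payload["seed"],
    )


def _search_space():
    return {
        "n_estimators": randint(50, 400),
        "max_depth": randint(2, 7),
        "learning_rate": loguniform(0.02, 0.3),
        "subsample": uniform(0.6, 0.4),
        "colsample_bytree": uniform(0.6, 0.4),
        "min_child_weight": randint(1, 11),
    }


def tune_and_train(
    table: FeatureTable,
    target: str,
    cv_spec: CVSpec | None = None,
    seed: int = 0,
    n_bag: int = 5,
) -> PredictorModel:
    """Randomized hyperparameter search + bagged refit, patient-grouped folds.

    CV folds never split a patient, mirroring the patient-level train/test
    separation; scoring is mean squared error.  The selected configuration
    is refit ``n_bag`` times on all rows with distinct seeds and the member
    mean is the final predictor (row/column subsampling makes a single
    boosted fit stochastic; averaging removes that variance).  Deterministic
    for fixed (table, cv_spec, seed).
    """
    cv_spec = cv_spec or CVSpec()
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}")
    if len(table) < 50:
        raise ValueError(f"need >= 50 rows to tune, got {len(table)}")
    if n_bag < 1:
        raise ValueError("n_bag must be >= 1")
    y = table.y(target)
    if np.std(y) == 0:
        raise ValueError(f"target {target} has zero variance")

    # max_bin: defocus spans ~15 D across the cohort, so the default 256
    # histogram bins would quantize it to ~0.06 D steps — coarser than the
    # precision the models compete at; 1024 bins keep binning error well
    # below the 0.25 D prescription grid.
    def make_regressor(random_state: int) -> xgb.XGBRegressor:
        return xgb.XGBRegressor(
            objective="reg:squarederror",
            tree_method="hist",
            max_bin=1024,
            n_jobs=1,
            random_state=random_state,
        )

    search = RandomizedSearchCV(
        make_regressor(seed),
        _search_space(),
        n_iter=cv_spec.n_candidates,
        cv=GroupKFold(n_splits=cv_spec.n_splits),
        scoring="neg_mean_squared_error",
        random_state=cv_spec.seed,
        refit=False,
        n_jobs=1,
        error_score="raise",
    )
    search.fit(table.X, y, groups=table.groups)
    best_params = {
        k: (v.item() if hasattr(v, "item") else v)
        for k, v in search.cv_results_["params"][search.best_index_].items()
    }
    members = []
    for k in range(n_bag):
        reg = make_regressor(seed + k)
        reg.set_params(**best_params)
        reg.fit(table.X, y)
        members.append(reg)
    return PredictorModel(
        target=target,
        feature_set=table.feature_set,
        features=list(table.features),
        model=BaggedGBT(members),
        best_params=best_params,
        cv_best_mse=float(-search.best_score_),
        seed=seed,
    )


def predict(model: PredictorModel, table: FeatureTable) -> np.ndarray:
    """Predict the model's target (D) for every row of ``table``."""
    if list(table.features) != list(model.features):
        raise ValueError(
            f"feature columns {table.features} do not match the model's "
            f"training columns {model.features}"
        )
    if len(table) == 0:
        return np.empty(0)
    out = model.model.predict(table.X).astype(float)
    if not np.all(np.isfinite(out)):
        raise ArithmeticError("non-finite prediction")
    return out


@dataclass
class FeatureAttribution:
    """Additive per-eye, per-feature contributions (D) with base value.

    base + row-sum of contributions equals the model prediction for that eye;
    ``ranking`` orders features by global mean absolute contribution,
    descending.
    """

    contributions: pd.DataFrame  # columns = features, one row per eye
    base_values: np.ndarray
    ranking: pd.Series  # mean |contribution| indexed by feature, descending

    def rank_of(self, feature: str) -> int:
        """1-based global importance rank of a feature."""
        return int(np.where(self.ranking.index == feature)[0][0]) + 1


def feature_attribution(model: PredictorModel, table: FeatureTable) -> FeatureAttribution:
    """Exact tree-path additive (SHAP) attributions for every row."""
    if list(table.features) != list(model.features):
        raise ValueError("feature columns do not match the model")
    # (n, p+1), last column is the bias; member mean keeps additivity exact
    contrib = model.model.pred_contribs(table.X, list(model.features))
    contributions = pd.DataFrame(
        contrib[:, :-1], columns=list(model.features), index=table.data.index
    )
    ranking = contributions.abs().mean(axis=0).sort_values(ascending=False)
    return FeatureAttribution(
        contributions=contributions,
        base_values=contrib[:, -1].astype(float),
        ranking=ranking,
    )


def paraxial_predict_cohort(
    cohort: Cohort, transform: BasisTransform | None = None
) -> pd.DataFrame:
    """Paraxial-matching predictions for every eye (uses measured coefficients)."""
    if len(cohort) == 0:
        return pd.DataFrame(columns=["eye_id", "M", "J0", "J45"])
    max_order = cohort.eyes[0].measured_coeffs.max_order
    transform = transform or build_ldhd_transform(max_order)
    g = _ldhd_matrix(cohort, transform)
    modes = modes_up_to(max_order)
    pos = {(m.n, m.m): i for i, m in enumerate(modes)}
    r2 = cohort.eyes[0].measured_coeffs.pupil_radius_mm ** 2
    return pd.DataFrame(
        {
            "eye_id": [e.eye_id for e in cohort.eyes],
            "M": -g[:, pos[(2, 0)]] * 4.0 * _SQ3 / r2,
            "J0": -g[:, pos[(2, 2)]] * 2.0 * _SQ6 / r2,
            "J45": -g[:, pos[(2, -2)]] * 2.0 * _SQ6 / r2,
        }
    )
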