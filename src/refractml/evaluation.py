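"""Error metrics, paired statistics and agreement analyses.

Terminology follows the clinical wavefront-refraction literature: for a
prediction method and one power-vector component, the prediction error is
(predicted - subjective) in diopters; *accuracy* is the mean error,
*precision* is two sample standard deviations of the error.  Methods are
compared pairwise with the Wilcoxon signed-rank test (absolute and signed
errors) and Levene's test (error spread), Bonferroni-corrected within each
(vector, metric) family; agreement with the subjective endpoint uses
Bland-Altman limits and a one-sample t-test; the joint astigmatic error
(J0, J45) is summarized by a covariance confidence ellipse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ErrorSeries",
    "MetricSummary",
    "ComparisonResult",
    "BlandAltman",
    "ConfidenceEllipse",
    "compute_errors",
    "summarize",
    "compare_methods",
    "bland_altman",
    "confidence_ellipse",
    "density_summary",
    "group_comparability",
    "EvaluationReport",
    "build_report",
]

VECTORS = ("M", "J0", "J45")


@dataclass
class ErrorSeries:
    """Per-eye signed prediction error (predicted - subjective, D)."""

    method: str
    vector: str
    eye_ids: np.ndarray
    errors: np.ndarray

    def __post_init__(self) -> None:
        self.eye_ids = np.asarray(self.eye_ids)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.eye_ids.shape != self.errors.shape:
            raise ValueError("eye_ids and errors must align")
        if not np.all(np.isfinite(self.errors)):
            raise ValueError("errors must be finite")

    def __len__(self) -> int:
        return len(self.errors)


def compute_errors(
    predictions: pd.DataFrame, subjective: pd.DataFrame, method: str
) -> dict[str, ErrorSeries]:
    """Signed errors per vector, aligned by eye_id.

    Both frames need columns eye_id, M, J0, J45; every subjective eye must be
    predicted exactly once.
    """
    pred = predictions.set_index("eye_id")
    subj = subjective.set_index("eye_id")
    if pred.index.has_duplicates or subj.index.has_duplicates:
        raise ValueError("duplicate eye_id")
    missing = subj.index.difference(pred.index)
    if len(missing):
        raise ValueError(f"predictions missing for eyes: {list(missing[:5])} ...")
    pred = pred.loc[subj.index]
    return {
        v: ErrorSeries(
            method=method,
            vector=v,
            eye_ids=subj.index.to_numpy(),
            errors=(pred[v] - subj[v]).to_numpy(),
        )
        for v in VECTORS
    }


@dataclass(frozen=True)
class MetricSummary:
    mae: float
    mae_sd: float
    accuracy: float  # mean signed error
    sd: float  # sample SD (n-1) of signed error
    precision: float  # 2 * sd
    min: float
    max: float
    n: int


def summarize(e: ErrorSeries) -> MetricSummary:
    """MAE, accuracy (mean error) and precision (2 x sample SD) of a series."""
    if len(e) < 2:
        raise ValueError("need at least 2 errors to summarize")
    err = e.errors
    sd = float(np.std(err, ddof=1))
    return MetricSummary(
        mae=float(np.mean(np.abs(err))),
        mae_sd=float(np.std(np.abs(err), ddof=1)),
        accuracy=float(np.mean(err)),
        sd=sd,
        precision=2.0 * sd,
        min=float(np.min(err)),
        max=float(np.max(err)),
        n=len(e),
    )


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0  # identical samples: no evidence of a difference
    res = stats.wilcoxon(a, b, zero_method="pratt", alternative="two-sided")
    return float(res.pvalue)


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise method comparison for one vector.

    Raw and Bonferroni-adjusted p-values for the MAE (Wilcoxon on |error|),
    accuracy (Wilcoxon on signed error) and precision (Levene, mean-centered)
    contrasts; significance flags use the adjusted p at alpha = 0.05.
    """

    method_a: str
    method_b: str
    vector: str
    family_size: int
    p_mae: float
    p_accuracy: float
    p_precision: float
    p_mae_adj: float
    p_accuracy_adj: float
    p_precision_adj: float
    sig_mae: bool
    sig_accuracy: bool
    sig_precision: bool


def compare_methods(
    a: ErrorSeries, b: ErrorSeries, family_size: int = 3, alpha: float = 0.05,
    levene_center: str = "mean",
) -> ComparisonResult:
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if a.vector != b.vector:
        raise ValueError("series compare different vectors")
    if len(a) != len(b) or not np.array_equal(a.eye_ids, b.eye_ids):
        raise ValueError("error series are not aligned on the same eyes")
    p_mae = _wilcoxon_p(np.abs(a.errors), np.abs(b.errors))
    p_acc = _wilcoxon_p(a.errors, b.errors)
    if np.allclose(a.errors, b.errors):
        p_prec = 1.0
    else:
        p_prec = float(stats.levene(a.errors, b.errors, center=levene_center).pvalue)

    def adj(p: float) -> float:
        return min(1.0, p * family_size)

    return ComparisonResult(
        method_a=a.method,
        method_b=b.method,
        vector=a.vector,
        family_size=family_size,
        p_mae=p_mae,
        p_accuracy=p_acc,
        p_precision=p_prec,
        p_mae_adj=adj(p_mae),
        p_accuracy_adj=adj(p_acc),
        p_precision_adj=adj(p_prec),
        sig_mae=adj(p_mae) < alpha,
        sig_accuracy=adj(p_acc) < alpha,
        sig_precision=adj(p_prec) < alpha,
    )


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    t_p: float  # one-sample t-test of the differences against 0


def bland_altman(predicted: np.ndarray, subjective: np.ndarray) -> BlandAltman:
    """Bias and 95% limits of agreement (bias +- 1.96 SD) of the differences."""
    predicted = np.asarray(predicted, dtype=float)
    subjective = np.asarray(subjective, dtype=float)
    if predicted.shape != subjective.shape or predicted.size < 2:
        raise ValueError("need two aligned samples of size >= 2")
    d = predicted - subjective
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        p = 1.0 if bias == 0.0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return BlandAltman(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, sd=sd, t_p=p
    )


@dataclass(frozen=True)
class ConfidenceEllipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    orientation_deg: float  # of the major axis, in (-90, 90]
    level: float
    degenerate: bool


def confidence_ellipse(
    j0_err: np.ndarray, j45_err: np.ndarray, level: float = 0.95
) -> ConfidenceEllipse:
    """Covariance confidence ellipse of the bivariate (J0, J45) error sample.

    Semi-axes are sqrt(eigenvalue * chi2_2.ppf(level)); the orientation is the
    leading eigenvector's angle.
    """
    x = np.asarray(j0_err, dtype=float)
    y = np.asarray(j45_err, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two aligned samples of size >= 3")
    center = (float(np.mean(x)), float(np.mean(y)))
    cov = np.cov(x, y, ddof=1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals, 0.0, None)
    q = stats.chi2.ppf(level, df=2)
    major, minor = math.sqrt(evals[1] * q), math.sqrt(evals[0] * q)
    v = evecs[:, 1]
    angle = math.degrees(math.atan2(v[1], v[0]))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return ConfidenceEllipse(
        center=center,
        semi_axes=(major, minor),
        orientation_deg=angle,
        level=level,
        degenerate=bool(evals[1] <= 1e-15),
    )


def density_summary(
    errors: np.ndarray, grid: np.ndarray | None = None, n_grid: int = 512
) -> pd.DataFrame:
    """Gaussian KDE of an error sample on a stated grid (Scott's bandwidth)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("need >= 2 points for a density estimate")
    kde = stats.gaussian_kde(errors)  # Scott's rule
    if grid is None:
        pad = 4.0 * errors.std() * errors.size ** (-1 / 5) + 1e-12
        grid = np.linspace(errors.min() - pad, errors.max() + pad, n_grid)
    return pd.DataFrame({"x": grid, "density": kde(grid)})


def group_comparability(train: pd.DataFrame, test: pd.DataFrame) -> pd.DataFrame:
    """Demographics table comparing the two cohort sides.

    Continuous variables (age, SE, cylinder) get mean/SD/min/max per side and
    a two-sample t-test; binary shares (%female, %right eye) get a two-sample
    proportion z-test.  Expects cohort frames from Cohort.to_frame().
    """
    if len(train) == 0 or len(test) == 0:
        raise ValueError("both cohorts must be non-empty")
    from statsmodels.stats.proportion import proportions_ztest

    rows = []

    def cont(name: str, a: np.ndarray, b: np.ndarray) -> None:
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "variable": name,
                "train_mean": np.mean(a), "train_sd": np.std(a, ddof=1),
                "train_min": np.min(a), "train_max": np.max(a),
                "test_mean": np.mean(b), "test_sd": np.std(b, ddof=1),
                "test_min": np.min(b), "test_max": np.max(b),
                "p_value": p,
            }
        )

    def prop(name: str, a: np.ndarray, b: np.ndarray) -> None:
        counts = np.array([a.sum(), b.sum()])
        nobs = np.array([a.size, b.size])
        if counts[0] * nobs[1] == counts[1] * nobs[0]:
            p = 1.0
        else:
            p = float(proportions_ztest(counts, nobs)[1])
        rows.append(
            {
                "variable": name,
                "train_mean": a.mean(), "test_mean": b.mean(), "p_value": p,
            }
        )

    tr_pat = train.drop_duplicates("patient_id")
    te_pat = test.drop_duplicates("patient_id")
    cont("age", tr_pat["age"].to_numpy(), te_pat["age"].to_numpy())
    cont(
        "spherical_equivalent",
        (train["sphere_D"] + train["cylinder_D"] / 2).to_numpy(),
        (test["sphere_D"] + test["cylinder_D"] / 2).to_numpy(),
    )
    cont("cylinder", train["cylinder_D"].to_numpy(), test["cylinder_D"].to_numpy())
    prop(
        "fraction_female",
        (tr_pat["sex"] == "F").to_numpy(),
        (te_pat["sex"] == "F").to_numpy(),
    )
    prop(
        "fraction_right_eye",
        (train["side"] == "OD").to_numpy(),
        (test["side"] == "OD").to_numpy(),
    )
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Full per-method evaluation on one test cohort."""

    metrics: pd.DataFrame  # method x vector metric grid
    comparisons: list[ComparisonResult]
    bland_altman: dict[tuple[str, str], BlandAltman]  # (method, vector)
    ellipses: dict[str, ConfidenceEllipse]  # per method, (J0, J45) errors
    comparability: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])

    def to_json_dict(self) -> dict:
        out = {
            "metrics": self.metrics.to_dict(orient="records"),
            "comparisons": [vars(c) for c in self.comparisons],
            "bland_altman": {
                f"{m}:{v}": vars(b) for (m, v), b in self.bland_altman.items()
            },
            "ellipses": {
                m: {
                    "center": e.center,
                    "semi_axes": e.semi_axes,
                    "orientation_deg": e.orientation_deg,
                    "level": e.level,
                    "degenerate": e.degenerate,
                }
                for m, e in self.ellipses.items()
            },
            "metadata": self.metadata,
        }
        if self.comparability is not None:
            out["comparability"] = self.comparability.to_dict(orient="records")
        return out


def build_report(
    predictions: dict[str, pd.DataFrame],
    subjective: pd.DataFrame,
    family_size: int = 3,
    comparability: pd.DataFrame | None = None,
    metadata: dict | None = None,
) -> EvaluationReport:
    """Assemble metrics, pairwise tests and agreement stats for all methods.

    ``predictions`` maps method name -> frame (eye_id, M, J0, J45);
    ``subjective`` is the matching ground-truth frame.
    """
    series: dict[str, dict[str, ErrorSeries]] = {
        method: compute_errors(frame, subjective, method)
        for method, frame in predictions.items()
    }
    rows = []
    for method, per_vec in series.items():
        for vec, err in per_vec.items():
            s = summarize(err)
            rows.append({"method": method, "vector": vec, **vars(s)})
    metrics = pd.DataFrame(rows)

    methods = list(predictions)
    comparisons = []
    for vec in VECTORS:
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                comparisons.append(
                    compare_methods(
                        series[methods[i]][vec],
                        series[methods[j]][vec],
                        family_size=family_size,
                    )
                )

    subj_idx = subjective.set_index("eye_id")
    ba = {}
    ellipses = {}
    for method, frame in predictions.items():
        pred = frame.set_index("eye_id").loc[subj_idx.index]
        for vec in VECTORS:
            ba[(method, vec)] = bland_altman(
                pred[vec].to_numpy(), subj_idx[vec].to_numpy()
            )
        ellipses[method] = confidence_ellipse(
            series[method]["J0"].errors, series[method]["J45"].errors
        )
    return EvaluationReport(
        metrics=metrics,
        comparisons=comparisons,
        bland_altman=ba,
        ellipses=ellipses,
        comparability=comparability,
        metadata=metadata or {},
    )
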