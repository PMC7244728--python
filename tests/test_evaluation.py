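"""Error metrics, pairwise tests, agreement and comparability statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refractml.evaluation import (
    ErrorSeries,
    bland_altman,
    build_report,
    compare_methods,
    compute_errors,
    confidence_ellipse,
    density_summary,
    group_comparability,
    summarize,
)


def _series(errors, method="m", vector="M", ids=None):
    errors = np.asarray(errors, dtype=float)
    if ids is None:
        ids = np.arange(len(errors))
    return ErrorSeries(method=method, vector=vector, eye_ids=ids, errors=errors)


def _pv_frame(eye_ids, values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {"eye_id": eye_ids, "M": values, "J0": values * 0.5, "J45": values * -0.25}
    )


class TestComputeErrors:
    def test_perfect_predictions(self):
        subj = _pv_frame(["a", "b"], [1.0, -2.0])
        out = compute_errors(subj.copy(), subj, "exact")
        for v in ("M", "J0", "J45"):
            assert np.all(out[v].errors == 0)

    def test_constant_offset(self):
        subj = _pv_frame(["a", "b", "c"], [0.0, 1.0, 2.0])
        pred = subj.copy()
        pred["M"] = pred["M"] + 0.25
        out = compute_errors(pred, subj, "biased")
        np.testing.assert_allclose(out["M"].errors, 0.25)

    def test_sign_antisymmetry(self):
        subj = _pv_frame(["a", "b"], [0.0, 0.0])
        pred = _pv_frame(["a", "b"], [0.3, -0.7])
        plus = compute_errors(pred, subj, "p")["M"].errors
        neg = pred.copy()
        neg[["M", "J0", "J45"]] *= -1
        minus = compute_errors(neg, subj, "n")["M"].errors
        np.testing.assert_allclose(minus, -plus)

    def test_alignment_is_by_eye_id_not_order(self):
        subj = _pv_frame(["a", "b"], [1.0, 2.0])
        pred = _pv_frame(["b", "a"], [2.0, 1.0])  # same values, swapped rows
        out = compute_errors(pred, subj, "m")
        np.testing.assert_allclose(out["M"].errors, 0.0)

    def test_missing_eye_rejected(self):
        subj = _pv_frame(["a", "b"], [1.0, 2.0])
        pred = _pv_frame(["a"], [1.0])
        with pytest.raises(ValueError):
            compute_errors(pred, subj, "m")


class TestSummarize:
    def test_hand_computed_example(self):
        s = summarize(_series([0.1, -0.1, 0.3]))
        assert s.mae == pytest.approx(1 / 6)
        assert s.accuracy == pytest.approx(0.1)
        assert s.sd == pytest.approx(0.2)
        assert s.precision == pytest.approx(0.4)
        assert (s.min, s.max) == (-0.1, 0.3)

    def test_precision_is_twice_sd(self, rng):
        s = summarize(_series(rng.normal(0, 0.53, 400)))
        assert s.precision == pytest.approx(2 * s.sd)
        # a 0.53 D error SD reads as 1.06 D precision
        assert s.precision == pytest.approx(1.06, abs=0.08)

    def test_zero_errors(self):
        s = summarize(_series([0.0, 0.0, 0.0]))
        assert (s.mae, s.accuracy, s.sd, s.precision) == (0, 0, 0, 0)

    def test_mae_bounds_accuracy(self, rng):
        for _ in range(20):
            s = summarize(_series(rng.normal(rng.normal(), 0.5, 50)))
            assert s.mae >= abs(s.accuracy)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            summarize(_series([0.1]))


class TestCompareMethods:
    def test_identical_series_not_significant(self):
        a = _series([0.1, -0.2, 0.3, 0.0, 0.5])
        b = _series([0.1, -0.2, 0.3, 0.0, 0.5], method="other")
        res = compare_methods(a, b)
        assert res.p_mae == 1.0 and res.p_accuracy == 1.0 and res.p_precision == 1.0
        assert not (res.sig_mae or res.sig_accuracy or res.sig_precision)

    def test_large_shift_detected(self, rng):
        e = rng.normal(0, 0.1, 350)
        res = compare_methods(_series(e), _series(e + 1.0, method="shifted"))
        assert res.sig_accuracy and res.p_accuracy_adj < 0.05

    def test_variance_difference_detected(self, rng):
        """Levene flags a 0.1 vs 0.4 D spread difference at n=350."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = _series(r.normal(0, 0.1, 350))
            b = _series(r.normal(0, 0.4, 350), method="wide")
            hits += compare_methods(a, b).p_precision_adj < 0.05
        assert hits >= 19

    def test_bonferroni_never_decreases_and_caps(self, rng):
        a = _series(rng.normal(0, 0.2, 40))
        b = _series(rng.normal(0, 0.21, 40), method="b")
        res = compare_methods(a, b, family_size=30)
        assert res.p_mae_adj >= res.p_mae
        assert res.p_mae_adj <= 1.0

    def test_misaligned_series_rejected(self):
        a = _series([0.1, 0.2], ids=np.array(["x", "y"]))
        b = _series([0.1, 0.2], ids=np.array(["x", "z"]), method="b")
        with pytest.raises(ValueError):
            compare_methods(a, b)


class TestBlandAltman:
    def test_perfect_agreement(self):
        ba = bland_altman(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert ba.bias == 0 and ba.loa_low == 0 and ba.loa_high == 0
        assert ba.t_p == 1.0

    def test_constant_difference(self):
        ba = bland_altman(np.array([1.5, 2.5]), np.array([1.0, 2.0]))
        assert ba.bias == pytest.approx(0.5)
        assert ba.loa_low == pytest.approx(0.5)
        assert ba.loa_high == pytest.approx(0.5)

    def test_unbiased_noise_not_significant(self, rng):
        subj = rng.normal(0, 2, 350)
        pred = subj + rng.normal(0, 0.2, 350)
        ba = bland_altman(pred, subj)
        assert abs(ba.bias) < 0.04
        assert ba.t_p > 0.05
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * ba.sd)


class TestConfidenceEllipse:
    def test_isotropic_sample_axes(self, rng):
        sigma = 0.3
        e = confidence_ellipse(rng.normal(0, sigma, 4000), rng.normal(0, sigma, 4000))
        expected = sigma * np.sqrt(stats.chi2.ppf(0.95, 2))
        assert e.semi_axes[0] == pytest.approx(expected, rel=0.08)
        assert e.semi_axes[1] == pytest.approx(expected, rel=0.08)

    def test_degenerate_point_sample(self):
        e = confidence_ellipse(np.ones(5), np.ones(5))
        assert e.degenerate
        assert e.semi_axes == (0.0, 0.0)
        assert e.center == (1.0, 1.0)

    def test_scaling_homogeneity(self, rng):
        x = rng.normal(0, 0.2, 500)
        y = 0.5 * x + rng.normal(0, 0.1, 500)
        e1 = confidence_ellipse(x, y)
        e2 = confidence_ellipse(2 * x, 2 * y)
        assert e2.semi_axes[0] == pytest.approx(2 * e1.semi_axes[0], rel=1e-9)
        assert e2.semi_axes[1] == pytest.approx(2 * e1.semi_axes[1], rel=1e-9)
        assert e2.orientation_deg == pytest.approx(e1.orientation_deg, abs=1e-6)


class TestDensitySummary:
    def test_integrates_to_one(self, rng):
        d = density_summary(rng.normal(0, 0.3, 500))
        mass = np.trapezoid(d["density"], d["x"])
        assert 0.999 <= mass <= 1.001

    def test_symmetric_sample_symmetric_density(self, rng):
        x = rng.normal(0, 0.5, 400)
        sample = np.concatenate([x, -x])
        grid = np.linspace(-3, 3, 301)
        d = density_summary(sample, grid=grid)
        np.testing.assert_allclose(
            d["density"].to_numpy(), d["density"].to_numpy()[::-1], atol=1e-10
        )

    def test_narrower_sample_has_higher_peak(self, rng):
        narrow = density_summary(rng.normal(0, 0.1, 500))
        wide = density_summary(rng.normal(0, 0.5, 500))
        assert narrow["density"].max() > wide["density"].max()


class TestGroupComparability:
    @staticmethod
    def _frame(rng, n, age_shift=0.0):
        patient = np.repeat(np.arange(n), 2)
        return pd.DataFrame(
            {
                "patient_id": patient,
                "eye_id": [f"{p}-{s}" for p in range(n) for s in ("OD", "OS")],
                "side": ["OD", "OS"] * n,
                "age": np.repeat(rng.normal(36 + age_shift, 11, n), 2),
                "sex": np.repeat(
                    np.where(rng.random(n) < 0.57, "F", "M"), 2
                ),
                "sphere_D": rng.normal(-1.5, 2.5, 2 * n),
                "cylinder_D": -np.abs(rng.normal(0.8, 0.9, 2 * n)),
            }
        )

    def test_identical_groups_p_one(self, rng):
        df = self._frame(rng, 80)
        out = group_comparability(df, df.copy())
        assert (out["p_value"] == 1.0).all()

    def test_shifted_age_detected(self, rng):
        a = self._frame(rng, 300)
        b = self._frame(rng, 300, age_shift=20.0)
        out = group_comparability(a, b).set_index("variable")
        assert out.loc["age", "p_value"] < 0.05

    def test_null_split_comparable(self, rng):
        df = self._frame(rng, 400)
        patients = df["patient_id"].unique()
        test_pat = rng.choice(patients, 40, replace=False)
        mask = df["patient_id"].isin(test_pat)
        out = group_comparability(df[~mask], df[mask])
        assert (out["p_value"] > 0.05).all()


def test_build_report_consistency(rng):
    ids = [f"e{i}" for i in range(200)]
    subj = pd.DataFrame(
        {
            "eye_id": ids,
            "M": rng.normal(-2, 2.5, 200),
            "J0": rng.normal(0, 0.4, 200),
            "J45": rng.normal(0, 0.4, 200),
        }
    )
    good = subj.copy()
    for v in ("M", "J0", "J45"):
        good[v] += rng.normal(0, 0.1, 200)
    bad = subj.copy()
    for v in ("M", "J0", "J45"):
        bad[v] += rng.normal(0.1, 0.4, 200)
    report = build_report({"good": good, "bad": bad}, subj)
    metrics = report.metrics.set_index(["method", "vector"])
    for v in ("M", "J0", "J45"):
        assert metrics.loc[("good", v), "mae"] < metrics.loc[("bad", v), "mae"]
        for m in ("good", "bad"):
            assert metrics.loc[(m, v), "precision"] == pytest.approx(
                2 * metrics.loc[(m, v), "sd"]
            )
    assert len(report.comparisons) == 3  # one method pair per vector
    assert set(report.ellipses) == {"good", "bad"}
    # report JSON round-trips through plain types
    import json

    json.dumps(report.to_json_dict())


def test_plot_helpers_render(rng, tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from refractml.plots import (
        plot_astigmatic_errors,
        plot_bland_altman,
        plot_error_density,
    )

    e1, e2 = rng.normal(0, 0.2, 100), rng.normal(0, 0.4, 100)
    ax = plot_error_density({"a": e1, "b": e2})
    assert len(ax.lines) == 2
    ax2 = plot_astigmatic_errors({"a": (e1, e2)})
    assert len(ax2.patches) == 1
    subj = rng.normal(-2, 2, 80)
    ax3 = plot_bland_altman(subj + rng.normal(0, 0.1, 80), subj)
    fig = ax3.get_figure()
    fig.savefig(tmp_path / "ba.png")
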