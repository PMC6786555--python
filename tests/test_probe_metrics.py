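"""Per-probe variability metrics and probe-property correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bloodconcord import (
    correlate_with_properties,
    cross_platform_test,
    within_platform_metrics,
)
from bloodconcord.probe_metrics import (
    pearson_with_pvalue,
    plot_variance_vs_gc,
)
from conftest import make_matrix, make_sheet


def _sheet_2x2(platform="p"):
    return make_sheet([
        ("s1", "d1", platform, 1), ("s2", "d1", platform, 2),
        ("s3", "d2", platform, 1), ("s4", "d2", platform, 2),
    ])


class TestWithinPlatformMetrics:
    def test_hand_worked_var_and_fd(self):
        """Donor 1 replicates (1.0, 1.2), donor 2 (0.8, 1.0):
        Var = (0.02 + 0.02) / 2 = 0.02, FD = (0.2 + 0.2) / 2 = 0.2."""
        em = make_matrix(np.array([[1.0, 1.2, 0.8, 1.0]]), _sheet_2x2())
        out = within_platform_metrics(em, "p")
        assert out["Var"].iloc[0] == pytest.approx(0.02)
        assert out["FD"].iloc[0] == pytest.approx(0.2)
        assert out["meanM"].iloc[0] == pytest.approx(1.0)

    def test_identical_replicates_zero_var_fd(self):
        em = make_matrix(np.array([[1.5, 1.5, 0.7, 0.7]]), _sheet_2x2())
        out = within_platform_metrics(em, "p")
        assert out["Var"].iloc[0] == 0.0
        assert out["FD"].iloc[0] == 0.0
        # donors differ with zero within-noise: p -> 0
        assert out["pval"].iloc[0] == 0.0

    def test_fully_constant_probe_p_is_one(self):
        em = make_matrix(np.array([[2.0, 2.0, 2.0, 2.0]]), _sheet_2x2())
        out = within_platform_metrics(em, "p")
        assert out["pval"].iloc[0] == 1.0

    def test_anova_matches_scipy(self):
        """Donor-effect p-values agree with scipy's one-way ANOVA."""
        rng = np.random.default_rng(10)
        sheet = make_sheet([
            (f"s{d}{r}", f"d{d}", "p", r)
            for d in range(3) for r in range(1, 4)
        ])
        X = rng.normal(size=(20, 9))
        em = make_matrix(X, sheet)
        out = within_platform_metrics(em, "p")
        for i in range(20):
            groups = [X[i, 0:3], X[i, 3:6], X[i, 6:9]]
            expected = stats.f_oneway(*groups).pvalue
            assert out["pval"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_ttest_alternative_flag(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0.5, 1.0, size=(30, 4))
        em = make_matrix(X, _sheet_2x2())
        out = within_platform_metrics(em, "p", pval_method="ttest")
        expected = stats.ttest_1samp(X, 0.0, axis=1).pvalue
        np.testing.assert_allclose(out["pval"], expected, atol=1e-12)

    def test_single_replicate_donor_dropped_with_warning(self):
        sheet = make_sheet([
            ("s1", "d1", "p", 1), ("s2", "d1", "p", 2),
            ("s3", "d2", "p", 1), ("s4", "d2", "p", 2),
            ("s5", "d3", "p", 1),
        ])
        rng = np.random.default_rng(3)
        em = make_matrix(rng.normal(size=(10, 5)), sheet)
        with pytest.warns(UserWarning, match="d3"):
            out = within_platform_metrics(em, "p")
        # meanM still uses all five samples
        np.testing.assert_allclose(out["meanM"], em.M.mean(axis=1))

    def test_too_few_donors_rejected(self):
        sheet = make_sheet([
            ("s1", "d1", "p", 1), ("s2", "d1", "p", 2), ("s3", "d2", "p", 1),
        ])
        em = make_matrix(np.random.default_rng(0).normal(size=(5, 3)), sheet)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="fewer than 2 donors"):
                within_platform_metrics(em, "p")


def _paired_design(n_donors=8, n_probes=30, seed=9, shift=None):
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_donors):
        rows.append((f"a{d}", f"d{d}", "A", 1))
        rows.append((f"b{d}", f"d{d}", "B", 1))
    sheet = make_sheet(rows)
    order = list(sheet["sample_id"])
    X = pd.DataFrame(
        rng.normal(size=(n_probes, 2 * n_donors)), columns=order
    )
    if shift is not None:
        X.loc[:, [c for c in order if c.startswith("a")]] += shift[:, None]
    sheet_sorted = sheet
    return make_matrix(X.to_numpy(), sheet_sorted), sheet


class TestCrossPlatformTest:
    def test_constant_difference_zero_variance_p_zero(self):
        em, _ = _paired_design(n_donors=4, n_probes=1, seed=1)
        M = em.M.copy()
        M.loc[:, ["a0", "a1", "a2", "a3"]] = 1.5
        M.loc[:, ["b0", "b1", "b2", "b3"]] = 1.0
        em.M.iloc[:, :] = M
        out = cross_platform_test(em, "A", "B")
        assert out["cross_pval"].iloc[0] == 0.0
        assert out["mean_diff"].iloc[0] == pytest.approx(0.5)

    def test_identical_platforms_p_one(self):
        em, _ = _paired_design(n_donors=4, n_probes=5, seed=2)
        for d in range(4):
            em.M[f"b{d}"] = em.M[f"a{d}"]
        out = cross_platform_test(em, "A", "B")
        assert (out["cross_pval"] == 1.0).all()

    def test_matches_scipy_paired_t(self):
        em, _ = _paired_design(n_donors=8, n_probes=30, seed=9)
        out = cross_platform_test(em, "A", "B")
        a = em.M[[f"a{d}" for d in range(8)]].to_numpy()
        b = em.M[[f"b{d}" for d in range(8)]].to_numpy()
        expected = stats.ttest_rel(a, b, axis=1).pvalue
        np.testing.assert_allclose(out["cross_pval"], expected, atol=1e-12)

    def test_replicates_averaged_before_pairing(self):
        sheet = make_sheet([
            ("a1", "d1", "A", 1), ("a2", "d1", "A", 2),
            ("a3", "d2", "A", 1), ("a4", "d3", "A", 1),
            ("b1", "d1", "B", 1), ("b2", "d2", "B", 1), ("b3", "d3", "B", 1),
        ])
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 7))
        em = make_matrix(X, sheet)
        out = cross_platform_test(em, "A", "B")
        a = np.column_stack([X[:, 0:2].mean(axis=1), X[:, 2], X[:, 3]])
        b = X[:, 4:7]
        expected = stats.ttest_rel(a, b, axis=1).pvalue
        np.testing.assert_allclose(out["cross_pval"], expected, atol=1e-12)

    def test_too_few_common_donors_rejected(self):
        em, _ = _paired_design(n_donors=2, n_probes=3, seed=3)
        with pytest.raises(ValueError, match=">=3 donors"):
            cross_platform_test(em, "A", "B")

    def test_welch_flag_runs(self):
        em, _ = _paired_design(n_donors=5, n_probes=10, seed=7)
        out = cross_platform_test(em, "A", "B", method="welch")
        assert out["cross_pval"].between(0, 1).all()


def _annotation(n, seed=0, gc=None):
    rng = np.random.default_rng(seed)
    transcript = rng.integers(200, 3000, n)
    d5 = rng.integers(0, 100, n)
    return pd.DataFrame({
        "probe_id": [f"P{i:03d}" for i in range(n)],
        "gene_id": [f"G{i:03d}" for i in range(n)],
        "Dist3": transcript - 60 - d5,
        "Dist5": d5,
        "TranscriptSize": transcript,
        "GeneSize": transcript + rng.integers(0, 5000, n),
        "GCpercent": gc if gc is not None else rng.uniform(30, 70, n),
    })


class TestPropertyCorrelations:
    def test_perfect_linearity(self):
        n = 25
        ann = _annotation(n, seed=1)
        metrics = pd.DataFrame(
            {"Var": ann["GCpercent"].to_numpy() * 0.01,
             "meanM": np.zeros(n) + np.arange(n) * 0.001,
             "meanA": 10 + np.arange(n) * 0.01},
            index=pd.Index(ann["probe_id"], name="probe_id"),
        )
        out = correlate_with_properties(metrics, ann, measures=["Var"])
        row = out[(out["measure"] == "Var")
                  & (out["property"] == "GCpercent")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(0.0, abs=1e-12)
        assert row["significant"]

    def test_constant_property_flagged_undefined(self):
        n = 15
        ann = _annotation(n, seed=2, gc=np.full(n, 50.0))
        metrics = pd.DataFrame(
            {"Var": np.random.default_rng(0).uniform(size=n),
             "meanM": np.zeros(n), "meanA": np.full(n, 10.0)},
            index=pd.Index(ann["probe_id"], name="probe_id"),
        )
        out = correlate_with_properties(metrics, ann, measures=["Var"])
        row = out[out["property"] == "GCpercent"].iloc[0]
        assert row["undefined"] and not row["significant"]

    def test_p_matches_t_transform_and_scipy(self):
        """The t-transform p-value reproduces scipy's pearsonr on an
        n=20 fixture with moderate correlation."""
        rng = np.random.default_rng(20)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(0, 0.86, size=20)
        r, p = pearson_with_pvalue(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-9)
        # and against the explicit formula
        t = r * np.sqrt((20 - 2) / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 18), abs=1e-15)

    def test_unannotated_probes_dropped(self):
        ann = _annotation(10, seed=3)
        metrics = pd.DataFrame(
            {"Var": np.arange(12, dtype=float),
             "meanM": np.zeros(12), "meanA": np.full(12, 10.0)},
            index=pd.Index([f"P{i:03d}" for i in range(12)], name="probe_id"),
        )
        out = correlate_with_properties(metrics, ann, measures=["Var"])
        assert (out["n"] == 10).all()

    def test_properties_include_meanM_meanA(self):
        ann = _annotation(15, seed=4)
        rng = np.random.default_rng(1)
        metrics = pd.DataFrame(
            {"Var": rng.uniform(size=15), "meanM": rng.normal(size=15),
             "meanA": rng.normal(10, 1, size=15)},
            index=pd.Index(ann["probe_id"], name="probe_id"),
        )
        out = correlate_with_properties(metrics, ann, measures=["Var"])
        assert set(out["property"]) == {
            "Dist3", "Dist5", "TranscriptSize", "GeneSize", "GCpercent",
            "meanM", "meanA",
        }


class TestVarianceGcPlot:
    def test_collinear_points_exact_slope(self, tmp_path):
        ann = _annotation(3, seed=5, gc=np.array([40.0, 50.0, 60.0]))
        metrics = pd.DataFrame(
            {"Var": np.array([0.1, 0.2, 0.3])},
            index=pd.Index(ann["probe_id"], name="probe_id"),
        )
        path = tmp_path / "fig.png"
        _, slope, intercept = plot_variance_vs_gc(metrics, ann, str(path))
        assert slope == pytest.approx(0.01)
        assert intercept == pytest.approx(-0.3)
        assert path.exists() and path.stat().st_size > 0

    def test_flat_data_zero_slope(self):
        ann = _annotation(10, seed=6)
        metrics = pd.DataFrame(
            {"Var": np.full(10, 0.25)},
            index=pd.Index(ann["probe_id"], name="probe_id"),
        )
        _, slope, _ = plot_variance_vs_gc(metrics, ann)
        assert slope == pytest.approx(0.0, abs=1e-12)
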