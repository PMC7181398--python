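"""NIPALS PLS1, VIP, and the per-cluster selection/scoring rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methaniche.data import AbundanceTable, SampleMetadata
from methaniche.pls import (
    final_cluster_pls,
    fit_pls1,
    run_all_clusters,
    select_cluster_variables,
    vip,
)


def _xy(n=40, p=5, seed=0):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"v{j}" for j in range(p)]
    )
    y = pd.Series(rng.normal(size=n))
    return x, y


class TestFitPls1:
    def test_single_predictor_equals_ols(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame({"v": rng.normal(size=30)})
        y = pd.Series(2.5 * x["v"].to_numpy() + rng.normal(0, 0.5, 30) + 7.0)
        model = fit_pls1(x, y, scale=True)
        slope, intercept = np.polyfit(x["v"], y, 1)
        assert model.coefficients[0] == pytest.approx(slope, abs=1e-10)
        assert model.intercept == pytest.approx(intercept, abs=1e-10)
        assert np.allclose(model.fitted, intercept + slope * x["v"], atol=1e-10)

    def test_perfect_signal(self):
        rng = np.random.default_rng(8)
        x, _ = _xy(50, 4, seed=8)
        y = pd.Series(x["v0"].to_numpy())
        model = fit_pls1(x, y)
        assert model.variance_explained >= 0.99

    def test_null_variance_explained_small_on_average(self):
        """y independent of X: one-component in-sample R^2 stays modest."""
        r2 = []
        for seed in range(200):
            x, y = _xy(n=63, p=5, seed=seed)
            r2.append(fit_pls1(x, y).variance_explained)
        assert np.mean(r2) < 0.15

    def test_matches_sklearn_one_component(self):
        from sklearn.cross_decomposition import PLSRegression

        x, y = _xy(40, 6, seed=2)
        y = pd.Series(y.to_numpy() + 0.8 * x["v1"].to_numpy())
        model = fit_pls1(x, y, n_components=1, scale=True)
        ref = PLSRegression(n_components=1, scale=True).fit(x.to_numpy(), y.to_numpy())
        assert np.allclose(model.coefficients, ref.coef_.ravel(), atol=1e-8)
        fitted_ref = ref.predict(x.to_numpy()).ravel()
        assert np.allclose(model.fitted, fitted_ref, atol=1e-8)

    def test_prediction_invariant_to_predictor_order(self):
        x, y = _xy(35, 6, seed=9)
        y = pd.Series(y.to_numpy() + x["v2"].to_numpy())
        m1 = fit_pls1(x, y)
        m2 = fit_pls1(x[list(reversed(x.columns))], y)
        assert np.allclose(m1.fitted, m2.fitted, atol=1e-10)

    def test_unit_norm_weights(self):
        x, y = _xy(30, 4, seed=1)
        model = fit_pls1(x, y, n_components=2)
        norms = np.linalg.norm(model.weights, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-10)

    def test_constant_predictor_error(self):
        x, y = _xy(20, 3, seed=0)
        x["v1"] = 3.14
        with pytest.raises(ValueError, match="v1"):
            fit_pls1(x, y)

    def test_constant_response_error(self):
        x, _ = _xy(20, 3, seed=0)
        with pytest.raises(ValueError, match="zero variance"):
            fit_pls1(x, pd.Series(np.ones(20)))


class TestVip:
    def test_single_predictor_is_one(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame({"v": rng.normal(size=25)})
        y = pd.Series(x["v"].to_numpy() + rng.normal(0, 0.1, 25))
        assert vip(fit_pls1(x, y)) == pytest.approx([1.0], abs=1e-10)

    def test_hand_computed_weight_ratio(self):
        """w proportional to (2, 1, 1) gives VIP = sqrt(3 w_j^2 / sum w^2)."""
        # orthonormal centered predictors with y = 2 x1 + x2 + x3 make
        # X'y proportional to (2, 1, 1) exactly
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(12, 4)))
        base = q[:, :3] - q[:, :3].mean(axis=0)
        q2, _ = np.linalg.qr(base)
        x = pd.DataFrame(q2, columns=["a", "b", "c"])
        y = pd.Series(2 * x["a"] + x["b"] + x["c"])
        model = fit_pls1(x, y, scale=False)
        expected = np.sqrt(3 * np.array([4.0, 1.0, 1.0]) / 6.0)
        assert np.allclose(vip(model), expected, atol=1e-8)
        assert vip(model) == pytest.approx([1.414, 0.707, 0.707], abs=1e-3)

    @given(st.integers(2, 8), st.integers(0, 1000))
    def test_sum_of_squares_identity(self, p, seed):
        """Sum VIP_j^2 = p for every fitted model."""
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(
            rng.normal(size=(25, p)), columns=[f"v{j}" for j in range(p)]
        )
        y = pd.Series(rng.normal(size=25) + x.iloc[:, 0].to_numpy())
        model = fit_pls1(x, y)
        assert float((vip(model) ** 2).sum()) == pytest.approx(p, abs=1e-9)


def _cluster_scenario(vips_wanted, n=63, seed=0):
    """Build a cluster table whose features have graded response signal."""
    rng = np.random.default_rng(seed)
    f = rng.normal(size=n)
    rows = {}
    for i, strength in enumerate(vips_wanted):
        rows[f"feat{i}"] = 5 + strength * f + rng.normal(0, 1.0, n)
    values = pd.DataFrame(rows).T
    values.columns = [f"animal{j:03d}" for j in range(n)]
    values = values.clip(lower=0)
    table = AbundanceTable(values, "gene", "counts")
    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "animal_id": list(values.columns),
                "breed": (["AA", "LIM"] * 32)[:n],
                "diet": (["FOR"] * 32 + ["CONC"] * 31)[:n],
                "ch4": 17 + 2 * f + rng.normal(0, 0.8, n),
            }
        )
    )
    return table, metadata


class TestSelection:
    def test_max_vars_cap(self):
        table, metadata = _cluster_scenario([3, 2.8, 2.6, 2.4, 2.2, 2.0, 1.8], seed=1)
        sel = select_cluster_variables(table, metadata, vip_threshold=0.8, max_vars=5)
        assert len(sel) == 5
        assert (sel["vip"] > 0.8).all()

    def test_threshold_excludes_weak(self):
        table, metadata = _cluster_scenario([3.0, 2.5, 0.0, 0.0], seed=2)
        sel = select_cluster_variables(table, metadata)
        assert set(sel["feature_id"]) <= {"feat0", "feat1"}
        assert len(sel) == 2

    def test_all_noise_can_select_nothing(self):
        table, metadata = _cluster_scenario([0.0] * 4, seed=3)
        # decouple ch4 from the latent factor entirely
        rng = np.random.default_rng(9)
        meta = metadata.frame.copy()
        meta["ch4"] = rng.uniform(12, 20, len(meta))
        sel = select_cluster_variables(
            table, SampleMetadata(meta), vip_threshold=1.9
        )
        assert len(sel) == 0

    def test_dummies_never_selected(self):
        table, metadata = _cluster_scenario([2.0, 1.5], seed=4)
        sel = select_cluster_variables(table, metadata)
        assert not set(sel["feature_id"]) & {"diet_FOR", "breed_AA"}

    def test_empty_cluster_error(self):
        table, metadata = _cluster_scenario([1.0], seed=0)
        with pytest.raises(ValueError, match="empty"):
            select_cluster_variables(table.subset_features([]), metadata)

    def test_residualized_option_runs(self):
        table, metadata = _cluster_scenario([2.0, 1.0, 0.5], seed=5)
        sel = select_cluster_variables(
            table, metadata, residualize_fixed_effects=True
        )
        assert (sel["vip"] > 0.8).all()


class TestFinalPls:
    def test_duplicated_response_gives_full_variance(self):
        table, metadata = _cluster_scenario([1.0], seed=6)
        y = metadata.frame["ch4"]
        dup = table.values.copy()
        dup.loc["ydup"] = y.to_numpy()
        t2 = AbundanceTable(dup, "gene", "counts")
        report = final_cluster_pls(t2.subset_features(["ydup"]), y, cluster=1)
        assert report.variance_explained_percent == pytest.approx(100.0, abs=1e-6)

    def test_empty_selection_report(self):
        table, metadata = _cluster_scenario([1.0], seed=0)
        report = final_cluster_pls(
            table.subset_features([]), metadata.frame["ch4"], cluster=3
        )
        assert report.variance_explained_percent == 0.0
        assert report.direction is None
        assert not report.informative

    def test_direction_sign_consensus(self):
        rng = np.random.default_rng(12)
        f = rng.normal(size=63)
        values = pd.DataFrame(
            {"up": 10 + 2 * f, "up2": 11 + 1.5 * f},
        ).T
        values.columns = [f"a{j}" for j in range(63)]
        table = AbundanceTable(values, "gene", "counts")
        y = pd.Series(5 + f + rng.normal(0, 0.3, 63))
        report = final_cluster_pls(table, y, cluster=1)
        assert report.direction == "positive"
        neg_table = AbundanceTable(40 - values, "gene", "counts")
        report2 = final_cluster_pls(neg_table, y, cluster=1)
        assert report2.direction == "negative"


def test_run_all_clusters_orders_by_variance(small_config):
    from methaniche.model import FunctionalNicheModel

    results = FunctionalNicheModel.from_synthetic(small_config, seed=0).fit()
    reports = results.cluster_reports
    explained = [r.variance_explained_percent for r in reports]
    assert explained == sorted(explained, reverse=True)
    for r in reports:
        assert len(r.selected) <= 5
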