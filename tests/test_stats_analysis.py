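"""Statistical battery: each estimator against planted truth or oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from sklearn.metrics import adjusted_rand_score, silhouette_score

from matrixlft import (
    compare_clusters,
    correlation_ci,
    hierarchical_regression,
    iap_mixed_model,
    incremental_r2,
    mediation_path,
    quadratic_tot_effect,
    ward_cluster,
)

from _brute import silhouette_mean, ward_merge_heights


class TestQuadraticToT:
    def test_planted_pure_quadratic_dominates_linear(self):
        rng = np.random.default_rng(0)
        tot = rng.normal(50, 10, 300)
        z = (tot - tot.mean()) / tot.std()
        score = -(z**2) + rng.normal(0, 1e-6, 300)
        res = quadratic_tot_effect(score, tot)
        assert res.beta_quadratic < 0
        assert res.delta_r2 == pytest.approx(1.0 - res.r2_linear, abs=1e-6)
        assert res.r2_quadratic > 0.999

    def test_linear_association_gives_no_curvature_gain(self):
        rng = np.random.default_rng(1)
        tot = rng.normal(50, 10, 400)
        score = 0.5 * tot + rng.normal(0, 5, 400)
        res = quadratic_tot_effect(score, tot)
        assert res.delta_r2 < 0.02

    def test_f_change_type_one_error_calibrated(self):
        """Under a purely linear model the F-change test rejects ~5%."""
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 500
        for _ in range(reps):
            tot = rng.normal(0, 1, 60)
            score = tot + rng.normal(0, 1, 60)
            res = quadratic_tot_effect(score, tot)
            rejections += res.p_change < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            quadratic_tot_effect(np.ones(20), np.ones(20))


class TestWardClustering:
    def test_merge_heights_match_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for n in (4, 5, 6):
            X = rng.normal(size=(n, 2))
            link = sch.linkage(X, method="ward")
            assert np.allclose(
                sorted(link[:, 2]), sorted(ward_merge_heights(X)), atol=1e-10
            )

    def test_hand_computed_four_point_tree(self):
        """1-d points 0, 2, 9, 10: merges at 1, 2 and sqrt(144.5)."""
        X = np.array([[0.0], [2.0], [9.0], [10.0]])
        link = sch.linkage(X, method="ward")
        assert np.allclose(sorted(link[:, 2]), [1.0, 2.0, np.sqrt(144.5)])

    def test_silhouette_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 3))
        labels = rng.integers(0, 3, 50)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 3, 50)
        assert silhouette_score(X, labels) == pytest.approx(
            silhouette_mean(X, labels), abs=1e-12
        )

    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(6, 1, (35, 2))])
        truth = np.repeat([0, 1], [40, 35])
        sol = ward_cluster(X, n_boot=10, seed=0)
        assert sol.k_selected == 2
        assert adjusted_rand_score(truth, sol.labels) == 1.0
        assert sol.bootstrap_stability > 0.95

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError, match="identical"):
            ward_cluster(np.ones((20, 2)), n_boot=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.random.default_rng(0).normal(size=(2, 2)), k_range=[5])


class TestGroupComparison:
    def test_identical_groups_zero_effect(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p, d = compare_clusters(x, x.copy())
        assert t == 0 and d == 0 and p == pytest.approx(1.0)

    def test_one_pooled_sd_shift_gives_unit_d(self):
        rng = np.random.default_rng(6)
        x1 = rng.normal(0, 1, 50)
        x2 = x1 + x1.std(ddof=1)  # equal variances, shift = pooled SD
        _t, _df, _p, d = compare_clusters(x1, x2)
        assert d == pytest.approx(1.0)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(1000):
            ps.append(compare_clusters(rng.normal(0, 1, 20), rng.normal(0, 1, 25))[2])
        from scipy import stats as st

        assert st.kstest(ps, "uniform").pvalue > 0.01


class TestCorrelationCI:
    def test_perfect_correlation_collapses_ci(self):
        x = np.arange(10.0)
        r, (lo, hi), _p = correlation_ci(x, x)
        assert r == pytest.approx(1.0)
        assert lo == pytest.approx(1.0, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-9)

    def test_sign_flip_negates_r(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 40))
        r1, _, _ = correlation_ci(x, y)
        r2, _, _ = correlation_ci(x, -y)
        assert r1 == pytest.approx(-r2)

    def test_ci_coverage_under_null(self):
        rng = np.random.default_rng(9)
        cover = 0
        reps = 1000
        for _ in range(reps):
            x, y = rng.normal(size=(2, 30))
            _r, (lo, hi), _p = correlation_ci(x, y)
            cover += lo <= 0 <= hi
        assert 0.93 <= cover / reps <= 0.97

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlation_ci(np.ones(10), np.arange(10.0))


def _mediation_data(n, a1=0.5, a2=0.0, b1=-0.4, b2=0.0, direct=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    m1 = a1 * x + rng.normal(0, np.sqrt(max(1 - a1**2, 0.05)), n)
    m2 = a2 * x + rng.normal(0, np.sqrt(max(1 - a2**2, 0.05)), n)
    y = direct * x + b1 * m1 + b2 * m2 + rng.normal(0, 0.6, n)
    return x, m1, m2, y


class TestMediation:
    def test_total_equals_direct_plus_indirects(self):
        x, m1, m2, y = _mediation_data(120, a1=0.4, a2=0.3, b1=0.2, b2=-0.3,
                                       direct=0.25, seed=1)
        res = mediation_path(x, m1, m2, y, n_boot=50, seed=0)
        simple = np.corrcoef(x, y)[0, 1]  # OLS total on standardized data
        assert res.total == pytest.approx(
            res.paths["direct"] + res.indirect1 + res.indirect2, abs=1e-12
        )
        assert res.total == pytest.approx(simple, abs=1e-8)

    def test_saturated_model_has_zero_chi2(self):
        x, m1, m2, y = _mediation_data(100, seed=2)
        res = mediation_path(x, m1, m2, y, n_boot=20, seed=0, free_mediator_cov=True)
        assert res.df == 0
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_point_estimates_independent_of_bootstrap_seed(self):
        x, m1, m2, y = _mediation_data(90, seed=3)
        r1 = mediation_path(x, m1, m2, y, n_boot=30, seed=1)
        r2 = mediation_path(x, m1, m2, y, n_boot=30, seed=99)
        assert r1.paths == r2.paths
        assert r1.ci["indirect1"] != r2.ci["indirect1"]

    def test_fit_indices_within_bounds(self):
        x, m1, m2, y = _mediation_data(200, a2=0.3, b2=-0.2, direct=0.2, seed=4)
        res = mediation_path(x, m1, m2, y, n_boot=30, seed=0)
        assert res.df == 1
        assert 0 <= res.cfi <= 1
        assert res.rmsea >= 0 and res.srmr >= 0

    def test_small_sample_rejected(self):
        x, m1, m2, y = _mediation_data(20, seed=5)
        with pytest.raises(ValueError, match="n >= 30"):
            mediation_path(x, m1, m2, y)


class TestHierarchicalRegression:
    def test_orthogonal_predictors_unique_r2_sums_to_model_r2(self):
        rng = np.random.default_rng(10)
        A = rng.normal(size=(80, 4))
        A -= A.mean(axis=0)  # centred columns stay centred under QR
        Q, _ = np.linalg.qr(A)
        tot, onset, inter, intra = Q.T
        score = 0.5 * tot - 0.3 * inter + 0.2 * intra + rng.normal(0, 0.05, 80)
        rep = hierarchical_regression(score, tot, onset, inter, intra)
        # exactly orthogonal columns: semipartials add up to the model R^2
        assert rep.unique_r2.sum() == pytest.approx(rep.r2_full, abs=1e-8)

    def test_duplicated_predictor_rejected_by_name(self):
        rng = np.random.default_rng(11)
        tot = rng.normal(size=50)
        onset = rng.normal(size=50)
        intra = rng.normal(size=50)
        score = rng.normal(size=50)
        with pytest.raises(ValueError, match="inter"):
            hierarchical_regression(score, tot, onset, tot.copy(), intra)

    def test_planted_interrule_effect_dominates_unique_r2(self):
        rng = np.random.default_rng(12)
        medians = {"tot": [], "onset": [], "inter": [], "intra": []}
        for _ in range(7):
            tot, onset, inter, intra = rng.normal(size=(4, 150))
            score = 0.5 * inter + rng.normal(0, 1, 150)
            rep = hierarchical_regression(score, tot, onset, inter, intra)
            for k in medians:
                medians[k].append(rep.unique_r2[k])
        assert np.median(medians["inter"]) > 0.05
        for k in ("tot", "onset", "intra"):
            assert np.median(medians[k]) < 0.05

    def test_delta_r2_nonnegative_and_f_consistent(self):
        rng = np.random.default_rng(13)
        tot, onset, inter, intra = rng.normal(size=(4, 60))
        score = tot + 0.3 * onset + rng.normal(0, 1, 60)
        rep = hierarchical_regression(score, tot, onset, inter, intra)
        assert rep.delta_r2 >= 0
        assert rep.r2_full == pytest.approx(rep.r2_base + rep.delta_r2)
        assert (rep.vif >= 1).all()


class TestMixedModel:
    @staticmethod
    def _long_data(rng, n_p=60, n_i=8, b_global=15.0, b_current=0.0,
                   sd_p=5.0, sd_i=3.0, sd_e=8.0):
        g = rng.uniform(0, 0.4, n_p)
        u = rng.normal(0, sd_p, n_p)
        v = rng.normal(0, sd_i, n_i)
        rows = []
        for i in range(n_p):
            cur = rng.normal(0, 0.2, n_i)
            cur -= cur.mean()
            for j in range(n_i):
                y = 50 + b_global * g[i] + b_current * cur[j] + u[i] + v[j] \
                    + rng.normal(0, sd_e)
                rows.append((y, g[i], cur[j], f"p{i}", f"i{j}"))
        return pd.DataFrame(rows, columns=["y", "g", "c", "pid", "item"])

    def test_zero_random_variance_matches_ols(self):
        """When the REML variance-component estimates sit at the zero
        boundary, the mixed-model coefficients collapse to OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        df = self._long_data(rng, n_p=40, n_i=6, sd_p=0.0, sd_i=0.0, sd_e=5.0,
                             b_current=0.0)
        rep = iap_mixed_model(df.y, df.g, df.c, df.pid, df.item)
        X = sm.add_constant(df[["g", "c"]])
        ols = sm.OLS(df.y, X).fit()
        assert rep.var_item == pytest.approx(0.0, abs=1e-6)
        assert rep.b_global == pytest.approx(ols.params["g"], abs=1e-4)
        assert rep.b_current == pytest.approx(ols.params["c"], abs=1e-4)

    def test_recovers_planted_global_effect(self):
        rng = np.random.default_rng(15)
        df = self._long_data(rng, n_p=80, n_i=10, b_global=15.0)
        rep = iap_mixed_model(df.y, df.g, df.c, df.pid, df.item)
        assert rep.converged
        assert abs(rep.b_global - 15.0) < 3 * rep.se_global
        assert rep.var_participant > 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            iap_mixed_model([], [], [], [], [])


class TestIncrementalR2:
    def test_redundant_addition_gains_nothing(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 1, 50)
        r2, delta, f, p = incremental_r2(y, x, 2.0 * x + 1.0)
        assert delta == 0.0 and p == 1.0

    def test_null_addition_gains_little(self):
        rng = np.random.default_rng(17)
        deltas = []
        for _ in range(50):
            x = rng.normal(size=80)
            y = x + rng.normal(0, 1, 80)
            z = rng.normal(size=80)
            deltas.append(incremental_r2(y, x, z)[1])
        assert np.median(deltas) < 0.02

    def test_planted_increment_recovered(self):
        """y = x0 + 0.5 z with unit-variance orthogonal parts: the analytic
        incremental R^2 of z beyond x0 is 0.25 / 2.25."""
        rng = np.random.default_rng(18)
        x0 = rng.normal(size=5000)
        z = rng.normal(size=5000)
        y = x0 + 0.5 * z + rng.normal(0, 1, 5000)
        _r2, delta, f, p = incremental_r2(y, x0, z)
        assert delta == pytest.approx(0.25 / 2.25, abs=0.02)
        assert p < 1e-6
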