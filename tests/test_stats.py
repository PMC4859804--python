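"""Smoothing, correlation, clustering and topography regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from topoflat import (
    ExperimentLabelMap,
    cluster_experiments,
    fit_age_dichotomized,
    fit_topography,
    flatmap_correlations,
    regression_diagnostics,
    smooth_flatmap,
)
from topoflat.stats import (
    FlatmapKMeans,
    TopographyRegression,
    backward_eliminate,
    gaussian_kernel,
    smooth_grid,
)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

class TestSmoothing:
    def test_constant_map_is_preserved(self):
        v = np.full((9, 9), 0.7)
        out = smooth_grid(v, np.ones_like(v, dtype=bool))
        assert np.allclose(out, 0.7)

    def test_interior_impulse_reproduces_kernel(self):
        v = np.zeros((11, 11))
        v[5, 5] = 1.0
        out = smooth_grid(v, np.ones_like(v, dtype=bool))
        assert np.allclose(out[3:8, 3:8], gaussian_kernel(5, 1.5), atol=1e-12)
        assert np.allclose(out[0, :], 0.0)

    def test_corner_impulse_matches_bruteforce_normalized_convolution(self):
        """Boundary handling agrees with a direct double-loop oracle that
        renormalizes the kernel over the in-region support."""
        v = np.zeros((6, 6))
        v[0, 0] = 1.0
        mask = np.ones_like(v, dtype=bool)
        mask[:, 5] = False  # a ragged edge
        k = gaussian_kernel(5, 1.5)
        expected = np.zeros_like(v)
        for i in range(6):
            for j in range(6):
                if not mask[i, j]:
                    continue
                num = den = 0.0
                for di in range(-2, 3):
                    for dj in range(-2, 3):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < 6 and 0 <= jj < 6 and mask[ii, jj]:
                            w = k[di + 2, dj + 2]
                            num += w * v[ii, jj]
                            den += w
                expected[i, j] = num / den
        out = smooth_grid(v, mask)
        assert np.allclose(out, expected, atol=1e-12)

    def test_out_of_region_bins_do_not_bleed(self, spec_set):
        lm = ExperimentLabelMap("e", spec_set)
        for i in range(10):
            lm.grids["PaS_deep"][i][:] = 1.0
        out = smooth_flatmap(lm)
        for i in range(10):
            assert np.allclose(out.grids["PaS_deep"][i], 1.0)


# ---------------------------------------------------------------------------
# correlation + clustering
# ---------------------------------------------------------------------------

def _random_map(spec_set, rng, exp):
    lm = ExperimentLabelMap(exp, spec_set)
    for sub in lm.grids:
        lm.grids[sub] = [rng.uniform(0, 1, len(r)) for r in lm.grids[sub]]
    return lm


class TestCorrelations:
    def test_self_correlation_is_one(self, spec_set):
        rng = np.random.default_rng(0)
        m = _random_map(spec_set, rng, "a")
        corr = flatmap_correlations([m, m.copy()])
        assert np.allclose(np.diag(corr), 1.0)
        assert np.isclose(corr.iloc[0, 1], 1.0)

    def test_complement_is_anticorrelated(self, spec_set):
        rng = np.random.default_rng(1)
        m = _random_map(spec_set, rng, "a")
        comp = m.copy()
        comp.experiment_id = "b"
        comp.grids = {s: [1 - r for r in g] for s, g in comp.grids.items()}
        corr = flatmap_correlations([m, comp])
        assert np.isclose(corr.iloc[0, 1], -1.0)

    def test_independent_maps_are_near_zero(self, spec_set):
        """Null simulation: |r| < 0.15 for independent uniform maps with
        hundreds of bins, in at least 95 of 100 seeds."""
        n_bins = sum(s.bin_counts.sum() for s in spec_set.values())
        assert n_bins >= 300
        small = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            corr = flatmap_correlations(
                [_random_map(spec_set, rng, "a"), _random_map(spec_set, rng, "b")]
            )
            if abs(corr.iloc[0, 1]) < 0.15:
                small += 1
        assert small >= 95

    def test_zero_variance_map_reported(self, spec_set):
        rng = np.random.default_rng(2)
        flat = ExperimentLabelMap("flat-one", spec_set)
        with pytest.raises(ValueError, match="flat-one"):
            flatmap_correlations([_random_map(spec_set, rng, "a"), flat])


class TestClustering:
    def test_two_identical_groups_are_separated(self, spec_set):
        rng = np.random.default_rng(3)
        a = _random_map(spec_set, rng, "a")
        b = _random_map(spec_set, rng, "b")
        maps = []
        for i in range(5):
            ai = a.copy()
            ai.experiment_id = f"a{i}"
            bi = b.copy()
            bi.experiment_id = f"b{i}"
            maps += [ai, bi]
        km = FlatmapKMeans(k_range=range(2, 5), random_state=0).fit(maps)
        assert km.chosen_k_ == 2
        assert km.ratio_curve_[2] < 1e-9
        labels = km.labels_
        assert len(set(labels[::2])) == 1 and len(set(labels[1::2])) == 1

    def test_identical_maps_are_degenerate(self, spec_set):
        rng = np.random.default_rng(4)
        m = _random_map(spec_set, rng, "m")
        maps = []
        for i in range(6):
            mi = m.copy()
            mi.experiment_id = f"m{i}"
            maps.append(mi)
        corr = pd.DataFrame(np.ones((6, 6)), index=[m.experiment_id for m in maps],
                            columns=[m.experiment_id for m in maps])
        res = cluster_experiments(corr, k_range=range(2, 4))
        assert res.degenerate

    def test_archetype_recovery_under_noise(self, spec_set):
        """Three archetype groups with additive noise are recovered."""
        rng0 = np.random.default_rng(99)
        archetypes = [_random_map(spec_set, rng0, f"arch{g}") for g in range(3)]
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            maps, truth = [], []
            for g, arch in enumerate(archetypes):
                for i in range(10):
                    m = arch.copy()
                    m.experiment_id = f"g{g}i{i}"
                    m.grids = {
                        s: [np.clip(r + rng.normal(0, 0.05, len(r)), 0, None) for r in gr]
                        for s, gr in m.grids.items()
                    }
                    maps.append(m)
                    truth.append(g)
            km = FlatmapKMeans(
                k_range=range(2, 6), random_state=seed, n_restarts=10
            ).fit(maps)
            if adjusted_rand_score(truth, km.labels_) > 0.9:
                hits += 1
        assert hits >= 95

    def test_order_invariance(self, spec_set):
        rng = np.random.default_rng(5)
        maps = [_random_map(spec_set, rng, f"m{i}") for i in range(8)]
        km1 = FlatmapKMeans(k_range=range(2, 4), random_state=1).fit(maps)
        perm = [maps[i] for i in [3, 0, 7, 1, 5, 2, 6, 4]]
        km2 = FlatmapKMeans(k_range=range(2, 4), random_state=1).fit(perm)
        lab1 = dict(zip([m.experiment_id for m in maps], km1.labels_))
        lab2 = dict(zip([m.experiment_id for m in perm], km2.labels_))
        part1 = {}
        part2 = {}
        for k in lab1:
            part1.setdefault(lab1[k], set()).add(k)
            part2.setdefault(lab2[k], set()).add(k)
        assert set(map(frozenset, part1.values())) == set(map(frozenset, part2.values()))

    def test_k_not_smaller_than_n_rejected(self, spec_set):
        corr = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            cluster_experiments(corr, k_range=range(2, 5))


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def _com_table(n=60, seed=0, fn=None, noise=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "rc": rng.uniform(0, 1, n),
            "dv": rng.uniform(0, 1, n),
            "age": rng.integers(1, 20, n).astype(float),
        }
    )
    fn = fn or (lambda d: 0.5 - 0.3 * d["rc"])
    df["y"] = fn(df) + rng.normal(0, noise, n)
    return df


class TestFitTopography:
    def test_noiseless_main_effect_recovery(self):
        df = _com_table(noise=1e-6)
        res = fit_topography(df, "y")
        assert np.isclose(res.params.loc["rc", "beta"], -0.3, atol=1e-6)
        assert all(":" not in t for t in res.predictors)

    def test_pure_interaction_is_retained(self):
        df = _com_table(n=200, seed=1, fn=lambda d: d["rc"] * d["dv"], noise=0.01)
        res = fit_topography(df, "y")
        assert "rc:dv" in res.predictors
        assert res.params.loc["rc:dv", "p"] < 0.05

    def test_matches_normal_equations_oracle(self):
        """Coefficients, SEs and CIs on a 12-row table match a direct
        normal-equations computation to 1e-8."""
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "rc": rng.uniform(0, 1, 12),
                "dv": rng.uniform(0, 1, 12),
                "age": rng.integers(1, 20, 12).astype(float),
            }
        )
        y = rng.uniform(0, 1, 12)
        df["y"] = y
        res = fit_topography(df, "y", alpha=0.0)  # main-effects model

        X = np.column_stack([np.ones(12), df["rc"], df["dv"], df["age"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        dfres = 12 - 4
        s2 = resid @ resid / dfres
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tcrit = sps.t.ppf(0.975, dfres)
        got = res.params.loc[["const", "rc", "dv", "age"]]
        assert np.allclose(got["beta"], beta, atol=1e-8)
        assert np.allclose(got["se"], se, atol=1e-8)
        assert np.allclose(got["ci_low"], beta - tcrit * se, atol=1e-8)
        assert np.allclose(got["ci_high"], beta + tcrit * se, atol=1e-8)
        assert res.df_resid == dfres

    def test_alpha_zero_returns_main_effects_model(self):
        """Every interaction is 'non-significant' at alpha 0 and eliminated."""
        res = fit_topography(_com_table(noise=0.1), "y", alpha=0.0)
        assert sorted(res.predictors) == ["age", "dv", "rc"]
        assert len(res.trace) == 3

    def test_alpha_one_returns_full_model(self):
        """No interaction can reach p >= 1, so none is eliminated."""
        res = fit_topography(_com_table(noise=0.1), "y", alpha=1.0)
        assert sorted(res.predictors) == [
            "age", "dv", "dv:age", "rc", "rc:age", "rc:dv",
        ]
        assert res.trace == []

    def test_standardized_beta_gives_identical_t_and_p(self):
        """Fitting z-scored variables reproduces each term's t and p."""
        import statsmodels.api as sm

        df = _com_table(n=80, seed=3, noise=0.1)
        res = fit_topography(df, "y", alpha=0.0)

        z = (df[["rc", "dv", "age", "y"]] - df[["rc", "dv", "age", "y"]].mean()) / df[
            ["rc", "dv", "age", "y"]
        ].std()
        zres = sm.OLS(z["y"], sm.add_constant(z[["rc", "dv", "age"]])).fit()
        for term in ("rc", "dv", "age"):
            assert np.isclose(res.params.loc[term, "t"], zres.tvalues[term], atol=1e-8)
            assert np.isclose(res.params.loc[term, "p"], zres.pvalues[term], atol=1e-8)
            assert np.isclose(
                res.params.loc[term, "std_beta"], zres.params[term], atol=1e-8
            )

    def test_df_equals_n_minus_terms_minus_one(self):
        res = fit_topography(_com_table(n=50, noise=0.1), "y", alpha=0.0)
        assert res.df_resid == 50 - (3 + 1)

    def test_age_filter_and_nan_exclusion(self):
        df = _com_table(n=40, noise=0.05)
        df.loc[:4, "y"] = np.nan
        df.loc[5:9, "age"] = 25.0
        res = fit_topography(df, "y", age_max=19)
        assert res.n == 30

    def test_rank_deficient_design_names_aliased_terms(self):
        df = _com_table(n=30, noise=0.05)
        df["dv"] = df["rc"]  # aliased
        with pytest.raises(ValueError, match="rc"):
            fit_topography(df, "y", alpha=1.0)

    def test_too_few_rows_rejected(self):
        df = _com_table(n=5, noise=0.05)
        with pytest.raises(ValueError, match="too few"):
            fit_topography(df, "y")

    def test_estimator_predict_on_training_data(self):
        df = _com_table(n=60, noise=1e-10)
        est = TopographyRegression(alpha=1.0).fit(df, df["y"])
        pred = est.predict(df)
        assert np.allclose(pred, df["y"], atol=1e-6)


class TestAgeDichotomized:
    def test_group_difference_recovery(self):
        df = _com_table(n=60, seed=4, fn=lambda d: 0.2 + 0.3 * (d["age"] >= 7), noise=1e-10)
        res = fit_age_dichotomized(df, "y", cut=7)
        assert np.isclose(res.params.loc["age", "beta"], 0.3, atol=1e-6)

    def test_identical_groups_are_null(self):
        """Indicator coefficient stays non-significant when the groups share
        one mean, in at least 95 of 100 seeds."""
        nonsig = 0
        for seed in range(100):
            df = _com_table(n=100, seed=seed, fn=lambda d: 0.5 + 0 * d["rc"], noise=0.1)
            res = fit_age_dichotomized(df, "y", cut=7, alpha=0.0)
            if res.params.loc["age", "p"] > 0.05:
                nonsig += 1
        assert nonsig >= 95

    def test_single_sided_cut_rejected(self):
        df = _com_table(n=30, noise=0.05)
        with pytest.raises(ValueError, match="one group empty|dichotomization"):
            fit_age_dichotomized(df, "y", cut=50)


class TestDiagnostics:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 32
        df = pd.DataFrame(
            {
                "rc": np.tile([0.0, 1.0], n // 2),
                "dv": np.repeat([0.0, 1.0], n // 2),
                "age": np.tile([1.0, 1.0, 10.0, 10.0], n // 4),
            }
        )
        # orthogonalize age against the others by construction check
        rng = np.random.default_rng(0)
        df["y"] = rng.uniform(0, 1, n)
        res = fit_topography(df, "y", alpha=0.0)
        diag = regression_diagnostics(res)
        corr = df[["rc", "dv", "age"]].corr().to_numpy()
        if np.allclose(corr[~np.eye(3, dtype=bool)], 0, atol=1e-12):
            assert np.allclose(diag.vif[["rc", "dv", "age"]], 1.0, atol=1e-9)

    def test_duplicated_predictor_flagged_infinite(self):
        df = _com_table(n=40, noise=0.1)
        res = fit_topography(df, "y", alpha=0.0)
        X = res.design.copy()
        X["rc2"] = X["rc"]
        res.design = X
        res.params.loc["rc2"] = res.params.loc["rc"]
        diag = regression_diagnostics(res)
        assert np.isinf(diag.vif["rc"]) and np.isinf(diag.vif["rc2"])

    def test_vif_matches_analytic_relation(self):
        """Two predictors correlated at r=0.6 give VIF close to 1/(1-0.36)."""
        rng = np.random.default_rng(11)
        n = 500
        rc = rng.normal(0, 1, n)
        dv = 0.6 * rc + np.sqrt(1 - 0.36) * rng.normal(0, 1, n)
        df = pd.DataFrame({"rc": rc, "dv": dv, "age": rng.normal(0, 1, n)})
        df["y"] = rng.normal(0, 1, n)
        res = fit_topography(df, "y", alpha=0.0, age_max=None)
        diag = regression_diagnostics(res)
        assert abs(diag.vif["rc"] - 1.5625) < 0.1

    def test_collinearity_threshold_on_pairwise_r(self):
        rng = np.random.default_rng(12)
        n = 200
        rc = rng.normal(0, 1, n)
        df = pd.DataFrame(
            {"rc": rc, "dv": 0.95 * rc + 0.1 * rng.normal(0, 1, n), "age": rng.normal(0, 1, n)}
        )
        df["y"] = rng.normal(0, 1, n)
        res = fit_topography(df, "y", alpha=0.0, age_max=None)
        assert not regression_diagnostics(res).collinearity_ok


class TestBackwardElimination:
    def test_trace_strictly_shrinks_terms(self):
        df = _com_table(n=60, seed=6, noise=0.2)
        res = backward_eliminate(
            df[["rc", "dv", "age"]],
            df["y"].to_numpy(),
            main=["rc", "dv", "age"],
            interactions=[("rc", "dv"), ("rc", "age"), ("dv", "age")],
            alpha=0.05,
        )
        dropped = [t["dropped"] for t in res.trace]
        assert len(dropped) == len(set(dropped))
        assert len(res.predictors) == 6 - len(dropped)
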