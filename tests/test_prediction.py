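"""Kernel BLUP, cross-validation, scenario machinery tests."""

import numpy as np
import pandas as pd
import pytest

from psblup.kernels import RelationshipMatrix, additive_kernel
from psblup.prediction import (PredictionResult, ScenarioSpec, cross_validate,
                               enumerate_cases, fit_blup, flight_date_subsets,
                               make_folds, pearson_pa, predict_masked,
                               quality_filter, run_scenario,
                               weight_grid_search)

from conftest import toy_kernel


def series(vals, ids=None):
    ids = ids or [f"c{i}" for i in range(len(vals))]
    return pd.Series(np.asarray(vals, float), index=ids)


class TestPearson:
    def test_perfect_and_inverse(self):
        o = series([1, 2, 3, 4])
        assert pearson_pa(o, o) == pytest.approx(1.0)
        assert pearson_pa(o, -o) == pytest.approx(-1.0)

    def test_constant_prediction_is_missing(self):
        o = series([1, 2, 3])
        assert np.isnan(pearson_pa(o, series([5, 5, 5])))

    def test_too_few_pairs_missing(self):
        o = series([1, 2])
        assert np.isnan(pearson_pa(o, o))


class TestFolds:
    def test_partition_properties(self):
        clones = [f"c{i}" for i in range(23)]
        for rep in range(5):
            folds = make_folds(clones, 5, rep, seed=1)
            flat = np.concatenate(folds)
            assert sorted(flat) == sorted(clones)  # exactly once each
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_deterministic(self):
        clones = [f"c{i}" for i in range(10)]
        a = make_folds(clones, 3, 2, seed=7)
        b = make_folds(clones, 3, 2, seed=7)
        for x, y in zip(a, b):
            assert list(x) == list(y)


class TestBlup:
    def test_identity_kernel_predicts_training_mean(self):
        rng = np.random.default_rng(0)
        ids = [f"c{i}" for i in range(30)]
        K = RelationshipMatrix(np.eye(30), ids, "G")
        y = series(rng.normal(2.0, 1.0, 25), ids[:25])
        fit = fit_blup(y, K)
        pred = predict_masked(fit, K, ids[25:], y)
        assert np.allclose(pred, y.mean(), atol=1e-6)

    def test_orthogonal_validation_block_predicts_intercept(self):
        ids = [f"c{i}" for i in range(12)]
        K = np.zeros((12, 12))
        K[:8, :8] = toy_kernel(8, rho=0.8, seed=1)
        K[8:, 8:] = np.eye(4)
        Km = RelationshipMatrix(K, ids, "G")
        rng = np.random.default_rng(2)
        y = series(rng.normal(size=8), ids[:8])
        fit = fit_blup(y, Km)
        pred = predict_masked(fit, Km, ids[8:], y)
        mu = fit.beta[0]
        assert np.allclose(pred, mu, atol=1e-10)

    def test_perfect_proxy_clone(self):
        """A validation clone identical in K to a training clone converges
        to that clone's entry mean as the residual variance vanishes."""
        n = 10
        base = toy_kernel(n, rho=0.9, seed=3)
        K = np.zeros((n + 1, n + 1))
        K[:n, :n] = base
        K[n, :n] = base[0, :]
        K[:n, n] = base[:, 0]
        K[n, n] = base[0, 0]
        ids = [f"c{i}" for i in range(n + 1)]
        rng = np.random.default_rng(4)
        u = np.linalg.cholesky(base + 1e-10 * np.eye(n)) @ rng.normal(size=n)
        y = series(1.0 + u, ids[:n])  # noiseless -> s2e fitted ~ 0
        Km = RelationshipMatrix(K, ids, "G")
        fit = fit_blup(y, Km)
        pred = predict_masked(fit, Km, [ids[n]], y)
        assert pred.iloc[0] == pytest.approx(y.iloc[0], abs=1e-3)

    def test_masked_mme_equals_closed_form(self):
        """Two-route oracle on a small instance: Henderson equations with
        masked responses vs the conditional-expectation formula."""
        n = 16
        ids = [f"c{i}" for i in range(n)]
        K = RelationshipMatrix(toy_kernel(n, rho=0.7, seed=5), ids, "G")
        rng = np.random.default_rng(6)
        y_all = series(rng.normal(size=n), ids)
        train, valid = ids[:12], ids[12:]
        fit = fit_blup(y_all[train], K, all_clones=ids)
        closed = predict_masked(fit, K, valid, y_all[train], route="closed")
        mme = predict_masked(fit, K, valid, y_all[train], route="mme")
        assert np.allclose(closed, mme, atol=1e-8)

    def test_multi_kernel_masked_mme_equals_closed_form(self):
        n = 14
        ids = [f"c{i}" for i in range(n)]
        G = RelationshipMatrix(toy_kernel(n, rho=0.7, seed=8), ids, "G")
        D = RelationshipMatrix(toy_kernel(n, rho=0.4, seed=9), ids, "D")
        rng = np.random.default_rng(10)
        y = series(rng.normal(size=n), ids)
        train, valid = ids[:10], ids[10:]
        fit = fit_blup(y[train], [G, D], all_clones=ids, method="dense")
        closed = predict_masked(fit, [G, D], valid, y[train])
        mme = predict_masked(fit, [G, D], valid, y[train], route="mme")
        assert np.allclose(closed, mme, atol=1e-8)

    def test_equals_kernel_ridge_at_fitted_penalty(self):
        n = 18
        ids = [f"c{i}" for i in range(n)]
        Kv = toy_kernel(n, rho=0.8, seed=11)
        K = RelationshipMatrix(Kv, ids, "G")
        rng = np.random.default_rng(12)
        u = np.linalg.cholesky(Kv + 1e-9 * np.eye(n)) @ rng.normal(size=n)
        y = series(2.0 * u + rng.normal(0, 0.5, n), ids)
        fit = fit_blup(y, K, compute_blups=True)
        lam = (fit.variance_components["residual"]
               / fit.variance_components["G"])
        mu = fit.beta[0]
        ridge_u = Kv @ np.linalg.solve(Kv + lam * np.eye(n),
                                       y.to_numpy() - mu)
        assert np.allclose(fit.blups["G"], ridge_u, atol=1e-6)

    def test_noiseless_marker_trait_predicts_near_perfectly(self):
        """Exact-interpolation limit: with fewer markers than training
        clones, a noiseless linear function of the centered dosages lies in
        the training span, so held-out PA approaches 1."""
        rng = np.random.default_rng(13)
        n, m = 90, 40
        Z = pd.DataFrame(rng.integers(0, 5, (n, m)).astype(float),
                         index=[f"c{i}" for i in range(n)],
                         columns=[f"m{j}" for j in range(m)])
        G = additive_kernel(Z)
        Xc = Z.to_numpy() - Z.to_numpy().mean(axis=0)
        y = series(Xc @ rng.normal(size=m) / np.sqrt(m), list(Z.index))
        res = cross_validate(y, G, n_folds=5, n_reps=2, seed=0)
        assert res.median_pa > 0.99


class TestCrossValidation:
    def test_slot_count_is_folds_times_reps(self):
        rng = np.random.default_rng(1)
        ids = [f"c{i}" for i in range(40)]
        K = RelationshipMatrix(toy_kernel(40, rho=0.6, seed=1), ids, "G")
        y = series(rng.normal(size=40), ids)
        res = cross_validate(y, K, n_folds=5, n_reps=25, seed=2)
        assert res.pa.shape == (125,)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        ids = [f"c{i}" for i in range(30)]
        K = RelationshipMatrix(toy_kernel(30, rho=0.6, seed=2), ids, "G")
        y = series(rng.normal(size=30), ids)
        a = cross_validate(y, K, n_reps=3, seed=9)
        b = cross_validate(y, K, n_reps=3, seed=9)
        np.testing.assert_array_equal(a.pa, b.pa)


class TestQualityFilter:
    def _result(self, pa):
        return PredictionResult(pa=np.asarray(pa, float), n_folds=5,
                                n_reps=25, seed=0)

    def test_constant_positive_pa_passes(self):
        res = quality_filter(self._result([0.5] * 125))
        assert res.passed_quality_filter

    def test_many_missing_fail(self):
        pa = np.full(125, np.nan)
        pa[:15] = 0.5 + 0.01 * np.arange(15)
        res = quality_filter(self._result(pa))  # 110 missing > 100
        assert not res.passed_quality_filter
        assert "missing" in res.filter_reason

    def test_extreme_cv_fails(self):
        rng = np.random.default_rng(0)
        pa = rng.normal(0.001, 0.5, 125)
        pa = pa - pa.mean() + 0.001  # force mean 0.001
        res = quality_filter(self._result(pa))
        assert abs(res.cv_percent) > 150
        assert not res.passed_quality_filter

    def test_zero_mean_cv_undefined_fails(self):
        pa = np.concatenate([np.full(60, 0.5), np.full(60, -0.5), [0.0] * 5])
        res = quality_filter(self._result(pa))
        assert not res.passed_quality_filter
        assert "undefined" in res.filter_reason


class TestScenarios:
    ENVS = ("G20", "G21", "W19", "W20", "W21")
    SPEC = ("W20", "W21")

    def test_s2_has_eight_cases(self):
        cases = enumerate_cases("S2", self.ENVS, self.SPEC)
        assert len(cases) == 8

    def test_s1_matched_pairs_only(self):
        cases = enumerate_cases("S1", self.ENVS, self.SPEC)
        assert [(c.phenotype_scope[1], c.kernel_source) for c in cases] == \
            [("W20", "W20"), ("W21", "W21")]

    def test_counts_for_remaining_scenarios(self):
        expected = {"S3": 2, "S3b": 2, "S4": 10, "S5": 2, "S6": 5, "S7": 1}
        for s, n in expected.items():
            assert len(enumerate_cases(s, self.ENVS, self.SPEC)) == n, s

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError, match="S2"):
            ScenarioSpec("S2", ("env", "W20"), "W20")
        with pytest.raises(ValueError, match="S3b"):
            ScenarioSpec("S3b", ("across_excluding", "W20"), "W21")
        with pytest.raises(ValueError, match="genomic"):
            ScenarioSpec("S6", ("env", "W20"), "W20")

    def test_s7_equals_direct_cross_validation(self, bundle):
        case = enumerate_cases("S7", bundle.phenotype_envs,
                               bundle.spectra_envs)[0]
        trait = bundle.traits[0]
        res = run_scenario(case, bundle, trait, n_reps=3, seed=5)
        direct = cross_validate(bundle.aems[(("across", None), trait)],
                                bundle.kernels["G"], n_reps=3, seed=5)
        np.testing.assert_array_equal(res.pa, direct.pa)

    def test_gde_model_assembles_five_kernels(self, bundle):
        case = ScenarioSpec("S7", ("across", None), "SNP",
                            ("G", "D", "AA", "AD", "DD"))
        kernels = bundle.kernel_for(case)
        assert len(kernels) == 5
        assert [k.kind for k in kernels] == ["G", "D", "AA", "AD", "DD"]


class TestWeightSearch:
    def _data(self, n=40, seed=0):
        ids = [f"c{i}" for i in range(n)]
        M = RelationshipMatrix(toy_kernel(n, rho=0.7, seed=seed), ids, "M")
        G = RelationshipMatrix(toy_kernel(n, rho=0.7, seed=seed + 50), ids,
                               "G")
        rng = np.random.default_rng(seed)
        uM = np.linalg.cholesky(M.values + 1e-9 * np.eye(n)) @ rng.normal(size=n)
        uG = np.linalg.cholesky(G.values + 1e-9 * np.eye(n)) @ rng.normal(size=n)
        y = series(uM + uG + rng.normal(0, 0.5, n), ids)
        return y, M, G

    def test_endpoints_reproduce_pure_runs_bit_for_bit(self):
        y, M, G = self._data()
        table, _ = weight_grid_search(y, M, G, grid=[0.0, 0.5, 1.0],
                                      n_reps=2, seed=3)
        pure_g = cross_validate(y, G, n_reps=2, seed=3)
        pure_m = cross_validate(y, M, n_reps=2, seed=3)
        assert table.loc[table.x == 0.0, "median_pa"].iloc[0] == pure_g.median_pa
        assert table.loc[table.x == 1.0, "median_pa"].iloc[0] == pure_m.median_pa

    def test_grid_max_dominates_endpoints(self):
        y, M, G = self._data(seed=4)
        table, best = weight_grid_search(y, M, G, n_reps=2, seed=1)
        ends = table[table.x.isin([0.0, 1.0])].median_pa.max()
        assert table.median_pa.max() >= ends - 1e-12

    def test_invalid_grid_rejected(self):
        y, M, G = self._data()
        with pytest.raises(ValueError, match="grid"):
            weight_grid_search(y, M, G, grid=[0.0, 1.5])


class TestFlightDates:
    def test_all_subsets_enumerated_and_identity_subset(self, bundle):
        S = bundle.spectra_clone["W20"]
        trait = bundle.traits[0]
        y = bundle.aems[(("across", None), trait)]
        table = flight_date_subsets(S, y, n_reps=2, seed=11)
        assert len(table) == 7  # 2^3 - 1 non-empty subsets
        full = table[table.subset == "D1+D2+D3"]
        from psblup.kernels import spectral_kernel
        direct = cross_validate(y, spectral_kernel(S), n_reps=2, seed=11)
        assert full.median_pa.iloc[0] == direct.median_pa

    def test_empty_subset_rejected(self, bundle):
        S = bundle.spectra_clone["W20"]
        trait = bundle.traits[0]
        y = bundle.aems[(("across", None), trait)]
        with pytest.raises(ValueError):
            flight_date_subsets(S, y, subsets=[()], n_reps=1, seed=0)
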