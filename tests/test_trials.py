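"""Trial adjustment, entry means, and heritability tests."""

import numpy as np
import pandas as pd
import pytest

from psblup.lmm import LmmFit
from psblup.simulate import SimConfig, TraitSpec, simulate_population, \
    simulate_trial, simulate_spectra
from psblup.trials import (AdjustedEntryMeans, adjust_for_trial,
                           apply_sqrt_transform, channel_heritability,
                           compute_aems, estimate_trial_effects, heritability,
                           mean_variance_of_difference, trait_heritability)

from conftest import small_config


def make_fit(vc):
    return LmmFit(variance_components=vc, beta=np.zeros(1),
                  beta_cov=np.eye(1), fixed_names=["intercept"], blups={},
                  blup_levels={}, loglik=0.0, converged=True)


@pytest.fixture(scope="module")
def injected_trial():
    cfg = small_config(
        seed=21, n_clones=80, n_families=20, n_markers=100,
        traits=(TraitSpec("t", 0.9, 0.0, 0.1, 0.0),),
        trial_effects={("W21", "early"): 0.0, ("W21", "late"): 5.0,
                       ("G21", "early"): 0.0, ("G21", "late"): 0.0},
    )
    pop = simulate_population(cfg)
    return cfg, pop, simulate_trial(pop, cfg)


class TestTrialEffects:
    def test_injected_effect_recovered(self, injected_trial, population):
        cfg, pop, trial = injected_trial
        checks = pop[1].loc[pop[1].is_check, "clone"]
        est = estimate_trial_effects(trial.plots, "t", "W21", checks)
        assert est["early"] == 0.0
        assert est["late"] == pytest.approx(5.0, abs=1.0)

    def test_single_trial_is_noop(self, injected_trial):
        cfg, pop, trial = injected_trial
        checks = pop[1].loc[pop[1].is_check, "clone"]
        est = estimate_trial_effects(trial.plots, "t", "W19", checks)
        assert est == {"main": 0.0}

    def test_noise_free_identical_checks_give_zero_contrast(self):
        cfg = small_config(
            seed=22, n_clones=40, n_families=10, n_markers=60,
            traits=(TraitSpec("t", 1.0, 0.0, 0.0, 0.0),),
            trial_effect_sd=0.0, env_sd=0.0)
        pop = simulate_population(cfg)
        trial = simulate_trial(pop, cfg)
        checks = pop[1].loc[pop[1].is_check, "clone"]
        est = estimate_trial_effects(trial.plots, "t", "W21", checks)
        assert est["late"] == pytest.approx(0.0, abs=1e-6)

    def test_missing_checks_raise(self, injected_trial):
        cfg, pop, trial = injected_trial
        df = trial.plots
        no_checks = df[~df.clone.isin(set(pop[1].loc[pop[1].is_check,
                                                     "clone"]))]
        with pytest.raises(ValueError, match="check"):
            estimate_trial_effects(no_checks, "t", "W21", ["CHK00"])


class TestAdjust:
    def test_zero_effect_is_identity(self, injected_trial):
        _, _, trial = injected_trial
        effects = {k: 0.0 for k in trial.plots.groupby(["env", "trial"]).groups}
        out = adjust_for_trial(trial.plots, effects)
        pd.testing.assert_frame_equal(out, trial.plots)

    def test_definitional_subtraction(self):
        plots = pd.DataFrame({
            "clone": ["a", "b"], "env": ["W21"] * 2,
            "trial": ["early", "late"], "block": [1, 4], "row": [1, 2],
            "column": [1, 1], "trait": ["t"] * 2, "value": [10.0, 10.0]})
        out = adjust_for_trial(plots, {("W21", "early"): 0.0,
                                       ("W21", "late"): 5.0})
        assert out.value.tolist() == [10.0, 5.0]

    def test_readjustment_contrast_near_zero(self, injected_trial):
        """Fixed point: after subtracting the estimated effects, the
        re-estimated contrasts are ~0."""
        cfg, pop, trial = injected_trial
        checks = pop[1].loc[pop[1].is_check, "clone"]
        est = estimate_trial_effects(trial.plots, "t", "W21", checks)
        adjusted = adjust_for_trial(
            trial.plots[trial.plots.env == "W21"],
            {("W21", t): e for t, e in est.items()})
        re_est = estimate_trial_effects(adjusted, "t", "W21", checks)
        assert re_est["late"] == pytest.approx(0.0, abs=1e-4)

    def test_missing_lookup_raises(self, injected_trial):
        _, _, trial = injected_trial
        with pytest.raises(KeyError):
            adjust_for_trial(trial.plots, {})


def balanced_plots(n_clones=6, n_envs=2, noise_sd=0.01, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, 1, n_clones)
    rows = []
    for e in range(n_envs):
        for c in range(n_clones):
            rows.append({
                "clone": f"c{c}", "env": f"E{10 + e}", "trial": "main",
                "block": c % 2 + 1, "row": c % 3 + 1, "column": c % 2 + 1,
                "trait": "t", "value": g[c] + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestAems:
    def test_equals_raw_means_without_nuisance_variance(self):
        plots = balanced_plots(noise_sd=0.01)
        aems = compute_aems(plots, "t", ("across", None), include_column=True,
                            outlier_threshold=None)
        raw = plots.groupby("clone").value.mean()
        assert np.allclose(aems.values.sort_index(), raw.sort_index(),
                           atol=0.02)

    def test_invariant_to_factor_relabeling(self):
        plots = balanced_plots(noise_sd=0.5, seed=3)
        a1 = compute_aems(plots, "t", ("across", None), include_column=True,
                          outlier_threshold=None)
        relabeled = plots.copy()
        relabeled["block"] = relabeled["block"].map({1: 9, 2: 4})
        relabeled["row"] = relabeled["row"].map({1: 30, 2: 10, 3: 20})
        a2 = compute_aems(relabeled, "t", ("across", None),
                          include_column=True, outlier_threshold=None)
        assert np.allclose(a1.values, a2.values, atol=1e-8)

    def test_matches_direct_gls_solution(self):
        """Two-route oracle: at the fitted variance components the AEMs
        equal the GLS solution computed by direct matrix inversion."""
        plots = balanced_plots(n_clones=6, noise_sd=0.5, seed=7)
        aems = compute_aems(plots, "t", ("across", None), include_column=True,
                            outlier_threshold=None)
        vc = aems.fit.variance_components
        df = plots
        n = len(df)
        X = pd.get_dummies(df.clone).to_numpy(float)
        clone_order = sorted(df.clone.unique())
        V = vc["residual"] * np.eye(n)
        for name, labels in [
                ("env", df.env), ("clone:env", df.clone + "|" + df.env),
                ("block", df.env + "|" + df.block.astype(str)),
                ("row", df.env + "|" + df.row.astype(str)),
                ("column", df.env + "|" + df.column.astype(str))]:
            Z = pd.get_dummies(labels).to_numpy(float)
            V += vc[name] * Z @ Z.T
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df.value.to_numpy())
        gls = pd.Series(beta, index=clone_order)
        assert np.allclose(aems.values.sort_index(), gls.sort_index(),
                           atol=1e-6)

    def test_scope_excluding_environment(self, trial):
        aems = compute_aems(trial.plots, "yield",
                            ("across_excluding", "W20"), include_column=True,
                            outlier_threshold=None)
        assert "W20" not in aems.fit.blup_levels["env"]

    def test_absent_trait_raises(self, trial):
        with pytest.raises(ValueError, match="no plots"):
            compute_aems(trial.plots, "nope")


class TestHeritability:
    def test_zero_genetic_variance(self):
        fit = make_fit({"clone": 0.0, "residual": 1.0})
        aems = AdjustedEntryMeans(pd.Series([0.0] * 3, index=list("abc")),
                                  np.eye(3), "t", ("across", None))
        h = heritability(fit, aems)
        assert h.h2 == 0.0

    def test_formula_arithmetic(self):
        fit = make_fit({"clone": 3.0, "residual": 1.0})
        aems = AdjustedEntryMeans(pd.Series([0.0] * 3, index=list("abc")),
                                  np.eye(3), "t", ("across", None))
        h = heritability(fit, aems)
        assert h.vbar == pytest.approx(2.0)
        assert h.h2 == pytest.approx(3.0 / 4.0)
        # identity holds exactly for the emitted estimate
        assert h.h2 == h.sigma2_g / (h.sigma2_g + h.vbar / 2)

    def test_plot_basis_uses_all_components(self):
        fit = make_fit({"clone": 1.0, "env": 1.0, "residual": 2.0})
        h = heritability(fit, None, basis="plot")
        assert h.h2 == pytest.approx(0.25)

    def test_degenerate_vbar_raises(self):
        fit = make_fit({"clone": 1.0, "residual": 1.0})
        aems = AdjustedEntryMeans(pd.Series([0.0] * 3, index=list("abc")),
                                  np.ones((3, 3)), "t", ("across", None))
        with pytest.raises(ValueError, match="vbar"):
            heritability(fit, aems)

    def test_mean_variance_of_difference_brute_force(self):
        rng = np.random.default_rng(0)
        L = rng.normal(size=(5, 5))
        cov = L @ L.T
        g = 5
        pairs = [cov[i, i] + cov[j, j] - 2 * cov[i, j]
                 for i in range(g) for j in range(i + 1, g)]
        assert mean_variance_of_difference(cov) == pytest.approx(
            np.mean(pairs))

    def test_high_heritability_recovered(self):
        """Parameter recovery at a configured entry-mean H2 of 0.9."""
        ests = []
        for seed in range(3):
            cfg = small_config(
                seed=100 + seed, n_clones=80, n_families=20, n_markers=100,
                traits=(TraitSpec("t", 0.9, 0.1, 0.2, 0.0),))
            pop = simulate_population(cfg)
            trial = simulate_trial(pop, cfg)
            h = trait_heritability(trial.plots, "t", include_column=True)
            ests.append(h.h2)
        assert abs(np.median(ests) - 0.9) < 0.05


class TestChannels:
    def test_zero_signal_channel_heritability_near_zero(self):
        cfg = small_config(
            seed=31, n_clones=50, n_families=15, n_markers=60,
            channel_h2_plot=0.0,
            traits=(TraitSpec("t", 0.7, 0.0, 0.2, 0.0),))
        pop = simulate_population(cfg)
        spectra = simulate_spectra(pop, cfg)
        sub = spectra[spectra.channel.isin(["b490"])]
        out = channel_heritability(sub, mode="per_date", basis="plot",
                                   include_column=True)
        assert out.h2.max() < 0.12

    def test_per_date_plot_heritability_recovered(self):
        cfg = small_config(
            seed=32, n_clones=60, n_families=15, n_markers=60,
            channel_h2_plot=0.4,
            traits=(TraitSpec("t", 0.7, 0.0, 0.2, 0.0),))
        pop = simulate_population(cfg)
        spectra = simulate_spectra(pop, cfg)
        sub = spectra[spectra.channel.isin(["b490", "g550"])]
        out = channel_heritability(sub, mode="per_date", basis="plot",
                                   include_column=True)
        assert abs(out.h2.median() - 0.4) < 0.1

    def test_across_dates_below_per_date_with_date_specific_signal(self):
        """Low date coherence: the across-date (entry-mean) heritability
        sits below the best per-date estimate, mirroring the observed
        ordering of across-date vs per-date channel heritabilities."""
        cfg = small_config(
            seed=33, n_clones=50, n_families=15, n_markers=60,
            channel_h2_plot=0.35, date_coherence=0.1,
            traits=(TraitSpec("t", 0.7, 0.0, 0.2, 0.0),))
        pop = simulate_population(cfg)
        spectra = simulate_spectra(pop, cfg)
        sub = spectra[spectra.channel == "b490"]
        per_date = channel_heritability(sub, mode="per_date",
                                        basis="entry_mean",
                                        include_column=True)
        across = channel_heritability(sub, mode="across_dates",
                                      basis="entry_mean", include_column=True)
        assert across.h2.iloc[0] <= per_date.h2.max()


class TestTransform:
    def test_sqrt_applied_to_flagged_traits_only(self):
        plots = pd.DataFrame({
            "clone": ["a", "a"], "env": ["W20"] * 2, "trial": ["main"] * 2,
            "block": [1, 1], "row": [1, 2], "column": [1, 1],
            "trait": ["frac_small", "yield"], "value": [4.0, 4.0]})
        out = apply_sqrt_transform(plots, ["frac_small"])
        assert out.value.tolist() == [2.0, 4.0]

    def test_negative_values_rejected(self):
        plots = pd.DataFrame({
            "clone": ["a"], "env": ["W20"], "trial": ["main"], "block": [1],
            "row": [1], "column": [1], "trait": ["t"], "value": [-1.0]})
        with pytest.raises(ValueError, match="negative"):
            apply_sqrt_transform(plots, ["t"])
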