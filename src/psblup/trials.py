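"""Trial adjustment, adjusted entry means, and heritability.

Implements the concrete field-trial models on top of the REML engine:

* trial-effect estimation from the replicated checks in split environments
  (trial fixed; check, block, row, column random) and subtraction of the
  estimated trial contrasts from all plot values;
* adjusted entry means (AEMs) per clone with the clone as a fixed effect,
  either within a single environment (block/row/column random) or across
  environments (environment, clone x environment, and the spatial factors
  nested in environment, all random);
* broad-sense heritability on an entry-mean basis, H2 = s2g / (s2g + vbar/2),
  where vbar is the exact mean variance of a difference between AEMs taken
  from the clone-BLUE covariance matrix and s2g comes from a refit with the
  clone random;
* channel-reflectance heritabilities per flight date (the across-environment
  model per channel-date column) or across flight dates (adding the flight
  date and all its interactions as random terms), on an entry-mean or plot
  basis.

The random column effect is optional: by default its inclusion is decided by
a restricted likelihood-ratio test on the column variance component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .lmm import (LmmFit, LmmSpec, RandomTerm, dummy_matrix, fit_reml,
                  rlrt_term)

__all__ = [
    "AdjustedEntryMeans",
    "HeritabilityEstimate",
    "estimate_trial_effects",
    "adjust_for_trial",
    "decide_column_effect",
    "compute_aems",
    "heritability",
    "trait_heritability",
    "channel_heritability",
    "apply_sqrt_transform",
]

log = logging.getLogger(__name__)


@dataclass
class AdjustedEntryMeans:
    """Clone AEMs for one response and scope, with the BLUE covariance."""

    values: pd.Series  # clone -> AEM
    cov: np.ndarray  # covariance of the clone effect estimates
    response: str
    scope: tuple  # ("env", id) | ("across", None) | ("across_excluding", id)
    fit: LmmFit | None = None

    @property
    def clones(self) -> list:
        return list(self.values.index)


@dataclass
class HeritabilityEstimate:
    """Piepho-Moehring broad-sense heritability with its ingredients."""

    response: str
    basis: str  # "entry_mean" | "plot"
    sigma2_g: float
    vbar: float | None
    h2: float
    variance_components: dict | None = None


def _interact(a: pd.Series, b: pd.Series) -> list[str]:
    return (a.astype(str) + "|" + b.astype(str)).tolist()


def _scope_filter(plots: pd.DataFrame, scope: tuple) -> pd.DataFrame:
    kind, env = scope
    if kind == "env":
        out = plots[plots["env"] == env]
        if out.empty:
            raise ValueError(f"no plots in environment {env!r}")
        return out
    if kind == "across":
        return plots
    if kind == "across_excluding":
        out = plots[plots["env"] != env]
        if out["env"].nunique() < 1:
            raise ValueError("no environments left after exclusion")
        return out
    raise ValueError(f"unknown scope kind {scope!r}")


def _random_terms(df: pd.DataFrame, multi_env: bool, include_column: bool,
                  clone_random: bool) -> list[RandomTerm]:
    terms = []
    if clone_random:
        terms.append(RandomTerm.factor("clone", df["clone"]))
    if multi_env:
        terms.append(RandomTerm.factor("env", df["env"]))
        terms.append(RandomTerm.factor("clone:env",
                                       _interact(df["clone"], df["env"])))
        terms.append(RandomTerm.factor("block", _interact(df["env"], df["block"])))
        terms.append(RandomTerm.factor("row", _interact(df["env"], df["row"])))
        if include_column:
            terms.append(RandomTerm.factor("column",
                                           _interact(df["env"], df["column"])))
    else:
        terms.append(RandomTerm.factor("block", df["block"]))
        terms.append(RandomTerm.factor("row", df["row"]))
        if include_column:
            terms.append(RandomTerm.factor("column", df["column"]))
    return terms


def _aem_spec(df: pd.DataFrame, multi_env: bool, include_column: bool,
              clone_random: bool) -> LmmSpec:
    y = df["value"].to_numpy(float)
    if clone_random:
        X = np.ones((len(df), 1))
        names = ["intercept"]
    else:
        X, names = dummy_matrix(df["clone"])
    terms = _random_terms(df, multi_env, include_column, clone_random)
    return LmmSpec(y, X, terms, fixed_names=list(names))


def estimate_trial_effects(plots: pd.DataFrame, trait: str, environment: str,
                           check_clones, **fit_kwargs) -> dict:
    """Per-trial fixed-effect contrasts from the check plots of one
    environment (trial fixed; check, block, row, column random).

    Returns {trial: effect} with 0 for the reference (first) trial.  A
    single-trial environment returns {trial: 0.0}.
    """
    df = plots[(plots["env"] == environment) & (plots["trait"] == trait)]
    if df.empty:
        raise ValueError(f"no plots for trait {trait!r} in {environment!r}")
    trials = sorted(df["trial"].unique())
    if len(trials) == 1:
        return {trials[0]: 0.0}
    checks = df[df["clone"].isin(set(check_clones))]
    for t in trials:
        if checks[checks["trial"] == t].empty:
            raise ValueError(f"trial {t!r} in {environment!r} has no check plots")
    Xt, _ = dummy_matrix(checks["trial"])
    X = sp.hstack([sp.csr_matrix(np.ones((len(checks), 1))),
                   Xt[:, 1:]], format="csr")
    names = ["intercept"] + [f"trial[{t}]" for t in trials[1:]]
    terms = [
        RandomTerm.factor("check", checks["clone"]),
        RandomTerm.factor("block", checks["block"]),
        RandomTerm.factor("row", checks["row"]),
        RandomTerm.factor("column", checks["column"]),
    ]
    fit = fit_reml(LmmSpec(checks["value"].to_numpy(float), X, terms, names),
                   **fit_kwargs)
    effects = {trials[0]: 0.0}
    for j, t in enumerate(trials[1:], start=1):
        effects[t] = float(fit.beta[j])
    return effects


def adjust_for_trial(plots: pd.DataFrame, trial_effects: dict) -> pd.DataFrame:
    """Subtract the estimated trial effect from every plot value.

    ``trial_effects`` maps (env, trial) -> effect; applied to all traits
    regardless of the significance of the trial contrast.
    """
    def effect(row):
        key = (row["env"], row["trial"])
        if key not in trial_effects:
            raise KeyError(f"no trial effect estimate for {key}")
        return trial_effects[key]

    out = plots.copy()
    shift = out.apply(effect, axis=1)
    out["value"] = out["value"] - shift
    return out


def decide_column_effect(df: pd.DataFrame, multi_env: bool,
                         method: str = "chibar", n_sim: int = 200,
                         alpha: float = 0.05, seed: int = 0,
                         **fit_kwargs) -> bool:
    """Likelihood-ratio test whether the random column variance is needed.

    Compares the clone-random model with and without the column term; the
    null distribution is the 50:50 chi2(0)/chi2(1) mixture by default, or a
    parametric bootstrap (``method='bootstrap'``)."""
    full = _aem_spec(df, multi_env, include_column=True, clone_random=True)
    red = _aem_spec(df, multi_env, include_column=False, clone_random=True)
    _, _, include = rlrt_term(full, red, n_sim=n_sim, alpha=alpha, seed=seed,
                              method=method, fit_kwargs=fit_kwargs)
    return include


def _studentized_outliers(df: pd.DataFrame, fit: LmmFit, spec: LmmSpec,
                          threshold: float) -> np.ndarray:
    Xd = spec.X.toarray() if sp.issparse(spec.X) else np.asarray(spec.X)
    resid = spec.y - Xd @ fit.beta
    for t in spec.terms:
        resid = resid - np.asarray(t.Z @ fit.blups[t.name]).ravel()
    s = np.sqrt(max(fit.variance_components["residual"], 1e-300))
    return np.abs(resid / s) > threshold


def compute_aems(plots: pd.DataFrame, response: str,
                 scope: tuple = ("across", None),
                 include_column: bool | str = "auto",
                 outlier_threshold: float | None = 4.0,
                 column_test_kwargs: dict | None = None,
                 **fit_kwargs) -> AdjustedEntryMeans:
    """Adjusted entry means per clone for one trait under the given scope.

    The clone enters as a fixed effect in cell-means coding, so the BLUEs
    are the AEMs directly and their covariance feeds vbar.  Plots whose
    absolute studentized residual exceeds ``outlier_threshold`` are dropped
    once and the model refitted (set to None to disable).  With
    ``include_column='auto'`` the random column effect is kept only when the
    likelihood-ratio test on its variance is significant.
    """
    df = plots[plots["trait"] == response]
    if df.empty:
        raise ValueError(f"no plots for response {response!r}")
    df = _scope_filter(df, scope)
    df = df[np.isfinite(df["value"].astype(float))]
    multi_env = df["env"].nunique() > 1
    if scope[0] != "env" and not multi_env:
        log.info("single environment in scope %s; falling back to the "
                 "single-environment model", scope)
    if include_column == "auto":
        include_column = decide_column_effect(
            df, multi_env, **(column_test_kwargs or {}), **fit_kwargs)

    spec = _aem_spec(df, multi_env, include_column, clone_random=False)
    fit = fit_reml(spec, **fit_kwargs)
    if outlier_threshold is not None:
        bad = _studentized_outliers(df, fit, spec, outlier_threshold)
        if bad.any():
            df = df.loc[~bad]
            spec = _aem_spec(df, multi_env, include_column, clone_random=False)
            fit = fit_reml(spec, **fit_kwargs)

    clones = [str(c) for c in spec.fixed_names]
    values = pd.Series(fit.beta, index=clones, name=response)
    return AdjustedEntryMeans(values=values, cov=fit.beta_cov,
                              response=response, scope=scope, fit=fit)


def mean_variance_of_difference(cov: np.ndarray) -> float:
    """Exact mean over clone pairs of Var(AEM_i - AEM_j)."""
    g = cov.shape[0]
    if g < 2:
        raise ValueError("need at least two clones")
    tr = float(np.trace(cov))
    total = float(cov.sum())
    return (g * tr - total) * 2.0 / (g * (g - 1))


def heritability(fit_random_clone: LmmFit, aems: AdjustedEntryMeans | None,
                 basis: str = "entry_mean",
                 response: str = "") -> HeritabilityEstimate:
    """Broad-sense heritability from a clone-random fit and (for the
    entry-mean basis) the AEM covariance: H2 = s2g / (s2g + vbar/2); on a
    plot basis s2g over the sum of all variance components."""
    s2g = fit_random_clone.variance_components["clone"]
    vc = dict(fit_random_clone.variance_components)
    if basis == "plot":
        total = sum(vc.values())
        return HeritabilityEstimate(response, "plot", s2g, None,
                                    s2g / total if total > 0 else 0.0, vc)
    if aems is None:
        raise ValueError("entry-mean basis requires the AEMs")
    vbar = mean_variance_of_difference(aems.cov)
    if vbar <= 0:
        raise ValueError("degenerate design: vbar <= 0")
    return HeritabilityEstimate(response or aems.response, "entry_mean",
                                s2g, vbar, s2g / (s2g + vbar / 2.0), vc)


def trait_heritability(plots: pd.DataFrame, trait: str,
                       scope: tuple = ("across", None),
                       include_column: bool | str = "auto",
                       basis: str = "entry_mean",
                       outlier_threshold: float | None = 4.0,
                       column_test_kwargs: dict | None = None,
                       **fit_kwargs) -> HeritabilityEstimate:
    """Convenience: AEMs (clone fixed) plus a clone-random refit, combined
    into the entry-mean (or plot) heritability for one trait."""
    df = plots[plots["trait"] == trait]
    if df.empty:
        raise ValueError(f"no plots for trait {trait!r}")
    df = _scope_filter(df, scope)
    df = df[np.isfinite(df["value"].astype(float))]
    multi_env = df["env"].nunique() > 1
    if include_column == "auto":
        include_column = decide_column_effect(
            df, multi_env, **(column_test_kwargs or {}), **fit_kwargs)
    aems = None
    if basis == "entry_mean":
        aems = compute_aems(plots, trait, scope, include_column,
                            outlier_threshold, **fit_kwargs)
    spec = _aem_spec(df, multi_env, include_column, clone_random=True)
    fit = fit_reml(spec, **fit_kwargs)
    return heritability(fit, aems, basis=basis, response=trait)


def _model5_spec(df: pd.DataFrame, include_column: bool, clone_random: bool
                 ) -> LmmSpec:
    """Across-flight-date model for one channel: base across-environment
    terms plus flight date F and its interactions GF, FE, GFE, BF, RF, CF."""
    y = df["value"].to_numpy(float)
    if clone_random:
        X = np.ones((len(df), 1))
        names = ["intercept"]
    else:
        X, names = dummy_matrix(df["clone"])
    terms = _random_terms(df, multi_env=True, include_column=include_column,
                          clone_random=clone_random)
    f = df["flight_date"]
    terms.append(RandomTerm.factor("date", f))
    terms.append(RandomTerm.factor("clone:date", _interact(df["clone"], f)))
    terms.append(RandomTerm.factor("date:env", _interact(f, df["env"])))
    terms.append(RandomTerm.factor("clone:date:env",
                                   _interact(df["clone"],
                                             pd.Series(_interact(f, df["env"]),
                                                       index=df.index))))
    terms.append(RandomTerm.factor("block:date",
                                   _interact(pd.Series(_interact(df["env"], df["block"]),
                                                       index=df.index), f)))
    terms.append(RandomTerm.factor("row:date",
                                   _interact(pd.Series(_interact(df["env"], df["row"]),
                                                       index=df.index), f)))
    if include_column:
        terms.append(RandomTerm.factor(
            "column:date",
            _interact(pd.Series(_interact(df["env"], df["column"]), index=df.index), f)))
    return LmmSpec(y, X, terms, fixed_names=list(names))


def channel_heritability(spectra_plots: pd.DataFrame,
                         mode: str = "per_date", basis: str = "entry_mean",
                         include_column: bool = True,
                         **fit_kwargs) -> pd.DataFrame:
    """Heritability of channel reflectances.

    ``mode='per_date'`` fits the across-environment trait model to each
    channel x flight-date column; ``mode='across_dates'`` fits the extended
    model with the flight date and all its interactions random, one fit per
    channel.  With a single spectra environment the single-environment model
    is used instead (logged).  Returns a tidy frame (response, basis,
    sigma2_g, vbar, h2).
    """
    rows = []
    multi_env = spectra_plots["env"].nunique() > 1
    if not multi_env:
        log.info("channel heritability: single environment; using the "
                 "single-environment model")
    if mode == "per_date":
        combos = sorted(set(zip(spectra_plots["channel"],
                                spectra_plots["flight_date"])))
        for ch, d in combos:
            df = spectra_plots[(spectra_plots["channel"] == ch)
                               & (spectra_plots["flight_date"] == d)]
            df = df[np.isfinite(df["value"].astype(float))]
            if df.empty:
                continue
            multi_env = df["env"].nunique() > 1  # channel may miss a year
            spec_r = _aem_spec(df, multi_env, include_column, clone_random=True)
            fit_r = fit_reml(spec_r, **fit_kwargs)
            name = f"{ch}:{d}"
            if basis == "plot":
                rows.append(heritability(fit_r, None, "plot", name))
                continue
            spec_f = _aem_spec(df, multi_env, include_column, clone_random=False)
            fit_f = fit_reml(spec_f, **fit_kwargs)
            aems = AdjustedEntryMeans(
                pd.Series(fit_f.beta, index=[str(c) for c in spec_f.fixed_names]),
                fit_f.beta_cov, name, ("across", None), fit_f)
            rows.append(heritability(fit_r, aems, basis, name))
    elif mode == "across_dates":
        if spectra_plots["flight_date"].nunique() < 2:
            raise ValueError("across-dates mode requires at least 2 flight dates")
        for ch in sorted(spectra_plots["channel"].unique()):
            df = spectra_plots[spectra_plots["channel"] == ch]
            df = df[np.isfinite(df["value"].astype(float))]
            fit_r = fit_reml(_model5_spec(df, include_column, True), **fit_kwargs)
            if basis == "plot":
                rows.append(heritability(fit_r, None, "plot", ch))
                continue
            spec_f = _model5_spec(df, include_column, False)
            fit_f = fit_reml(spec_f, **fit_kwargs)
            aems = AdjustedEntryMeans(
                pd.Series(fit_f.beta, index=[str(c) for c in spec_f.fixed_names]),
                fit_f.beta_cov, ch, ("across", None), fit_f)
            rows.append(heritability(fit_r, aems, basis, ch))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame([{
        "response": h.response, "basis": h.basis, "sigma2_g": h.sigma2_g,
        "vbar": h.vbar, "h2": h.h2,
    } for h in rows])


def apply_sqrt_transform(plots: pd.DataFrame, traits) -> pd.DataFrame:
    """Square-root transform the flagged traits in place of their values;
    all AEMs for those traits are then on the transformed scale."""
    out = plots.copy()
    mask = out["trait"].isin(set(traits))
    if (out.loc[mask, "value"] < 0).any():
        raise ValueError("cannot square-root transform negative values")
    out.loc[mask, "value"] = np.sqrt(out.loc[mask, "value"])
    return out
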