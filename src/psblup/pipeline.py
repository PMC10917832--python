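"""End-to-end orchestration: preprocess -> trial models -> kernels -> prediction.

The stages mirror the analysis workflow: trial adjustment via checks, marker
QC and genomic kernels, spectral preprocessing (scaling, PCA outliers,
median imputation, predictive-mean-matching of channel-year blocks),
clone-level channel entry means and multispectral kernels, trait entry
means per scope, and the cross-validated prediction scenarios.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import Dataset, RunConfig, write_kernel
from .kernels import (additive_kernel, combine_spectra, dominance_kernel,
                      epistatic_kernels, spectral_kernel)
from .prediction import (DataBundle, PredictionResult, enumerate_cases,
                         run_scenario, weight_grid_search)
from .preprocess import (flag_spectral_outliers, median_impute, pmm_impute,
                         qc_markers, scale_spectra)
from .trials import (adjust_for_trial, apply_sqrt_transform, compute_aems,
                     estimate_trial_effects, trait_heritability)

log = logging.getLogger(__name__)

__all__ = ["adjust_all_trials", "preprocess_spectra_wide", "channel_entry_means",
           "build_bundle", "run_pipeline"]

_FEATURE_SEP = "|"


def feature_label(flight_date, channel) -> str:
    return f"{flight_date}{_FEATURE_SEP}{channel}"


def adjust_all_trials(plots: pd.DataFrame, check_clones, **fit_kwargs
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate and subtract trial effects per trait in every split
    environment; returns (adjusted plot table, effect estimates)."""
    parts, effects = [], []
    for trait, df in plots.groupby("trait", sort=False):
        shift = {}
        for env in df["env"].unique():
            est = estimate_trial_effects(df, trait, env, check_clones,
                                         **fit_kwargs)
            for trial, e in est.items():
                shift[(env, trial)] = e
                effects.append({"trait": trait, "env": env, "trial": trial,
                                "effect": e})
        parts.append(adjust_for_trial(df, shift))
    return (pd.concat(parts, ignore_index=True),
            pd.DataFrame(effects))


def preprocess_spectra_wide(spectra: pd.DataFrame, outlier_z: float = 4.0,
                            n_pcs: int | None = None, k_donors: int = 5,
                            seed: int = 0) -> pd.DataFrame:
    """Plot x channel-date matrix after the full spectral preprocessing.

    Per environment: scale/center each observed column, flag PCA outlier
    rows (set to missing), median-impute them.  The per-environment blocks
    are then stacked and the channel-date columns that are entirely missing
    in one environment (year-specific sensors, dropped channel) are filled
    by predictive mean matching against the shared channels.
    """
    df = spectra.copy()
    df["feature"] = [feature_label(d, c)
                     for d, c in zip(df["flight_date"], df["channel"])]
    wide = df.pivot_table(
        index=["env", "clone", "trial", "block", "row", "column"],
        columns="feature", values="value")
    all_features = sorted(wide.columns)
    blocks = []
    for env in wide.index.get_level_values("env").unique():
        block = wide.loc[[env]]
        observed = [c for c in block.columns if block[c].notna().any()]
        block = block[observed]
        block = scale_spectra(block)
        res = flag_spectral_outliers(block, n_pcs=n_pcs, z_threshold=outlier_z)
        log.info("spectra %s: flagged %.1f%% outlier rows (%d PCs)",
                 env, 100 * res.flagged_fraction, res.n_pcs)
        block = median_impute(res.spectra)
        blocks.append(block.reindex(columns=all_features))
    stacked = pd.concat(blocks)
    targets = [c for c in all_features if stacked[c].isna().any()]
    if targets:
        stacked = pmm_impute(stacked, targets, k_donors=k_donors, seed=seed)
    return stacked


def _wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    long = wide.stack().rename("value").reset_index()
    long = long.rename(columns={"feature": "trait"})
    return long


def channel_entry_means(wide: pd.DataFrame, scope: tuple,
                        include_column: bool | str = True,
                        **fit_kwargs) -> pd.DataFrame:
    """Clone x channel-date matrix of reflectance entry means under the
    given scope (single-environment model per feature, or the
    across-environment model for the entry-mean combination route)."""
    long = _wide_to_long(wide)
    cols = {}
    for feature in sorted(long["trait"].unique()):
        aems = compute_aems(long, feature, scope,
                            include_column=include_column,
                            outlier_threshold=None, **fit_kwargs)
        cols[feature] = aems.values
    return pd.DataFrame(cols)


@dataclass
class BundleOptions:
    center_markers: bool = True
    outlier_z: float = 4.0
    k_donors: int = 5
    include_column: bool | str = "auto"
    pheno_outlier_z: float | None = 4.0
    with_dominance: bool = True
    with_epistasis: bool = True
    seed: int = 0

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "BundleOptions":
        return cls(center_markers=cfg.center_markers, outlier_z=cfg.outlier_z,
                   k_donors=cfg.k_donors, include_column=cfg.include_column,
                   pheno_outlier_z=cfg.pheno_outlier_z, seed=cfg.seed)


def build_bundle(data: Dataset, traits=None, sqrt_traits=(),
                 options: BundleOptions | None = None,
                 max_missing: float = 0.20, min_maf: float = 0.05,
                 **fit_kwargs) -> DataBundle:
    """Run every stage up to (but excluding) cross-validation and collect
    entry means, kernels and clone-level spectra into a DataBundle."""
    opt = options or BundleOptions()
    plots = data.phenotypes
    if plots is None:
        raise ValueError("phenotypes are required")
    if sqrt_traits:
        plots = apply_sqrt_transform(plots, sqrt_traits)
    plots, trial_effects = adjust_all_trials(plots, data.check_clones,
                                             **fit_kwargs)
    traits = tuple(traits) if traits else tuple(plots["trait"].unique())
    phenotype_envs = tuple(sorted(plots["env"].unique()))

    kernels = {}
    if data.genotypes is not None:
        Z = qc_markers(data.genotypes, max_missing=max_missing,
                       min_maf=min_maf)
        G = additive_kernel(Z, center=opt.center_markers).validate()
        kernels["G"] = G
        if opt.with_dominance:
            D = dominance_kernel(Z).validate()
            kernels["D"] = D
            if opt.with_epistasis:
                AA, AD, DD = epistatic_kernels(G, D)
                kernels.update({"AA": AA.validate(), "AD": AD.validate(),
                                "DD": DD.validate()})

    spectra_envs = ()
    spectra_clone = {}
    if data.spectra is not None:
        spectra_envs = tuple(sorted(data.spectra["env"].unique()))
        wide = preprocess_spectra_wide(data.spectra, outlier_z=opt.outlier_z,
                                       k_donors=opt.k_donors, seed=opt.seed)
        env_level = wide.index.get_level_values("env")
        for env in spectra_envs:
            S = channel_entry_means(wide[env_level == env], ("env", env),
                                    include_column=opt.include_column,
                                    **fit_kwargs)
            spectra_clone[env] = scale_spectra(S)
            kernels[f"M:{env}"] = spectral_kernel(
                spectra_clone[env], source=env).validate()
        if len(spectra_envs) >= 2:
            e1, e2 = spectra_envs[:2]
            cj = combine_spectra(spectra_clone[e1], spectra_clone[e2], "cjM")
            spectra_clone["cjM"] = cj
            kernels["M:cjM"] = spectral_kernel(cj, source="cjM").validate()
            maem = scale_spectra(channel_entry_means(
                wide, ("across", None), include_column=opt.include_column,
                **fit_kwargs))
            spectra_clone["MAEM"] = maem
            kernels["M:MAEM"] = spectral_kernel(maem, source="MAEM").validate()

    aems = {}
    for trait in traits:
        scopes = [("across", None)] + [("env", e) for e in phenotype_envs]
        scopes += [("across_excluding", e) for e in spectra_envs]
        for scope in scopes:
            try:
                a = compute_aems(plots, trait, scope,
                                 include_column=opt.include_column,
                                 outlier_threshold=opt.pheno_outlier_z,
                                 **fit_kwargs)
            except ValueError as exc:
                log.warning("no entry means for %s under %s: %s",
                            trait, scope, exc)
                continue
            aems[(scope, trait)] = a.values

    return DataBundle(aems=aems, kernels=kernels,
                      phenotype_envs=phenotype_envs,
                      spectra_envs=spectra_envs, traits=traits,
                      spectra_clone=spectra_clone,
                      trial_effects=trial_effects, adjusted_plots=plots)


def run_pipeline(config: RunConfig, data: Dataset | None = None,
                 **fit_kwargs) -> Path:
    """Execute the full pipeline and write all result tables.

    Writes, under ``config.out_dir``: the trial-effect estimates, trait
    heritabilities, all kernels, a tidy per-case prediction summary, the
    weight-search table, and a provenance sidecar (config hash, seed,
    version).  Re-running with the same config and seed reproduces every
    table byte for byte.
    """
    from .io import load_dataset

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = load_dataset(config)

    bundle = build_bundle(
        data, traits=config.traits, sqrt_traits=config.sqrt_traits,
        options=BundleOptions.from_config(config),
        max_missing=config.max_missing, min_maf=config.min_maf, **fit_kwargs)

    bundle.trial_effects.to_csv(out / "trial_effects.tsv", sep="\t",
                                index=False)
    for name, K in bundle.kernels.items():
        write_kernel(K, out / f"kernel_{name.replace(':', '_')}.tsv")

    herit_rows = []
    plots = bundle.adjusted_plots
    for trait in bundle.traits:
        h = trait_heritability(plots, trait,
                               include_column=config.include_column,
                               outlier_threshold=config.pheno_outlier_z,
                               **fit_kwargs)
        herit_rows.append({"response": trait, "basis": h.basis,
                           "sigma2_g": h.sigma2_g, "vbar": h.vbar, "h2": h.h2})
    pd.DataFrame(herit_rows).to_csv(out / "heritability.tsv", sep="\t",
                                    index=False)

    rows = []
    for scenario in config.scenarios:
        models = ([tuple(m) for m in config.genetic_models]
                  if scenario in ("S6", "S7") else [("M",)])
        for model in models:
            for case in enumerate_cases(scenario, bundle.phenotype_envs,
                                        bundle.spectra_envs, model):
                for trait in bundle.traits:
                    key = (case.phenotype_scope, trait)
                    if key not in bundle.aems:
                        continue
                    try:
                        res = run_scenario(case, bundle, trait,
                                           n_folds=config.n_folds,
                                           n_reps=config.n_reps,
                                           seed=config.seed, **fit_kwargs)
                    except (ValueError, KeyError) as exc:
                        log.warning("case %s / %s failed: %s",
                                    case.label, trait, exc)
                        continue
                    rows.append(_result_row(res))
    pd.DataFrame(rows).to_csv(out / "predictions.tsv", sep="\t", index=False)

    if "M:cjM" in bundle.kernels and "G" in bundle.kernels:
        grids = []
        for trait in bundle.traits:
            key = (("across", None), trait)
            if key not in bundle.aems:
                continue
            table, best = weight_grid_search(
                bundle.aems[key], bundle.kernels["M:cjM"],
                bundle.kernels["G"], grid=config.weight_grid,
                n_folds=config.n_folds, n_reps=config.n_reps,
                seed=config.seed, **fit_kwargs)
            table.insert(0, "trait", trait)
            table["best_x"] = best
            grids.append(table)
        if grids:
            pd.concat(grids, ignore_index=True).to_csv(
                out / "weight_search.tsv", sep="\t", index=False)

    digest = hashlib.sha256(
        json.dumps(config.__dict__, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out / "provenance.json").write_text(json.dumps({
        "version": __version__, "seed": config.seed, "config_sha256": digest,
    }, indent=1))
    return out


def _result_row(res: PredictionResult) -> dict:
    case = res.scenario
    kind, env = case.phenotype_scope
    return {
        "scenario": case.scenario,
        "phenotype_scope": env if kind == "env" else (
            "AEM" if kind == "across" else f"AEM-{env}"),
        "kernel_source": case.kernel_source,
        "genetic_model": "+".join(case.genetic_model),
        "trait": res.trait,
        "median_pa": res.median_pa,
        "mean_pa": res.mean_pa,
        "cv_percent": res.cv_percent,
        "n_missing": res.n_missing,
        "passed_quality_filter": res.passed_quality_filter,
    }
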