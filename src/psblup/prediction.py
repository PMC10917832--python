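"""Kernel BLUP prediction, cross-validation, and the prediction scenarios.

The prediction model regresses clone-level adjusted entry means on one or
more random genetic effects with clone x clone relationship kernels
(genomic G / D / epistatic products, multispectral M, or a weighted
combination C).  Predictive ability (PA) is the Pearson correlation between
observed and predicted entry means of the validation folds of a five-fold
cross-validation with 25 replicates (125 PA values per trait and scenario),
followed by a quality filter on the coefficient of variation of the PAs and
the number of missing predictions.

Seven scenarios pair phenotype scopes (single environment, across all
environments, across all but one) with kernel sources (single-environment
spectra, column-joined or entry-mean combined spectra, SNP kernels), plus a
grid search over the spectral weight of C = x*M + (1-x)*G and flight-date
subset analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .kernels import RelationshipMatrix, spectral_kernel, weighted_kernel
from .lmm import LmmFit, LmmSpec, RandomTerm, fit_reml

__all__ = [
    "ScenarioSpec",
    "PredictionResult",
    "DataBundle",
    "fit_blup",
    "predict_masked",
    "pearson_pa",
    "make_folds",
    "cross_validate",
    "quality_filter",
    "enumerate_cases",
    "run_scenario",
    "weight_grid_search",
    "flight_date_subsets",
    "SCENARIOS",
]

SCENARIOS = ("S1", "S2", "S3", "S3b", "S4", "S5", "S6", "S7")


@dataclass(frozen=True)
class ScenarioSpec:
    """One prediction case: a phenotype scope paired with a kernel source.

    ``phenotype_scope`` is ("env", id), ("across", None) or
    ("across_excluding", id); ``kernel_source`` is a spectral environment
    id, "cjM", "MAEM", or "SNP"; ``genetic_model`` lists the kernels of the
    genetic effect (("G",), ("G", "D"), ("G", "D", "AA", "AD", "DD"), or
    ("M",) / ("C",) style spectral entries resolved by the bundle).
    """

    scenario: str
    phenotype_scope: tuple
    kernel_source: str
    genetic_model: tuple = ("M",)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        kind, env = self.phenotype_scope
        if self.scenario == "S2" and env == self.kernel_source:
            raise ValueError(
                "S2 requires the phenotype environment to differ from the "
                "spectral environment"
            )
        if self.scenario == "S3b":
            if kind != "across_excluding" or env != self.kernel_source:
                raise ValueError(
                    "S3b must exclude exactly the spectral source environment"
                )
        if self.scenario in ("S6", "S7") and self.kernel_source != "SNP":
            raise ValueError(f"{self.scenario} uses genomic kernels only")

    @property
    def label(self) -> str:
        kind, env = self.phenotype_scope
        pheno = env if kind == "env" else ("AEM" if kind == "across"
                                           else f"AEM-{env}")
        return f"{self.scenario} {pheno}x{self.kernel_source}"


@dataclass
class PredictionResult:
    """Per-fold predictive abilities of one prediction case."""

    pa: np.ndarray  # n_folds * n_reps values, NaN for missing predictions
    n_folds: int
    n_reps: int
    seed: int
    trait: str = ""
    scenario: ScenarioSpec | None = None
    passed_quality_filter: bool | None = None
    filter_reason: str = ""

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.pa).sum())

    @property
    def median_pa(self) -> float:
        ok = self.pa[np.isfinite(self.pa)]
        return float(np.median(ok)) if ok.size else float("nan")

    @property
    def mean_pa(self) -> float:
        ok = self.pa[np.isfinite(self.pa)]
        return float(np.mean(ok)) if ok.size else float("nan")

    @property
    def cv_percent(self) -> float:
        """100 * SD / mean over the non-missing PAs (undefined mean 0 -> inf)."""
        ok = self.pa[np.isfinite(self.pa)]
        if ok.size < 2:
            return float("nan")
        mean = ok.mean()
        if mean == 0:
            return float("inf")
        return float(100.0 * ok.std(ddof=1) / mean)


def fit_blup(y: pd.Series, kernels, all_clones=None, method: str = "auto",
             **fit_kwargs) -> LmmFit:
    """REML fit of the kernel BLUP model on training entry means.

    ``y`` holds the training clones' AEMs; ``kernels`` is one
    RelationshipMatrix or a list (one random genetic term each).  With
    ``all_clones`` the random effects span that full clone set (masked
    mixed-model-equation route), otherwise the training set only.
    """
    if isinstance(kernels, RelationshipMatrix):
        kernels = [kernels]
    y = y.dropna()
    train = list(y.index)
    for k in kernels:
        known = set(k.clones)
        missing = [c for c in train if c not in known]
        if missing:
            raise ValueError(f"training clones missing from kernel "
                             f"{k.kind}: {missing[:5]}...")
    span = list(all_clones) if all_clones is not None else train
    terms = []
    for k in kernels:
        terms.append(RandomTerm.kernel(k.kind, train, span,
                                       k.subset(span).values,
                                       A=k.subset(train).values))
    X = np.ones((len(train), 1))
    spec = LmmSpec(y.to_numpy(float), X, terms, fixed_names=["intercept"])
    if method == "auto":
        method = "eigen" if len(terms) == 1 else "dense"
    return fit_reml(spec, method=method, **fit_kwargs)


def predict_masked(fit: LmmFit, kernels, validation, y_train: pd.Series,
                   route: str = "closed") -> pd.Series:
    """Predict held-out clones' entry means at the fitted components.

    ``route='closed'`` uses the conditional-expectation formula
    mu + sum_t s2_t K_vt (sum_t s2_t K_tt + s2_e I)^-1 (y_t - mu);
    ``route='mme'`` reads the BLUPs of a fit made with ``all_clones``
    covering the validation clones (Henderson equations with the validation
    responses masked).  Clones absent from a kernel get a missing value.
    """
    if isinstance(kernels, RelationshipMatrix):
        kernels = [kernels]
    validation = list(validation)
    mu = float(fit.beta[0])

    if route == "mme":
        out = pd.Series(mu, index=validation, dtype=float)
        for k in kernels:
            levels = fit.blup_levels[k.kind]
            u = pd.Series(fit.blups[k.kind], index=levels)
            for c in validation:
                if c in u.index:
                    out[c] += float(u[c])
                else:
                    out[c] = np.nan
        return out

    y = y_train.dropna()
    train = list(y.index)
    n_t = len(train)
    s2e = fit.variance_components["residual"]
    V = s2e * np.eye(n_t)
    for k in kernels:
        s2 = fit.variance_components[k.kind]
        V += s2 * k.subset(train).values
    alpha = sla.solve(V, y.to_numpy(float) - mu, assume_a="pos")
    out = pd.Series(mu, index=validation, dtype=float)
    for k in kernels:
        s2 = fit.variance_components[k.kind]
        kmap = {c: i for i, c in enumerate(k.clones)}
        ti = np.array([kmap[c] for c in train])
        for c in validation:
            if c not in kmap:
                out[c] = np.nan
                continue
            out[c] += s2 * float(k.values[kmap[c], ti] @ alpha)
    return out


def pearson_pa(observed: pd.Series, predicted: pd.Series) -> float:
    """Pearson correlation between observed and predicted entry means of a
    validation set; missing (NaN) with fewer than 3 complete pairs or a
    zero-variance side."""
    df = pd.concat([observed.rename("o"), predicted.rename("p")], axis=1).dropna()
    if len(df) < 3:
        return float("nan")
    o, p = df["o"].to_numpy(float), df["p"].to_numpy(float)
    if o.std() == 0 or p.std() == 0:
        return float("nan")
    return float(np.corrcoef(o, p)[0, 1])


def make_folds(clones, n_folds: int, rep: int, seed: int) -> list[np.ndarray]:
    """Random partition into n_folds of sizes differing by at most one;
    deterministic in (seed, rep, clone order)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
    perm = rng.permutation(np.asarray(list(clones)))
    return np.array_split(perm, n_folds)


def cross_validate(y: pd.Series, kernels, n_folds: int = 5, n_reps: int = 25,
                   seed: int = 0, trait: str = "",
                   scenario: ScenarioSpec | None = None,
                   **fit_kwargs) -> PredictionResult:
    """Five-fold (by default) cross-validated kernel BLUP prediction.

    Per replicate, the clones with non-missing entry means are partitioned
    at random into ``n_folds`` validation folds; each fold is predicted
    from the remainder and scored with the Pearson PA.  Non-converged fits
    and degenerate folds yield missing PA values.  The quality filter is
    applied to the finished result.
    """
    y = y.dropna()
    if len(y) < n_folds:
        raise ValueError("fewer clones with entry means than folds")
    if isinstance(kernels, RelationshipMatrix):
        kernels = [kernels]
    pas = np.full(n_folds * n_reps, np.nan)
    for rep in range(n_reps):
        folds = make_folds(y.index, n_folds, rep, seed)
        for f, fold in enumerate(folds):
            fold = list(fold)
            y_train = y.drop(index=fold)
            try:
                fit = fit_blup(y_train, kernels, compute_blups=False,
                               **fit_kwargs)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not fit.converged:
                continue
            pred = predict_masked(fit, kernels, fold, y_train)
            pas[rep * n_folds + f] = pearson_pa(y.loc[fold], pred)
    result = PredictionResult(pa=pas, n_folds=n_folds, n_reps=n_reps,
                              seed=seed, trait=trait, scenario=scenario)
    return quality_filter(result)


def quality_filter(result: PredictionResult, cv_max: float = 150.0,
                   missing_max: int = 100) -> PredictionResult:
    """Flag results whose PA coefficient of variation exceeds ``cv_max`` in
    absolute value or with more than ``missing_max`` missing predictions.
    Filtered results are flagged, not discarded."""
    reasons = []
    cv = result.cv_percent
    if np.isnan(cv):
        reasons.append("cv undefined (too few PAs)")
    elif np.isinf(cv):
        reasons.append("cv undefined (mean PA is 0); treated as failing")
    elif abs(cv) > cv_max:
        reasons.append(f"|CV| = {abs(cv):.1f} > {cv_max:g}")
    if result.n_missing > missing_max:
        reasons.append(f"{result.n_missing} missing predictions > {missing_max}")
    result.passed_quality_filter = not reasons
    result.filter_reason = "; ".join(reasons)
    return result


@dataclass
class DataBundle:
    """Everything a scenario run needs.

    ``aems``   maps (scope, trait) -> Series of clone entry means, with
               scope one of ("env", e), ("across", None),
               ("across_excluding", e);
    ``kernels`` maps names to RelationshipMatrix: "M:<env>", "M:cjM",
               "M:MAEM", "G", "D", "AA", "AD", "DD", optionally "C".
    ``phenotype_envs`` / ``spectra_envs`` list the environment ids.
    """

    aems: dict
    kernels: dict
    phenotype_envs: tuple
    spectra_envs: tuple
    traits: tuple = ()
    spectra_clone: dict = field(default_factory=dict)
    trial_effects: object = None
    adjusted_plots: object = None

    def kernel_for(self, spec: ScenarioSpec) -> list[RelationshipMatrix]:
        if spec.kernel_source == "SNP":
            return [self.kernels[name] for name in spec.genetic_model]
        return [self.kernels[f"M:{spec.kernel_source}"]]


def enumerate_cases(scenario: str, phenotype_envs, spectra_envs,
                    genetic_model: tuple = ("G",)) -> list[ScenarioSpec]:
    """All valid prediction cases of one scenario for the given environments."""
    phenotype_envs = list(phenotype_envs)
    spectra_envs = list(spectra_envs)
    cases = []
    if scenario == "S1":
        for e in spectra_envs:
            if e in phenotype_envs:
                cases.append(ScenarioSpec("S1", ("env", e), e))
    elif scenario == "S2":
        for p, s in itertools.product(phenotype_envs, spectra_envs):
            if p != s:
                cases.append(ScenarioSpec("S2", ("env", p), s))
    elif scenario == "S3":
        for s in spectra_envs:
            cases.append(ScenarioSpec("S3", ("across", None), s))
    elif scenario == "S3b":
        for s in spectra_envs:
            cases.append(ScenarioSpec("S3b", ("across_excluding", s), s))
    elif scenario == "S4":
        for p, m in itertools.product(phenotype_envs, ("cjM", "MAEM")):
            cases.append(ScenarioSpec("S4", ("env", p), m))
    elif scenario == "S5":
        for m in ("cjM", "MAEM"):
            cases.append(ScenarioSpec("S5", ("across", None), m))
    elif scenario == "S6":
        for p in phenotype_envs:
            cases.append(ScenarioSpec("S6", ("env", p), "SNP", genetic_model))
    elif scenario == "S7":
        cases.append(ScenarioSpec("S7", ("across", None), "SNP", genetic_model))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return cases


def run_scenario(spec: ScenarioSpec, bundle: DataBundle, trait: str,
                 n_folds: int = 5, n_reps: int = 25, seed: int = 0,
                 **fit_kwargs) -> PredictionResult:
    """Run one prediction case: pick the phenotype scope and kernel the
    case prescribes and cross-validate."""
    key = (spec.phenotype_scope, trait)
    if key not in bundle.aems:
        raise ValueError(f"no entry means for scope {spec.phenotype_scope} "
                         f"and trait {trait!r}")
    kernels = bundle.kernel_for(spec)
    return cross_validate(bundle.aems[key], kernels, n_folds=n_folds,
                          n_reps=n_reps, seed=seed, trait=trait,
                          scenario=spec, **fit_kwargs)


def weight_grid_search(y: pd.Series, M: RelationshipMatrix,
                       G: RelationshipMatrix, grid=None, n_folds: int = 5,
                       n_reps: int = 25, seed: int = 0,
                       **fit_kwargs) -> tuple[pd.DataFrame, float]:
    """Cross-validated PA for C = x*M + (1-x)*G over a grid of weights.

    All weights share the same seed, hence identical fold assignments, so
    x = 0 reproduces the pure-G run and x = 1 the pure-M run exactly.
    Returns (per-weight summary frame, best weight by median PA).
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    grid = list(grid)
    if any(x < 0 or x > 1 for x in grid):
        raise ValueError("grid weights must lie in [0, 1]")
    rows = []
    for x in grid:
        C = weighted_kernel(M, G, float(x))
        res = cross_validate(y, C, n_folds=n_folds, n_reps=n_reps, seed=seed,
                             **fit_kwargs)
        ok = res.pa[np.isfinite(res.pa)]
        rows.append({"x": float(x), "median_pa": res.median_pa,
                     "sd_pa": float(ok.std(ddof=1)) if ok.size > 1 else np.nan,
                     "n_missing": res.n_missing})
    table = pd.DataFrame(rows)
    best_x = float(table.loc[table["median_pa"].idxmax(), "x"])
    return table, best_x


def flight_date_subsets(S: pd.DataFrame, y: pd.Series, subsets=None,
                        date_of=None, n_folds: int = 5, n_reps: int = 25,
                        seed: int = 0, **fit_kwargs) -> pd.DataFrame:
    """PA per flight-date subset: rebuild M from the selected dates' columns
    only and cross-validate with shared folds.

    ``S`` is the clone-level (scaled) spectral matrix whose column labels
    encode the flight date; by default the date is the part of the label
    before the first ``|``.  ``subsets=None`` enumerates all non-empty
    subsets of the observed dates.
    """
    if date_of is None:
        date_of = lambda c: str(c).split("|")[0]
    dates = sorted({date_of(c) for c in S.columns})
    if subsets is None:
        subsets = [combo for r in range(1, len(dates) + 1)
                   for combo in itertools.combinations(dates, r)]
    rows = []
    for sub in subsets:
        sub = tuple(sorted(sub))
        if not sub:
            raise ValueError("empty flight-date subset")
        cols = [c for c in S.columns if date_of(c) in sub]
        if not cols:
            raise ValueError(f"no spectral columns for dates {sub}")
        M = spectral_kernel(S[cols], source="+".join(sub))
        res = cross_validate(y, M, n_folds=n_folds, n_reps=n_reps, seed=seed,
                             **fit_kwargs)
        rows.append({"subset": "+".join(sub), "n_columns": len(cols),
                     "median_pa": res.median_pa, "n_missing": res.n_missing})
    return pd.DataFrame(rows)
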