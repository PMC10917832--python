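"""Synthetic tetraploid breeding populations, field trials, and spectra.

Emulates the study design the analysis pipeline assumes: several hundred
full-sib tetraploid clones plus a handful of replicated check cultivars,
grown in augmented row-column designs across five environments (two of which
also carry UAV multispectral plot reflectances on three flight dates), with
traits of configurable entry-mean heritability and additive + dominance
architecture.

Gametes follow bivalent pairing without double reduction: a parent of allele
dosage d transmits a gamete dosage drawn hypergeometrically (2 of its 4
alleles without replacement), so offspring dosage is the sum of two such
draws and the expected offspring dosage equals the mid-parent mean.

All randomness flows from ``SimConfig.seed`` through named child streams, so
the population, the trial layout, the trait values, and the spectra are
individually and jointly reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "SimConfig",
    "TrialData",
    "simulate_population",
    "simulate_trial",
    "simulate_spectra",
    "gamete_distribution",
]

PLOT_COLUMNS = ["clone", "env", "trial", "block", "row", "column", "trait", "value"]
SPECTRA_COLUMNS = ["clone", "env", "trial", "block", "row", "column",
                   "flight_date", "channel", "value"]


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait.

    h2 is the target entry-mean heritability across environments;
    dominance_fraction is the share of genetic variance from digenic
    dominance; ge_fraction is sigma2_GxE relative to sigma2_g;
    spectral_overlap is the correlation between the trait's genetic values
    and the latent genetic score driving the spectra.
    """

    name: str
    h2: float
    dominance_fraction: float = 0.0
    ge_fraction: float = 0.3
    spectral_overlap: float = 0.5
    sqrt_transform: bool = False

    def __post_init__(self):
        for fname in ("h2", "dominance_fraction", "ge_fraction",
                      "spectral_overlap"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fname} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SimConfig:
    """Dimensions and variance structure of the simulated study.

    Defaults mirror the emulated breeding experiment: 458 test clones in 107
    full-sib families plus 8 checks replicated once per block (8 blocks) in
    each of 5 environments; the two most recent environments are split into
    an early (3-block) and a late (5-block) maturity trial and carry
    multispectral data (3 flight dates; 5 shared channels of which one is
    missing in the second spectra year, plus one year-specific channel per
    year).
    """

    n_clones: int = 458
    n_families: int = 107
    n_checks: int = 8
    n_markers: int = 1000
    n_founders: int = 60
    causal_fraction: float = 1.0
    envs: tuple = ("W19", "W20", "G20", "W21", "G21")
    split_envs: tuple = ("W21", "G21")
    envs_with_spectra: tuple = ("W20", "W21")
    n_flight_dates: int = 3
    shared_channels: tuple = ("b490", "g550", "r680", "re730", "r670")
    dropped_channel: str = "r670"  # missing in the second spectra year
    year_channels: tuple = ("nir840", "nir860")  # one per spectra env
    traits: tuple = (
        TraitSpec("emergence", 0.85, 0.1, 0.2, 0.8),
        TraitSpec("yield", 0.75, 0.3, 0.3, 0.6),
        TraitSpec("starch_content", 0.93, 0.1, 0.2, 0.2),
        TraitSpec("shape_short_axis", 0.30, 0.2, 0.4, 0.1),
    )
    n_blocks: int = 8
    split_blocks: tuple = (3, 5)  # early / late trial in split environments
    cols_per_block: int = 6
    rows_per_block: int | None = None  # derived from capacity when None
    check_reps: int = 8
    env_sd: float = 0.7
    trial_effect_sd: float = 1.0
    trial_effects: dict | None = None  # (env, trial) -> effect override
    spatial_fraction: float = 0.1  # of sigma2_eps, for each of block/row/col
    channel_h2_plot: float = 0.25
    date_coherence: float = 0.15  # share of spectral genetic variance common to dates
    spectra_ge_share: float = 0.30  # split of non-genetic spectral variance
    spectra_spatial_share: float = 0.15
    mu: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.cols_per_block > 6:
            raise ValueError("augmented row-column blocks have at most 6 columns")
        if self.check_reps != self.n_blocks:
            raise ValueError("one check replicate per block: check_reps must "
                             "equal n_blocks")
        if sum(self.split_blocks) != self.n_blocks:
            raise ValueError("split_blocks must sum to n_blocks")
        for e in self.envs_with_spectra:
            if e not in self.envs:
                raise ValueError(f"spectra environment {e!r} not in envs")
        if len(self.year_channels) != len(self.envs_with_spectra):
            raise ValueError("one year-specific channel per spectra environment")
        if self.dropped_channel not in self.shared_channels:
            raise ValueError("dropped_channel must be one of shared_channels")
        if self.n_flight_dates < 1:
            raise ValueError("need at least one flight date")

    @property
    def all_channels(self) -> tuple:
        return tuple(self.shared_channels) + tuple(self.year_channels)

    def channels_for_env(self, env: str) -> tuple:
        """Channels actually recorded in a spectra environment."""
        idx = list(self.envs_with_spectra).index(env)
        chans = list(self.shared_channels)
        if idx == 1 and self.dropped_channel in chans:
            chans.remove(self.dropped_channel)
        chans.append(self.year_channels[idx])
        return tuple(chans)

    def rng(self, stream: str) -> np.random.Generator:
        h = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, h]))


@dataclass
class TrialData:
    """Simulated trial: plot table plus ground truth for test oracles."""

    plots: pd.DataFrame
    genetic_values: pd.DataFrame  # clone x trait total genetic value
    variance_components: dict  # trait -> component dict
    trial_effects: dict  # (env, trial) -> simulated effect


def gamete_distribution(d: int) -> np.ndarray:
    """P(gamete dosage = 0, 1, 2) for a parent of dosage d (bivalent pairing)."""
    if not 0 <= d <= 4:
        raise ValueError(f"dosage must be in 0..4, got {d}")
    return np.array([
        math.comb(d, g) * math.comb(4 - d, 2 - g) / math.comb(4, 2)
        for g in range(3)
    ])


def _family_sizes(cfg: SimConfig, rng) -> np.ndarray:
    """Family sizes with mean ~n_clones/n_families, adjusted to the exact total."""
    if cfg.n_families > cfg.n_clones:
        raise ValueError("more families than clones")
    mean = cfg.n_clones / cfg.n_families
    sizes = 1 + rng.poisson(max(mean - 1.0, 0.0), cfg.n_families)
    while sizes.sum() != cfg.n_clones:
        i = rng.integers(cfg.n_families)
        if sizes.sum() > cfg.n_clones:
            if sizes[i] > 1:
                sizes[i] -= 1
        else:
            sizes[i] += 1
    return sizes


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw founders, cross them into full-sib families, and return
    (dosage matrix, pedigree).

    Founder dosages per marker are Binomial(4, p_m) with marker allele
    frequencies p_m ~ Uniform(0.1, 0.9).  Each family is a biparental cross;
    offspring dosage is the sum of two hypergeometric gametes.  Checks are
    additional founder-type draws.
    """
    rng = config.rng("population")
    m = config.n_markers
    freqs = rng.uniform(0.1, 0.9, m)
    founders = rng.binomial(4, freqs, size=(config.n_founders, m))

    sizes = _family_sizes(config, rng)
    rows, ped = [], []
    clone_ids = []
    for f, size in enumerate(sizes):
        p1, p2 = rng.choice(config.n_founders, 2, replace=False)
        d1, d2 = founders[p1], founders[p2]
        g1 = rng.hypergeometric(d1, 4 - d1, 2, size=(size, m))
        g2 = rng.hypergeometric(d2, 4 - d2, 2, size=(size, m))
        off = g1 + g2
        for j in range(size):
            cid = f"C{len(clone_ids):04d}"
            clone_ids.append(cid)
            ped.append((cid, f"F{f:03d}", f"P{p1:03d}", f"P{p2:03d}", False))
        rows.append(off)
    for c in range(config.n_checks):
        cid = f"CHK{c:02d}"
        clone_ids.append(cid)
        ped.append((cid, f"CHKFAM{c:02d}", "", "", True))
        rows.append(rng.binomial(4, freqs, size=(1, m)))

    dosages = np.vstack(rows)
    if dosages.min() < 0 or dosages.max() > 4:
        raise ValueError("dosage outside 0..4 generated")  # pragma: no cover
    marker_ids = [f"M{j:05d}" for j in range(m)]
    Z = pd.DataFrame(dosages, index=clone_ids, columns=marker_ids, dtype=np.int8)
    pedigree = pd.DataFrame(
        ped, columns=["clone", "family", "parent1", "parent2", "is_check"]
    )
    return Z, pedigree


def _genetic_values(Z: pd.DataFrame, pedigree: pd.DataFrame, config: SimConfig
                    ) -> dict[str, pd.Series]:
    """Per-trait total genetic values (additive + dominance), variance 1.

    Dominance deviations are generated from the digenic heterozygosity
    covariate d(4-d)/6, so a G+D kernel model is the true model whenever the
    dominance fraction is positive.
    """
    D = Z.to_numpy(float)
    Zc = D - D.mean(axis=0)
    W = D * (4.0 - D) / 6.0
    Wc = W - W.mean(axis=0)
    out = {}
    for i, trait in enumerate(config.traits):
        rng = config.rng(f"genetics:{trait.name}")
        m = Z.shape[1]
        n_causal = max(1, int(round(config.causal_fraction * m)))
        causal = rng.choice(m, n_causal, replace=False)
        a = np.zeros(m)
        a[causal] = rng.normal(0.0, 1.0, n_causal)
        add = Zc @ a
        sd = add.std()
        add = add / sd if sd > 0 else add
        val = np.sqrt(1.0 - trait.dominance_fraction) * add
        if trait.dominance_fraction > 0:
            b = np.zeros(m)
            b[causal] = rng.normal(0.0, 1.0, n_causal)
            dom = Wc @ b
            sdd = dom.std()
            dom = dom / sdd if sdd > 0 else dom
            val = val + np.sqrt(trait.dominance_fraction) * dom
        out[trait.name] = pd.Series(val, index=Z.index, name=trait.name)
    return out


@dataclass
class _Plot:
    clone: str
    env: str
    trial: str
    block: int
    row: int
    column: int


def _field_design(pedigree: pd.DataFrame, config: SimConfig) -> list[_Plot]:
    """Deterministic augmented row-column layout for every environment.

    Each environment has ``n_blocks`` blocks of up to ``cols_per_block``
    columns; every check appears once per block; test clones get one plot
    per environment.  In split ("2021-style") environments families go
    alternately to the early and the late trial, and checks are present in
    every block of both trials.
    """
    rng = config.rng("design")
    checks = pedigree.loc[pedigree.is_check, "clone"].tolist()
    entries = pedigree.loc[~pedigree.is_check, ["clone", "family"]]
    families = entries.family.unique()
    plots: list[_Plot] = []
    for env in config.envs:
        split = env in config.split_envs
        if split:
            early = set(families[::2])
            trial_of = {
                c: ("early" if f in early else "late")
                for c, f in zip(entries.clone, entries.family)
            }
            trial_blocks = {
                "early": list(range(1, config.split_blocks[0] + 1)),
                "late": list(range(config.split_blocks[0] + 1,
                                   config.n_blocks + 1)),
            }
        else:
            trial_of = {c: "main" for c in entries.clone}
            trial_blocks = {"main": list(range(1, config.n_blocks + 1))}

        block_members: dict[int, list[str]] = {
            b: list(checks) for b in range(1, config.n_blocks + 1)
        }
        for trial, blocks in trial_blocks.items():
            members = [c for c in entries.clone if trial_of[c] == trial]
            members = list(rng.permutation(members))
            for i, clone in enumerate(members):
                block_members[blocks[i % len(blocks)]].append(clone)

        max_block = max(len(v) for v in block_members.values())
        need_rows = math.ceil(max_block / config.cols_per_block)
        rows_per_block = config.rows_per_block or need_rows
        if rows_per_block * config.cols_per_block < max_block:
            raise ValueError(
                f"design capacity violated in {env}: block needs {max_block} "
                f"plots but rows_per_block*cols_per_block = "
                f"{rows_per_block * config.cols_per_block}"
            )
        block_trial = {
            b: t for t, bs in trial_blocks.items() for b in bs
        }
        for b, members in block_members.items():
            members = list(rng.permutation(members))
            for i, clone in enumerate(members):
                local_row, col = divmod(i, config.cols_per_block)
                plots.append(_Plot(
                    clone=clone, env=env, trial=block_trial[b], block=b,
                    row=(b - 1) * rows_per_block + local_row + 1,
                    column=col + 1,
                ))
    return plots


def _trait_variances(trait: TraitSpec, n_envs: int) -> dict:
    """Solve plot-level variances so the realized entry-mean heritability
    matches the target: H2 = s2g / (s2g + (s2ge + s2e)/E) with s2g = 1."""
    s2g = 1.0
    s2ge = trait.ge_fraction
    if trait.h2 <= 0:
        raise ValueError("target heritability must be positive")
    total_noise = n_envs * s2g * (1.0 - trait.h2) / trait.h2
    s2eps = total_noise - s2ge
    if s2eps < 0:
        raise ValueError(
            f"trait {trait.name!r}: GxE fraction {trait.ge_fraction} exceeds "
            f"the noise budget implied by h2={trait.h2}"
        )
    return {"genotype": s2g, "gxe": s2ge, "residual": s2eps}


def simulate_trial(pop: tuple[pd.DataFrame, pd.DataFrame], config: SimConfig
                   ) -> TrialData:
    """Simulate the multi-environment augmented row-column trial.

    Trait value = mu + genetic value + trial effect + environment + GxE +
    block + row + column + residual, with variances solved so the realized
    entry-mean heritability matches each TraitSpec target (sigma2_g = 1).
    Spatial block/row/column effects are i.i.d. with variance
    ``spatial_fraction * sigma2_eps`` each.
    """
    Z, pedigree = pop
    plots = _field_design(pedigree, config)
    gvals = _genetic_values(Z, pedigree, config)
    E = len(config.envs)
    env_index = {e: i for i, e in enumerate(config.envs)}
    clone_ids = list(Z.index)
    clone_index = {c: i for i, c in enumerate(clone_ids)}

    trial_rng = config.rng("trial:trial-effects")
    trial_effects: dict = {}
    for env in config.envs:
        trials = (("early", "late") if env in config.split_envs else ("main",))
        for t in trials:
            if config.trial_effects and (env, t) in config.trial_effects:
                trial_effects[(env, t)] = float(config.trial_effects[(env, t)])
            elif len(trials) == 1:
                trial_effects[(env, t)] = 0.0
            else:
                trial_effects[(env, t)] = float(
                    trial_rng.normal(0.0, config.trial_effect_sd))

    records = []
    varcomps = {}
    for trait in config.traits:
        vc = _trait_variances(trait, E)
        varcomps[trait.name] = dict(vc)
        rng = config.rng(f"trial:{trait.name}")
        env_eff = rng.normal(0.0, config.env_sd, E)
        ge = rng.normal(0.0, np.sqrt(vc["gxe"]), (len(clone_ids), E))
        s_sp = np.sqrt(config.spatial_fraction * vc["residual"])
        blocks = sorted({(p.env, p.block) for p in plots})
        rows = sorted({(p.env, p.row) for p in plots})
        cols = sorted({(p.env, p.column) for p in plots})
        b_eff = dict(zip(blocks, rng.normal(0.0, s_sp, len(blocks))))
        r_eff = dict(zip(rows, rng.normal(0.0, s_sp, len(rows))))
        c_eff = dict(zip(cols, rng.normal(0.0, s_sp, len(cols))))
        eps = rng.normal(0.0, np.sqrt(vc["residual"]), len(plots))
        g = gvals[trait.name]
        for i, p in enumerate(plots):
            value = (config.mu + g[p.clone]
                     + trial_effects[(p.env, p.trial)]
                     + env_eff[env_index[p.env]]
                     + ge[clone_index[p.clone], env_index[p.env]]
                     + b_eff[(p.env, p.block)]
                     + r_eff[(p.env, p.row)]
                     + c_eff[(p.env, p.column)]
                     + eps[i])
            records.append((p.clone, p.env, p.trial, p.block, p.row, p.column,
                            trait.name, value))

    table = pd.DataFrame(records, columns=PLOT_COLUMNS)
    genetic = pd.DataFrame({t.name: gvals[t.name] for t in config.traits})
    return TrialData(plots=table, genetic_values=genetic,
                     variance_components=varcomps, trial_effects=trial_effects)


def simulate_spectra(pop: tuple[pd.DataFrame, pd.DataFrame], config: SimConfig
                     ) -> pd.DataFrame:
    """Simulate plot-level multispectral reflectances for the spectra
    environments (long format, one row per plot x flight date x channel).

    Each channel/date reflectance loads on a clone-specific latent genetic
    score that is partially shared across flight dates (``date_coherence``)
    and correlated with the traits' genetic values through their
    spectral_overlap fractions.  Per-channel plot-level heritability is
    ``channel_h2_plot``; the remaining variance is split between clone x
    environment, spatial (block/row/column), and residual noise.  Channels
    missing in a year (year-specific sensors, one dropped channel) are simply
    absent, which downstream imputation has to repair.
    """
    if not config.envs_with_spectra:
        raise ValueError("no environments with spectra configured")
    Z, pedigree = pop
    plots = [p for p in _field_design(pedigree, config)
             if p.env in config.envs_with_spectra]
    gvals = _genetic_values(Z, pedigree, config)
    clone_ids = list(Z.index)
    n = len(clone_ids)
    rng = config.rng("spectra")

    # latent genetic score shared across channels, correlated with traits
    weights = np.array([t.spectral_overlap for t in config.traits], float)
    if weights.sum() > 0:
        parts = np.column_stack([
            (gvals[t.name] - gvals[t.name].mean()) / max(gvals[t.name].std(), 1e-12)
            for t in config.traits
        ])
        target = parts @ weights
        tsd = target.std()
        rho = min(np.linalg.norm(weights), 1.0)
        base = target / tsd if tsd > 0 else np.zeros(n)
        lat = rho * base + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(0, 1, n)
    else:
        lat = rng.normal(0.0, 1.0, n)
    lat = (lat - lat.mean()) / max(lat.std(), 1e-12)

    kappa = config.date_coherence
    lat_dates = []
    for d in range(config.n_flight_dates):
        z = rng.normal(0.0, 1.0, n)
        z = (z - z.mean()) / max(z.std(), 1e-12)
        lat_dates.append(np.sqrt(kappa) * lat + np.sqrt(1.0 - kappa) * z)

    h = config.channel_h2_plot
    nongen = 1.0 - h
    s2_ge = config.spectra_ge_share * nongen
    s2_sp = config.spectra_spatial_share * nongen / 3.0
    s2_eps = max(nongen - s2_ge - 3 * s2_sp, 0.0)

    env_list = list(config.envs_with_spectra)
    clone_index = {c: i for i, c in enumerate(clone_ids)}
    records = []
    for env in env_list:
        channels = config.channels_for_env(env)
        env_plots = [p for p in plots if p.env == env]
        blocks = sorted({p.block for p in env_plots})
        rows = sorted({p.row for p in env_plots})
        cols = sorted({p.column for p in env_plots})
        for d in range(1, config.n_flight_dates + 1):
            for ch in channels:
                loading = np.sqrt(h)
                intercept = rng.uniform(-0.5, 0.5)
                ge = rng.normal(0.0, np.sqrt(s2_ge), n)
                b_eff = dict(zip(blocks, rng.normal(0, np.sqrt(s2_sp), len(blocks))))
                r_eff = dict(zip(rows, rng.normal(0, np.sqrt(s2_sp), len(rows))))
                c_eff = dict(zip(cols, rng.normal(0, np.sqrt(s2_sp), len(cols))))
                eps = rng.normal(0.0, np.sqrt(s2_eps), len(env_plots))
                for i, p in enumerate(env_plots):
                    ci = clone_index[p.clone]
                    value = (intercept + loading * lat_dates[d - 1][ci]
                             + ge[ci] + b_eff[p.block] + r_eff[p.row]
                             + c_eff[p.column] + eps[i])
                    records.append((p.clone, p.env, p.trial, p.block, p.row,
                                    p.column, f"D{d}", ch, value))
    return pd.DataFrame(records, columns=SPECTRA_COLUMNS)
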