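"""Shared fixtures: a small synthetic breeding study reused across tests.

The session-scoped bundle keeps the expensive plot-level REML fits to a
single build; tests that need different study conditions construct their
own configs at reduced size.
"""

import numpy as np
import pandas as pd
import pytest

from psblup.io import Dataset
from psblup.pipeline import BundleOptions, build_bundle
from psblup.simulate import (SimConfig, TraitSpec, simulate_population,
                             simulate_spectra, simulate_trial)


def small_config(seed=1, **overrides) -> SimConfig:
    defaults = dict(
        n_clones=96, n_families=24, n_markers=250, n_founders=24,
        traits=(
            TraitSpec("emergence", 0.85, 0.1, 0.2, 0.8),
            TraitSpec("yield", 0.7, 0.3, 0.3, 0.6),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim_config():
    return small_config()


@pytest.fixture(scope="session")
def population(sim_config):
    return simulate_population(sim_config)


@pytest.fixture(scope="session")
def trial(sim_config, population):
    return simulate_trial(population, sim_config)


@pytest.fixture(scope="session")
def spectra(sim_config, population):
    return simulate_spectra(population, sim_config)


@pytest.fixture(scope="session")
def dataset(population, trial, spectra):
    Z, ped = population
    return Dataset(phenotypes=trial.plots, genotypes=Z.astype(float),
                   spectra=spectra, pedigree=ped)


@pytest.fixture(scope="session")
def bundle(dataset):
    # include_column=True skips the per-model column LRT to keep the
    # session build fast; the LRT itself is tested in test_lmm
    return build_bundle(dataset, options=BundleOptions(include_column=True))


def clone_spectra_matrix(spectra: pd.DataFrame, env: str) -> pd.DataFrame:
    """Quick clone-level spectral matrix for one environment: plot values
    per clone (checks averaged over their replicates), columns scaled.
    The model-based entry-mean route lives in the pipeline; this shortcut
    keeps Monte-Carlo calibration tests affordable."""
    from psblup.preprocess import scale_spectra

    df = spectra[spectra.env == env].copy()
    df["feature"] = df.flight_date + "|" + df.channel
    wide = df.pivot_table(index="clone", columns="feature", values="value",
                          aggfunc="mean")
    return scale_spectra(wide)


def toy_kernel(n, rho=0.5, seed=0, ids=None):
    """Small dense PSD kernel for unit tests."""
    rng = np.random.default_rng(seed)
    L = rng.normal(size=(n, max(2, n // 2 + 1)))
    K = L @ L.T / L.shape[1]
    d = np.sqrt(np.diag(K))
    K = rho * K / np.outer(d, d) + (1 - rho) * np.eye(n)
    return K
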