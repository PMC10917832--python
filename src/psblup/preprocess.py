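"""Quality control and imputation for dosage and spectral tables.

Marker QC drops markers by missingness and tetraploid minor-allele
frequency (mean dosage / 4) and median-imputes the remainder.  Spectral
preprocessing is: per-column scaling/centering, PCA-based outlier flagging
of whole plot-spectrum rows, median imputation of the flagged cells, and
predictive-mean-matching (PMM) imputation of channel blocks that are
entirely missing in one year but observed in the other.

All functions take and return pandas DataFrames (rows = clones or plots,
columns = markers or channel/flight-date combinations); missing values are
NaN; observed cells are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "qc_markers",
    "scale_spectra",
    "flag_spectral_outliers",
    "median_impute",
    "pmm_impute",
    "OutlierResult",
]


def qc_markers(raw: pd.DataFrame, max_missing: float = 0.20,
               min_maf: float = 0.05) -> pd.DataFrame:
    """Filter a clones x markers tetraploid dosage matrix and impute.

    Markers with a missing fraction >= ``max_missing`` are removed first;
    minor allele frequency is then computed on the remaining markers as
    min(p, 1-p) with p = mean dosage / 4 over non-missing calls, and markers
    with MAF < ``min_maf`` are removed.  Remaining missing calls are set to
    the marker's median dosage (which may be half-integer for even counts).
    """
    if not 0 < max_missing < 1 or not 0 < min_maf < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    vals = raw.to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 4:
            raise ValueError("dosages must be in 0..4 or missing")
    miss_frac = raw.isna().mean(axis=0)
    kept = raw.loc[:, miss_frac < max_missing]
    p = kept.mean(axis=0, skipna=True) / 4.0
    maf = np.minimum(p, 1.0 - p)
    kept = kept.loc[:, maf >= min_maf]
    if kept.shape[1] == 0:
        raise ValueError("marker QC removed all markers")
    medians = kept.median(axis=0, skipna=True)
    return kept.fillna(medians)


def scale_spectra(raw: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to unit sample SD (ddof=1),
    computed over non-missing entries; missing entries stay missing."""
    n_obs = raw.notna().sum(axis=0)
    if (n_obs < 2).any():
        bad = list(raw.columns[n_obs < 2])
        raise ValueError(f"columns with fewer than 2 observations: {bad}")
    sd = raw.std(axis=0, ddof=1, skipna=True)
    if (sd <= 0).any():
        bad = list(raw.columns[sd <= 0])
        raise ValueError(f"zero-variance spectral columns: {bad}")
    return (raw - raw.mean(axis=0, skipna=True)) / sd


@dataclass
class OutlierResult:
    spectra: pd.DataFrame  # flagged rows set to missing
    row_mask: pd.Series  # True where the row was flagged
    flagged_fraction: float
    n_pcs: int


def flag_spectral_outliers(S: pd.DataFrame, n_pcs: int | None = None,
                           z_threshold: float = 4.0) -> OutlierResult:
    """Flag whole plot-spectrum rows by principal-component scores.

    A row is flagged when its score on any of the first ``n_pcs`` principal
    components exceeds ``z_threshold`` standard deviations of that
    component; flagged rows have all their values set to missing.  With
    ``n_pcs=None`` the components explaining 90% of the variance are used.
    Missing cells are mean-filled (zero on the scaled data) for the PCA only.
    """
    if n_pcs is not None and n_pcs <= 0:
        raise ValueError("n_pcs must be positive")
    X = S.to_numpy(float)
    X = np.where(np.isfinite(X), X, 0.0)
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if n_pcs is None:
        var = s**2
        frac = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
        n_pcs = int(np.searchsorted(frac, 0.90) + 1)
    n_pcs = min(n_pcs, S.shape[1])
    scores = U[:, :n_pcs] * s[:n_pcs]
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.abs(scores / sd)
    flagged = (z > z_threshold).any(axis=1)
    out = S.copy()
    out.loc[flagged, :] = np.nan
    mask = pd.Series(flagged, index=S.index)
    return OutlierResult(out, mask, float(flagged.mean()), n_pcs)


def median_impute(S: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells with their column median (over observed rows)."""
    fully_missing = S.isna().all(axis=0)
    if fully_missing.any():
        raise ValueError(
            f"fully missing columns: {list(S.columns[fully_missing])}"
        )
    return S.fillna(S.median(axis=0, skipna=True))


def pmm_impute(S: pd.DataFrame, target_columns, k_donors: int = 5,
               seed: int = 0) -> pd.DataFrame:
    """Predictive-mean-matching imputation of the given columns.

    For each target column, an ordinary least-squares regression of the
    column on the complete predictor columns is fitted over the rows where
    the target is observed.  Each missing cell is then filled with the
    observed value of one of the ``k_donors`` rows whose predicted values
    are nearest to the missing row's prediction, chosen uniformly at random
    (semi-parametric: imputed values always occur among the donors).
    Deterministic for a given seed; observed cells are untouched.
    """
    target_columns = list(target_columns)
    rng = np.random.default_rng(seed)
    predictors = [c for c in S.columns
                  if c not in target_columns and S[c].notna().all()]
    if not predictors:
        raise ValueError("no complete predictor columns available")
    Xp = np.column_stack([np.ones(len(S))] + [S[c].to_numpy(float)
                                              for c in predictors])
    out = S.copy()
    for col in target_columns:
        yc = S[col].to_numpy(float)
        obs = np.isfinite(yc)
        mis = ~obs
        if not mis.any():
            continue
        n_obs = int(obs.sum())
        if n_obs == 0:
            raise ValueError(f"target column {col!r} has no observed rows")
        if n_obs < k_donors:
            raise ValueError(
                f"target column {col!r} has {n_obs} observed rows, fewer "
                f"than k_donors={k_donors}"
            )
        beta, *_ = np.linalg.lstsq(Xp[obs], yc[obs], rcond=None)
        pred = Xp @ beta
        obs_idx = np.where(obs)[0]
        for i in np.where(mis)[0]:
            d = np.abs(pred[obs_idx] - pred[i])
            donors = obs_idx[np.argsort(d, kind="stable")[:k_donors]]
            out.iloc[i, out.columns.get_loc(col)] = yc[rng.choice(donors)]
    return out
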