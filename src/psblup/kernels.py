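"""Relationship matrices for genomic and phenomic prediction.

Builds the additive genomic kernel G = ZZ'/m from tetraploid allele dosages
(optionally column-centered), the digenic dominance kernel from the
heterozygosity covariate d(4-d)/6, the three first-degree epistatic kernels
as Hadamard products, the multispectral kernel M = SS'/m_s from clone-level
channel reflectances, column-joined and AEM-combined two-environment
spectra, and convex weighted combinations C = x M + (1-x) G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RelationshipMatrix",
    "additive_kernel",
    "dominance_kernel",
    "epistatic_kernels",
    "spectral_kernel",
    "combine_spectra",
    "weighted_kernel",
]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass
class RelationshipMatrix:
    """Symmetric PSD clone x clone kernel with a kind tag and provenance."""

    values: np.ndarray
    clones: list
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.clones = list(self.clones)
        n = len(self.clones)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match clone list")

    def validate(self) -> "RelationshipMatrix":
        asym = np.max(np.abs(self.values - self.values.T)) if self.values.size else 0
        if asym > _SYM_TOL:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:g})")
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        floor = -_PSD_TOL * max(w.max(), 1.0)
        if w.min() < floor:
            raise ValueError(f"kernel not PSD (min eigenvalue {w.min():g})")
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.clones, columns=self.clones)

    def subset(self, clones) -> "RelationshipMatrix":
        pos = {c: i for i, c in enumerate(self.clones)}
        idx = [pos[c] for c in clones]
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(clones),
                                  self.kind, dict(self.meta))


def _symmetrize(A: np.ndarray) -> np.ndarray:
    return (A + A.T) / 2.0


def additive_kernel(Z: pd.DataFrame, center: bool = True) -> RelationshipMatrix:
    """Additive genomic kernel G = ZZ'/m from a clones x markers dosage
    matrix; with ``center`` (default) markers are centered by their mean
    dosage first, without it the literal cross-product is returned."""
    if Z.shape[1] == 0:
        raise ValueError("no markers")
    X = Z.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("dosage matrix contains missing values; run QC first")
    if center:
        X = X - X.mean(axis=0)
    G = _symmetrize(X @ X.T / Z.shape[1])
    return RelationshipMatrix(G, Z.index, "G",
                              {"m": Z.shape[1], "centered": center})


def dominance_covariate(Z: pd.DataFrame) -> pd.DataFrame:
    """Digenic heterozygosity covariate w = d(4-d)/6 per marker: the
    fraction of heterozygous pairs among the C(4,2)=6 allele pairings."""
    X = Z.to_numpy(float)
    return pd.DataFrame(X * (4.0 - X) / 6.0, index=Z.index, columns=Z.columns)


def dominance_kernel(Z: pd.DataFrame) -> RelationshipMatrix:
    """Digenic dominance kernel: centered heterozygosity covariates,
    cross-product normalised to mean diagonal 1."""
    W = dominance_covariate(Z).to_numpy(float)
    W = W - W.mean(axis=0)
    D = _symmetrize(W @ W.T)
    scale = np.mean(np.diag(D))
    if scale <= 0:
        warnings.warn("all markers monomorphic for dominance; D is zero")
        return RelationshipMatrix(np.zeros_like(D), Z.index, "D",
                                  {"m": Z.shape[1], "degenerate": True})
    return RelationshipMatrix(D / scale, Z.index, "D", {"m": Z.shape[1]})


def _rescale_mean_diag(A: np.ndarray) -> np.ndarray:
    scale = np.mean(np.diag(A))
    return A / scale if scale > 0 else np.zeros_like(A)


def epistatic_kernels(G: RelationshipMatrix, D: RelationshipMatrix
                      ) -> tuple[RelationshipMatrix, RelationshipMatrix,
                                 RelationshipMatrix]:
    """First-degree epistatic kernels as Hadamard products (AA = G*G,
    AD = G*D, DD = D*D), each rescaled to mean diagonal 1."""
    if G.clones != D.clones:
        raise ValueError("G and D are defined on different clone sets")
    aa = _rescale_mean_diag(G.values * G.values)
    ad = _rescale_mean_diag(G.values * D.values)
    dd = _rescale_mean_diag(D.values * D.values)
    return (RelationshipMatrix(aa, G.clones, "AA"),
            RelationshipMatrix(ad, G.clones, "AD"),
            RelationshipMatrix(dd, G.clones, "DD"))


def spectral_kernel(S: pd.DataFrame, source: str = "") -> RelationshipMatrix:
    """Multispectral kernel M = SS'/m_s from a complete clone x
    channel-date matrix of (scaled) reflectance entry means."""
    if S.shape[1] == 0:
        raise ValueError("no spectral columns (m_s = 0)")
    X = S.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("spectral matrix contains missing values; impute first")
    M = _symmetrize(X @ X.T / S.shape[1])
    return RelationshipMatrix(M, S.index, "M",
                              {"m_s": S.shape[1], "source": source})


def combine_spectra(S_env1: pd.DataFrame, S_env2: pd.DataFrame,
                    mode: str = "cjM") -> pd.DataFrame:
    """Combine two single-environment clone-level spectral matrices.

    ``cjM`` column-joins the two matrices on the shared clone set (m_s adds
    up); ``MAEM`` averages per clone over the environments where each
    channel-date column is observed (the two-stage entry-mean route; the
    plot-level model-based route lives in :mod:`psblup.trials`).
    """
    shared = S_env1.index.intersection(S_env2.index)
    if len(shared) == 0:
        raise ValueError("no shared clones between the two spectra sets")
    a, b = S_env1.loc[shared], S_env2.loc[shared]
    if mode == "cjM":
        a = a.copy()
        b = b.copy()
        a.columns = [f"{c}@1" for c in a.columns]
        b.columns = [f"{c}@2" for c in b.columns]
        return pd.concat([a, b], axis=1)
    if mode == "MAEM":
        cols = list(dict.fromkeys(list(a.columns) + list(b.columns)))
        out = {}
        for c in cols:
            parts = [m[c] for m in (a, b) if c in m.columns]
            out[c] = pd.concat(parts, axis=1).mean(axis=1)
        return pd.DataFrame(out, index=shared)
    raise ValueError(f"unknown combination mode {mode!r}")


def weighted_kernel(M: RelationshipMatrix, G: RelationshipMatrix,
                    x: float) -> RelationshipMatrix:
    """Convex combination C = x*M + (1-x)*G on an identical clone set."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"weight x must lie in [0, 1], got {x}")
    if M.clones != G.clones:
        raise ValueError("M and G are defined on different clone sets")
    C = x * M.values + (1.0 - x) * G.values
    return RelationshipMatrix(C, M.clones, "C",
                              {"x": x, "M": M.kind, "G": G.kind})
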