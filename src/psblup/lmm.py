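"""Restricted-maximum-likelihood engine for Gaussian linear mixed models.

Supports an arbitrary fixed-effect design plus any number of random terms,
each either a categorical grouping factor (identity covariance across levels)
or a clone-level relationship kernel.  The residual variance is profiled out
and the remaining variance ratios are optimised numerically; three
computational routes share one objective:

* ``eigen``  -- single random term: rotate into the eigenbasis of ZKZ' and
  optimise one ratio on a bounded interval (fast, used heavily by BLUP
  cross-validation),
* ``dense``  -- build V = sum(sigma2_t Z_t K_t Z_t') + sigma2_e I explicitly
  (small row counts),
* ``sparse`` -- Henderson mixed-model equations assembled as a sparse system
  and factorised with SuperLU (plot-level trial models with thousands of
  rows and random levels).

The reported restricted log-likelihood includes a +0.5*log|X'X| term so that
it is invariant to the fixed-effect parameterisation (contrast coding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

__all__ = [
    "RandomTerm",
    "LmmSpec",
    "LmmFit",
    "AliasedDesignError",
    "dummy_matrix",
    "fit_reml",
    "restricted_loglik",
    "rlrt_term",
]

# log-scale bounds for variance ratios gamma_t = sigma2_t / sigma2_eps;
# the lower bound acts as the zero boundary (ratio ~1.4e-11)
_LOG_GAMMA_MIN = -25.0
_LOG_GAMMA_MAX = 12.0
_ZERO_RATIO = 1e-8
_DENSE_N_MAX = 700


class AliasedDesignError(ValueError):
    """Fixed design is rank deficient; message names the aliased columns."""


def dummy_matrix(labels: Sequence) -> tuple[sp.csr_matrix, list]:
    """Sparse 0/1 incidence matrix for a categorical factor.

    Returns (Z, levels) with one column per distinct level, in first-seen
    order, and exactly one 1 per row.
    """
    labels = np.asarray(labels)
    levels, inverse = np.unique(labels, return_inverse=True)
    n = labels.shape[0]
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), inverse)), shape=(n, len(levels))
    )
    return Z, list(levels)


@dataclass
class RandomTerm:
    """One random effect: u ~ N(0, sigma2 * K) entering the model as Z @ u.

    ``K`` is None for an identity covariance (plain grouping factor).
    ``levels`` labels the columns of Z (BLUP ordering).  ``A`` optionally
    caches the n x n contribution Z K Z' (used by the dense and eigen
    routes; handy when Z is a plain selection of kernel rows).
    """

    name: str
    Z: sp.spmatrix | np.ndarray
    K: np.ndarray | None = None
    levels: list | None = None
    A: np.ndarray | None = None

    @classmethod
    def factor(cls, name: str, labels: Sequence) -> "RandomTerm":
        Z, levels = dummy_matrix(labels)
        return cls(name=name, Z=Z, levels=levels)

    @classmethod
    def kernel(cls, name: str, labels: Sequence, clone_ids: Sequence,
               K: np.ndarray, A: np.ndarray | None = None) -> "RandomTerm":
        """Kernel term: rows indexed by ``labels`` map into ``clone_ids``."""
        index = {c: i for i, c in enumerate(clone_ids)}
        cols = np.array([index[c] for c in labels])
        n = len(cols)
        Z = sp.csr_matrix(
            (np.ones(n), (np.arange(n), cols)), shape=(n, len(clone_ids))
        )
        return cls(name=name, Z=Z, K=np.asarray(K, float),
                   levels=list(clone_ids), A=A)

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]


@dataclass
class LmmSpec:
    """Model specification: y = X beta + sum_t Z_t u_t + eps."""

    y: np.ndarray
    X: np.ndarray | sp.spmatrix
    terms: list[RandomTerm]
    fixed_names: list | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, float).ravel()
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError("fixed design rows do not match response length")
        for t in self.terms:
            if t.Z.shape[0] != n:
                raise ValueError(f"random term {t.name!r} rows do not match response")
        if self.fixed_names is None:
            self.fixed_names = [f"b{j}" for j in range(self.X.shape[1])]

    def dropna(self) -> "LmmSpec":
        """Listwise-delete rows with a missing response."""
        keep = np.isfinite(self.y)
        if keep.all():
            return self
        X = self.X[keep] if sp.issparse(self.X) else np.asarray(self.X)[keep]
        terms = []
        for t in self.terms:
            A = t.A[np.ix_(keep, keep)] if t.A is not None else None
            terms.append(RandomTerm(t.name, t.Z[keep], t.K, t.levels, A))
        return LmmSpec(self.y[keep], X, terms, list(self.fixed_names))


@dataclass
class LmmFit:
    """REML fit: variance components, BLUEs with covariance, BLUPs."""

    variance_components: dict  # term name -> sigma2, plus "residual"
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list
    blups: dict  # term name -> level-ordered predictions
    blup_levels: dict  # term name -> level labels
    loglik: float  # restricted log-likelihood at the optimum
    converged: bool
    n_obs: int = 0
    method: str = ""

    def sigma2(self, name: str) -> float:
        return self.variance_components[name]


def _psd_factor(K: np.ndarray) -> np.ndarray:
    """Symmetric square-root factor L with K = L L' (PSD, may be singular)."""
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def _folded_Z(term: RandomTerm) -> np.ndarray | sp.spmatrix:
    """Design with the kernel folded in, so the effect covariance is I."""
    if term.K is None:
        return term.Z
    return np.asarray(term.Z @ _psd_factor(term.K))


def _check_fixed_rank(X, names) -> None:
    Xd = X.toarray() if sp.issparse(X) else np.asarray(X, float)
    n, p = Xd.shape
    if p == 0:
        raise ValueError("empty fixed design")
    _, R, piv = sla.qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        aliased = [names[j] for j in piv[rank:]]
        raise AliasedDesignError(
            f"fixed design is rank deficient; aliased columns: {aliased}"
        )


def _logdet_xtx(X) -> float:
    XtX = (X.T @ X)
    XtX = XtX.toarray() if sp.issparse(XtX) else np.asarray(XtX)
    sign, ld = np.linalg.slogdet(XtX)
    return ld


# ---------------------------------------------------------------------------
# profiled objectives.  All return
#   f(gamma) = (n-p) log(y'Py) + log|H| + log|X' H^-1 X|
# up to the same additive constant, where H = I + sum gamma_t Z_t Z_t'
# (kernels folded into Z).  -2 logRL = f + (n-p)(1 + log(2 pi /(n-p)))
#                                      - log|X'X|.


def _term_A(term: RandomTerm) -> np.ndarray:
    """The n x n covariance contribution Z K Z' of one term."""
    if term.A is not None:
        return term.A
    Zd = term.Z.toarray() if sp.issparse(term.Z) else np.asarray(term.Z, float)
    if term.K is None:
        return Zd @ Zd.T
    return Zd @ term.K @ Zd.T


class _DenseObjective:
    def __init__(self, y, X, terms):
        self.y = y
        self.X = X.toarray() if sp.issparse(X) else np.asarray(X, float)
        self.n, self.p = self.X.shape
        self.A = [_term_A(t) for t in terms]

    def components(self, gammas):
        H = np.eye(self.n)
        for g, A in zip(gammas, self.A):
            H += g * A
        try:
            c, low = sla.cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdetH = 2.0 * np.sum(np.log(np.diag(c)))
        Hix = sla.cho_solve((c, low), np.column_stack([self.X, self.y]))
        HiX, Hiy = Hix[:, :-1], Hix[:, -1]
        XtHiX = self.X.T @ HiX
        XtHiy = self.X.T @ Hiy
        cx, lowx = sla.cho_factor(XtHiX)
        beta = sla.cho_solve((cx, lowx), XtHiy)
        quad = float(self.y @ Hiy - XtHiy @ beta)
        logdetXtHiX = 2.0 * np.sum(np.log(np.diag(cx)))
        return dict(chol=(c, low), beta=beta, quad=quad, logdetH=logdetH,
                    logdetXtHiX=logdetXtHiX, XtHiX=XtHiX, Hiy=Hiy, HiX=HiX)

    def __call__(self, log_gammas):
        comp = self.components(np.exp(log_gammas))
        if comp is None or comp["quad"] <= 0:
            return np.inf
        return ((self.n - self.p) * np.log(comp["quad"])
                + comp["logdetH"] + comp["logdetXtHiX"])


class _SparseObjective:
    """Henderson-MME form of the same profiled objective.

    M(gamma) = [[X'X, X'Z], [Z'X, Z'Z + diag(1/gamma)]];
    log|H| + log|X' H^-1 X| = sum_t q_t log gamma_t + log|M|.
    """

    def __init__(self, y, X, folded):
        Xs = sp.csr_matrix(X)
        parts = [Xs] + [sp.csr_matrix(Z) for Z in folded]
        self.W = sp.hstack(parts, format="csc")
        self.p = Xs.shape[1]
        self.q_t = [Z.shape[1] for Z in folded]
        self.n = y.shape[0]
        self.WtW = (self.W.T @ self.W).tocsc()
        self.Wty = np.asarray(self.W.T @ y).ravel()
        self.yty = float(y @ y)
        starts = np.cumsum([self.p] + self.q_t)
        self.slices = [slice(a, b) for a, b in zip(starts[:-1], starts[1:])]
        self.dim = self.WtW.shape[0]

    def factorize(self, gammas):
        d = np.zeros(self.dim)
        for g, slc in zip(gammas, self.slices):
            d[slc] = 1.0 / g
        M = self.WtW + sp.diags(d)
        # symmetric fill-reducing ordering: much faster than COLAMD here
        return spla.splu(M.tocsc(), permc_spec="MMD_AT_PLUS_A")

    def __call__(self, log_gammas):
        gammas = np.exp(log_gammas)
        try:
            lu = self.factorize(gammas)
        except RuntimeError:
            return np.inf
        logdetM = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        theta = lu.solve(self.Wty)
        quad = self.yty - float(self.Wty @ theta)
        if quad <= 0 or not np.isfinite(logdetM):
            return np.inf
        pen = sum(q * lg for q, lg in zip(self.q_t, log_gammas))
        return (self.n - self.p) * np.log(quad) + pen + logdetM


class _EigenObjective:
    """Single random term: H = I + gamma * Z K Z' diagonalised once."""

    def __init__(self, y, X, terms):
        A = _term_A(terms[0])
        self.w, self.U = np.linalg.eigh((A + A.T) / 2.0)
        self.w = np.clip(self.w, 0.0, None)
        Xd = X.toarray() if sp.issparse(X) else np.asarray(X, float)
        self.n, self.p = Xd.shape
        self.ys = self.U.T @ y
        self.Xs = self.U.T @ Xd

    def components(self, gamma):
        h = 1.0 + gamma * self.w
        logdetH = float(np.sum(np.log(h)))
        Xw = self.Xs / h[:, None]
        XtHiX = self.Xs.T @ Xw
        XtHiy = Xw.T @ self.ys
        cx, lowx = sla.cho_factor(XtHiX)
        beta = sla.cho_solve((cx, lowx), XtHiy)
        quad = float(self.ys @ (self.ys / h) - XtHiy @ beta)
        logdetXtHiX = 2.0 * np.sum(np.log(np.diag(cx)))
        return dict(beta=beta, quad=quad, logdetH=logdetH,
                    logdetXtHiX=logdetXtHiX, XtHiX=XtHiX, h=h)

    def __call__(self, log_gamma):
        comp = self.components(np.exp(float(log_gamma)))
        if comp["quad"] <= 0:
            return np.inf
        return ((self.n - self.p) * np.log(comp["quad"])
                + comp["logdetH"] + comp["logdetXtHiX"])


def _loglik_from_objective(fval, n, p, logdet_xtx):
    """Convert the profiled objective value to the restricted log-likelihood."""
    const = (n - p) * (1.0 + np.log(2.0 * np.pi) - np.log(n - p))
    return -0.5 * (fval + const - logdet_xtx)


def fit_reml(spec: LmmSpec, max_iter: int = 500, tol: float = 1e-8,
             method: str = "auto", compute_blups: bool = True) -> LmmFit:
    """Fit the model by REML, profiling the residual variance.

    ``method`` is one of ``auto``, ``dense``, ``sparse``, ``eigen``.  ``auto``
    uses the eigen route for a single random term with modest row count, the
    dense route below ~700 rows, and the sparse mixed-model-equation route
    otherwise.  Variance components may sit on the zero boundary.  A
    non-converged optimisation is returned with ``converged=False`` rather
    than raised, so callers can record a missing prediction.
    """
    spec = spec.dropna()
    y, X, terms = spec.y, spec.X, spec.terms
    n = y.shape[0]
    _check_fixed_rank(X, spec.fixed_names)
    p = X.shape[1]
    if not terms:
        raise ValueError("at least one random term is required")
    for t in terms:
        if t.n_levels < 2:
            raise ValueError(f"random term {t.name!r} has fewer than 2 levels")

    k = len(terms)
    if method == "auto":
        if k == 1 and n <= 2000:
            method = "eigen"
        elif n <= _DENSE_N_MAX:
            method = "dense"
        else:
            method = "sparse"
    if method == "eigen" and k != 1:
        raise ValueError("eigen route requires exactly one random term")

    logdet_xtx = _logdet_xtx(X)

    if method == "eigen":
        obj = _EigenObjective(y, X, terms)
        res = minimize_scalar(
            obj, bounds=(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX), method="bounded",
            options={"xatol": max(tol, 1e-12), "maxiter": max_iter},
        )
        log_gammas = np.array([res.x])
        fval = float(res.fun)
        converged = bool(res.success) and np.isfinite(fval)
    else:
        if method == "dense":
            obj = _DenseObjective(y, X, terms)
        else:
            obj = _SparseObjective(y, X, [_folded_Z(t) for t in terms])
        if k == 1:
            # one ratio: precise bounded 1-D search on the same objective
            res = minimize_scalar(
                lambda x: obj(np.array([x])),
                bounds=(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX), method="bounded",
                options={"xatol": max(tol, 1e-12), "maxiter": max_iter},
            )
            log_gammas = np.array([res.x])
        else:
            x0 = np.full(k, np.log(0.5))
            bounds = [(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX)] * k
            res = minimize(
                obj, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-12, "gtol": max(tol * 10, 1e-7),
                         "eps": 1e-5, "maxiter": max_iter},
            )
            log_gammas = np.atleast_1d(res.x)
        fval = float(res.fun)
        converged = bool(res.success) and np.isfinite(fval)

    gammas = np.exp(log_gammas)
    gammas[gammas < _ZERO_RATIO] = 0.0

    # final quantities at the optimum, via the dense/eigen components or MME
    fit = _solution_at(y, X, terms, gammas, method, obj, compute_blups)
    sigma2_eps = fit["sigma2_eps"]
    vc = {t.name: g * sigma2_eps for t, g in zip(terms, gammas)}
    vc["residual"] = sigma2_eps
    loglik = _loglik_from_objective(fval, n, p, logdet_xtx)

    return LmmFit(
        variance_components=vc,
        beta=fit["beta"],
        beta_cov=fit["beta_cov"],
        fixed_names=list(spec.fixed_names),
        blups=fit["blups"],
        blup_levels={t.name: t.levels for t in terms},
        loglik=loglik,
        converged=converged,
        n_obs=n,
        method=method,
    )


def _term_blup(term: RandomTerm, gamma: float, Hir: np.ndarray) -> np.ndarray:
    """BLUP u = gamma * K Z' H^-1 r for one term (K = I when absent)."""
    if gamma <= 0:
        return np.zeros(term.n_levels)
    ZtHir = np.asarray(term.Z.T @ Hir).ravel()
    return gamma * (ZtHir if term.K is None else term.K @ ZtHir)


def _solution_at(y, X, terms, gammas, method, obj, compute_blups):
    """BLUEs, BLUPs, residual variance and BLUE covariance at given ratios."""
    n = y.shape[0]
    p = X.shape[1]
    safe = np.where(gammas <= 0, _ZERO_RATIO * 1e-3, gammas)

    if method == "sparse":
        lu = obj.factorize(safe)
        rhs = obj.Wty
        theta = lu.solve(rhs)
        quad = obj.yty - float(rhs @ theta)
        sigma2_eps = quad / (n - p)
        beta = theta[:p]
        # BLUE covariance: top-left p x p block of M^-1, times sigma2_eps
        E = np.zeros((obj.dim, p))
        E[:p, :] = np.eye(p)
        Minv_cols = lu.solve(E)
        beta_cov = sigma2_eps * Minv_cols[:p, :]
        beta_cov = (beta_cov + beta_cov.T) / 2.0
        blups = {}
        if compute_blups:
            for t, g, slc in zip(terms, gammas, obj.slices):
                u = theta[slc]
                if g <= 0:
                    u = np.zeros_like(u)
                if t.K is not None:
                    u = _psd_factor(t.K) @ u
                blups[t.name] = u
        return dict(beta=beta, beta_cov=beta_cov, sigma2_eps=sigma2_eps,
                    blups=blups)

    comp = obj.components(max(safe[0], 1e-300) if method == "eigen" else safe)
    sigma2_eps = comp["quad"] / (n - p)
    beta = comp["beta"]
    beta_cov = sigma2_eps * np.linalg.inv(comp["XtHiX"])
    beta_cov = (beta_cov + beta_cov.T) / 2.0
    blups = {}
    if compute_blups:
        Xd = X.toarray() if sp.issparse(X) else np.asarray(X, float)
        resid = y - Xd @ beta
        if method == "eigen":
            # H^-1 r in the eigenbasis, rotated back
            Hir = obj.U @ ((obj.U.T @ resid) / comp["h"])
            blups[terms[0].name] = _term_blup(terms[0], gammas[0], Hir)
        else:
            Hir = sla.cho_solve(comp["chol"], resid)
            for t, g in zip(terms, gammas):
                blups[t.name] = _term_blup(t, g, Hir)
    return dict(beta=beta, beta_cov=beta_cov, sigma2_eps=sigma2_eps,
                blups=blups)


def restricted_loglik(spec: LmmSpec, variance_components: dict) -> float:
    """Direct evaluation of the restricted log-likelihood at given components.

    Builds V explicitly (dense); intended for small instances, grid checks
    and tests rather than production fits.
    """
    spec = spec.dropna()
    y = spec.y
    Xd = spec.X.toarray() if sp.issparse(spec.X) else np.asarray(spec.X, float)
    n, p = Xd.shape
    V = variance_components["residual"] * np.eye(n)
    for t in spec.terms:
        Zd = t.Z.toarray() if sp.issparse(t.Z) else np.asarray(t.Z)
        K = np.eye(t.n_levels) if t.K is None else t.K
        V += variance_components[t.name] * (Zd @ K @ Zd.T)
    c = sla.cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(c[0])))
    Vi_yX = sla.cho_solve(c, np.column_stack([y, Xd]))
    Viy, ViX = Vi_yX[:, 0], Vi_yX[:, 1:]
    XtViX = Xd.T @ ViX
    cx = sla.cho_factor(XtViX)
    beta = sla.cho_solve(cx, Xd.T @ Viy)
    quad = float(y @ Viy - (Xd.T @ Viy) @ beta)
    logdetXtViX = 2.0 * np.sum(np.log(np.diag(cx[0])))
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetXtViX
                   - _logdet_xtx(Xd) + quad)


def simulate_response(spec: LmmSpec, fit: LmmFit, rng: np.random.Generator
                      ) -> np.ndarray:
    """Draw a response vector from the fitted model (parametric bootstrap)."""
    Xd = spec.X.toarray() if sp.issparse(spec.X) else np.asarray(spec.X, float)
    y = Xd @ fit.beta
    for t in spec.terms:
        s2 = fit.variance_components[t.name]
        if s2 <= 0:
            continue
        if t.K is None:
            u = rng.normal(0.0, np.sqrt(s2), t.n_levels)
        else:
            u = _psd_factor(t.K) @ rng.normal(0.0, np.sqrt(s2), t.n_levels)
        y = y + np.asarray(t.Z @ u).ravel()
    y = y + rng.normal(0.0, np.sqrt(fit.variance_components["residual"]),
                       y.shape[0])
    return y


def rlrt_term(spec_full: LmmSpec, spec_reduced: LmmSpec, n_sim: int = 1000,
              alpha: float = 0.05, seed: int = 0,
              method: str = "bootstrap", fit_kwargs: dict | None = None
              ) -> tuple[float, float, bool]:
    """Restricted likelihood-ratio test for one variance component.

    The reduced model must equal the full model minus exactly one random
    term.  The null distribution is obtained by parametric bootstrap from the
    reduced fit (``method='bootstrap'``), or approximated by an equal mixture
    of a point mass at zero and chi-square(1) (``method='chibar'``).

    Returns ``(statistic, p_value, include_term)`` with
    ``include_term = p_value < alpha``.
    """
    full_names = [t.name for t in spec_full.terms]
    red_names = [t.name for t in spec_reduced.terms]
    extra = [nm for nm in full_names if nm not in red_names]
    if len(extra) != 1 or len(full_names) != len(red_names) + 1:
        raise ValueError(
            "models must differ by exactly one random term; "
            f"full={full_names}, reduced={red_names}"
        )
    fk = fit_kwargs or {}
    fit_full = fit_reml(spec_full, **fk)
    fit_red = fit_reml(spec_reduced, **fk)
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))

    if method == "chibar":
        pval = 0.5 * float(chi2.sf(stat, df=1)) + (0.5 if stat == 0 else 0.0)
        return stat, pval, pval < alpha

    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_sim)
    for b in range(n_sim):
        y_b = simulate_response(spec_reduced, fit_red, rng)
        sf = LmmSpec(y_b, spec_full.X, spec_full.terms,
                     list(spec_full.fixed_names))
        sr = LmmSpec(y_b, spec_reduced.X, spec_reduced.terms,
                     list(spec_reduced.fixed_names))
        lf = fit_reml(sf, **fk)
        lr = fit_reml(sr, **fk)
        null_stats[b] = max(0.0, 2.0 * (lf.loglik - lr.loglik))
    pval = float(np.mean(null_stats >= stat))
    return stat, pval, pval < alpha
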