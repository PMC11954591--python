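"""Generalized least squares on a phylogeny with profiled Pagel's lambda,
and a Poisson phylogenetic GLM (GEE) for count responses.

The lambda profile is evaluated in a rotated basis.  Writing the residual
covariance as ``C(lam) = S (I + lam (R - I)) S`` — where ``R`` is the BM
correlation matrix, ``S = diag(sqrt(V_ii / w_i))`` absorbs tip variances and
observation weights — a single symmetric eigendecomposition ``R = Q G Q'``
turns every lambda evaluation into a weighted least squares problem with
diagonal variances ``1 + lam (g_i - 1)``.  :class:`LambdaProfiler` caches the
decomposition so screens fitting thousands of models on one tree pay for it
once.

Weights follow the measurement-reliability convention: an observation with
weight ``w`` has its residual variance scaled by ``1/w``, reducing to classic
WLS at ``lam = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .tree import (
    CovarianceMatrix,
    Phylogeny,
    bm_covariance,
    lambda_transform,
    normalize_label,
)

__all__ = [
    "DesignSpec",
    "PGLSFit",
    "PGLMFit",
    "RankError",
    "LambdaProfiler",
    "fit_gls",
    "fit_pgls",
    "coefficient_test",
    "fit_poisson_pglm",
]

LAMBDA_XATOL = 1e-6


class RankError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass
class DesignSpec:
    """A regression design aligned over one species set.

    ``predictors`` holds named columns without an intercept (one is added
    automatically).  ``weights`` defaults to 1 for every species; only
    relative weights matter.
    """

    response: pd.Series
    predictors: pd.DataFrame
    weights: pd.Series | None = None

    def __post_init__(self):
        self.response = pd.Series(self.response, dtype=float)
        self.predictors = pd.DataFrame(self.predictors, dtype=float)
        if not self.response.index.equals(self.predictors.index):
            self.predictors = self.predictors.reindex(self.response.index)
        if self.weights is None:
            self.weights = pd.Series(1.0, index=self.response.index)
        else:
            self.weights = pd.Series(self.weights, dtype=float).reindex(
                self.response.index
            )
        if self.response.isna().any():
            bad = list(self.response.index[self.response.isna()])
            raise ValueError(f"missing response values for species: {bad}")
        if self.predictors.isna().any().any():
            bad = list(
                self.predictors.index[self.predictors.isna().any(axis=1)]
            )
            raise ValueError(f"missing predictor values for species: {bad}")
        if (self.weights <= 0).any() or self.weights.isna().any():
            raise ValueError("weights must be positive and complete")

    @property
    def species(self) -> list[str]:
        return list(self.response.index)

    def matrices(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (y, X-with-intercept, term names)."""
        y = self.response.to_numpy()
        X = np.column_stack(
            [np.ones(len(y)), self.predictors.to_numpy()]
        )
        names = ["intercept", *self.predictors.columns]
        return y, X, names


@dataclass
class PGLSFit:
    """Result of a (weighted) phylogenetic GLS fit."""

    beta: pd.Series
    se: pd.Series
    lambda_hat: float
    sigma2_hat: float
    loglik: float
    n: int
    p: int
    tstats: pd.Series
    pvalues: pd.Series
    method: str = "pgls-ml"

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "t": self.tstats,
                "p": self.pvalues,
            }
        )


@dataclass
class PGLMFit:
    """Result of the Poisson phylogenetic GLM (GEE) fit."""

    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series
    lambda_work: float
    n: int
    converged: bool
    method: str = "poisson-gee-phylo"


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of dependent columns via QR pivoting
        _, R, piv = _qr_pivot(X)
        dependent = sorted(names[j] for j in piv[rank:])
        raise RankError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {dependent}"
        )


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, pivoting=True, mode="economic")
    return Q, R, piv


def _t_pvalues(t: np.ndarray, df: int) -> np.ndarray:
    if df <= 0:
        return np.full_like(np.asarray(t, dtype=float), np.nan)
    return 2.0 * stats.t.sf(np.abs(t), df)


class LambdaProfiler:
    """Profile-likelihood machinery for Pagel's lambda on a fixed
    (covariance, weights) pair.

    Transforms responses and designs once; each lambda evaluation is then a
    diagonal-variance weighted least squares solve.
    """

    def __init__(self, V: CovarianceMatrix, weights: np.ndarray | None = None):
        vals = V.values
        n = len(V)
        self.labels = V.labels
        self.n = n
        diag = np.diag(vals).copy()
        if np.any(diag <= 0):
            raise ValueError("tip variances must be positive")
        if weights is None:
            weights = np.ones(n)
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n,) or np.any(weights <= 0):
            raise ValueError("weights must be positive, one per species")
        R = vals / np.outer(np.sqrt(diag), np.sqrt(diag))
        gamma, Q = np.linalg.eigh(R)
        self._gamma = np.clip(gamma, 0.0, None)
        self._Q = Q
        self._s = np.sqrt(diag / weights)
        self._logdet_S2 = float(np.sum(np.log(diag / weights)))

    def transform(self, a: np.ndarray) -> np.ndarray:
        """Rotate a vector or column-stacked matrix into the diagonal basis."""
        a = np.asarray(a, dtype=float)
        if a.ndim == 1:
            return self._Q.T @ (a / self._s)
        return self._Q.T @ (a / self._s[:, None])

    def _variances(self, lam: float) -> np.ndarray:
        d = 1.0 + lam * (self._gamma - 1.0)
        floor = 1e-12 * max(1.0, self._gamma.max())
        return np.maximum(d, floor)

    def profile_loglik(
        self, ystar: np.ndarray, Xstar: np.ndarray, lam: float
    ) -> float:
        """ML log-likelihood at ``lam`` with beta and sigma2 profiled out."""
        n = self.n
        d = self._variances(lam)
        sw = 1.0 / np.sqrt(d)
        A = Xstar * sw[:, None]
        b = ystar * sw
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        rss = float(np.sum((b - A @ beta) ** 2))
        sigma2_ml = max(rss / n, 1e-300)
        return (
            -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
            - 0.5 * (np.sum(np.log(d)) + self._logdet_S2)
        )

    def fit_at(
        self,
        ystar: np.ndarray,
        Xstar: np.ndarray,
        lam: float,
        names: list[str],
    ) -> PGLSFit:
        n, p = Xstar.shape
        d = self._variances(lam)
        sw = 1.0 / np.sqrt(d)
        A = Xstar * sw[:, None]
        b = ystar * sw
        XtX = A.T @ A
        beta = np.linalg.solve(XtX, A.T @ b)
        resid = b - A @ beta
        rss = float(resid @ resid)
        sigma2_ml = max(rss / n, 0.0)
        sigma2_hat = rss / (n - p) if n > p else np.nan
        loglik = (
            -0.5 * n * (np.log(2 * np.pi * max(sigma2_ml, 1e-300)) + 1.0)
            - 0.5 * (np.sum(np.log(d)) + self._logdet_S2)
        )
        cov = sigma2_hat * np.linalg.inv(XtX)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
        pvals = _t_pvalues(t, n - p)
        pvals = np.where((se == 0) & (beta == 0), 1.0, pvals)
        idx = pd.Index(names, name="term")
        return PGLSFit(
            beta=pd.Series(beta, index=idx),
            se=pd.Series(se, index=idx),
            lambda_hat=float(lam),
            sigma2_hat=float(sigma2_hat),
            loglik=float(loglik),
            n=n,
            p=p,
            tstats=pd.Series(t, index=idx),
            pvalues=pd.Series(pvals, index=idx),
        )

    def fit(
        self, y: np.ndarray, X: np.ndarray, names: list[str]
    ) -> PGLSFit:
        """Maximize the profile likelihood over lambda in [0, 1] and return
        the full fit at the optimum.  Boundary ties resolve to the boundary."""
        n, p = X.shape
        if n < p + 1:
            raise ValueError(
                f"insufficient data: {n} species for {p} coefficients"
            )
        _check_rank(X, names)
        ystar = self.transform(y)
        Xstar = self.transform(X)

        def neg_ll(lam: float) -> float:
            return -self.profile_loglik(ystar, Xstar, lam)

        res = minimize_scalar(
            neg_ll,
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": LAMBDA_XATOL},
        )
        candidates = [(0.0, -neg_ll(0.0)), (1.0, -neg_ll(1.0))]
        if res.success or np.isfinite(res.fun):
            candidates.append((float(res.x), -float(res.fun)))
        # prefer boundaries on (near-)ties
        best_lam, best_ll = max(
            candidates, key=lambda c: (round(c[1] / LAMBDA_XATOL), c[0] in (0.0, 1.0))
        )
        return self.fit_at(ystar, Xstar, best_lam, names)


def _design_covariance(design: DesignSpec, tree: Phylogeny) -> CovarianceMatrix:
    mapping = tree.match_tips(design.species)
    missing = [s for s in design.species if s not in mapping]
    if missing:
        raise KeyError(f"species not found in tree: {missing}")
    V = bm_covariance(tree).subset([mapping[s] for s in design.species])
    return CovarianceMatrix(tuple(design.species), V.values)


def fit_gls(design: DesignSpec, C: CovarianceMatrix) -> PGLSFit:
    """Generalized least squares with a fixed residual covariance ``C``.

    ``beta = (X' C^-1 X)^-1 X' C^-1 y``; ``sigma2_hat`` uses the n - p
    denominator while the reported log-likelihood is the ML (profiled-sigma2)
    multivariate-normal value.  Weights in the design scale ``C`` as
    ``D^-1/2 C D^-1/2`` before solving.
    """
    y, X, names = design.matrices()
    _check_rank(X, names)
    order = {normalize_label(lab): i for i, lab in enumerate(C.labels)}
    if len(order) != len(C.labels):
        raise ValueError("covariance labels collide after normalization")
    try:
        idx = [order[normalize_label(s)] for s in design.species]
    except KeyError as exc:
        raise KeyError(
            f"species {exc.args[0]!r} not in covariance matrix"
        ) from None
    Cv = C.values[np.ix_(idx, idx)]
    w = design.weights.to_numpy()
    sw = 1.0 / np.sqrt(w)
    Cw = Cv * np.outer(sw, sw)
    n, p = X.shape
    try:
        L = np.linalg.cholesky(Cw)
    except np.linalg.LinAlgError:
        Cw = Cw + 1e-10 * np.trace(Cw) * np.eye(n)
        L = np.linalg.cholesky(Cw)
    # whiten: solve L z = a
    from scipy.linalg import solve_triangular

    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_hat = rss / (n - p) if n > p else np.nan
    sigma2_ml = max(rss / n, 1e-300)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0) - 0.5 * logdet
    cov = sigma2_hat * np.linalg.inv(XtX)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
    pvals = _t_pvalues(t, n - p)
    pvals = np.where((se == 0) & (beta == 0), 1.0, pvals)
    index = pd.Index(names, name="term")
    return PGLSFit(
        beta=pd.Series(beta, index=index),
        se=pd.Series(se, index=index),
        lambda_hat=np.nan,
        sigma2_hat=float(sigma2_hat),
        loglik=float(loglik),
        n=n,
        p=p,
        tstats=pd.Series(t, index=index),
        pvalues=pd.Series(pvals, index=index),
        method="gls-fixed-cov",
    )


def fit_pgls(
    design: DesignSpec, tree: Phylogeny, lam: float | None = None
) -> PGLSFit:
    """Weighted PGLS with Pagel's lambda estimated by maximum likelihood.

    The residual covariance is ``D^-1/2 V(lam) D^-1/2`` with
    ``D = diag(weights)`` and ``V(lam)`` the lambda-transformed BM
    covariance; lambda maximizes the profile likelihood on [0, 1] unless a
    fixed ``lam`` is supplied.
    """
    y, X, names = design.matrices()
    V = _design_covariance(design, tree)
    prof = LambdaProfiler(V, design.weights.to_numpy())
    if lam is not None:
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        _check_rank(X, names)
        return prof.fit_at(prof.transform(y), prof.transform(X), lam, names)
    return prof.fit(y, X, names)


def coefficient_test(fit: PGLSFit, term: str) -> tuple[float, float]:
    """Two-sided t-test of a single coefficient (df = n - p)."""
    if term not in fit.beta.index:
        raise KeyError(
            f"unknown term {term!r}; available: {list(fit.beta.index)}"
        )
    return float(fit.tstats[term]), float(fit.pvalues[term])


# ---------------------------------------------------------------------------
# Poisson phylogenetic GLM (GEE)
# ---------------------------------------------------------------------------


def fit_poisson_pglm(
    counts: pd.Series,
    predictors: pd.DataFrame,
    tree: Phylogeny,
    lam: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> PGLMFit:
    """Log-link Poisson regression with phylogenetic dependence.

    Estimation is by generalized estimating equations with the
    lambda-transformed BM *correlation* as working correlation; standard
    errors are model-based (the single-cluster phylogenetic layout leaves no
    replication for a sandwich estimator).  With an identity working
    correlation (e.g. a star tree) the estimates coincide with an ordinary
    Poisson GLM.

    When ``lam`` is None the working lambda is estimated by a Gaussian
    lambda-PGLS on ``log1p(counts)`` against the same predictors.
    """
    counts = pd.Series(counts, dtype=float)
    predictors = pd.DataFrame(predictors, dtype=float).reindex(counts.index)
    yv = counts.to_numpy()
    if np.any(yv < 0) or np.any(yv != np.round(yv)):
        raise ValueError("counts must be non-negative integers")
    if np.all(yv == 0):
        raise ValueError("degenerate response: all counts are zero")

    if lam is None:
        gauss = fit_pgls(
            DesignSpec(response=np.log1p(counts), predictors=predictors), tree
        )
        lam = gauss.lambda_hat
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"working lambda must lie in [0, 1], got {lam}")

    design = DesignSpec(response=counts, predictors=predictors)
    y, X, names = design.matrices()
    _check_rank(X, names)
    V = _design_covariance(design, tree)
    R = lambda_transform(V, lam).correlation()
    n, p = X.shape

    # start from the independence fit (Poisson IRLS)
    beta = _poisson_irls(y, X)
    Rinv = np.linalg.inv(R + 1e-12 * np.eye(n))
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        rootmu = np.sqrt(mu)
        # B = X' A^1/2 R^-1 A^1/2 X ; U = X' A^1/2 R^-1 A^-1/2 (y - mu)
        Xa = X * rootmu[:, None]
        B = Xa.T @ Rinv @ Xa
        U = Xa.T @ (Rinv @ ((y - mu) / rootmu))
        step = np.linalg.solve(B, U)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = np.exp(eta)
    Xa = X * np.sqrt(mu)[:, None]
    B = Xa.T @ Rinv @ Xa
    cov = np.linalg.inv(B)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    if not converged:
        warnings.warn("Poisson PGLM did not converge", UserWarning)
    index = pd.Index(names, name="term")
    return PGLMFit(
        beta=pd.Series(beta, index=index),
        se=pd.Series(se, index=index),
        pvalues=pd.Series(pvals, index=index),
        lambda_work=float(lam),
        n=n,
        converged=converged,
    )


def _poisson_irls(y: np.ndarray, X: np.ndarray, max_iter: int = 50) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / mu
        Xw = X * np.sqrt(W)[:, None]
        zw = z * np.sqrt(W)
        new, *_ = np.linalg.lstsq(Xw, zw, rcond=None)
        if np.max(np.abs(new - beta)) < 1e-12:
            beta = new
            break
        beta = new
    return beta
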