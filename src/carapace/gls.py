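"""Generalized least squares under a lambda-scaled phylogenetic covariance.

The core model: for species trait vectors y (response) and design X,

    y = X beta + eps,   eps ~ MVN(0, sigma2 * C_lambda)

where C_lambda is the Brownian-motion covariance with its off-diagonal
multiplied by Pagel's lambda.  Estimation is by maximum likelihood (not
REML), because AICc comparisons across models with different fixed effects
require ML.  lambda is jointly estimated with the coefficients by profiling
the log-likelihood over a grid on [0, 1] followed by bounded scalar
refinement; ties are broken toward the smaller lambda.

Two linear-algebra routes compute the identical profile likelihood:

* a general route (one Cholesky factorization per lambda), valid for any
  covariance, including non-ultrametric trees with fossil tips;
* a fast route used when all tip variances are equal (ultrametric trees,
  including bootstrap resamples with duplicated tips): C_lambda =
  lambda*C + (1-lambda)*h*I shares C's eigenvectors for every lambda, so a
  single eigendecomposition turns each lambda evaluation into a weighted
  least squares of cost O(n k^2).

Reported coefficient standard errors use the unbiased residual-variance
scaling n/(n-k); p-values use Student's t with df = n - k.  The ML
sigma2-hat (divide by n) enters the likelihood and is the value reported as
the rate of residual variance accumulation per unit time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .phylo import PhyloCov

__all__ = [
    "FitResult",
    "RateEstimate",
    "gls_fit_fixed",
    "fit_ols",
    "fit_pgls",
    "eig_precompute",
    "aicc",
    "aicc_weights",
    "likelihood_r2",
    "slope_difference_test",
    "univariate_bm_rate",
]

_LOG2PI = np.log(2.0 * np.pi)
#: lambda grid for the profile search (then refined by bounded optimization)
LAMBDA_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


@dataclass
class FitResult:
    """One fitted regression model (one row-block of a results table).

    ``sigma2`` is the ML rate of residual variance accumulation per unit
    branch-length time.  ``k_aicc`` counts coefficients + 1 (sigma2) + 1
    when lambda was estimated; the convention is recorded here so AICc
    comparisons are internally consistent.
    """

    model: str
    terms: list
    coef: np.ndarray
    se: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    lam: float
    sigma2: float
    loglik: float
    n: int
    k_coef: int
    k_aicc: int
    aicc: float
    method: str  # "PGLS" | "GLS-fixed" | "OLS"
    lambda_estimated: bool
    degenerate: bool = False
    r2: float | None = None
    ci95: dict = field(default_factory=dict)  # term -> (lo, hi), from bootstrap

    def coef_of(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def p_of(self, term: str) -> float:
        return float(self.pvals[self.terms.index(term)])

    @property
    def noninterc_terms(self) -> list:
        return [t for t in self.terms if t != "intercept"]


@dataclass(frozen=True)
class RateEstimate:
    """Univariate Brownian-motion rate with optional measurement error."""

    sigma2: float
    root_state: float
    me_fraction: float
    loglik: float


def _as_matrix(C) -> np.ndarray:
    return C.matrix if isinstance(C, PhyloCov) else np.asarray(C, float)


def _check_yX(y, X, nC):
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.shape[0] != n or n != nC:
        raise ValueError("y, X and C must have aligned rows")
    if n <= k:
        raise ValueError(f"need n > k (got n={n}, k={k})")
    return y, X, n, k


def _gls_core(y, X, V):
    """GLS solve via Cholesky.  Returns (beta, XtViX_inv, rss, logdetV)."""
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError("covariance matrix is singular")
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = linalg.cho_solve(cf, X, check_finite=False)
    Vi_y = linalg.cho_solve(cf, y, check_finite=False)
    XtViX = X.T @ Vi_X
    try:
        XtViX_inv = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular design matrix")
    beta = XtViX_inv @ (X.T @ Vi_y)
    r = y - X @ beta
    rss = float(r @ linalg.cho_solve(cf, r, check_finite=False))
    return beta, XtViX_inv, rss, logdetV


def _finalize(
    model, terms, beta, XtViX_inv, rss, logdetV, n, k, lam, method,
    lambda_estimated,
):
    """Assemble a FitResult from GLS sufficient statistics."""
    sigma2_ml = rss / n
    degenerate = sigma2_ml <= 1e-14 * max(1.0, float(np.abs(beta).max()) ** 2)
    if degenerate:
        warnings.warn(
            "zero residual variance: fit is degenerate (exact linear "
            "relationship); sigma2=0, lambda at lower bound",
            stacklevel=3,
        )
        se = np.zeros(k)
        tvals = np.full(k, np.inf)
        pvals = np.full(k, np.nan)
        loglik = np.inf
        aicc_val = -np.inf
        sigma2_ml = 0.0
        lam = 0.0
    else:
        loglik = -0.5 * (n * _LOG2PI + n * np.log(sigma2_ml) + logdetV + n)
        sigma2_unb = rss / (n - k)
        se = np.sqrt(np.maximum(sigma2_unb * np.diag(XtViX_inv), 0.0))
        with np.errstate(divide="ignore"):
            tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        aicc_val = np.nan  # filled below
    k_aicc = k + 1 + (1 if lambda_estimated else 0)
    if not degenerate:
        # AICc is undefined when n <= k_aicc + 1 (tiny fits still return)
        aicc_val = aicc(loglik, k_aicc, n) if n - k_aicc - 1 > 0 else np.nan
    return FitResult(
        model=model,
        terms=list(terms),
        coef=beta,
        se=se,
        tvals=tvals,
        pvals=pvals,
        lam=float(lam),
        sigma2=float(sigma2_ml),
        loglik=float(loglik),
        n=n,
        k_coef=k,
        k_aicc=k_aicc,
        aicc=float(aicc_val),
        method=method,
        lambda_estimated=lambda_estimated,
        degenerate=degenerate,
    )


def gls_fit_fixed(y, X, C, lam: float, terms=None, model: str = "") -> FitResult:
    """GLS fit with Pagel's lambda held fixed.

    ``V = lambda_transform(C, lam)``; beta-hat solves the generalized
    normal equations, sigma2-hat = r' V^-1 r / n (ML), and the
    log-likelihood is the multivariate-normal density at the optimum.
    """
    M = _as_matrix(C)
    y, X, n, k = _check_yX(y, X, M.shape[0])
    V = lam * M + (1.0 - lam) * np.diag(np.diag(M))
    beta, XtViX_inv, rss, logdetV = _gls_core(y, X, V)
    terms = list(terms) if terms is not None else [f"b{i}" for i in range(k)]
    return _finalize(
        model, terms, beta, XtViX_inv, rss, logdetV, n, k, lam,
        method="GLS-fixed", lambda_estimated=False,
    )


def fit_ols(y, X, terms=None, model: str = "") -> FitResult:
    """Ordinary least squares (independent, homoscedastic residuals)."""
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.shape[0]
    beta, XtX_inv, rss, logdetV = _gls_core(y, X, np.eye(n))
    k = X.shape[1]
    terms = list(terms) if terms is not None else [f"b{i}" for i in range(k)]
    return _finalize(
        model, terms, beta, XtX_inv, rss, logdetV, n, k, lam=0.0,
        method="OLS", lambda_estimated=False,
    )


# -- profile likelihood over lambda ---------------------------------------


def _profile_general(y, X, M):
    """Profile lnL(lambda) via one Cholesky per lambda (any covariance)."""
    D = np.diag(np.diag(M))
    n, k = X.shape

    def lnl(lam):
        V = lam * M + (1.0 - lam) * D
        try:
            beta, XtViX_inv, rss, logdetV = _gls_core(y, X, V)
        except np.linalg.LinAlgError:
            return -np.inf, None
        s2 = rss / n
        if s2 <= 0:
            return np.inf, (beta, XtViX_inv, rss, logdetV)
        ll = -0.5 * (n * _LOG2PI + n * np.log(s2) + logdetV + n)
        return ll, (beta, XtViX_inv, rss, logdetV)

    return lnl


def eig_precompute(M: np.ndarray):
    """Eigendecomposition bundle reusable across fits sharing one C.

    Only valid together with the fast profile route, i.e., when the
    diagonal of M is constant (ultrametric trees).
    """
    w, Q = np.linalg.eigh(M)
    return float(M[0, 0]), w, Q


def _profile_eigh(y, X, M, eig=None):
    """Profile lnL(lambda) via a single eigendecomposition.

    Requires constant diagonal h: then V(lam) = Q diag(lam*w + (1-lam)*h) Q'
    with C = Q diag(w) Q', and each lambda is a weighted least squares.
    """
    h, w, Q = eig if eig is not None else eig_precompute(M)
    yt = Q.T @ y
    Xt = Q.T @ X
    n, k = X.shape

    def lnl(lam):
        d = lam * w + (1.0 - lam) * h
        if d.min() <= 1e-12 * h:
            return -np.inf, None
        Xw = Xt / d[:, None]
        XtViX = Xt.T @ Xw
        try:
            XtViX_inv = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return -np.inf, None
        beta = XtViX_inv @ (Xw.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (r / d))
        logdetV = float(np.sum(np.log(d)))
        s2 = rss / n
        if s2 <= 0:
            return np.inf, (beta, XtViX_inv, rss, logdetV)
        ll = -0.5 * (n * _LOG2PI + n * np.log(s2) + logdetV + n)
        return ll, (beta, XtViX_inv, rss, logdetV)

    return lnl


def fit_pgls(y, X, C, terms=None, model: str = "", grid=None, eig=None) -> FitResult:
    """PGLS with Pagel's lambda jointly estimated by maximum likelihood.

    The profile log-likelihood is evaluated on a grid over [0, 1]
    (default step 0.01) and the best grid point is refined by bounded
    scalar optimization; ties break toward the smaller lambda.

    ``eig`` may carry :func:`eig_precompute` output for the covariance,
    letting many fits that share one (constant-diagonal) C skip the
    per-fit eigendecomposition; the likelihood is unchanged.
    """
    M = _as_matrix(C)
    y, X, n, k = _check_yX(y, X, M.shape[0])
    diag = np.diag(M)
    equal_diag = np.ptp(diag) <= 1e-10 * max(diag.max(), 1e-300)
    if equal_diag:
        lnl = _profile_eigh(y, X, M, eig=eig)
    else:
        lnl = _profile_general(y, X, M)

    grid = LAMBDA_GRID if grid is None else np.asarray(grid, float)
    vals = np.array([lnl(l)[0] for l in grid])
    if not np.isfinite(vals).any():
        if np.isposinf(vals).any():
            best_lam = float(grid[int(np.argmax(np.isposinf(vals)))])
        else:
            raise np.linalg.LinAlgError("non-finite likelihood over lambda grid")
    else:
        i = int(np.argmax(vals))  # argmax returns the first (smallest lambda) tie
        if np.isposinf(vals[i]):
            best_lam = float(grid[i])
        else:
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            best_lam = float(grid[i])
            if hi > lo:
                res = optimize.minimize_scalar(
                    lambda l: -lnl(l)[0],
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": 1e-6},
                )
                if np.isfinite(res.fun) and -res.fun > vals[i]:
                    best_lam = float(res.x)

    ll, parts = lnl(best_lam)
    if parts is None:
        raise np.linalg.LinAlgError("singular covariance at optimal lambda")
    beta, XtViX_inv, rss, logdetV = parts
    terms = list(terms) if terms is not None else [f"b{i}" for i in range(k)]
    return _finalize(
        model, terms, beta, XtViX_inv, rss, logdetV, n, k, best_lam,
        method="PGLS", lambda_estimated=True,
    )


# -- information criteria and derived statistics ---------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n-k-1 > 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_weights(aiccs) -> np.ndarray:
    """Akaike weights: w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    a = np.asarray(aiccs, float)
    if a.size < 2:
        raise ValueError("need at least 2 AICc values")
    if not np.isfinite(a).all():
        raise ValueError("non-finite AICc values")
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def likelihood_r2(fit: FitResult, null_fit: FitResult, n: int | None = None) -> float:
    """Likelihood-ratio R^2 against an intercept-only null.

    r2 = 1 - exp(-(2/n) (lnL_fit - lnL_null)), clipped to [0, 1).  The
    null model carries its own estimated lambda.  No maximum rescaling is
    applied.
    """
    if n is None:
        n = fit.n
    if fit.n != null_fit.n:
        raise ValueError("fit and null must use the same taxa")
    if np.isinf(fit.loglik):  # degenerate perfect fit
        return 1.0 - 1e-16
    r2 = 1.0 - np.exp(-(2.0 / n) * (fit.loglik - null_fit.loglik))
    return float(np.clip(r2, 0.0, 1.0 - 1e-16))


def slope_difference_test(fit_a: FitResult, fit_b: FitResult, term: str):
    """t-test for equality of one coefficient between two fitted models.

    t = (b_a - b_b) / sqrt(SE_a^2 + SE_b^2), with df = n - k - 1
    (two-sided p from Student's t).  Used to compare OLS vs PGLS slopes
    of the purely allometric models.
    """
    for f in (fit_a, fit_b):
        if term not in f.terms:
            raise ValueError(f"term {term!r} missing from model {f.model!r}")
    if fit_a.n != fit_b.n:
        raise ValueError("fits must share the same sample size")
    n, k = fit_a.n, fit_a.k_coef
    df = n - k - 1
    if df <= 0:
        raise ValueError(f"non-positive df = {df}")
    ba, bb = fit_a.coef_of(term), fit_b.coef_of(term)
    sa, sb = fit_a.se_of(term), fit_b.se_of(term)
    denom = np.hypot(sa, sb)
    t = 0.0 if (ba == bb) else (ba - bb) / denom
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return float(t), int(df), min(p, 1.0)


# -- univariate Brownian-motion rate ---------------------------------------


def univariate_bm_rate(x, C, me_fraction: float = 0.0) -> RateEstimate:
    """ML Brownian-motion rate of a single trait, with measurement error.

    Maximizes the MVN likelihood of x with mean mu*1 and covariance
    sigma2*C + diag((me_fraction * x_i)^2).  With me_fraction = 0 the
    estimator is closed-form: mu-hat is the GLS mean and
    sigma2-hat = r' C^-1 r / n.
    """
    if me_fraction < 0:
        raise ValueError("me_fraction must be >= 0")
    M = _as_matrix(C)
    x = np.asarray(x, float).ravel()
    n = x.shape[0]
    if n != M.shape[0]:
        raise ValueError("x must align with C")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    ones = np.ones((n, 1))

    if me_fraction == 0.0:
        beta, _, rss, logdetC = _gls_core(x, ones, M)
        s2 = rss / n
        if s2 <= 0:
            return RateEstimate(0.0, float(beta[0]), 0.0, np.inf)
        ll = -0.5 * (n * _LOG2PI + n * np.log(s2) + logdetC + n)
        return RateEstimate(float(s2), float(beta[0]), 0.0, float(ll))

    E = np.diag((me_fraction * x) ** 2)

    def negll(log_s2):
        s2 = np.exp(log_s2)
        V = s2 * M + E
        try:
            cf = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi_1 = linalg.cho_solve(cf, ones, check_finite=False)
        mu = float(np.squeeze((Vi_1.T @ x) / (ones.T @ Vi_1)))
        r = x - mu
        quad = float(r @ linalg.cho_solve(cf, r, check_finite=False))
        return 0.5 * (n * _LOG2PI + logdet + quad)

    # initialize at the me=0 closed form, search a wide log-scale bracket
    s2_0 = max(univariate_bm_rate(x, M, 0.0).sigma2, 1e-12)
    res = optimize.minimize_scalar(
        negll,
        bounds=(np.log(s2_0) - 12.0, np.log(s2_0) + 6.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    s2 = float(np.exp(res.x))
    V = s2 * M + E
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    Vi_1 = linalg.cho_solve(cf, ones, check_finite=False)
    mu = float(np.squeeze((Vi_1.T @ x) / (ones.T @ Vi_1)))
    return RateEstimate(s2, mu, float(me_fraction), float(-res.fun))
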