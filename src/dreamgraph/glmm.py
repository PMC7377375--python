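"""Maximum-likelihood random-intercept models via Gauss–Hermite quadrature.

Two likelihoods are implemented:

- logistic regression with an optional Gaussian random intercept per group
  (participants), and
- a proportional-odds cumulative-link (logit) model for ordinal outcomes,
  again with an optional group random intercept.

The marginal likelihood integrates the random intercept out with
Gauss–Hermite quadrature (default 25 nodes); for ``sigma = 0`` the quadrature
collapses exactly to the plain fixed-effects likelihood, which makes nesting
limits checkable against standard fixed-effects fits.  All log-likelihoods
are full (no dropped constants), so nested fits are directly comparable by
likelihood-ratio tests.

Continuous predictors are standardized internally for optimizer stability;
reported coefficients are mapped back to the raw predictor scale, and the
log-likelihood is unaffected by this reparameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp

_SQRT2 = np.sqrt(2.0)
_LOG_SQRT_PI = 0.5 * np.log(np.pi)


@dataclass
class GlmmFit:
    """Result of a quadrature ML fit."""

    family: str
    loglik: float
    n_params: int
    n_obs: int
    beta: np.ndarray
    beta_names: tuple[str, ...]
    sigma: float | None  # random-intercept SD (None = no random effect)
    thresholds: np.ndarray | None  # ordinal cutpoints on the latent scale
    converged: bool
    message: str = ""
    diagnostics: dict = field(default_factory=dict)


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Sort order and group start offsets for reduceat-style group sums."""
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    starts = np.flatnonzero(
        np.r_[True, sorted_groups[1:] != sorted_groups[:-1]]
    )
    return order, starts, len(starts)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale columns with >2 distinct values; leave others untouched."""
    Xs = X.astype(float).copy()
    center = np.zeros(X.shape[1])
    scale = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if len(np.unique(col)) > 2:
            mu, sd = col.mean(), col.std()
            if sd > 0:
                Xs[:, j] = (col - mu) / sd
                center[j], scale[j] = mu, sd
    return Xs, center, scale


def _logistic_logpmf(eta: np.ndarray, sgn: np.ndarray) -> np.ndarray:
    # log P(y | eta) with sgn = 2y - 1
    return -np.logaddexp(0.0, -sgn * eta)


def _binomial_loglik(beta, sigma, y, X, starts, nq_x, nq_logw):
    eta0 = X @ beta
    sgn = 2.0 * y - 1.0
    if sigma == 0.0:
        return float(_logistic_logpmf(eta0, sgn).sum())
    E = eta0[:, None] + (_SQRT2 * sigma) * nq_x[None, :]
    ll_obs = _logistic_logpmf(E, sgn[:, None])
    gsum = np.add.reduceat(ll_obs, starts, axis=0)
    return float(logsumexp(gsum + (nq_logw - _LOG_SQRT_PI)[None, :], axis=1).sum())


def fit_binomial(
    y,
    X,
    groups=None,
    beta_names: tuple[str, ...] | None = None,
    n_quad: int = 25,
    sigma_fixed: float | None = None,
) -> GlmmFit:
    """ML logistic regression, optionally with a group random intercept.

    ``X`` must include an intercept column if one is wanted.  ``sigma_fixed``
    pins the random-intercept SD (0 reproduces plain logistic ML exactly).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if beta_names is None:
        beta_names = tuple(f"x{j}" for j in range(p))
    Xs, center, scale = _standardize(X)

    has_re = groups is not None and sigma_fixed != 0.0
    if groups is not None:
        groups = np.asarray(groups)
        order, starts, _ = _group_index(groups)
        ys, Xss = y[order], Xs[order]
    else:
        starts = np.array([0])
        ys, Xss = y, Xs
    nq_x, nq_w = hermgauss(n_quad)
    nq_logw = np.log(nq_w)

    # plain-logistic start values via a few Newton steps
    beta0 = np.zeros(p)
    for _ in range(25):
        eta = Xss @ beta0
        mu = 1.0 / (1.0 + np.exp(-eta))
        wvec = np.clip(mu * (1 - mu), 1e-10, None)
        grad = Xss.T @ (ys - mu)
        H = (Xss * wvec[:, None]).T @ Xss + 1e-8 * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta0 = beta0 + step
        if np.max(np.abs(step)) < 1e-8:
            break
    sep_warn = bool(np.any(np.abs(Xss @ beta0) > 15))
    if sep_warn:
        warnings.warn("possible separation in binomial fit", stacklevel=2)

    if not has_re:
        sigma = 0.0 if groups is not None or sigma_fixed == 0.0 else None
        ll = _binomial_loglik(beta0, 0.0, ys, Xss, starts, nq_x, nq_logw)
        beta_raw, = _unscale(beta0[None, :], center, scale)
        return GlmmFit(
            family="binomial",
            loglik=ll,
            n_params=p,
            n_obs=n,
            beta=beta_raw,
            beta_names=beta_names,
            sigma=0.0 if groups is not None else None,
            thresholds=None,
            converged=True,
            diagnostics={"separation": sep_warn},
        )

    def negll(theta):
        beta, sigma = theta[:p], theta[p]
        return -_binomial_loglik(beta, sigma, ys, Xss, starts, nq_x, nq_logw)

    x0 = np.r_[beta0, 0.3 if sigma_fixed is None else sigma_fixed]
    bounds = [(None, None)] * p + [
        (0.0, 20.0) if sigma_fixed is None else (sigma_fixed, sigma_fixed)
    ]
    res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-11})
    beta_hat, sigma_hat = res.x[:p], float(res.x[p])
    beta_raw, = _unscale(beta_hat[None, :], center, scale)
    return GlmmFit(
        family="binomial",
        loglik=float(-res.fun),
        n_params=p + (0 if sigma_fixed is not None else 1),
        n_obs=n,
        beta=beta_raw,
        beta_names=beta_names,
        sigma=sigma_hat,
        thresholds=None,
        converged=bool(res.success),
        message=str(res.message),
        diagnostics={"separation": sep_warn},
    )


def _unscale(beta_rows: np.ndarray, center: np.ndarray, scale: np.ndarray):
    """Map standardized-scale coefficients back to the raw predictor scale.

    Assumes column 0 is the intercept whenever any column was centered; the
    intercept absorbs sum(beta_j * center_j / scale_j).
    """
    out = []
    for b in beta_rows:
        raw = b / scale
        shift = float(np.sum(b * center / scale))
        raw = raw.copy()
        if len(raw) and scale[0] == 1.0 and center[0] == 0.0:
            raw[0] -= shift
        out.append(raw)
    return out


def _ordinal_loglik(theta_cuts, beta, sigma, y, X, starts, nq_x, nq_logw):
    eta0 = X @ beta
    K = len(theta_cuts) + 1
    upper = np.r_[theta_cuts, np.inf]
    lower = np.r_[-np.inf, theta_cuts]
    up = upper[y]
    lo = lower[y]
    if sigma == 0.0:
        a = up - eta0
        b = lo - eta0
        p = _sigmoid(a) - _sigmoid(b)
        return float(np.log(np.clip(p, 1e-300, None)).sum())
    shift = (_SQRT2 * sigma) * nq_x[None, :]
    a = (up - eta0)[:, None] - shift
    b = (lo - eta0)[:, None] - shift
    p = _sigmoid(a) - _sigmoid(b)
    ll_obs = np.log(np.clip(p, 1e-300, None))
    gsum = np.add.reduceat(ll_obs, starts, axis=0)
    return float(logsumexp(gsum + (nq_logw - _LOG_SQRT_PI)[None, :], axis=1).sum())


def _sigmoid(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def _cuts_from_free(free: np.ndarray) -> np.ndarray:
    # increasing cutpoints: first free, remaining are log-spacings
    return np.r_[free[0], free[0] + np.cumsum(np.exp(free[1:]))]


def _free_from_cuts(cuts: np.ndarray) -> np.ndarray:
    d = np.diff(cuts)
    return np.r_[cuts[0], np.log(np.clip(d, 1e-6, None))]


def fit_ordinal(
    y,
    X,
    groups=None,
    beta_names: tuple[str, ...] | None = None,
    n_quad: int = 25,
    sigma_fixed: float | None = None,
) -> GlmmFit:
    """Proportional-odds cumulative-logit ML fit, optional group intercept.

    ``y`` holds ordinal categories (any integers); they are mapped to
    0..K-1 by sorted unique value.  ``X`` must NOT contain an intercept
    (cutpoints play that role).
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    cats = np.unique(y)
    K = len(cats)
    if K < 2:
        raise ValueError("ordinal outcome needs >= 2 observed categories")
    ymap = np.searchsorted(cats, y)
    if beta_names is None:
        beta_names = tuple(f"x{j}" for j in range(p))
    Xs, center, scale = _standardize(X)

    has_re = groups is not None and sigma_fixed != 0.0
    if groups is not None:
        groups = np.asarray(groups)
        order, starts, _ = _group_index(groups)
        ys, Xss = ymap[order], Xs[order]
    else:
        starts = np.array([0])
        ys, Xss = ymap, Xs
    nq_x, nq_w = hermgauss(n_quad)
    nq_logw = np.log(nq_w)

    # start: cutpoints at marginal cumulative logits, beta = 0
    freqs = np.bincount(ys, minlength=K) / n
    cum = np.clip(np.cumsum(freqs)[:-1], 1e-4, 1 - 1e-4)
    cuts0 = np.log(cum / (1 - cum))
    cuts0 = np.maximum.accumulate(cuts0 + 1e-6 * np.arange(K - 1))
    free0 = _free_from_cuts(cuts0)

    nfree = K - 1
    if has_re:
        def negll(theta):
            cuts = _cuts_from_free(theta[:nfree])
            beta = theta[nfree : nfree + p]
            sigma = theta[-1]
            return -_ordinal_loglik(cuts, beta, sigma, ys, Xss, starts, nq_x, nq_logw)

        x0 = np.r_[free0, np.zeros(p), 0.3 if sigma_fixed is None else sigma_fixed]
        bounds = (
            [(None, None)] * (nfree + p)
            + [(0.0, 20.0) if sigma_fixed is None else (sigma_fixed, sigma_fixed)]
        )
    else:
        def negll(theta):
            cuts = _cuts_from_free(theta[:nfree])
            beta = theta[nfree : nfree + p]
            return -_ordinal_loglik(cuts, beta, 0.0, ys, Xss, starts, nq_x, nq_logw)

        x0 = np.r_[free0, np.zeros(p)]
        bounds = [(None, None)] * (nfree + p)

    res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 1000, "ftol": 1e-11})
    cuts_hat = _cuts_from_free(res.x[:nfree])
    beta_hat = res.x[nfree : nfree + p]
    sigma_hat = float(res.x[-1]) if has_re else (0.0 if groups is not None else None)

    # map beta and cutpoints back to raw predictor scale
    beta_raw = beta_hat / scale
    cuts_raw = cuts_hat - float(np.sum(beta_hat * center / scale))
    n_params = nfree + p + (1 if (has_re and sigma_fixed is None) else 0)
    return GlmmFit(
        family="ordinal",
        loglik=float(-res.fun),
        n_params=n_params,
        n_obs=n,
        beta=beta_raw,
        beta_names=beta_names,
        sigma=sigma_hat,
        thresholds=cuts_raw,
        converged=bool(res.success),
        message=str(res.message),
        diagnostics={"categories": cats.tolist()},
    )
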