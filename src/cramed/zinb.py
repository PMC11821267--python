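"""Zero-inflated negative-binomial (ZINB) regression for a single taxon.

The count vector :math:`M_j` of one taxon is modelled as a mixture of a
structural zero (probability :math:`\\pi_i`) and a negative-binomial draw
with mean :math:`\\lambda_i` and dispersion :math:`\\phi` (variance
:math:`\\lambda + \\lambda^2/\\phi`), with

.. math::

    \\mathrm{logit}(\\pi_i) = \\gamma_0 + \\gamma_1 T_i + \\gamma_x^\\top X_i,
    \\qquad
    \\log(\\lambda_i) = o_i + \\alpha_0 + \\alpha_1 T_i + \\alpha_x^\\top X_i,

where :math:`o_i` is an optional per-sample offset (log sequencing depth).

Fitting runs a short EM over the latent presence-absence indicator (weighted
logistic and NB regressions as M-steps) followed by a quasi-Newton polish of
the observed-data likelihood with an analytic score.  The covariance of
:math:`(\\hat\\alpha_1, \\hat\\gamma_1)` comes from the inverse observed
information, differentiated numerically from the analytic score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "ZinbParams", "ZinbFit", "WaldResult", "zinb_logpmf", "fit_zinb",
    "sample_zinb", "wald_test", "AllZeroError", "ZinbFitError",
    "SingularCovarianceError",
]

_LOGPHI_LO, _LOGPHI_HI = -7.0, 13.0
_COEF_LO, _COEF_HI = -40.0, 40.0


class ZinbFitError(RuntimeError):
    """The ZINB optimizer failed beyond all fallbacks."""


class AllZeroError(ZinbFitError):
    """Taxon has no positive counts; the model is degenerate."""


class SingularCovarianceError(RuntimeError):
    """cov(theta) is numerically singular; the Wald test is unavailable."""


@dataclass
class ZinbParams:
    """Coefficients of the ZINB regression for one taxon.

    ``gamma*`` parameterize the logit of the structural-zero probability,
    ``alpha*`` the log of the NB mean, ``phi`` the NB dispersion.  For a
    taxon with no zeros the zero-model is non-identifiable and the gamma
    entries are NaN.
    """

    gamma0: float
    gamma1: float
    gamma_x: np.ndarray
    alpha0: float
    alpha1: float
    alpha_x: np.ndarray
    phi: float

    def __post_init__(self) -> None:
        self.gamma_x = np.atleast_1d(np.asarray(self.gamma_x, dtype=float))
        self.alpha_x = np.atleast_1d(np.asarray(self.alpha_x, dtype=float))
        if self.gamma_x.shape != self.alpha_x.shape:
            raise ValueError("gamma_x and alpha_x must have equal length")
        if not (np.isfinite(self.phi) and self.phi > 0):
            raise ValueError(f"phi must be positive and finite, got {self.phi}")


@dataclass
class ZinbFit:
    """A fitted ZINB regression with per-sample fitted quantities.

    ``fitted_mean[i] = (1 - fitted_pi[i]) * fitted_lambda[i]`` is the
    conditional mean used as the "fitted value" of the mixture model.
    ``cov_theta`` is the estimated covariance of
    ``theta = (alpha1, gamma1)``; for a no-zeros fallback fit it is 1x1
    (alpha1 only) and ``wald_df`` is 1.
    """

    params: ZinbParams
    fitted_pi: np.ndarray
    fitted_lambda: np.ndarray
    fitted_mean: np.ndarray
    cov_theta: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    wald_df: int = 2
    flags: list = field(default_factory=list)


@dataclass
class WaldResult:
    """Wald test of the treatment -> mediator path, H0: alpha1 = gamma1 = 0."""

    w2: float
    p2: float
    df: int


# ---------------------------------------------------------------------------
# log-density


def _nb_logpmf(k, lam, phi):
    # NB parameterized by mean lam and dispersion phi (variance lam+lam^2/phi)
    k = np.asarray(k, dtype=float)
    lp = (special.gammaln(k + phi) - special.gammaln(phi)
          - special.gammaln(k + 1.0)
          + phi * (np.log(phi) - np.log(phi + lam))
          + k * (np.log(lam) - np.log(phi + lam)))
    return lp


def zinb_logpmf(k, pi, lam, phi):
    """Log-pmf of the ZINB mixture at count ``k``.

    ``log(pi + (1-pi) NB(0; lam, phi))`` at zero and
    ``log(1-pi) + log NB(k; lam, phi)`` for positive counts.  Scalar or
    elementwise on broadcastable arrays.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or not np.all(np.equal(np.mod(k_arr, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    pi = np.asarray(pi, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0) or phi <= 0 or np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("require lam > 0, phi > 0 and pi in [0, 1]")
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    log_nb = _nb_logpmf(k_arr, lam, phi)
    zero_branch = np.logaddexp(log_pi, log_1mpi + phi * (np.log(phi) - np.log(phi + lam)))
    out = np.where(k_arr == 0, zero_branch, log_1mpi + log_nb)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# likelihood machinery on the packed parameter vector
#
# theta = [gamma (p), alpha (p), log(phi)] with p = 2 + q and design
# Z = [1, T, X].  The no-zeros fallback drops the gamma block.


def _unpack(theta, p):
    return theta[:p], theta[p:2 * p], theta[-1]


def _zinb_negll_grad(theta, Z, y, offset, zero_mask):
    p = Z.shape[1]
    g, a, logphi = _unpack(theta, p)
    phi = np.exp(logphi)
    eta_g = Z @ g
    eta_a = offset + Z @ a
    eta_a = np.clip(eta_a, -30.0, 30.0)
    lam = np.exp(eta_a)

    log_pi = -np.logaddexp(0.0, -eta_g)       # log sigmoid
    log_1mpi = -np.logaddexp(0.0, eta_g)
    pi = np.exp(log_pi)
    logp0 = phi * (np.log(phi) - np.log(phi + lam))
    frac = lam / (phi + lam)

    ll = np.empty_like(lam)
    dg = np.empty_like(lam)
    da = np.empty_like(lam)
    dphi_terms = np.empty_like(lam)

    zm = zero_mask
    pm = ~zero_mask
    # zero observations: mixture of structural zero and NB zero
    ll0 = np.logaddexp(log_pi[zm], log_1mpi[zm] + logp0[zm])
    ll[zm] = ll0
    A = np.exp(log_pi[zm] - ll0)              # weight on the structural-zero term
    B = 1.0 - A
    dg[zm] = A - pi[zm]
    da[zm] = -B * phi * frac[zm]
    dphi_terms[zm] = B * (np.log(phi) - np.log(phi + lam[zm]) + frac[zm])
    # positive observations
    yp = y[pm]
    lamp = lam[pm]
    ll[pm] = log_1mpi[pm] + (special.gammaln(yp + phi) - special.gammaln(phi)
                             - special.gammaln(yp + 1.0)
                             + phi * (np.log(phi) - np.log(phi + lamp))
                             + yp * (eta_a[pm] - np.log(phi + lamp)))
    dg[pm] = -pi[pm]
    da[pm] = yp - (yp + phi) * frac[pm]
    dphi_terms[pm] = (special.digamma(yp + phi) - special.digamma(phi)
                      + np.log(phi) + 1.0 - np.log(phi + lamp)
                      - (yp + phi) / (phi + lamp))

    nll = -float(np.sum(ll))
    grad = np.empty_like(theta)
    grad[:p] = -(Z.T @ dg)
    grad[p:2 * p] = -(Z.T @ da)
    grad[-1] = -phi * float(np.sum(dphi_terms))
    return nll, grad


def _nb_negll_grad(theta, Z, y, offset):
    # plain NB regression (no-zeros fallback); theta = [alpha (p), log(phi)]
    p = Z.shape[1]
    a, logphi = theta[:p], theta[-1]
    phi = np.exp(logphi)
    eta = np.clip(offset + Z @ a, -30.0, 30.0)
    lam = np.exp(eta)
    ll = (special.gammaln(y + phi) - special.gammaln(phi)
          - special.gammaln(y + 1.0)
          + phi * (np.log(phi) - np.log(phi + lam))
          + y * (eta - np.log(phi + lam)))
    da = y - (y + phi) * lam / (phi + lam)
    dphi = (special.digamma(y + phi) - special.digamma(phi)
            + np.log(phi) + 1.0 - np.log(phi + lam)
            - (y + phi) / (phi + lam))
    grad = np.empty_like(theta)
    grad[:p] = -(Z.T @ da)
    grad[-1] = -phi * float(np.sum(dphi))
    return -float(np.sum(ll)), grad


def _numeric_hessian(grad_fn, theta):
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# initialization and EM refinement


def _irls_logistic(Z, w, ridge=1e-6, n_iter=15):
    # weighted logistic regression with fractional responses w in [0,1]
    p = Z.shape[1]
    beta = np.zeros(p)
    for _ in range(n_iter):
        eta = np.clip(Z @ beta, -30, 30)
        mu = special.expit(eta)
        W = np.maximum(mu * (1 - mu), 1e-8)
        z = eta + (w - mu) / W
        A = (Z * W[:, None]).T @ Z + ridge * np.eye(p)
        beta_new = np.linalg.solve(A, (Z * W[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _irls_poisson(Z, y, offset, weights=None, ridge=1e-6, n_iter=25):
    p = Z.shape[1]
    w = np.ones_like(y, dtype=float) if weights is None else weights
    mu0 = max(float(np.sum(w * y) / max(np.sum(w), 1e-12)), 0.1)
    beta = np.zeros(p)
    beta[0] = np.log(mu0) - float(np.mean(offset))
    for _ in range(n_iter):
        eta = np.clip(offset + Z @ beta, -30, 30)
        mu = np.exp(eta)
        W = np.maximum(w * mu, 1e-10)
        z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-10)
        A = (Z * W[:, None]).T @ Z + ridge * np.eye(p)
        beta_new = np.linalg.solve(A, (Z * W[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _moment_phi(y, mu, weights=None):
    w = np.ones_like(mu) if weights is None else weights
    sw = max(float(np.sum(w)), 1e-12)
    excess = float(np.sum(w * ((y - mu) ** 2 - mu)) / sw)
    mu2 = float(np.sum(w * mu ** 2) / sw)
    if excess <= 0 or mu2 <= 0:
        return 10.0  # near-Poisson
    return float(np.clip(mu2 / excess, 1e-3, 1e5))


def _init_theta(Z, y, offset):
    zero = (y == 0).astype(float)
    g = _irls_logistic(Z, zero)
    pos = y > 0
    a = _irls_poisson(Z[pos], y[pos].astype(float), offset[pos])
    mu = np.exp(np.clip(offset[pos] + Z[pos] @ a, -30, 30))
    phi = _moment_phi(y[pos].astype(float), mu)
    return np.concatenate([g, a, [np.log(phi)]])


def _em_refine(theta, Z, y, offset, zero_mask, n_steps):
    p = Z.shape[1]
    yf = y.astype(float)
    for _ in range(n_steps):
        g, a, logphi = _unpack(theta, p)
        phi = np.exp(logphi)
        eta_g = np.clip(Z @ g, -30, 30)
        lam = np.exp(np.clip(offset + Z @ a, -30, 30))
        log_pi = -np.logaddexp(0.0, -eta_g)
        log_1mpi = -np.logaddexp(0.0, eta_g)
        logp0 = phi * (np.log(phi) - np.log(phi + lam))
        w = np.zeros_like(lam)
        w[zero_mask] = np.exp(log_pi[zero_mask] - np.logaddexp(
            log_pi[zero_mask], log_1mpi[zero_mask] + logp0[zero_mask]))
        # M-steps: weighted logistic for gamma, weighted Poisson-like for alpha
        g = _irls_logistic(Z, w, n_iter=8)
        cw = 1.0 - w
        a = _irls_poisson(Z, yf, offset, weights=cw, n_iter=8)
        mu = np.exp(np.clip(offset + Z @ a, -30, 30))
        phi = _moment_phi(yf, mu, weights=cw)
        theta = np.concatenate([g, a, [np.log(phi)]])
    return theta


# ---------------------------------------------------------------------------
# public fitting API


def _design(treatment, covariates, n):
    t = np.asarray(treatment, dtype=float).reshape(-1)
    if t.shape[0] != n:
        raise ValueError("treatment length does not match counts")
    if covariates is None or (hasattr(covariates, "size") and np.asarray(covariates).size == 0):
        X = np.empty((n, 0))
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("covariates row count does not match counts")
    return np.column_stack([np.ones(n), t, X])


def fit_zinb(counts, treatment, covariates=None, offset=None, *,
             start=None, em_steps=4, maxiter=200, retry=True):
    """Fit the ZINB regression of one taxon's counts on treatment (+ covariates).

    Parameters
    ----------
    counts : array of non-negative integers, length n
    treatment : binary array, length n
    covariates : (n, q) array or None
    offset : length-n array added to the log-mean (log sequencing depth),
        or None for no offset
    start : optional packed start vector (warm start, used when re-fitting
        conditional-randomization resamples)
    em_steps : EM refinement iterations before the quasi-Newton polish
    retry : restart once from a perturbed init on optimizer failure

    Returns
    -------
    ZinbFit
        With ``converged=False`` (never an exception) if every fallback ran
        out; callers must check the flag.  A taxon with no positive count
        raises :class:`AllZeroError`; a taxon with no zero count falls back
        to a plain NB fit with a 1-df Wald covariance.
    """
    y = np.asarray(counts)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    y = y.astype(np.int64)
    n = y.shape[0]
    if n < 10:
        raise ValueError("need at least 10 observations to fit the ZINB model")
    if not np.any(y > 0):
        raise AllZeroError("all counts are zero; taxon must be skipped")
    Z = _design(treatment, covariates, n)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float).reshape(-1)
    if off.shape[0] != n:
        raise ValueError("offset length does not match counts")

    if not np.any(y == 0):
        return _fit_nb_only(Z, y, off, flags=["no-zeros: NB fallback"])

    zero_mask = y == 0
    p = Z.shape[1]
    if start is not None:
        theta0 = np.asarray(start, dtype=float).copy()
    else:
        theta0 = _init_theta(Z, y, off)
        if em_steps > 0:
            theta0 = _em_refine(theta0, Z, y, off, zero_mask, em_steps)
    theta0 = _clip_theta(theta0)

    bounds = [(_COEF_LO, _COEF_HI)] * (2 * p) + [(_LOGPHI_LO, _LOGPHI_HI)]
    res = optimize.minimize(
        _zinb_negll_grad, theta0, args=(Z, y, off, zero_mask),
        method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    flags: list = []
    if not res.success and retry:
        rng = np.random.default_rng(np.abs(int(np.sum(y))) % (2**31))
        theta_r = _clip_theta(theta0 + 0.25 * rng.standard_normal(theta0.size))
        res2 = optimize.minimize(
            _zinb_negll_grad, theta_r, args=(Z, y, off, zero_mask),
            method="L-BFGS-B", jac=True, bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        if res2.fun < res.fun or res2.success:
            res = res2
            flags.append("em-restart")
    if not res.success and not np.isfinite(res.fun):
        nb = _fit_nb_only(Z, y, off, flags=["zinb-optimizer-failed: NB fallback"])
        nb.converged = False
        return nb

    theta = res.x
    g, a, logphi = _unpack(theta, p)
    phi = float(np.exp(logphi))
    pi = special.expit(Z @ g)
    lam = np.exp(np.clip(off + Z @ a, -30, 30))
    cov_theta, cov_flag = _cov_block(
        lambda t: _zinb_negll_grad(t, Z, y, off, zero_mask)[1],
        theta, idx=(p + 1, 1))
    if cov_flag:
        flags.append(cov_flag)
    params = ZinbParams(
        gamma0=float(g[0]), gamma1=float(g[1]), gamma_x=g[2:].copy(),
        alpha0=float(a[0]), alpha1=float(a[1]), alpha_x=a[2:].copy(), phi=phi,
    )
    return ZinbFit(
        params=params, fitted_pi=pi, fitted_lambda=lam,
        fitted_mean=(1.0 - pi) * lam, cov_theta=cov_theta,
        loglik=-float(res.fun), converged=bool(res.success),
        n_obs=n, wald_df=2, flags=flags,
    )


def _clip_theta(theta):
    theta = theta.copy()
    theta[:-1] = np.clip(theta[:-1], _COEF_LO + 1, _COEF_HI - 1)
    theta[-1] = np.clip(theta[-1], _LOGPHI_LO + 0.5, _LOGPHI_HI - 0.5)
    return theta


def _cov_block(grad_fn, theta, idx):
    """Invert the numerically differentiated observed information and
    extract the covariance block of theta[idx] (order preserved)."""
    H = _numeric_hessian(grad_fn, theta)
    flag = None
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(H)
        flag = "information-singular: pseudo-inverse covariance"
    ix = np.asarray(idx)
    cov = cov_full[np.ix_(ix, ix)]
    cov = 0.5 * (cov + cov.T)
    if np.any(np.diag(cov) < 0):
        flag = "negative-variance: covariance unreliable"
    return cov, flag


def _fit_nb_only(Z, y, off, flags):
    p = Z.shape[1]
    a0 = _irls_poisson(Z, y.astype(float), off)
    mu = np.exp(np.clip(off + Z @ a0, -30, 30))
    theta0 = np.concatenate([a0, [np.log(_moment_phi(y.astype(float), mu))]])
    bounds = [(_COEF_LO, _COEF_HI)] * p + [(_LOGPHI_LO, _LOGPHI_HI)]
    res = optimize.minimize(
        _nb_negll_grad, theta0, args=(Z, y.astype(float), off),
        method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-11},
    )
    a, logphi = res.x[:p], res.x[-1]
    phi = float(np.exp(logphi))
    lam = np.exp(np.clip(off + Z @ a, -30, 30))
    cov, cov_flag = _cov_block(
        lambda t: _nb_negll_grad(t, Z, y.astype(float), off)[1],
        res.x, idx=(1,))
    if cov_flag:
        flags = flags + [cov_flag]
    q = p - 2
    params = ZinbParams(
        gamma0=np.nan, gamma1=np.nan, gamma_x=np.full(q, np.nan),
        alpha0=float(a[0]), alpha1=float(a[1]), alpha_x=a[2:].copy(), phi=phi,
    )
    return ZinbFit(
        params=params, fitted_pi=np.zeros(y.shape[0]), fitted_lambda=lam,
        fitted_mean=lam, cov_theta=cov, loglik=-float(res.fun),
        converged=bool(res.success), n_obs=y.shape[0], wald_df=1, flags=flags,
    )


def packed_params(fit: ZinbFit) -> np.ndarray:
    """Packed parameter vector of a (full) ZINB fit, for warm starts."""
    p = fit.params
    return np.concatenate([
        [p.gamma0, p.gamma1], p.gamma_x,
        [p.alpha0, p.alpha1], p.alpha_x,
        [np.log(p.phi)],
    ])


def sample_zinb(fit: ZinbFit, rng: np.random.Generator) -> np.ndarray:
    """Draw one count vector from the fitted ZINB model.

    Each entry is 0 with its fitted structural-zero probability, otherwise a
    gamma-Poisson (NB) draw with the fitted mean and dispersion.
    """
    lam = fit.fitted_lambda
    phi = fit.params.phi
    n = lam.shape[0]
    y = rng.poisson(rng.gamma(shape=phi, scale=lam / phi))
    structural = rng.random(n) < fit.fitted_pi
    y[structural] = 0
    return y


def wald_test(fit: ZinbFit) -> WaldResult:
    """Wald test of H0: alpha1 = gamma1 = 0 (treatment -> mediator path).

    W^2 = theta' cov(theta)^{-1} theta with theta = (alpha1, gamma1) and an
    asymptotic chi-square reference with 2 df (1 df for the no-zeros NB
    fallback, where only alpha1 is testable).
    """
    if fit.wald_df == 1:
        theta = np.array([fit.params.alpha1])
    else:
        theta = np.array([fit.params.alpha1, fit.params.gamma1])
    cov = np.atleast_2d(fit.cov_theta)
    try:
        sol = np.linalg.solve(cov, theta)
    except np.linalg.LinAlgError as err:
        raise SingularCovarianceError(str(err)) from err
    if not np.all(np.isfinite(sol)):
        raise SingularCovarianceError("non-finite Wald solve")
    w2 = float(theta @ sol)
    if w2 < 0:
        raise SingularCovarianceError("covariance not positive definite")
    p2 = float(stats.chi2.sf(w2, df=fit.wald_df))
    return WaldResult(w2=w2, p2=p2, df=fit.wald_df)
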