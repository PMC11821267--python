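"""Synthetic microbiome mediation datasets with known causal taxa.

Three generators share one coefficient scheme over ``m >= 26`` taxa:

==========  ==============  ==============  ===========
taxa (1-based)  gamma1          alpha1          beta_m
==========  ==============  ==============  ===========
1-3         N(mu_path,1)    N(mu_path,1)    N(mu_out,1)
4           0               N(mu_path,1)    N(mu_out,1)
5           N(mu_path,1)    0               N(mu_out,1)
6-10        0               0               N(mu_out,1)
11-15       N(mu_path,1)    N(mu_path,1)    0
16-20       N(mu_path,1)    0               0
21-25       0               N(mu_path,1)    0
26-m        0               0               0
==========  ==============  ==============  ===========

with ``mu_path = -2`` and ``mu_out = 2`` by default, plus
``gamma0 ~ U(-2,2)``, ``phi ~ U(0.1,10)``, ``alpha0 = -7``, ``beta0 = 1``,
``beta1 = -2``, ``sigma2 = 1``.  A taxon is a causal mediator iff its
outcome coefficient is nonzero AND at least one treatment -> mediator
coefficient is nonzero: exactly taxa 1-5.

Counts are drawn from a ZINB mixture, or from hurdle (zero-truncated)
Poisson/NB variants, with a Bernoulli(0.5) treatment and per-sample log
depths ``log S_i ~ U(7.1, 10.5)`` entering the count mean as an offset.
The confounded variant draws treatment and outcome through d unmeasured
Gaussian confounders with strength ``h``, breaking the no-unmeasured-
confounding assumption for the treatment-outcome relationship.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats

__all__ = [
    "CoefficientScheme", "SimData", "draw_scheme", "simulate_zinb_dataset",
    "hurdle_logpmf", "simulate_hurdle_dataset", "simulate_confounded_dataset",
]


@dataclass
class CoefficientScheme:
    """Per-taxon generating coefficients and shared outcome parameters."""

    gamma0: np.ndarray
    gamma1: np.ndarray
    alpha0: float
    alpha1: np.ndarray
    beta_m: np.ndarray
    phi: np.ndarray
    beta0: float = 1.0
    beta1: float = -2.0
    sigma2: float = 1.0

    @property
    def m(self) -> int:
        return self.gamma1.shape[0]

    @property
    def truth(self) -> np.ndarray:
        """Causal-mediator labels: beta_m != 0 and (alpha1, gamma1) != (0, 0)."""
        return (self.beta_m != 0) & ((self.alpha1 != 0) | (self.gamma1 != 0))


@dataclass
class SimData:
    """One simulated dataset with its generating truth attached."""

    M: np.ndarray
    T: np.ndarray
    Y: np.ndarray
    log_depth: np.ndarray
    scheme: CoefficientScheme
    truth: np.ndarray
    generator: str
    seed: Optional[int]
    X_u: Optional[np.ndarray] = None


def draw_scheme(m, rng, *, path_mean=-2.0, outcome_mean=2.0) -> CoefficientScheme:
    """Draw the class-structured coefficient scheme for ``m`` taxa."""
    if m < 26:
        raise ValueError("the coefficient class structure needs m >= 26")
    rng = np.random.default_rng(rng)
    gamma0 = rng.uniform(-2.0, 2.0, size=m)
    phi = rng.uniform(0.1, 10.0, size=m)
    gamma1 = np.zeros(m)
    alpha1 = np.zeros(m)
    beta_m = np.zeros(m)

    def npath(size):
        return rng.normal(path_mean, 1.0, size=size)

    def nout(size):
        return rng.normal(outcome_mean, 1.0, size=size)

    # 0-based slices of the 1-based class table in the module docstring
    gamma1[0:3] = npath(3);  alpha1[0:3] = npath(3);  beta_m[0:3] = nout(3)
    alpha1[3] = npath(1)[0]; beta_m[3] = nout(1)[0]            # taxon 4
    gamma1[4] = npath(1)[0]; beta_m[4] = nout(1)[0]            # taxon 5
    beta_m[5:10] = nout(5)                                     # taxa 6-10
    gamma1[10:15] = npath(5); alpha1[10:15] = npath(5)         # taxa 11-15
    gamma1[15:20] = npath(5)                                   # taxa 16-20
    alpha1[20:25] = npath(5)                                   # taxa 21-25
    return CoefficientScheme(gamma0=gamma0, gamma1=gamma1, alpha0=-7.0,
                             alpha1=alpha1, beta_m=beta_m, phi=phi)


def _shared_draws(n, rng):
    T = (rng.random(n) < 0.5).astype(np.int64)
    log_depth = rng.uniform(7.1, 10.5, size=n)
    return T, log_depth


def _linpreds(scheme, T, log_depth):
    pi = special.expit(scheme.gamma0[None, :] + scheme.gamma1[None, :] * T[:, None])
    lam = np.exp(log_depth[:, None] + scheme.alpha0
                 + scheme.alpha1[None, :] * T[:, None])
    return pi, lam


def _outcome(scheme, T, M, rng, extra=0.0):
    mu = scheme.beta0 + scheme.beta1 * T + M @ scheme.beta_m + extra
    return mu + np.sqrt(scheme.sigma2) * rng.standard_normal(T.shape[0])


def simulate_zinb_dataset(n, m, seed, *, scheme=None) -> SimData:
    """ZINB-mixture counts, Bernoulli(0.5) treatment, Gaussian outcome."""
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    if scheme is None:
        scheme = draw_scheme(m, rng)
    T, log_depth = _shared_draws(n, rng)
    pi, lam = _linpreds(scheme, T, log_depth)
    counts = rng.poisson(rng.gamma(shape=scheme.phi[None, :], scale=lam / scheme.phi[None, :]))
    counts[rng.random((n, scheme.m)) < pi] = 0
    Y = _outcome(scheme, T, counts, rng)
    return SimData(M=counts, T=T, Y=Y, log_depth=log_depth, scheme=scheme,
                   truth=scheme.truth, generator="zinb",
                   seed=seed if np.isscalar(seed) else None)


def hurdle_logpmf(k, pi, lam, phi):
    """Log-pmf of the hurdle (zero-truncated) count model.

    ``P(M=0) = pi`` and for k >= 1 the zero-truncated NB,
    ``(1-pi) NB(k)/(1-NB(0))``; ``phi = inf`` gives the hurdle Poisson.
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
    if np.isinf(phi):
        log_nb = stats.poisson.logpmf(k_arr, lam)
        log_p0 = -lam
    else:
        log_nb = stats.nbinom.logpmf(k_arr, phi, phi / (phi + lam))
        log_p0 = phi * (np.log(phi) - np.log(phi + lam))
    with np.errstate(divide="ignore", invalid="ignore"):
        log_trunc = log_1mpi + log_nb - np.log(-np.expm1(log_p0))
    out = np.where(k_arr == 0, log_pi, log_trunc)
    return out if out.ndim else float(out)


def _sample_truncated(rng, lam, phi):
    """Zero-truncated NB via inverse CDF (uniform on the positive tail)."""
    p0 = np.exp(phi * (np.log(phi) - np.log(phi + lam)))
    u = p0 + (1 - p0) * rng.random(lam.shape)
    with np.errstate(invalid="ignore"):
        draw = stats.nbinom.ppf(np.minimum(u, 1 - 1e-16), phi, phi / (phi + lam))
    return np.maximum(draw, 1).astype(np.int64)


def simulate_hurdle_dataset(n, m, family, seed, *, scheme=None) -> SimData:
    """Hurdle-count variant: zero w.p. pi, else a zero-truncated NB/Poisson."""
    if family not in ("poisson", "nb"):
        raise ValueError("family must be 'poisson' or 'nb'")
    rng = np.random.default_rng(seed)
    if scheme is None:
        scheme = draw_scheme(m, rng)
    T, log_depth = _shared_draws(n, rng)
    pi, lam = _linpreds(scheme, T, log_depth)
    counts = np.zeros((n, scheme.m), dtype=np.int64)
    nonzero = rng.random((n, scheme.m)) >= pi
    for j in range(scheme.m):
        idx = nonzero[:, j]
        if not np.any(idx):
            continue
        phi_j = np.inf if family == "poisson" else scheme.phi[j]
        if family == "poisson":
            p0 = np.exp(-lam[idx, j])
            u = p0 + (1 - p0) * rng.random(int(idx.sum()))
            counts[idx, j] = np.maximum(stats.poisson.ppf(u, lam[idx, j]), 1).astype(np.int64)
        else:
            counts[idx, j] = _sample_truncated(rng, lam[idx, j], phi_j)
    Y = _outcome(scheme, T, counts, rng)
    return SimData(M=counts, T=T, Y=Y, log_depth=log_depth, scheme=scheme,
                   truth=scheme.truth, generator=f"hurdle_{family}",
                   seed=seed if np.isscalar(seed) else None)


def simulate_confounded_dataset(n, m, h, d=3, seed=None, *, scheme=None) -> SimData:
    """ZINB counts with ``d`` unmeasured Gaussian confounders of strength ``h``.

    The confounders drive both the treatment (logit(eta_i) = Delta_u'X_i^u)
    and the outcome (additive beta_u'X_i^u term), with Delta_u and beta_u
    drawn i.i.d. from N(0.2h, 0.5); larger h means stronger confounding.
    The treatment-path and outcome coefficients of the scheme are amplified
    (means -5 and +5) so the mediation signal is strong relative to the
    confounding noise.
    """
    rng = np.random.default_rng(seed)
    if scheme is None:
        scheme = draw_scheme(m, rng, path_mean=-5.0, outcome_mean=5.0)
    X_u = rng.standard_normal((n, d))
    sd = np.sqrt(0.5)
    delta_u = rng.normal(0.2 * h, sd, size=d)
    beta_u = rng.normal(0.2 * h, sd, size=d)
    T = (rng.random(n) < special.expit(X_u @ delta_u)).astype(np.int64)
    log_depth = rng.uniform(7.1, 10.5, size=n)
    pi, lam = _linpreds(scheme, T, log_depth)
    counts = rng.poisson(rng.gamma(shape=scheme.phi[None, :], scale=lam / scheme.phi[None, :]))
    counts[rng.random((n, scheme.m)) < pi] = 0
    Y = _outcome(scheme, T, counts, rng, extra=X_u @ beta_u)
    return SimData(M=counts, T=T, Y=Y, log_depth=log_depth, scheme=scheme,
                   truth=scheme.truth, generator="confounded",
                   seed=seed if np.isscalar(seed) else None, X_u=X_u)
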