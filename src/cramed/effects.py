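"""Natural direct/indirect effects and the presence-absence vs abundance split.

With outcome model ``Y = beta0 + beta1*T + beta_x'X + beta_m'M + eps`` and the
ZINB mediator model, the per-taxon natural indirect effect evaluated at the
covariate profile ``x`` is

    NIE_j  = beta_mj * (a1/g1 - a0/g0)
    NIEP_j = beta_mj * (a1/g1 - a1/g0)      (through the presence indicator)
    NIEA_j = beta_mj * (a1/g0 - a0/g0)      (through abundance when present)

where ``a_t = exp(alpha0 + alpha1*t + alpha_x'x)`` and
``g_t = 1 + exp(gamma0 + gamma1*t + gamma_x'x)``; NIE_j = NIEP_j + NIEA_j is
an algebraic identity.  The natural direct effect is beta1.  All ratios are
evaluated in log space so large linear predictors cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .zinb import fit_zinb, ZinbFit

__all__ = [
    "EffectEstimate", "EffectCI", "nie_components", "total_nie",
    "estimate_effects", "effect_ci",
]


@dataclass
class EffectEstimate:
    """Point estimates of NDE and the per-taxon NIE decomposition."""

    nde: float
    nie_j: dict
    niep_j: dict
    niea_j: dict
    x_profile: np.ndarray
    beta_m: dict
    beta0: float
    sigma2: float


@dataclass
class EffectCI:
    """A percentile resampling interval for one effect component."""

    point: float
    lower: float
    upper: float
    level: float = 0.95
    n_rep: int = 1000


def _log1pexp(z):
    return np.logaddexp(0.0, z)


def nie_components(beta_mj, alpha0j, alpha1j, alpha_xj, gamma0j, gamma1j,
                   gamma_xj, x):
    """Return ``(nie, niep, niea)`` for one taxon at covariate profile ``x``.

    A taxon with no identifiable zero model (NaN gammas, i.e. a structurally
    always-present taxon) has g1 = g0 = 1: the presence path carries nothing
    and the whole effect is abundance-mediated.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    ax = np.atleast_1d(np.asarray(alpha_xj, dtype=float))
    gx = np.atleast_1d(np.asarray(gamma_xj, dtype=float))
    if ax.size != x.size or gx.size != x.size:
        raise ValueError("covariate profile length mismatch")
    la0 = alpha0j + float(ax @ x)
    la1 = la0 + alpha1j
    if np.isnan(gamma0j):  # always-present taxon: pi == 0
        lg0 = lg1 = -np.inf
    else:
        lg0 = gamma0j + float(gx @ x)
        lg1 = lg0 + gamma1j
    t11 = np.exp(la1 - _log1pexp(lg1))  # a1/g1
    t10 = np.exp(la1 - _log1pexp(lg0))  # a1/g0
    t00 = np.exp(la0 - _log1pexp(lg0))  # a0/g0
    nie = beta_mj * (t11 - t00)
    niep = beta_mj * (t11 - t10)
    niea = beta_mj * (t10 - t00)
    return float(nie), float(niep), float(niea)


def total_nie(per_taxon_nie) -> float:
    """Total natural indirect effect: the sum of per-taxon components."""
    return float(np.sum(np.asarray(list(per_taxon_nie), dtype=float))) \
        if len(list(per_taxon_nie)) else 0.0


def _ols(design, y):
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the collinear ones
        _, _, piv = linalg.qr(design, pivoting=True, mode="economic")
        bad = sorted(piv[rank:].tolist())
        raise ValueError(f"design is rank-deficient; collinear columns {bad}")
    resid = y - design @ beta
    return beta, resid


def estimate_effects(Y, T, X, M, selected, x_profile=None, offset=None,
                     *, fits=None) -> EffectEstimate:
    """Post-selection effect estimation for the taxa in ``selected``.

    Outcome coefficients come from an unpenalized least-squares regression of
    Y on (T, X, M_selected); mediator coefficients from per-taxon ZINB fits
    (reused from ``fits`` when provided); effects from
    :func:`nie_components` at ``x_profile`` (default: the zero/reference
    covariate profile).
    """
    Y = np.asarray(Y, dtype=float).reshape(-1)
    T = np.asarray(T, dtype=float).reshape(-1)
    n = Y.shape[0]
    if np.unique(T).size < 2:
        raise ValueError("treatment is constant; no contrast to estimate")
    X = np.empty((n, 0)) if X is None else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    M = np.asarray(M)
    selected = list(selected)
    if not selected:
        raise ValueError("selected taxon set is empty")
    q = X.shape[1]
    x = np.zeros(q) if x_profile is None else np.atleast_1d(np.asarray(x_profile, float))

    design = np.column_stack([np.ones(n), T, X, M[:, selected].astype(float)])
    beta, resid = _ols(design, Y)
    dof = max(n - design.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    beta0, beta1 = float(beta[0]), float(beta[1])
    beta_m = {j: float(beta[2 + q + k]) for k, j in enumerate(selected)}

    nie_j, niep_j, niea_j = {}, {}, {}
    for j in selected:
        fit = fits.get(j) if fits else None
        if fit is None:
            fit = fit_zinb(M[:, j], T, X if q else None, offset)
        p = fit.params
        nie_j[j], niep_j[j], niea_j[j] = nie_components(
            beta_m[j], p.alpha0, p.alpha1, p.alpha_x,
            p.gamma0, p.gamma1, p.gamma_x, x)
    return EffectEstimate(
        nde=beta1, nie_j=nie_j, niep_j=niep_j, niea_j=niea_j,
        x_profile=x, beta_m=beta_m, beta0=beta0, sigma2=sigma2,
    )


def effect_ci(Y, T, X, M, taxon, n_rep=1000, level=0.95, rng=None,
              offset=None, x_profile=None):
    """Nonparametric-bootstrap percentile intervals for one taxon's
    (NIE, NIEP, NIEA).

    Samples rows with replacement, re-estimates the effect decomposition on
    each resample, and takes percentile intervals.  Resamples where the
    re-fit fails (constant treatment, all-zero taxon, optimizer failure) are
    dropped; more than 20% failures raises.
    """
    if n_rep <= 0:
        raise ValueError("n_rep must be a positive integer")
    rng = np.random.default_rng(rng)
    Y = np.asarray(Y, dtype=float).reshape(-1)
    T = np.asarray(T, dtype=float).reshape(-1)
    n = Y.shape[0]
    X = None if X is None or np.asarray(X).size == 0 else np.asarray(X, float)
    M = np.asarray(M)
    off = None if offset is None else np.asarray(offset, dtype=float)

    point = estimate_effects(Y, T, X, M, [taxon], x_profile, off)
    draws = np.full((n_rep, 3), np.nan)
    failures = 0
    for b in range(n_rep):
        idx = rng.integers(0, n, size=n)
        try:
            est = estimate_effects(
                Y[idx], T[idx], None if X is None else X[idx], M[idx],
                [taxon], x_profile, None if off is None else off[idx])
            draws[b] = (est.nie_j[taxon], est.niep_j[taxon], est.niea_j[taxon])
        except Exception:
            failures += 1
    if failures > 0.2 * n_rep:
        raise RuntimeError(
            f"{failures}/{n_rep} bootstrap re-fits failed; interval unreliable")
    ok = draws[~np.isnan(draws).any(axis=1)]
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    out = {}
    for k, name in enumerate(("nie", "niep", "niea")):
        pt = (point.nie_j, point.niep_j, point.niea_j)[k][taxon]
        lo, hi = np.percentile(ok[:, k], [lo_q, hi_q])
        out[name] = EffectCI(point=float(pt), lower=float(lo), upper=float(hi),
                             level=level, n_rep=n_rep)
    return out
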