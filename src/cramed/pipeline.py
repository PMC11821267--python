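"""The CRAmed testing pipeline.

For each candidate taxon j the null of no mediation is composite:

    H0j:  beta_mj = 0   or   alpha1j = gamma1j = 0.

The first branch (mediator -> outcome) is tested with a zero-inflated
distilled conditional randomization test (zidCRT): the taxon's counts are
re-drawn B times from its fitted ZINB law given (T, X), each draw is re-fit,
and the observed residual-alignment statistic

    |(Y - Yhat_j)' (Mj - Mhat_j)| / ||Mj - Mhat_j||_2

is ranked among the resampled ones.  Here Yhat_j is a cross-validated LASSO
fit of Y on (T, X, M_{-j}) ("distillation") and Mhat_j the fitted ZINB
conditional mean.  The second branch (treatment -> mediator) is a 2-df Wald
test on (alpha1, gamma1).  Joint significance takes pmax = max(p1, p2),
Benjamini-Hochberg adjusts pmax across the screened set D (taxa with a
nonzero coefficient in a cross-validated LASSO of Y on T, X and all
mediators), and taxa with adjusted pmax below the FDR level are reported as
mediators together with their NIE decomposition.

``run_naive_cramed`` is the Gaussian baseline: identical pipeline, but the
mediator model is a linear regression of log(count+1) on (T, X) with
Gaussian resampling and a 1-df Wald test on the slope.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .zinb import (
    fit_zinb, sample_zinb, wald_test, packed_params,
    AllZeroError, ZinbFitError, SingularCovarianceError,
)
from .effects import estimate_effects, effect_ci

__all__ = [
    "CramedConfig", "CramedResult", "ScreenResult", "TaxonResult",
    "screen_mediators", "distill_outcome", "crt_statistic", "zidcrt_pvalue",
    "joint_significance", "bh_adjust", "run_cramed", "run_naive_cramed",
    "DegenerateStatisticError",
]


class DegenerateStatisticError(RuntimeError):
    """The mediator residual has zero norm; the CRT statistic is undefined."""


@dataclass
class CramedConfig:
    """Tuning knobs of the pipeline.

    B is the number of conditional-randomization resamples (the p-value
    floor is 1/(B+1)); fdr the Benjamini-Hochberg level; offset_mode one of
    ``"library-size"`` (log of per-sample totals), ``"none"``, or
    ``"provided"`` (caller passes the log-depth vector, e.g. the true
    simulated one).  ``refit_resamples=False`` reuses the original fitted
    means for the resampled statistics instead of re-fitting each draw
    (faster, slightly anticonservative; off by default).
    """

    B: int = 100
    fdr: float = 0.05
    seed: int = 0
    do_screen: bool = True
    offset_mode: str = "library-size"
    n_folds: int = 10
    refit_resamples: bool = True
    compute_ci: bool = True
    ci_reps: int = 1000
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.offset_mode not in ("library-size", "none", "provided"):
            raise ValueError(f"unknown offset_mode {self.offset_mode!r}")


@dataclass
class ScreenResult:
    """Outcome of the LASSO screening step: the candidate set D."""

    D: list
    lambda_chosen: float
    n_folds: int


@dataclass
class TaxonResult:
    """Per-taxon p-values, selection flag and effect decomposition."""

    taxon: int
    p1: float
    p2: float
    pmax: float
    p_adj: float = np.nan
    selected: bool = False
    nie: float = np.nan
    niep: float = np.nan
    niea: float = np.nan
    ci: Optional[dict] = None
    flags: list = field(default_factory=list)


@dataclass
class CramedResult:
    """Full pipeline output: tested taxa, screen info and global effects."""

    results: list
    screen: Optional[ScreenResult]
    config: CramedConfig
    method: str
    nde: float = np.nan
    skipped: list = field(default_factory=list)

    @property
    def selected(self) -> list:
        return [r.taxon for r in self.results if r.selected]

    def selected_mask(self, m: int) -> np.ndarray:
        mask = np.zeros(m, dtype=bool)
        mask[self.selected] = True
        return mask


# ---------------------------------------------------------------------------
# LASSO screening / distillation (treatment and covariates unpenalized)


def _tx_design(T, X, n):
    if X is None or np.asarray(X).size == 0:
        X = np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(n), np.asarray(T, dtype=float), X])


def _residualizer(P):
    Q, _ = np.linalg.qr(P)

    def resid(v):
        return v - Q @ (Q.T @ v)

    return Q, resid


class _LassoEngine:
    """CV-LASSO of Y on (T, X, M) with the (1, T, X) block unpenalized.

    Profiling out the unpenalized block reduces the problem to a LASSO of
    the (T, X)-residualized outcome on the residualized, standardized
    mediator columns.  The cross-validation is run once per dataset; the
    CV-minimum penalty (best prediction) is reused for every leave-one-
    mediator-out distillation fit, while screening uses the sparser
    one-standard-error penalty.
    """

    def __init__(self, Y, T, X, Mmat, config):
        self.Y = np.asarray(Y, dtype=float).reshape(-1)
        n = self.Y.shape[0]
        if np.ptp(self.Y) == 0:
            raise ValueError("outcome is constant")
        if n < 2 * config.n_folds:
            raise ValueError("need n >= 2 * n_folds for cross-validation")
        self.config = config
        self.Mmat = np.asarray(Mmat, dtype=float)
        self.P = _tx_design(T, X, n)
        _, self._resid = _residualizer(self.P)
        self.Yr = self._resid(self.Y)
        Mr = self._resid(self.Mmat)
        self.sd = Mr.std(axis=0)
        self.keep = self.sd > 1e-12
        self.Ms = Mr[:, self.keep] / self.sd[self.keep]
        self._kept_cols = np.flatnonzero(self.keep)
        self.alpha_min = np.nan
        self.alpha_1se = np.nan
        self._coef_1se = np.zeros(self.Mmat.shape[1])
        if self.Ms.shape[1] and np.ptp(self.Yr) > 0:
            cv = KFold(n_splits=config.n_folds, shuffle=True,
                       random_state=config.seed % (2**31))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = LassoCV(cv=cv, fit_intercept=False, alphas=50,
                                eps=1e-2, max_iter=10000, tol=1e-4)
                model.fit(self.Ms, self.Yr)
                self.alpha_min = float(model.alpha_)
                mse = model.mse_path_.mean(axis=1)
                se = (model.mse_path_.std(axis=1, ddof=1)
                      / np.sqrt(model.mse_path_.shape[1]))
                i_min = int(np.argmin(mse))
                ok = mse <= mse[i_min] + se[i_min]
                self.alpha_1se = float(model.alphas_[ok].max())
                coef_1se = self._lasso_at(self.alpha_1se)
            self._coef_1se[self.keep] = coef_1se / self.sd[self.keep]

    def _lasso_at(self, alpha, cols=slice(None)):
        model = Lasso(alpha=alpha, fit_intercept=False, max_iter=10000,
                      tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(self.Ms[:, cols], self.Yr)
        return model.coef_

    def screen(self) -> "ScreenResult":
        D = np.flatnonzero(self._coef_1se != 0.0).tolist()
        return ScreenResult(D=D, lambda_chosen=self.alpha_1se,
                            n_folds=self.config.n_folds)

    def distill(self, j) -> np.ndarray:
        """Fitted values of the LASSO of Y on (T, X, M_{-j}) at the
        CV-minimum penalty, mapped back to the original scale."""
        m = self.Mmat.shape[1]
        if not 0 <= j < m:
            raise IndexError(f"taxon index {j} out of range")
        b_m = np.zeros(m)
        mask = self._kept_cols != j
        if np.any(mask) and np.isfinite(self.alpha_min):
            coef_s = self._lasso_at(self.alpha_min, cols=mask)
            kept = self._kept_cols[mask]
            b_m[kept] = coef_s / self.sd[kept]
        b_m[j] = 0.0
        target = self.Y - self.Mmat @ b_m
        b_tx, *_ = np.linalg.lstsq(self.P, target, rcond=None)
        return self.P @ b_tx + self.Mmat @ b_m


def screen_mediators(Y, T, M, X=None, config=None) -> ScreenResult:
    """LASSO screen: D = taxa with a nonzero coefficient in the CV-LASSO of
    Y on (T, X, M), with T and X unpenalized (one-SE penalty)."""
    config = config or CramedConfig()
    return _LassoEngine(Y, T, X, np.asarray(M, float), config).screen()


def distill_outcome(Y, T, X, M, j, config=None) -> np.ndarray:
    """Fitted values of the CV-LASSO of Y on (T, X, M_{-j})."""
    config = config or CramedConfig()
    return _LassoEngine(Y, T, X, np.asarray(M, float), config).distill(j)


# ---------------------------------------------------------------------------
# CRT statistic and p-value


def crt_statistic(Y, Yhat, Mj, Mhat) -> float:
    """|residual(Y)' residual(Mj)| / ||residual(Mj)||_2."""
    r = np.asarray(Y, float) - np.asarray(Yhat, float)
    d = np.asarray(Mj, float) - np.asarray(Mhat, float)
    if r.shape != d.shape:
        raise ValueError("vector length mismatch")
    nd = float(np.linalg.norm(d))
    if nd == 0.0:
        raise DegenerateStatisticError("mediator residual has zero norm")
    return float(abs(r @ d)) / nd


def zidcrt_pvalue(Y, Yhat_j, Mj, fit, T, X=None, config=None, rng=None,
                  offset=None):
    """zidCRT p-value for the mediator -> outcome branch of H0j.

    Draws B count vectors from the fitted ZINB law, re-fits each one on
    (T, X) to obtain its fitted conditional mean, and returns

        p1 = (1 + #{b : stat_b >= stat_obs}) / (B + 1),

    with ties counted as exceedances.  Resample re-fits that fail fall back
    to the original fitted means (counted; >20% failures flags the taxon).
    Returns ``(p1, flags)``.
    """
    config = config or CramedConfig()
    rng = np.random.default_rng(rng)
    flags: list = []
    try:
        stat_obs = crt_statistic(Y, Yhat_j, Mj, fit.fitted_mean)
    except DegenerateStatisticError:
        return 1.0, ["degenerate-residual: p1 set to 1"]
    warm = packed_params(fit) if fit.wald_df == 2 else None
    n_fail = 0
    n_exceed = 0
    for _ in range(config.B):
        Mb = sample_zinb(fit, rng)
        fitted_b = fit.fitted_mean
        if config.refit_resamples:
            try:
                refit = fit_zinb(Mb, T, X, offset,
                                 start=warm if np.any(Mb == 0) else None,
                                 em_steps=0 if warm is not None else 2,
                                 maxiter=120, retry=False)
                fitted_b = refit.fitted_mean
            except (ZinbFitError, ValueError):
                n_fail += 1
        try:
            stat_b = crt_statistic(Y, Yhat_j, Mb, fitted_b)
        except DegenerateStatisticError:
            stat_b = np.inf  # conservative: counts as an exceedance
            n_fail += 1
        if stat_b >= stat_obs:
            n_exceed += 1
    if n_fail > 0.2 * config.B:
        flags.append(f"refit-failures: {n_fail}/{config.B}")
    p1 = (1 + n_exceed) / (config.B + 1)
    return float(p1), flags


def joint_significance(p1: float, p2: float) -> float:
    """Joint-significance (max-P) p-value: pmax = max(p1, p2)."""
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("p-values must lie in [0, 1]")
    return max(p1, p2)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# mediator-model strategies


class _ZinbMediator:
    """ZINB mediator law: fit, resample, refit (the CRAmed branch)."""

    name = "cramed"

    def __init__(self, M, T, X, offset):
        self.M = M
        self.T = T
        self.X = X
        self.offset = offset

    def matrix(self):
        return self.M.astype(float)

    def observed(self, j):
        return self.M[:, j].astype(float)

    def fit(self, j):
        return fit_zinb(self.M[:, j], self.T, self.X, self.offset)

    def crt_pvalue(self, Y, Yhat, j, fit, config, rng):
        return zidcrt_pvalue(Y, Yhat, self.M[:, j], fit, self.T, self.X,
                             config, rng, self.offset)

    def path_pvalue(self, fit):
        res = wald_test(fit)
        return res.p2, ([] if res.df == 2 else [f"wald-df={res.df}"])


class _GaussianFit:
    def __init__(self, coef, fitted, sigma2, var_slope):
        self.coef = coef
        self.fitted = fitted
        self.sigma2 = sigma2
        self.var_slope = var_slope


class _GaussianMediator:
    """Gaussian mediator law on log(count+1): the Naive-CRAmed baseline."""

    name = "naive"

    def __init__(self, M, T, X, offset):
        self.Mlog = np.log1p(np.asarray(M, dtype=float))
        self.T = T
        self.X = X
        n = self.Mlog.shape[0]
        self.P = _tx_design(T, X, n)
        self.PtPinv = np.linalg.pinv(self.P.T @ self.P)

    def matrix(self):
        return self.Mlog

    def observed(self, j):
        return self.Mlog[:, j]

    def fit(self, j):
        mj = self.Mlog[:, j]
        coef = self.PtPinv @ (self.P.T @ mj)
        fitted = self.P @ coef
        dof = max(self.P.shape[0] - self.P.shape[1], 1)
        sigma2 = float(np.sum((mj - fitted) ** 2)) / dof
        var_slope = sigma2 * self.PtPinv[1, 1]
        return _GaussianFit(coef, fitted, sigma2, var_slope)

    def crt_pvalue(self, Y, Yhat, j, fit, config, rng):
        flags: list = []
        try:
            stat_obs = crt_statistic(Y, Yhat, self.Mlog[:, j], fit.fitted)
        except DegenerateStatisticError:
            return 1.0, ["degenerate-residual: p1 set to 1"]
        n = self.Mlog.shape[0]
        n_exceed = 0
        sd = np.sqrt(fit.sigma2)
        for _ in range(config.B):
            mb = fit.fitted + sd * rng.standard_normal(n)
            fitted_b = self.P @ (self.PtPinv @ (self.P.T @ mb))
            try:
                stat_b = crt_statistic(Y, Yhat, mb, fitted_b)
            except DegenerateStatisticError:
                stat_b = np.inf
            if stat_b >= stat_obs:
                n_exceed += 1
        return (1 + n_exceed) / (config.B + 1), flags

    def path_pvalue(self, fit):
        if fit.var_slope <= 0:
            raise SingularCovarianceError("zero-variance mediator")
        w2 = float(fit.coef[1] ** 2 / fit.var_slope)
        return float(stats.chi2.sf(w2, df=1)), []


# ---------------------------------------------------------------------------
# orchestration


def _resolve_offset(config, M, offset):
    if config.offset_mode == "none":
        return None
    if config.offset_mode == "provided":
        if offset is None:
            raise ValueError("offset_mode='provided' but no offset given")
        return np.asarray(offset, dtype=float)
    totals = np.asarray(M).sum(axis=1).astype(float)
    return np.log(np.maximum(totals, 1.0))


def _validate(Y, T, M):
    Y = np.asarray(Y, dtype=float).reshape(-1)
    T = np.asarray(T).reshape(-1)
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != Y.shape[0] or T.shape[0] != Y.shape[0]:
        raise ValueError("Y, T and M have inconsistent shapes")
    levels = np.unique(T)
    if levels.size != 2:
        raise ValueError("treatment must be binary with both levels present")
    T = (T == levels.max()).astype(np.int64)
    return Y, T, M


def _run_pipeline(mediator, Y, T, M, X, config):
    med_matrix = mediator.matrix()
    engine = _LassoEngine(Y, T, X, med_matrix, config)
    screen = None
    if config.do_screen:
        screen = engine.screen()
        candidates = screen.D
    else:
        candidates = list(range(M.shape[1]))

    results: list = []
    skipped: list = []
    fits: dict = {}
    for j in candidates:
        rng_j = np.random.default_rng([config.seed % (2**31), int(j)])
        flags: list = []
        try:
            fit = mediator.fit(j)
        except AllZeroError:
            skipped.append((j, "all-zero taxon"))
            continue
        except (ZinbFitError, ValueError) as err:
            skipped.append((j, f"fit-failed: {err}"))
            continue
        if getattr(fit, "converged", True) is False:
            flags.append("non-converged mediator fit")
        if getattr(fit, "flags", None):
            flags.extend(fit.flags)
        Yhat_j = engine.distill(j)
        p1, crt_flags = mediator.crt_pvalue(Y, Yhat_j, j, fit, config, rng_j)
        flags.extend(crt_flags)
        try:
            p2, wald_flags = mediator.path_pvalue(fit)
            flags.extend(wald_flags)
        except SingularCovarianceError:
            skipped.append((j, "singular Wald covariance"))
            continue
        fits[j] = fit
        results.append(TaxonResult(taxon=int(j), p1=p1, p2=p2,
                                   pmax=joint_significance(p1, p2),
                                   flags=flags))

    if results:
        adj = bh_adjust([r.pmax for r in results])
        for r, a in zip(results, adj):
            r.p_adj = float(a)
            r.selected = bool(a < config.fdr)

    out = CramedResult(results=results, screen=screen, config=config,
                       method=mediator.name, skipped=skipped)
    sel = out.selected
    if sel and mediator.name == "cramed":
        est = estimate_effects(Y, T, X, M, sel, offset=mediator.offset,
                               fits=fits)
        out.nde = est.nde
        for r in results:
            if r.selected:
                r.nie = est.nie_j[r.taxon]
                r.niep = est.niep_j[r.taxon]
                r.niea = est.niea_j[r.taxon]
                if config.compute_ci:
                    ci_rng = np.random.default_rng(
                        [config.seed % (2**31), int(r.taxon), 7919])
                    r.ci = effect_ci(Y, T, X, M, r.taxon,
                                     n_rep=config.ci_reps,
                                     level=config.ci_level, rng=ci_rng,
                                     offset=mediator.offset)
    return out


def run_cramed(Y, T, M, X=None, config=None, offset=None) -> CramedResult:
    """Run the full CRAmed pipeline on a samples x taxa count matrix.

    Pipeline: optional LASSO screen -> per screened taxon: ZINB fit,
    outcome distillation, zidCRT p1, Wald p2, pmax -> BH across the screened
    set -> NIE/NIEP/NIEA (with optional bootstrap CIs) for selected taxa.
    Deterministic given (data, config.seed); taxa are independent work
    units with per-taxon random streams.
    """
    config = config or CramedConfig()
    Y, T, M = _validate(Y, T, M)
    off = _resolve_offset(config, M, offset)
    mediator = _ZinbMediator(M, T, X, off)
    return _run_pipeline(mediator, Y, T, M, X, config)


def run_naive_cramed(Y, T, M, X=None, config=None, offset=None) -> CramedResult:
    """Gaussian-dCRT baseline: same pipeline on log(count+1) mediators."""
    config = config or CramedConfig()
    Y, T, M = _validate(Y, T, M)
    mediator = _GaussianMediator(M, T, X, None)
    return _run_pipeline(mediator, Y, T, M, X, config)
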