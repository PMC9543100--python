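"""Laplace-approximation fitting of mixed models with crossed random intercepts.

This is the numerical core shared by the hierarchical establishment model,
the all-subsets GLMM comparison, and the piecewise-SEM component models.
Two response families are supported:

* ``bernoulli`` — logistic mixed model for binary establishment outcomes.
* ``gaussian`` — linear mixed model (the Laplace approximation is exact
  for a Gaussian likelihood, so this is ordinary maximum likelihood).

The latent vector stacks the fixed effects and all random-effect blocks.
For fixed variance parameters the conditional mode is found by Newton's
method (one linear solve for the Gaussian family); the marginal likelihood
of the variance parameters integrates the random effects by a Laplace
approximation at that mode.  A random-effect block may carry a correlation
structure (e.g. a phylogenetic covariance matrix), in which case the block
prior is N(0, sigma^2 * C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.special import expit

__all__ = ["RandomFactor", "MixedFit", "fit_mixed", "fit_glm"]

_LOG2PI = np.log(2.0 * np.pi)

# Variance SDs are optimized on the log scale inside this box; the lower
# edge acts as the "variance driven to zero" boundary.
_LOG_SD_LO = -6.0
_LOG_SD_HI = 4.0


@dataclass
class RandomFactor:
    """One random-intercept term.

    Parameters
    ----------
    name:
        Label used in fit summaries (e.g. ``"lake"``).
    codes:
        Integer level codes (0..n_levels-1) per observation.
    n_levels:
        Number of levels.
    corr:
        Optional n_levels x n_levels positive-definite matrix giving the
        correlation structure of the block (identity if omitted).  The
        block prior is N(0, sigma^2 * corr).
    """

    name: str
    codes: np.ndarray
    n_levels: int
    corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) >= self.n_levels:
            raise ValueError(f"factor {self.name}: codes out of range")
        if self.corr is not None:
            c = np.asarray(self.corr, dtype=float)
            if c.shape != (self.n_levels, self.n_levels):
                raise ValueError(f"factor {self.name}: corr shape mismatch")
            self.corr = c

    def precision(self) -> np.ndarray:
        """Inverse of the correlation structure (identity -> identity)."""
        if self.corr is None:
            return np.eye(self.n_levels)
        jitter = 1e-8 * np.trace(self.corr) / self.n_levels
        c = self.corr + jitter * np.eye(self.n_levels)
        cf = linalg.cho_factor(c, lower=True)
        return linalg.cho_solve(cf, np.eye(self.n_levels))

    def logdet_corr(self) -> float:
        if self.corr is None:
            return 0.0
        jitter = 1e-8 * np.trace(self.corr) / self.n_levels
        c = self.corr + jitter * np.eye(self.n_levels)
        L = linalg.cholesky(c, lower=True)
        return 2.0 * float(np.sum(np.log(np.diag(L))))


@dataclass
class MixedFit:
    """Result of a mixed-model fit."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    sigma: dict[str, float]           # random-effect SDs by factor name
    sigma_resid: float | None         # residual SD (gaussian family only)
    loglik: float                     # Laplace marginal log-likelihood
    family: str
    n: int
    converged: bool
    boundary: bool                    # any variance at the lower box edge
    re_modes: dict[str, np.ndarray] = field(default_factory=dict)
    eta: np.ndarray | None = None     # joint latent mode (beta first)
    hess: np.ndarray | None = None    # joint negative Hessian at the mode
    n_outer_evals: int = 0

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.zvalues))

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])


def _design(X: np.ndarray, factors: list[RandomFactor]) -> tuple[np.ndarray, list[slice]]:
    n, p = X.shape
    blocks = [X]
    slices = []
    off = p
    for f in factors:
        Z = np.zeros((n, f.n_levels))
        Z[np.arange(n), f.codes] = 1.0
        blocks.append(Z)
        slices.append(slice(off, off + f.n_levels))
        off += f.n_levels
    return np.concatenate(blocks, axis=1), slices


def _bern_loglik(psi: np.ndarray, y: np.ndarray) -> float:
    return float(y @ psi - np.logaddexp(0.0, psi).sum())


def _inner_mode_bernoulli(
    A: np.ndarray,
    y: np.ndarray,
    P: np.ndarray,
    eta0: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton maximization of loglik(A eta) - 0.5 eta' P eta."""
    eta = eta0.copy()
    psi = A @ eta

    def objective(eta, psi):
        return _bern_loglik(psi, y) - 0.5 * float(eta @ (P @ eta))

    f = objective(eta, psi)
    ok = False
    H = None
    for _ in range(max_iter):
        mu = expit(psi)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = A.T @ (y - mu) - P @ eta
        H = A.T @ (w[:, None] * A) + P
        try:
            cf = linalg.cho_factor(H, lower=True)
        except linalg.LinAlgError:
            H = H + 1e-6 * np.eye(H.shape[0])
            cf = linalg.cho_factor(H, lower=True)
        step = linalg.cho_solve(cf, grad)
        # step halving
        t = 1.0
        for _ in range(40):
            eta_new = eta + t * step
            psi_new = A @ eta_new
            f_new = objective(eta_new, psi_new)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        moved = f_new - f
        eta, psi, f = eta_new, psi_new, f_new
        if np.max(np.abs(grad)) < tol * (1.0 + abs(f)) or moved < 1e-12 * (1.0 + abs(f)):
            ok = True
            break
    mu = expit(psi)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = A.T @ (w[:, None] * A) + P
    return eta, H, f, ok


def _prior_precision(
    p: int,
    factors: list[RandomFactor],
    slices: list[slice],
    log_sd: np.ndarray,
    d: int,
    beta_prior_prec: float = 0.0,
    prec_cache: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    """Block-diagonal prior precision and the prior log-normalizer constant.

    Returns (P, c) with c = sum_k log N(b_k; 0, sigma_k^2 C_k) normalizers
    evaluated apart from the quadratic form, plus the (optional) Gaussian
    prior normalizer for beta.
    """
    P = np.zeros((d, d))
    c = 0.0
    if beta_prior_prec > 0.0:
        P[:p, :p] = beta_prior_prec * np.eye(p)
        c += 0.5 * p * (np.log(beta_prior_prec) - _LOG2PI)
    for k, (f, sl) in enumerate(zip(factors, slices)):
        s2 = np.exp(2.0 * log_sd[k])
        prec = prec_cache[k] if prec_cache is not None else f.precision()
        P[sl, sl] = prec / s2
        q = f.n_levels
        c += -0.5 * q * (_LOG2PI + 2.0 * log_sd[k]) - 0.5 * f.logdet_corr()
    return P, c


def _logdet_chol(M: np.ndarray) -> float:
    L = linalg.cholesky(M + 1e-10 * np.eye(M.shape[0]), lower=True)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def fit_mixed(
    X: np.ndarray,
    y: np.ndarray,
    factors: list[RandomFactor],
    names: list[str] | None = None,
    family: str = "bernoulli",
    start_log_sd: np.ndarray | None = None,
    maxiter_outer: int = 200,
    xatol: float = 1e-3,
    fatol: float = 1e-6,
) -> MixedFit:
    """Fit a mixed model by maximum (Laplace-approximate) likelihood.

    ``X`` must include the intercept column.  Fixed effects are profiled
    jointly with the random-effect modes in the inner optimization; the
    outer optimization is over log SDs (plus log residual SD for the
    Gaussian family) and uses Nelder-Mead.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if family not in ("bernoulli", "gaussian"):
        raise ValueError(f"unknown family {family!r}")
    if not factors and family == "bernoulli":
        return fit_glm(X, y, names=names)

    A, slices = _design(X, factors)
    d = A.shape[1]
    q = d - p
    prec_cache = [f.precision() for f in factors]
    logdet_cache = [f.logdet_corr() for f in factors]

    n_theta = len(factors) + (1 if family == "gaussian" else 0)
    eta_warm = np.zeros(d)
    n_evals = 0

    def laplace_negll(theta: np.ndarray) -> float:
        nonlocal eta_warm, n_evals
        n_evals += 1
        if np.any(theta < _LOG_SD_LO - 1e-9) or np.any(theta > _LOG_SD_HI + 1e-9):
            return 1e10
        log_sd = theta[: len(factors)]
        P = np.zeros((d, d))
        c = 0.0
        for k, (f, sl) in enumerate(zip(factors, slices)):
            s2 = np.exp(2.0 * log_sd[k])
            P[sl, sl] = prec_cache[k] / s2
            c += -0.5 * f.n_levels * (_LOG2PI + 2.0 * log_sd[k]) - 0.5 * logdet_cache[k]
        if family == "bernoulli":
            eta, H, f_val, _ = _inner_mode_bernoulli(A, y, P, eta_warm)
            eta_warm = eta
            g = f_val + c
        else:
            sig_e = np.exp(theta[-1])
            H = A.T @ A / sig_e**2 + P + 1e-12 * np.eye(d)
            rhs = A.T @ y / sig_e**2
            cf = linalg.cho_factor(H, lower=True)
            eta = linalg.cho_solve(cf, rhs)
            eta_warm = eta
            resid = y - A @ eta
            loglik = -0.5 * n * (_LOG2PI + 2.0 * theta[-1]) - 0.5 * float(resid @ resid) / sig_e**2
            quad = sum(
                float(eta[sl] @ (P[sl, sl] @ eta[sl])) for sl in slices
            )
            g = loglik - 0.5 * quad + c
        # integrate the random-effect block only (beta is profiled)
        H_bb = H[p:, p:] if q else np.empty((0, 0))
        ld = _logdet_chol(H_bb) if q else 0.0
        ll = g + 0.5 * q * _LOG2PI - 0.5 * ld
        return -ll

    if start_log_sd is None:
        theta0 = np.full(n_theta, np.log(0.3))
        if family == "gaussian":
            theta0[-1] = 0.5 * np.log(max(np.var(y), 1e-8))
    else:
        theta0 = np.asarray(start_log_sd, dtype=float)

    if n_theta:
        res = optimize.minimize(
            laplace_negll,
            theta0,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter_outer,
                "xatol": xatol,
                "fatol": fatol,
            },
        )
        theta_hat = np.clip(res.x, _LOG_SD_LO, _LOG_SD_HI)
        loglik = -laplace_negll(theta_hat)
        outer_ok = bool(res.success) or res.status == 2  # maxiter hit still usable
    else:  # gaussian with no factors: plain OLS — still handled for uniformity
        theta_hat = np.empty(0)
        loglik = -laplace_negll(theta_hat)
        outer_ok = True

    # final inner pass at theta_hat for the mode and Hessian
    log_sd = theta_hat[: len(factors)]
    P = np.zeros((d, d))
    for k, sl in enumerate(slices):
        P[sl, sl] = prec_cache[k] / np.exp(2.0 * log_sd[k])
    if family == "bernoulli":
        eta, H, _, inner_ok = _inner_mode_bernoulli(A, y, P, eta_warm)
        sigma_resid = None
    else:
        sig_e = float(np.exp(theta_hat[-1])) if len(theta_hat) else float(
            np.sqrt(np.mean((y - A @ np.linalg.lstsq(A, y, rcond=None)[0]) ** 2))
        )
        H = A.T @ A / sig_e**2 + P + 1e-12 * np.eye(d)
        cf = linalg.cho_factor(H, lower=True)
        eta = linalg.cho_solve(cf, A.T @ y / sig_e**2)
        sigma_resid = sig_e
        inner_ok = True

    cf = linalg.cho_factor(H + 1e-10 * np.eye(d), lower=True)
    vcov_full = linalg.cho_solve(cf, np.eye(d))
    vcov = vcov_full[:p, :p]
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))

    sigma = {f.name: float(np.exp(log_sd[k])) for k, f in enumerate(factors)}
    boundary = bool(np.any(log_sd <= _LOG_SD_LO + 1e-6))
    re_modes = {f.name: eta[sl].copy() for f, sl in zip(factors, slices)}

    return MixedFit(
        names=list(names),
        beta=eta[:p].copy(),
        se=se,
        vcov=vcov,
        sigma=sigma,
        sigma_resid=sigma_resid,
        loglik=float(loglik),
        family=family,
        n=n,
        converged=bool(outer_ok and inner_ok),
        boundary=boundary,
        re_modes=re_modes,
        eta=eta,
        hess=H,
        n_outer_evals=n_evals,
    )


def fit_glm(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> MixedFit:
    """Plain logistic regression by Newton's method (no random effects)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    P = np.zeros((p, p))
    eta, H, f, ok = _inner_mode_bernoulli(X, y, P, np.zeros(p))
    cf = linalg.cho_factor(H + 1e-10 * np.eye(p), lower=True)
    vcov = linalg.cho_solve(cf, np.eye(p))
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    return MixedFit(
        names=list(names),
        beta=eta,
        se=se,
        vcov=vcov,
        sigma={},
        sigma_resid=None,
        loglik=f,
        family="bernoulli",
        n=n,
        converged=ok,
        boundary=False,
        eta=eta,
        hess=H,
    )
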