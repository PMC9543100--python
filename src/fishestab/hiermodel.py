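"""Bayesian phylogenetic hierarchical model of establishment success.

The outcome of introduction event i (species s(i) into lake l(i)) is

    y_i ~ Bernoulli(logit^-1(beta0 + x_i' beta + u_{l(i)} + v_{s(i)} + w_{s(i)}))

with independent lake intercepts u ~ N(0, sigma_L^2 I), independent species
intercepts v ~ N(0, sigma_S^2 I), and a phylogenetically correlated species
effect w ~ N(0, sigma_P^2 Sigma), where Sigma is the Brownian-motion
covariance of the introduced species (shared root-to-MRCA branch length,
scaled to unit maximum diagonal).  Fixed effects carry N(0, 10^2) priors;
variance hyperparameters carry Gamma(0.01, 0.01) priors on the precisions.

Inference is a nested Laplace approximation in the spirit of the INLA
machinery commonly used for this model class: the latent field (fixed and
random effects) is integrated by a Laplace approximation at its conditional
mode, the three variance hyperparameters are optimized on the resulting
marginal posterior, and posterior draws are taken from the Gaussian
approximation at the modal hyperparameters.  Draws feed the credible
intervals and the WAIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit, gammaln

from .mixed import (
    _LOG2PI,
    RandomFactor,
    _design,
    _inner_mode_bernoulli,
    _logdet_chol,
)

__all__ = [
    "phylo_covariance",
    "HierFit",
    "fit_hier",
    "waic",
    "relative_importance",
    "grouped_importance",
    "prediction_curve",
    "PREDICTOR_GROUPS",
]

# grouping of the eight predictors used for the variance-partition summary
PREDICTOR_GROUPS = {
    "similarity": ["in_mpd", "in_mfd", "in_mntd", "in_mnfd"],
    "diversity": ["richness", "native_mpd", "native_mfd", "native_mntd", "native_mnfd"],
    "geography": ["area", "elevation", "latitude"],
}


def phylo_covariance(
    tree: dendropy.Tree, species_subset: list[str] | None = None, scale: bool = True
) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance: shared root-to-MRCA path length per pair.

    The covariance is computed on the full tree and the sub-matrix for the
    requested species extracted afterwards, so shared ancestry with
    non-subset lineages is retained.  With ``scale=True`` the matrix is
    divided by its maximum diagonal entry.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = [l for l in tree.leaf_node_iter()]
    labels = [l.taxon.label for l in leaves]
    depth = {l.taxon.label: l.root_distance for l in leaves}
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}

    full_order = sorted(labels)
    n = len(full_order)
    cov = np.zeros((n, n))
    for i, a in enumerate(full_order):
        cov[i, i] = depth[a]
        for j in range(i + 1, n):
            b = full_order[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            cov[i, j] = cov[j, i] = 0.5 * (depth[a] + depth[b] - d)
    if species_subset is not None:
        missing = sorted(set(species_subset) - set(full_order))
        if missing:
            raise ValueError(f"species not in tree: {missing}")
        order = sorted(species_subset)
        idx = [full_order.index(s) for s in order]
        cov = cov[np.ix_(idx, idx)]
    else:
        order = full_order
    if scale:
        m = cov.diagonal().max()
        if m > 0:
            cov = cov / m
    return order, cov


@dataclass
class HierFit:
    """Posterior summary of the phylogenetic Bernoulli hierarchical model."""

    predictors: list[str]
    summary: pd.DataFrame            # mean/median/CI rows per coefficient
    beta_draws: np.ndarray           # draws x (1 + p), intercept first
    sigma: dict[str, float]          # modal random-effect SDs
    waic: float
    p_waic: float
    lppd: float
    loglik_pointwise: np.ndarray     # draws x n
    loglik_joint_mode: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def coef_mean(self, name: str) -> float:
        return float(self.summary.loc[name, "mean"])

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = f"ci{int(level * 100)}_lo"
        hi = f"ci{int(level * 100)}_hi"
        return float(self.summary.loc[name, lo]), float(self.summary.loc[name, hi])


def _log_hyperprior(log_sd: np.ndarray, shape: float, rate: float) -> float:
    """Gamma(shape, rate) prior on precisions, with the log-SD Jacobian."""
    tau = np.exp(-2.0 * log_sd)
    lp = (shape * np.log(rate) - gammaln(shape)
          + (shape - 1.0) * np.log(tau) - rate * tau)
    # tau = exp(-2 theta); |d tau / d theta| = 2 tau
    return float(np.sum(lp + np.log(2.0 * tau)))


def fit_hier(
    covariates: pd.DataFrame,
    predictors: list[str],
    phylo_cov: tuple[list[str], np.ndarray] | None,
    outcome: str = "outcome",
    lake_col: str = "lake_id",
    species_col: str = "species_id",
    beta_prior_sd: float = 10.0,
    gamma_shape: float = 0.01,
    gamma_rate: float = 0.01,
    n_draws: int = 1000,
    seed: int | None = None,
    standardized: bool = True,
    maxiter_outer: int = 150,
) -> HierFit:
    """Fit the hierarchical establishment model on a covariate table.

    ``predictors`` name columns of ``covariates``; with ``standardized``
    they are z-scored internally (the scaling is recorded so prediction
    curves can be drawn on the raw scale).  ``phylo_cov`` is the output of
    :func:`phylo_covariance` restricted to the introduced species; pass
    ``None`` to omit the phylogenetically correlated effect.
    """
    df = covariates.reset_index(drop=True)
    y = df[outcome].to_numpy(dtype=float)
    n = len(df)

    X_raw = df[predictors].to_numpy(dtype=float)
    standardization: dict[str, tuple[float, float]] = {}
    if standardized:
        mu = X_raw.mean(axis=0)
        sd = X_raw.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [p for p, s in zip(predictors, sd) if s == 0]
            raise ValueError(f"constant predictor(s): {bad}")
        X_std = (X_raw - mu) / sd
        standardization = {p: (float(m), float(s)) for p, m, s in zip(predictors, mu, sd)}
    else:
        X_std = X_raw
    X = np.column_stack([np.ones(n), X_std])
    names = ["intercept"] + list(predictors)
    p = X.shape[1]

    lakes = pd.Categorical(df[lake_col].astype(str))
    factors = [RandomFactor("lake", lakes.codes.astype(int), len(lakes.categories))]
    species_levels = sorted(df[species_col].astype(str).unique())
    sp_index = {s: i for i, s in enumerate(species_levels)}
    sp_codes = df[species_col].astype(str).map(sp_index).to_numpy(dtype=int)
    factors.append(RandomFactor("species", sp_codes, len(species_levels)))
    if phylo_cov is not None:
        cov_order, Sigma = phylo_cov
        missing = sorted(set(species_levels) - set(cov_order))
        if missing:
            raise ValueError(f"species missing from phylogenetic covariance: {missing}")
        idx = [cov_order.index(s) for s in species_levels]
        factors.append(
            RandomFactor("phylo", sp_codes, len(species_levels),
                         corr=Sigma[np.ix_(idx, idx)])
        )

    A, slices = _design(X, factors)
    d = A.shape[1]
    prec_cache = [f.precision() for f in factors]
    logdet_cache = [f.logdet_corr() for f in factors]
    beta_prec = 1.0 / beta_prior_sd**2
    eta_warm = np.zeros(d)

    def build_P(log_sd: np.ndarray) -> tuple[np.ndarray, float]:
        P = np.zeros((d, d))
        P[:p, :p] = beta_prec * np.eye(p)
        c = 0.5 * p * (np.log(beta_prec) - _LOG2PI)
        for k, (f, sl) in enumerate(zip(factors, slices)):
            s2 = np.exp(2.0 * log_sd[k])
            P[sl, sl] = prec_cache[k] / s2
            c += -0.5 * f.n_levels * (_LOG2PI + 2.0 * log_sd[k]) - 0.5 * logdet_cache[k]
        return P, c

    def neg_log_marg_post(log_sd: np.ndarray) -> float:
        nonlocal eta_warm
        if np.any(np.abs(log_sd) > 8.0):
            return 1e10
        P, c = build_P(log_sd)
        eta, H, f_val, _ = _inner_mode_bernoulli(A, y, P, eta_warm)
        eta_warm = eta
        ll = (f_val + c + 0.5 * d * _LOG2PI - 0.5 * _logdet_chol(H)
              + _log_hyperprior(log_sd, gamma_shape, gamma_rate))
        return -ll

    theta0 = np.full(len(factors), np.log(0.5))
    res = optimize.minimize(
        neg_log_marg_post, theta0, method="Nelder-Mead",
        options={"maxiter": maxiter_outer, "xatol": 2e-3, "fatol": 1e-5},
    )
    theta_hat = res.x
    converged = bool(res.success or res.status == 2)

    P, _ = build_P(theta_hat)
    eta_mode, H, f_val, inner_ok = _inner_mode_bernoulli(A, y, P, eta_warm, tol=1e-10)
    converged = converged and inner_ok

    # posterior draws from the Gaussian approximation at the modal
    # hyperparameters: eta ~ N(eta_mode, H^-1)
    rng = np.random.default_rng(seed)
    L = linalg.cholesky(H + 1e-10 * np.eye(d), lower=True)
    z = rng.standard_normal((d, n_draws))
    draws = (eta_mode[:, None] + linalg.solve_triangular(L.T, z, lower=False)).T

    psi_draws = draws @ A.T                       # draws x n
    loglik_pw = y * psi_draws - np.logaddexp(0.0, psi_draws)
    w, pw, lppd = waic(loglik_pw)

    beta_draws = draws[:, :p]
    qs = np.quantile(beta_draws, [0.025, 0.15, 0.5, 0.85, 0.975], axis=0)
    summary = pd.DataFrame(
        {
            "mean": beta_draws.mean(axis=0),
            "median": qs[2],
            "ci95_lo": qs[0],
            "ci95_hi": qs[4],
            "ci70_lo": qs[1],
            "ci70_hi": qs[3],
            "sd": beta_draws.std(axis=0, ddof=1),
        },
        index=names,
    )

    grad_norm = float(np.max(np.abs(
        A.T @ (y - expit(A @ eta_mode)) - P @ eta_mode)))
    return HierFit(
        predictors=list(predictors),
        summary=summary,
        beta_draws=beta_draws,
        sigma={f.name: float(np.exp(theta_hat[k])) for k, f in enumerate(factors)},
        waic=w,
        p_waic=pw,
        lppd=lppd,
        loglik_pointwise=loglik_pw,
        loglik_joint_mode=float(y @ (A @ eta_mode) - np.logaddexp(0.0, A @ eta_mode).sum()),
        converged=converged,
        diagnostics={
            "outer_iterations": int(res.nit),
            "mode_gradient_norm": grad_norm,
            "theta": theta_hat.tolist(),
        },
        standardization=standardization,
    )


def waic(loglik_pointwise: np.ndarray) -> tuple[float, float, float]:
    """Widely applicable information criterion from pointwise draws.

    ``loglik_pointwise`` has one row per posterior draw and one column per
    observation.  Returns (WAIC, p_waic, lppd) with
    WAIC = -2 (lppd - p_waic) and p_waic the summed posterior variance of
    the pointwise log-likelihood.  A single draw yields p_waic = 0.
    """
    ll = np.asarray(loglik_pointwise, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expected draws x observations array")
    S = ll.shape[0]
    if S < 100:
        import warnings

        warnings.warn(f"WAIC from only {S} draws", stacklevel=2)
    m = ll.max(axis=0)
    lppd = float(np.sum(m + np.log(np.mean(np.exp(ll - m), axis=0))))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1))) if S > 1 else 0.0
    return -2.0 * (lppd - p_waic), p_waic, lppd


def relative_importance(fit: HierFit) -> pd.Series:
    """Percent share of each predictor: |beta| over the sum of |beta|.

    Defined only for standardized predictors; the intercept is excluded.
    """
    beta = fit.summary.loc[fit.predictors, "mean"].abs()
    total = float(beta.sum())
    if total == 0:
        raise ValueError("all coefficients zero; relative importance undefined")
    return 100.0 * beta / total


def grouped_importance(fit: HierFit) -> pd.Series:
    """Relative importance aggregated into similarity/diversity/geography."""
    shares = relative_importance(fit)
    out = {}
    for group, cols in PREDICTOR_GROUPS.items():
        out[group] = float(shares.reindex(cols).dropna().sum())
    return pd.Series(out)


def prediction_curve(
    fit: HierFit,
    predictor: str,
    grid: np.ndarray | None = None,
    n_points: int = 50,
) -> pd.DataFrame:
    """Establishment probability over one predictor, others at their means.

    The grid is on the raw covariate scale when the fit recorded
    standardization parameters.  Returns the posterior-mean curve with a
    95% credible band (random effects at zero, i.e. a typical lake and
    species).
    """
    if predictor not in fit.predictors:
        raise ValueError(f"{predictor!r} not among model predictors")
    j = fit.predictors.index(predictor) + 1  # offset for intercept
    mu, sd = fit.standardization.get(predictor, (0.0, 1.0))
    if grid is None:
        z = np.linspace(-2.5, 2.5, n_points)
        grid = mu + sd * z
    else:
        grid = np.asarray(grid, dtype=float)
        z = (grid - mu) / sd
    # other predictors at their means = 0 on the z scale
    psi = fit.beta_draws[:, [0]] + np.outer(fit.beta_draws[:, j], z)
    prob = expit(psi)
    lo, hi = np.quantile(prob, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {"x": grid, "prob": prob.mean(axis=0), "lo": lo, "hi": hi}
    )
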