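"""All-subsets GLMM comparison and AICc multi-model averaging.

Every subset of the eight fixed-effect predictors is fitted as a logistic
mixed model with lake and species random intercepts (the random structure
is never subset).  Models are ranked by small-sample-corrected AIC; those
within 2 AICc units of the best are averaged with Akaike weights, using
the full-average (zero-substitution) convention and Burnham-Anderson
unconditional standard errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed import MixedFit, RandomFactor, fit_glm, fit_mixed

__all__ = ["ModelRecord", "aicc", "dredge", "model_average", "AveragedCoefficients"]


def aicc(loglik: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); undefined for n <= k+1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelRecord:
    subset: tuple[str, ...]
    loglik: float
    k: int
    aicc: float
    delta: float = np.nan
    weight: float = np.nan
    coef: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    boundary: bool = False


def _fit_subset(
    subset: tuple[str, ...],
    df: pd.DataFrame,
    outcome: str,
    factors: list[RandomFactor] | None,
    start_log_sd: np.ndarray | None,
    maxiter_outer: int,
) -> MixedFit:
    n = len(df)
    X = np.column_stack(
        [np.ones(n)] + [df[c].to_numpy(dtype=float) for c in subset]
    )
    names = ["intercept"] + list(subset)
    y = df[outcome].to_numpy(dtype=float)
    if factors:
        return fit_mixed(
            X, y, factors, names=names,
            start_log_sd=start_log_sd, maxiter_outer=maxiter_outer,
        )
    return fit_glm(X, y, names=names)


def dredge(
    covariates: pd.DataFrame,
    predictors: list[str],
    outcome: str = "outcome",
    lake_col: str | None = "lake_id",
    species_col: str | None = "species_id",
    maxiter_outer: int = 60,
) -> list[ModelRecord]:
    """Fit all 2^p predictor subsets and rank them by AICc.

    Ties break toward fewer parameters, then lexicographic subset.  The
    parameter count k is |subset| + 1 (intercept) + the number of
    random-effect variances.  Per-model convergence failures are recorded
    on the ModelRecord, never aborting the sweep.  Pass ``lake_col`` and
    ``species_col`` as None to fit plain logistic regressions instead.
    """
    if len(predictors) > 12:
        raise ValueError("all-subsets sweep limited to 12 predictors")
    df = covariates.reset_index(drop=True)
    n = len(df)

    factors: list[RandomFactor] = []
    for name, col in (("lake", lake_col), ("species", species_col)):
        if col is not None:
            cats = pd.Categorical(df[col].astype(str))
            factors.append(RandomFactor(name, cats.codes.astype(int), len(cats.categories)))
    n_var = len(factors)

    # fit the full model first; its variance estimates warm-start the rest
    full = tuple(predictors)
    full_fit = _fit_subset(full, df, outcome, factors, None, maxiter_outer=200)
    warm = (
        np.log(np.clip([full_fit.sigma[f.name] for f in factors], 1e-3, None))
        if factors else None
    )

    records: list[ModelRecord] = []
    for r in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, r):
            if subset == full:
                fit = full_fit
            else:
                fit = _fit_subset(subset, df, outcome, factors, warm, maxiter_outer)
            k = len(subset) + 1 + n_var
            records.append(
                ModelRecord(
                    subset=subset,
                    loglik=fit.loglik,
                    k=k,
                    aicc=aicc(fit.loglik, k, n),
                    coef=dict(zip(fit.names, fit.beta)),
                    se=dict(zip(fit.names, fit.se)),
                    converged=fit.converged,
                    boundary=fit.boundary,
                )
            )
    records.sort(key=lambda m: (m.aicc, m.k, m.subset))
    best = records[0].aicc
    for m in records:
        m.delta = m.aicc - best
    wts = np.exp(-0.5 * np.array([m.delta for m in records]))
    wts /= wts.sum()
    for m, w in zip(records, wts):
        m.weight = float(w)
    return records


@dataclass
class AveragedCoefficients:
    coef: pd.Series
    se: pd.Series
    weights: pd.Series       # indexed by subset string
    n_models: int


def model_average(
    records: list[ModelRecord],
    predictors: list[str],
    delta_max: float = 2.0,
) -> AveragedCoefficients:
    """Akaike-weighted full-model average over models with dAICc < delta_max.

    Absent predictors contribute coefficient 0 (and SE 0) to the average;
    unconditional SEs follow Burnham & Anderson:
    se_bar = sum_i w_i sqrt(se_i^2 + (b_i - b_bar)^2).
    """
    retained = [m for m in records if m.delta < delta_max]
    if not retained:
        raise ValueError("no model within delta_max of the best (impossible if best included)")
    w = np.exp(-0.5 * np.array([m.delta for m in retained]))
    w = w / w.sum()
    terms = ["intercept"] + list(predictors)
    coef = {}
    se = {}
    for t in terms:
        b = np.array([m.coef.get(t, 0.0) for m in retained])
        s = np.array([m.se.get(t, 0.0) for m in retained])
        bbar = float(w @ b)
        coef[t] = bbar
        se[t] = float(w @ np.sqrt(s**2 + (b - bbar) ** 2))
    labels = ["+".join(m.subset) if m.subset else "(null)" for m in retained]
    return AveragedCoefficients(
        coef=pd.Series(coef),
        se=pd.Series(se),
        weights=pd.Series(w, index=labels),
        n_models=len(retained),
    )


def records_to_frame(records: list[ModelRecord]) -> pd.DataFrame:
    """Ranked model table (one row per candidate subset)."""
    return pd.DataFrame(
        {
            "subset": ["+".join(m.subset) if m.subset else "(null)" for m in records],
            "loglik": [m.loglik for m in records],
            "k": [m.k for m in records],
            "AICc": [m.aicc for m in records],
            "dAICc": [m.delta for m in records],
            "weight": [m.weight for m in records],
            "converged": [m.converged for m in records],
            "boundary": [m.boundary for m in records],
        }
    )
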