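"""Piecewise structural equation modeling with d-separation tests.

A path model over the measured variables is specified as a DAG.  Each
endogenous variable gets its own component regression (linear mixed for
continuous variables, logistic mixed for the binary establishment
outcome), optionally with lake and species random intercepts.  Model fit
is evaluated with Shipley's d-separation test: every independence claim in
the union basis set is tested by regression, the claim p-values combine
into Fisher's C = -2 sum ln p (chi-square with 2k df under a correct
model), and candidate models are compared with the d-sep AIC = C + 2K.

Standardized path coefficients use sd(x)/sd(y) scaling for linear
components; for the logistic component the latent-scale response SD
sqrt(var(Xb) + sigma_L^2 + sigma_S^2 + pi^2/3) replaces sd(y).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .mixed import MixedFit, RandomFactor, fit_glm, fit_mixed

__all__ = [
    "vif_check",
    "Claim",
    "basis_set",
    "ComponentFit",
    "SemFit",
    "DSepResult",
    "fit_sem",
    "dsep_test",
    "standardize_paths",
    "effects_decomposition",
    "conditional_r2",
    "sem_selection",
    "default_dag",
]

_LOGIT_RESID_VAR = np.pi**2 / 3.0  # latent-scale residual variance of a logit link


def vif_check(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j).

    Perfect collinearity yields an infinite VIF (reported, not raised).
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    X = design.to_numpy(dtype=float)
    for j, c in enumerate(cols):
        yj = X[:, j]
        Xj = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(yj, Xj).fit().rsquared
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass(frozen=True)
class Claim:
    """An independence claim X _||_ Y | cond implied by the DAG."""

    x: str
    y: str
    cond: tuple[str, ...]


def basis_set(dag: nx.DiGraph) -> list[Claim]:
    """Shipley's union basis set of a DAG.

    One claim per non-adjacent ordered pair (X, Y), with Y the later
    vertex in a (deterministic lexicographic) topological order; the
    conditioning set is parents(X) union parents(Y).
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph has a cycle")
    order = list(nx.lexicographical_topological_sort(dag))
    pos = {v: i for i, v in enumerate(order)}
    claims = []
    for x, y in itertools.combinations(order, 2):
        if dag.has_edge(x, y) or dag.has_edge(y, x):
            continue
        if pos[x] > pos[y]:
            x, y = y, x
        cond = sorted((set(dag.predecessors(x)) | set(dag.predecessors(y))) - {x, y})
        claims.append(Claim(x=x, y=y, cond=tuple(cond)))
    return claims


@dataclass
class ComponentFit:
    """One component regression of the piecewise SEM."""

    response: str
    parents: list[str]
    family: str
    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series
    sigma: dict[str, float]
    sigma_resid: float | None
    fixed_var: float          # variance of the fitted fixed-effect predictor
    n_params: int
    loglik: float
    boundary: bool = False


def _factors_from(data: pd.DataFrame, factor_cols: list[str] | None) -> list[RandomFactor]:
    factors = []
    for col in factor_cols or []:
        cats = pd.Categorical(data[col].astype(str))
        factors.append(RandomFactor(col, cats.codes.astype(int), len(cats.categories)))
    return factors


def _fit_component(
    data: pd.DataFrame,
    response: str,
    parents: list[str],
    family: str,
    factor_cols: list[str] | None,
) -> ComponentFit:
    n = len(data)
    X = np.column_stack(
        [np.ones(n)] + [data[c].to_numpy(dtype=float) for c in parents]
    )
    names = ["intercept"] + list(parents)
    y = data[response].to_numpy(dtype=float)
    factors = _factors_from(data, factor_cols)

    if family == "gaussian" and not factors:
        res = sm.OLS(y, X).fit()
        beta = pd.Series(res.params, index=names)
        fit = ComponentFit(
            response=response, parents=list(parents), family=family,
            beta=beta,
            se=pd.Series(res.bse, index=names),
            pvalues=pd.Series(res.pvalues, index=names),
            sigma={}, sigma_resid=float(np.sqrt(res.scale)),
            fixed_var=float(np.var(X @ res.params)),
            n_params=len(names) + 1,
            loglik=float(res.llf),
        )
        return fit

    mfit: MixedFit = (
        fit_mixed(X, y, factors, names=names, family=family)
        if factors
        else fit_glm(X, y, names=names)
    )
    pvals = pd.Series(mfit.pvalues(), index=names)
    n_params = len(names) + len(factors) + (1 if family == "gaussian" else 0)
    return ComponentFit(
        response=response, parents=list(parents), family=family,
        beta=pd.Series(mfit.beta, index=names),
        se=pd.Series(mfit.se, index=names),
        pvalues=pvals,
        sigma=dict(mfit.sigma),
        sigma_resid=mfit.sigma_resid,
        fixed_var=float(np.var(X @ mfit.beta)),
        n_params=n_params,
        loglik=mfit.loglik,
        boundary=mfit.boundary,
    )


@dataclass
class DSepResult:
    claims: list[Claim]
    pvalues: list[float]
    fisher_c: float
    df: int
    p_global: float
    k_params: int
    aic: float
    flagged: list[Claim] = field(default_factory=list)


def _combine_fisher(pvalues: list[float], k_params: int) -> tuple[float, int, float, float]:
    ps = np.clip(np.asarray(pvalues, dtype=float), 1e-300, 1.0)
    C = float(-2.0 * np.log(ps).sum())
    df = 2 * len(ps)
    p_global = float(stats.chi2.sf(C, df)) if df else 1.0
    return C, df, p_global, C + 2.0 * k_params


def dsep_test(
    dag: nx.DiGraph,
    data: pd.DataFrame,
    families: dict[str, str],
    factor_cols: list[str] | None = None,
    k_params: int | None = None,
) -> DSepResult:
    """Test every basis-set claim and combine the p-values into Fisher's C.

    Each claim X _||_ Y | cond is tested by regressing Y (in its own
    family) on the conditioning set plus X and taking the two-sided
    p-value of X's coefficient.  ``k_params`` is the total parameter count
    of the component models (for the d-sep AIC); when omitted it is
    computed by fitting them.
    """
    claims = basis_set(dag)
    if k_params is None:
        k_params = sum(
            c.n_params for c in _fit_components(dag, data, families, factor_cols).values()
        )
    pvalues = []
    flagged = []
    for cl in claims:
        fam = families.get(cl.y, "gaussian")
        predictors = list(cl.cond) + [cl.x]
        comp = _fit_component(data, cl.y, predictors, fam, factor_cols)
        p = float(comp.pvalues[cl.x])
        if not np.isfinite(p):
            flagged.append(cl)
            p = 1.0
        pvalues.append(p)
    C, df, p_global, aic = _combine_fisher(pvalues, k_params)
    return DSepResult(
        claims=claims, pvalues=pvalues, fisher_c=C, df=df,
        p_global=p_global, k_params=k_params, aic=aic, flagged=flagged,
    )


def _fit_components(
    dag: nx.DiGraph,
    data: pd.DataFrame,
    families: dict[str, str],
    factor_cols: list[str] | None,
) -> dict[str, ComponentFit]:
    comps = {}
    for node in nx.lexicographical_topological_sort(dag):
        parents = sorted(dag.predecessors(node))
        if not parents:
            continue
        comps[node] = _fit_component(
            data, node, parents, families.get(node, "gaussian"), factor_cols
        )
    return comps


@dataclass
class SemFit:
    graph: nx.DiGraph
    components: dict[str, ComponentFit]
    dsep: DSepResult
    edges: pd.DataFrame          # source, target, beta, beta_std, p
    r2c: dict[str, float]

    @property
    def aic(self) -> float:
        return self.dsep.aic


def standardize_paths(
    components: dict[str, ComponentFit], data: pd.DataFrame
) -> pd.DataFrame:
    """Standardized coefficient per edge of the fitted path model.

    Linear components: beta* = beta sd(x)/sd(y).  Logistic components use
    the latent-theoretic scale: beta* = beta sd(x) / sqrt(var(Xb) +
    sum(random-effect variances) + pi^2/3).
    """
    rows = []
    for node, comp in components.items():
        if comp.family == "bernoulli":
            sd_y = np.sqrt(
                comp.fixed_var
                + sum(s**2 for s in comp.sigma.values())
                + _LOGIT_RESID_VAR
            )
        else:
            sd_y = float(data[node].std(ddof=0))
        for parent in comp.parents:
            sd_x = float(data[parent].std(ddof=0))
            if sd_x == 0:
                raise ValueError(f"zero-variance predictor {parent!r}")
            rows.append(
                {
                    "source": parent,
                    "target": node,
                    "beta": float(comp.beta[parent]),
                    "beta_std": float(comp.beta[parent]) * sd_x / sd_y,
                    "p": float(comp.pvalues[parent]),
                }
            )
    return pd.DataFrame(rows)


def conditional_r2(comp: ComponentFit) -> float:
    """Nakagawa conditional R^2: (fixed + random) / (fixed + random + residual).

    The residual variance is sigma_resid^2 for linear components and
    pi^2/3 (latent logit scale) for Bernoulli components.
    """
    var_re = sum(s**2 for s in comp.sigma.values())
    var_resid = (
        _LOGIT_RESID_VAR if comp.family == "bernoulli" else float(comp.sigma_resid) ** 2
    )
    return (comp.fixed_var + var_re) / (comp.fixed_var + var_re + var_resid)


def fit_sem(
    dag: nx.DiGraph,
    data: pd.DataFrame,
    families: dict[str, str],
    factor_cols: list[str] | None = None,
) -> SemFit:
    """Fit all component models, run the d-sep test, standardize paths."""
    comps = _fit_components(dag, data, families, factor_cols)
    k = sum(c.n_params for c in comps.values())
    dsep = dsep_test(dag, data, families, factor_cols, k_params=k)
    edges = standardize_paths(comps, data)
    r2c = {node: conditional_r2(c) for node, c in comps.items()}
    return SemFit(graph=dag.copy(), components=comps, dsep=dsep, edges=edges, r2c=r2c)


@dataclass
class PathEffects:
    table: pd.DataFrame   # direct, indirect, total, relative_total per source


def effects_decomposition(
    fit: SemFit,
    target: str = "outcome",
    significant_only: bool = True,
    alpha: float = 0.05,
) -> PathEffects:
    """Direct, indirect, and relative total standardized effects on the target.

    The indirect effect of a variable is the sum over all directed paths
    of length >= 2 to the target of the product of standardized edge
    coefficients.  With ``significant_only`` (mirroring common display
    practice) edges with p >= alpha are pruned before the decomposition.
    Relative totals are |total| shares summing to 100%.
    """
    edges = fit.edges
    if significant_only:
        edges = edges[edges["p"] < alpha]
    g = nx.DiGraph()
    g.add_nodes_from(fit.graph.nodes)
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, beta_std=row.beta_std)
    rows = []
    for node in g.nodes:
        if node == target:
            continue
        direct = g.edges[node, target]["beta_std"] if g.has_edge(node, target) else 0.0
        indirect = 0.0
        for path in nx.all_simple_paths(g, node, target):
            if len(path) < 3:
                continue
            prod = 1.0
            for a, b in zip(path[:-1], path[1:]):
                prod *= g.edges[a, b]["beta_std"]
            indirect += prod
        if direct == 0.0 and indirect == 0.0 and not nx.has_path(fit.graph, node, target):
            continue
        rows.append({"source": node, "direct": direct, "indirect": indirect,
                     "total": direct + indirect})
    table = pd.DataFrame(rows).set_index("source")
    denom = table["total"].abs().sum()
    table["relative_total"] = (
        100.0 * table["total"].abs() / denom if denom > 0 else np.nan
    )
    return PathEffects(table=table)


def sem_selection(
    dag: nx.DiGraph,
    data: pd.DataFrame,
    families: dict[str, str],
    factor_cols: list[str] | None = None,
    max_added: int = 10,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> tuple[SemFit, list[dict]]:
    """Stepwise d-sep-guided edge addition, selecting by the d-sep AIC.

    The edge corresponding to the most significant *violated* claim (claim
    p below alpha, Bonferroni-corrected over the basis set by default so
    the familywise false-addition rate stays near alpha) is added, oriented
    from the earlier to the later vertex in topological order; the search
    stops when no claim is violated or the AIC stops decreasing.  Returns
    the best fit and a ledger of candidate steps.
    """
    current = dag.copy()
    fit = fit_sem(current, data, families, factor_cols)
    ledger = [{"action": "initial", "aic": fit.aic, "C": fit.dsep.fisher_c}]
    for _ in range(max_added):
        if not fit.dsep.claims:
            break
        thresh = alpha / len(fit.dsep.claims) if bonferroni else alpha
        i = int(np.argmin(fit.dsep.pvalues))
        if fit.dsep.pvalues[i] >= thresh:
            break
        claim = fit.dsep.claims[i]
        candidate = current.copy()
        candidate.add_edge(claim.x, claim.y)
        if not nx.is_directed_acyclic_graph(candidate):
            break
        cand_fit = fit_sem(candidate, data, families, factor_cols)
        ledger.append(
            {"action": f"add {claim.x}->{claim.y}", "aic": cand_fit.aic,
             "C": cand_fit.dsep.fisher_c, "claim_p": fit.dsep.pvalues[i]}
        )
        if cand_fit.aic < fit.aic:
            current, fit = candidate, cand_fit
        else:
            break
    return fit, ledger


def default_dag(variant: str = "geography", family: str = "mean") -> nx.DiGraph:
    """The initial path model.

    Geography (latitude, elevation, area) drives native richness; richness
    (plus area) drives native phylogenetic and functional diversity;
    diversity drives the exotic-native similarity metrics; similarity
    (plus a direct lake-area path) drives establishment.  The temperature
    variant replaces the geographic drivers with accumulated and maximum
    water temperature.  ``family`` picks mean (MPD/MFD) or nearest
    (MNTD/MNFD) metrics.
    """
    if family == "mean":
        div_p, div_f, sim_p, sim_f = "native_mpd", "native_mfd", "in_mpd", "in_mfd"
    elif family == "nearest":
        div_p, div_f, sim_p, sim_f = "native_mntd", "native_mnfd", "in_mntd", "in_mnfd"
    else:
        raise ValueError(f"unknown metric family {family!r}")
    g = nx.DiGraph()
    if variant == "geography":
        drivers = ["latitude", "elevation", "area"]
    elif variant == "temperature":
        drivers = ["accum_temp", "max_temp"]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    for d in drivers:
        g.add_edge(d, "richness")
    g.add_edge("richness", div_p)
    g.add_edge("richness", div_f)
    if variant == "geography":
        g.add_edge("area", div_p)
        g.add_edge("area", "outcome")
    g.add_edge("richness", sim_p)
    g.add_edge("richness", sim_f)
    g.add_edge(div_p, sim_p)
    g.add_edge(div_f, sim_f)
    g.add_edge(sim_p, "outcome")
    g.add_edge(sim_f, "outcome")
    return g
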