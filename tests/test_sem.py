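import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fishestab.sem import (
    ComponentFit,
    basis_set,
    conditional_r2,
    default_dag,
    dsep_test,
    effects_decomposition,
    fit_sem,
    sem_selection,
    standardize_paths,
    vif_check,
    _combine_fisher,
)

LOGIT_SD = np.pi / np.sqrt(3.0)


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 40
        x1 = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        x2 = np.tile([1.0, -1.0], n // 2)
        vifs = vif_check(pd.DataFrame({"x1": x1, "x2": x2}))
        np.testing.assert_allclose(vifs.values, 1.0, atol=1e-10)

    def test_duplicated_predictor_infinite(self):
        x = np.random.default_rng(0).normal(size=30)
        vifs = vif_check(pd.DataFrame({"x1": x, "x2": x}))
        assert np.isinf(vifs["x1"])

    def test_closed_form_at_exact_correlation(self):
        # construct two columns with sample correlation exactly 0.8
        n = 50
        rng = np.random.default_rng(1)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
        b /= b.std()
        x2 = 0.8 * a + np.sqrt(1 - 0.64) * b
        vifs = vif_check(pd.DataFrame({"x1": a, "x2": x2}))
        assert vifs["x1"] == pytest.approx(1 / (1 - 0.64), rel=1e-10)


class TestBasisSet:
    def test_chain_single_claim(self):
        g = nx.DiGraph([("X", "M"), ("M", "Y")])
        claims = basis_set(g)
        assert len(claims) == 1
        assert (claims[0].x, claims[0].y, claims[0].cond) == ("X", "Y", ("M",))

    def test_complete_dag_empty(self):
        g = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c")])
        assert basis_set(g) == []

    def test_cyclic_fatal(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="cycle"):
            basis_set(g)

    @pytest.mark.parametrize("n_nodes", [3, 4, 5])
    def test_claims_d_separated_in_graph(self, n_nodes):
        """All basis claims are d-separated per the graph-theoretic oracle."""
        nodes = [f"v{i}" for i in range(n_nodes)]
        n_pairs = n_nodes * (n_nodes - 1) // 2
        pairs = list(itertools.combinations(range(n_nodes), 2))
        for mask in range(2 ** n_pairs):
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            for b, (i, j) in enumerate(pairs):
                if mask >> b & 1:
                    g.add_edge(nodes[i], nodes[j])
            for cl in basis_set(g):
                assert nx.is_d_separator(g, {cl.x}, {cl.y}, set(cl.cond))


class TestFisherC:
    def test_all_p_one_gives_zero(self):
        C, df, p, aic = _combine_fisher([1.0, 1.0, 1.0], k_params=5)
        assert C == 0.0
        assert df == 6
        assert p == pytest.approx(1.0)
        assert aic == pytest.approx(10.0)

    def test_half_half_arithmetic(self):
        C, df, p, _ = _combine_fisher([0.5, 0.5], k_params=0)
        assert C == pytest.approx(-2 * (np.log(0.5) + np.log(0.5)))
        assert C == pytest.approx(2.7726, abs=1e-4)
        assert df == 4


def _chain_data(rng, n=120):
    x1 = rng.normal(size=n)
    x2 = 0.7 * x1 + rng.normal(size=n)
    x3 = 0.7 * x2 + rng.normal(size=n)
    x4 = 0.7 * x3 + rng.normal(size=n)
    return pd.DataFrame(dict(x1=x1, x2=x2, x3=x3, x4=x4))


CHAIN = nx.DiGraph([("x1", "x2"), ("x2", "x3"), ("x3", "x4")])


class TestDsep:
    def test_faithful_data_accepted(self):
        rng = np.random.default_rng(0)
        res = dsep_test(CHAIN, _chain_data(rng, 500), {}, factor_cols=None)
        assert res.p_global > 0.05
        assert res.df == 2 * len(res.claims)

    def test_violated_claim_detected(self):
        rng = np.random.default_rng(1)
        df = _chain_data(rng, 500)
        df["x4"] = df["x4"] + 0.8 * df["x1"]  # extra x1 -> x4 edge
        res = dsep_test(CHAIN, df, {}, factor_cols=None)
        assert res.p_global < 0.01


class TestStandardize:
    def test_prestandardized_linear_identity(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(0, 0.8, n)
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        df = pd.DataFrame({"x": x, "y": y})
        g = nx.DiGraph([("x", "y")])
        fit = fit_sem(g, df, {}, factor_cols=None)
        row = fit.edges.iloc[0]
        assert row["beta_std"] == pytest.approx(row["beta"], rel=1e-10)
        assert abs(row["beta_std"]) <= 1.0 + 1e-9

    def test_bernoulli_null_denominator_closed_form(self):
        comp = ComponentFit(
            response="y", parents=["x"], family="bernoulli",
            beta=pd.Series({"intercept": 0.0, "x": 1.0}),
            se=pd.Series({"intercept": 0.1, "x": 0.1}),
            pvalues=pd.Series({"intercept": 1.0, "x": 1.0}),
            sigma={}, sigma_resid=None, fixed_var=0.0, n_params=3, loglik=0.0,
        )
        data = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [0, 1, 0, 1]})
        edges = standardize_paths({"y": comp}, data)
        sd_x = data["x"].std(ddof=0)
        assert edges["beta_std"].iloc[0] == pytest.approx(sd_x / LOGIT_SD)
        assert LOGIT_SD == pytest.approx(1.8138, abs=1e-4)


class TestEffects:
    def _fit_from_edges(self, edge_rows, nodes):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        edges = pd.DataFrame(edge_rows)
        for r in edges.itertuples(index=False):
            g.add_edge(r.source, r.target)
        from fishestab.sem import SemFit, DSepResult

        dsep = DSepResult(claims=[], pvalues=[], fisher_c=0.0, df=0,
                          p_global=1.0, k_params=0, aic=0.0)
        return SemFit(graph=g, components={}, dsep=dsep, edges=edges, r2c={})

    def test_chain_indirect_only(self):
        fit = self._fit_from_edges(
            [{"source": "A", "target": "B", "beta": 0, "beta_std": 0.5, "p": 0.001},
             {"source": "B", "target": "Y", "beta": 0, "beta_std": 0.4, "p": 0.001}],
            ["A", "B", "Y"],
        )
        eff = effects_decomposition(fit, target="Y").table
        assert eff.loc["A", "direct"] == 0.0
        assert eff.loc["A", "indirect"] == pytest.approx(0.2)
        assert eff.loc["A", "total"] == pytest.approx(0.2)

    def test_two_path_sum(self):
        fit = self._fit_from_edges(
            [{"source": "A", "target": "Y", "beta": 0, "beta_std": 0.3, "p": 0.001},
             {"source": "A", "target": "B", "beta": 0, "beta_std": 0.5, "p": 0.001},
             {"source": "B", "target": "Y", "beta": 0, "beta_std": 0.4, "p": 0.001}],
            ["A", "B", "Y"],
        )
        eff = effects_decomposition(fit, target="Y").table
        assert eff.loc["A", "total"] == pytest.approx(0.3 + 0.5 * 0.4)
        assert eff["relative_total"].sum() == pytest.approx(100.0)

    def test_nonsignificant_paths_prunable(self):
        fit = self._fit_from_edges(
            [{"source": "A", "target": "Y", "beta": 0, "beta_std": 0.3, "p": 0.5},
             {"source": "B", "target": "Y", "beta": 0, "beta_std": 0.4, "p": 0.001}],
            ["A", "B", "Y"],
        )
        eff = effects_decomposition(fit, target="Y", significant_only=True).table
        assert eff.loc["A", "total"] == 0.0
        eff_all = effects_decomposition(fit, target="Y", significant_only=False).table
        assert eff_all.loc["A", "total"] == pytest.approx(0.3)


class TestConditionalR2:
    def _comp(self, fixed_var, sigma, resid, family="gaussian"):
        return ComponentFit(
            response="y", parents=["x"], family=family,
            beta=pd.Series(dtype=float), se=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float), sigma=sigma, sigma_resid=resid,
            fixed_var=fixed_var, n_params=2, loglik=0.0,
        )

    def test_perfect_fit_limit(self):
        assert conditional_r2(self._comp(10.0, {}, 1e-6)) == pytest.approx(1.0, abs=1e-9)

    def test_null_model_closed_form(self):
        comp = self._comp(0.0, {"lake": 0.5}, 1.0)
        assert conditional_r2(comp) == pytest.approx(0.25 / 1.25)

    def test_bernoulli_latent_scale_and_bound(self):
        comp = self._comp(0.3, {"lake": 0.4}, None, family="bernoulli")
        r2c = conditional_r2(comp)
        marginal = 0.3 / (0.3 + 0.16 + np.pi**2 / 3)
        assert r2c == pytest.approx((0.3 + 0.16) / (0.3 + 0.16 + np.pi**2 / 3))
        assert r2c >= marginal


class TestSelection:
    def test_specificity_no_spurious_edges(self):
        added = 0
        for s in range(10):
            rng = np.random.default_rng(300 + s)
            fit, ledger = sem_selection(CHAIN, _chain_data(rng, 300), {}, factor_cols=None)
            added += len(fit.graph.edges) - len(CHAIN.edges)
        assert added <= 1  # spurious additions are rare

    def test_sensitivity_recovers_strong_edge(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(400 + s)
            df = _chain_data(rng, 400)
            df["x4"] = df["x4"] + 0.8 * df["x1"]
            fit, _ = sem_selection(CHAIN, df, {}, factor_cols=None)
            hits += fit.graph.has_edge("x1", "x4")
        assert hits >= 9

    def test_selection_never_worsens_aic(self):
        rng = np.random.default_rng(500)
        df = _chain_data(rng, 250)
        df["x4"] = df["x4"] + 0.5 * df["x1"]
        initial = fit_sem(CHAIN, df, {}, factor_cols=None)
        best, ledger = sem_selection(CHAIN, df, {}, factor_cols=None)
        assert best.aic <= initial.aic
        assert ledger[0]["action"] == "initial"


class TestDefaultDag:
    @pytest.mark.parametrize("variant", ["geography", "temperature"])
    @pytest.mark.parametrize("family", ["mean", "nearest"])
    def test_acyclic_with_terminal_outcome(self, variant, family):
        g = default_dag(variant=variant, family=family)
        assert nx.is_directed_acyclic_graph(g)
        assert g.out_degree("outcome") == 0
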