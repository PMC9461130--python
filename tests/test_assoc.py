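import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdgnet import assoc

from conftest import grid_refine_minimize


def orthonormal_design(n: int, p: int, seed: int) -> np.ndarray:
    """Mean-zero columns with X'X = n I (unit variance, orthogonal)."""
    rng = np.random.default_rng(seed)
    Q = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, p))]))[0]
    return Q[:, 1:] * np.sqrt(n)


class TestLog2Transform:
    def test_exact_values(self):
        tab = pd.DataFrame({"line": ["a", "b"], "environment": ["r1", "r1"],
                            "variable": ["m", "m"], "value": [8.0, 1.0]})
        out = assoc.log2_transform(tab)
        assert out["value"].tolist() == [3.0, 0.0]

    def test_non_positive_rejected_with_cell(self):
        tab = pd.DataFrame({"line": ["a"], "environment": ["r1"],
                            "variable": ["m"], "value": [0.0]})
        with pytest.raises(ValueError, match="line=a"):
            assoc.log2_transform(tab)


class TestBlup:
    @staticmethod
    def _table(values: np.ndarray) -> pd.DataFrame:
        n, k = values.shape
        rows = []
        for i in range(n):
            for j in range(k):
                rows.append({"line": f"l{i:02d}", "environment": f"E{j + 1}",
                             "variable": "t", "value": values[i, j]})
        return pd.DataFrame(rows)

    def test_no_noise_limit_equals_centered_line_mean(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        blup = assoc.compute_blup(self._table(vals))
        assert np.allclose(blup["t"].to_numpy(), [-1.5, -0.5, 0.5, 1.5])

    def test_no_line_variance_floors_blups_at_zero(self):
        rng = np.random.default_rng(0)
        vals = np.tile([0.0, 1.0], (30, 1)) + rng.normal(0, 1, size=(30, 2))
        vals -= vals.mean(axis=1, keepdims=True)  # kill line variance
        blup = assoc.compute_blup(self._table(vals))
        assert np.allclose(blup["t"].to_numpy(), 0.0)

    def test_matches_hand_computed_shrinkage(self):
        # 3 lines x 2 envs, worked through the method-of-moments equations
        vals = np.array([[0.0, 2.0], [4.0, 6.0], [2.0, 10.0]])
        blup = assoc.compute_blup(self._table(vals))
        centered = vals - vals.mean(axis=0)
        lm = centered.mean(axis=1)
        ms_line = 2 * (lm ** 2).sum() / 2
        resid = centered - lm[:, None]
        ms_err = (resid ** 2).sum() / 2
        s2g = max((ms_line - ms_err) / 2, 0)
        k = 2 * s2g / (2 * s2g + ms_err)
        assert np.allclose(blup["t"].to_numpy(), k * lm)

    def test_single_environment_rejected(self):
        tab = pd.DataFrame({"line": ["a", "b"], "environment": ["E1", "E1"],
                            "variable": ["t", "t"], "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            assoc.compute_blup(tab)


class TestPenalizedRegression:
    def test_full_shrinkage_above_lambda_max(self):
        X = orthonormal_design(40, 3, 1)
        y = X @ np.array([1.0, -0.5, 0.2]) + 0.1
        lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / len(y))
        for fit_fn in (assoc.fit_mcp, assoc.fit_scad):
            fit = fit_fn(X, y, lam_max * 1.001)
            assert fit.selected == []

    def test_large_signal_unbiased(self):
        # |z| > gamma*lambda: both penalties return the OLS value exactly
        X = orthonormal_design(50, 1, 2)
        y = X[:, 0] * 2.5
        z = float(X[:, 0] @ (y - y.mean())) / len(y)
        assert abs(assoc.fit_mcp(X, y, 0.3).coefficients.iloc[0] - z) < 1e-8
        assert abs(assoc.fit_scad(X, y, 0.3).coefficients.iloc[0] - z) < 1e-8

    @pytest.mark.parametrize("method,gamma", [("MCP", 3.0), ("SCAD", 3.7)])
    @pytest.mark.parametrize("lam", [0.1, 0.35, 0.8])
    def test_orthonormal_solution_matches_grid_minimizer(self, method, gamma, lam):
        X = orthonormal_design(60, 3, 3)
        rng = np.random.default_rng(4)
        y = X @ np.array([1.8, 0.45, 0.0]) + rng.normal(0, 0.4, 60)
        yc = y - y.mean()
        z = X.T @ yc / len(y)
        if method == "MCP":
            fit = assoc.fit_mcp(X, y, lam, gamma)
            pen = lambda b: assoc.mcp_penalty(np.array([b]), lam, gamma)
        else:
            fit = assoc.fit_scad(X, y, lam, gamma)
            pen = lambda b: assoc.scad_penalty(np.array([b]), lam, gamma)
        # orthonormal loss separates: minimize 0.5 (b - z_j)^2 + P(b) per axis
        oracle = np.array([grid_refine_minimize(lambda b: 0.5 * (b - zj) ** 2 + pen(b))
                           for zj in z])
        assert np.abs(fit.coefficients.to_numpy() - oracle).max() < 1e-6

    def test_objective_not_above_competitors(self):
        # the CD solution should beat the zero vector and OLS on the objective
        rng = np.random.default_rng(5)
        X = assoc._standardize(rng.normal(size=(50, 3)))
        y = X @ np.array([1.0, 0.0, -0.6]) + rng.normal(0, 0.5, 50)
        yc = y - y.mean()
        for method, fit_fn in (("MCP", assoc.fit_mcp), ("SCAD", assoc.fit_scad)):
            fit = fit_fn(X, y, 0.25)
            obj = assoc.penalized_objective(X, yc, fit.coefficients.to_numpy(),
                                            0.25, fit.gamma, method)
            ols = np.linalg.lstsq(X, yc, rcond=None)[0]
            for other in (np.zeros(3), ols):
                assert obj <= assoc.penalized_objective(
                    X, yc, other, 0.25, fit.gamma, method) + 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.05, 1.0))
    def test_random_p2_problems_beat_random_search(self, seed, lam):
        rng = np.random.default_rng(seed)
        X = assoc._standardize(rng.normal(size=(30, 2)))
        y = rng.normal(size=30)
        yc = y - y.mean()
        fit = assoc.fit_mcp(X, y, lam)
        obj = assoc.penalized_objective(X, yc, fit.coefficients.to_numpy(),
                                        lam, 3.0, "MCP")
        trials = rng.normal(0, 2, size=(200, 2))
        objs = [assoc.penalized_objective(X, yc, b, lam, 3.0, "MCP")
                for b in trials]
        assert obj <= min(objs) + 1e-9

    def test_parameter_domains(self):
        X = orthonormal_design(30, 2, 6)
        y = X[:, 0]
        with pytest.raises(ValueError):
            assoc.fit_mcp(X, y, 0.1, gamma=1.0)
        with pytest.raises(ValueError):
            assoc.fit_scad(X, y, 0.1, a=2.0)
        with pytest.raises(ValueError):
            assoc.fit_mcp(X * 2.0, y, 0.1)  # not unit variance


class TestSelectTraitAssociations:
    def test_perfect_predictor_selected(self):
        rng = np.random.default_rng(7)
        n = 100
        omics = pd.DataFrame(
            rng.normal(size=(n, 5)), columns=[f"m{j}" for j in range(5)],
            index=[f"l{i}" for i in range(n)],
        )
        trait = omics["m0"].rename("t")
        edges = assoc.select_trait_associations(trait, omics, seed=1)
        hit = {e.node_b: e for e in edges}
        assert "m0" in hit and hit["m0"].p_value < 1e-10

    def test_planted_variable_power(self):
        # partial R^2 = 0.1, n = 398: selection should be near-certain
        rng = np.random.default_rng(8)
        n, hits = 398, 0
        n_rep = 20
        for rep in range(n_rep):
            omics = pd.DataFrame(
                rng.normal(size=(n, 10)), columns=[f"m{j}" for j in range(10)],
                index=[f"l{i}" for i in range(n)],
            )
            beta = np.sqrt(0.1 / 0.9)
            trait = pd.Series(
                beta * omics["m3"] + rng.normal(size=n), index=omics.index, name="t"
            )
            edges = assoc.select_trait_associations(trait, omics, seed=rep,
                                                    n_folds=5)
            hits += any(e.node_b == "m3" for e in edges)
        assert hits >= 0.8 * n_rep

    def test_null_familywise_false_selection_rate(self):
        rng = np.random.default_rng(9)
        n, false = 200, 0
        n_rep = 40
        for rep in range(n_rep):
            omics = pd.DataFrame(
                rng.normal(size=(n, 10)), columns=[f"m{j}" for j in range(10)],
                index=[f"l{i}" for i in range(n)],
            )
            trait = pd.Series(rng.normal(size=n), index=omics.index, name="t")
            edges = assoc.select_trait_associations(trait, omics, seed=rep,
                                                    n_folds=5)
            false += bool(edges)
        assert false <= 0.10 * n_rep

    def test_too_few_lines_rejected(self):
        omics = pd.DataFrame(np.eye(5), index=[f"l{i}" for i in range(5)])
        trait = pd.Series(np.arange(5.0), index=omics.index, name="t")
        with pytest.raises(ValueError):
            assoc.select_trait_associations(trait, omics)


class TestGeneticCorrelation:
    @staticmethod
    def _table(line_effects: dict, rng, rep_sd=0.3, n_reps=2) -> pd.DataFrame:
        rows = []
        for var, eff in line_effects.items():
            for rep in range(n_reps):
                noise = rng.normal(0, rep_sd, size=len(eff))
                for i, v in enumerate(eff + noise):
                    rows.append({"line": f"l{i:04d}", "environment": f"rep{rep + 1}",
                                 "variable": var, "value": v})
        return pd.DataFrame(rows)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(10)
        tab = self._table({"a": rng.normal(size=100)}, rng)
        res = assoc.genetic_correlation(tab, "a", "a")
        assert res.defined and abs(res.r_g - 1.0) < 1e-9

    def test_scaled_variable_fully_correlated(self):
        rng = np.random.default_rng(11)
        g = rng.normal(size=398)
        tab = self._table({"a": g, "b": 2.0 * g}, rng)
        res = assoc.genetic_correlation(tab, "a", "b")
        assert abs(res.r_g - 1.0) < 0.05

    def test_known_genetic_covariance_recovered(self):
        # construct line effects whose *sample* covariance is exactly 0.5
        rng = np.random.default_rng(12)
        raw = rng.normal(size=(1000, 2))
        raw -= raw.mean(axis=0)
        white = raw @ np.linalg.cholesky(np.linalg.inv(np.cov(raw.T)))
        eff = white @ np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]])).T
        tab = self._table({"a": eff[:, 0], "b": eff[:, 1]}, rng)
        res = assoc.genetic_correlation(tab, "a", "b")
        assert abs(res.r_g - 0.5) < 0.05

    def test_symmetry_and_degenerate_flag(self):
        rng = np.random.default_rng(13)
        tab = self._table({"a": rng.normal(size=50), "b": rng.normal(size=50)}, rng)
        ab = assoc.genetic_correlation(tab, "a", "b")
        ba = assoc.genetic_correlation(tab, "b", "a")
        assert ab.r_g == pytest.approx(ba.r_g)
        # pure-noise variable: genetic variance ~0 -> flagged undefined
        noise = self._table({"a": rng.normal(size=50), "c": np.zeros(50)}, rng,
                            rep_sd=2.0)
        res = assoc.genetic_correlation(noise, "a", "c")
        if not res.defined:
            assert np.isnan(res.r_g)


class TestGGM:
    def test_bonferroni_threshold_exact(self):
        assert assoc.bonferroni_threshold(0.05, 10) == 0.005
        p = 20
        res_fam = p * (p - 1) // 2
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.normal(size=(100, p)))
        out = assoc.ggm_edges(df)
        assert out.threshold == 0.05 / res_fam

    def test_published_family_size_threshold(self):
        cut = assoc.bonferroni_threshold(0.05, 119_316)
        assert f"{cut:.2E}" == "4.19E-07"

    def test_no_shrinkage_limit_matches_recursive_formula(self):
        rng = np.random.default_rng(15)
        omega = np.eye(3)
        omega[0, 1] = omega[1, 0] = -0.3
        X = rng.multivariate_normal(np.zeros(3), np.linalg.inv(omega), size=5000)
        df = pd.DataFrame(X, columns=list("abc"))
        res = assoc.ggm_edges(df, shrinkage=0.0)
        R = np.corrcoef(X.T)
        expected = (R[0, 1] - R[0, 2] * R[1, 2]) / np.sqrt(
            (1 - R[0, 2] ** 2) * (1 - R[1, 2] ** 2)
        )
        assert abs(res.pcor.loc["a", "b"] - expected) < 1e-6

    def test_pcor_matrix_symmetric_and_bounded(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(rng.normal(size=(80, 10)))
        res = assoc.ggm_edges(df)
        P = res.pcor.to_numpy()
        assert np.allclose(P, P.T)
        assert np.abs(P).max() <= 1.0 + 1e-9

    def test_input_domains(self):
        rng = np.random.default_rng(17)
        with pytest.raises(ValueError):
            assoc.ggm_edges(pd.DataFrame(rng.normal(size=(50, 2))))
        with pytest.raises(ValueError):
            assoc.ggm_edges(pd.DataFrame(rng.normal(size=(3, 5))))


class TestTraitCliques:
    @staticmethod
    def _edge(a, b):
        return assoc.AssociationEdge(a, b, "x", 1.0, 0.01, "GGM")

    def test_triangle_with_trait(self):
        edges = [self._edge("t", "m"), self._edge("m", "l"), self._edge("t", "l")]
        cliques = assoc.trait_cliques(edges, {"t": "trait", "m": "metabolite",
                                              "l": "lipid"})
        assert len(cliques) == 1 and cliques[0]["members"] == ["l", "m", "t"]

    def test_no_trait_node_gives_empty(self):
        edges = [self._edge("m1", "m2")]
        assert assoc.trait_cliques(edges, {"m1": "metabolite", "m2": "metabolite"}) == []

    def test_matches_subset_enumeration_on_random_graphs(self):
        import networkx as nx

        from conftest import brute_force_maximal_cliques

        rng = np.random.default_rng(18)
        for _ in range(10):
            G = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1e6)))
            types = {n: ("trait" if n % 5 == 0 else "metabolite") for n in G.nodes}
            edges = [self._edge(str(a), str(b)) for a, b in G.edges]
            got = {frozenset(c["members"]) for c in assoc.trait_cliques(
                edges, {str(n): t for n, t in types.items()})}
            # isolated nodes are not part of the edge-defined association graph
            expect = {
                frozenset(str(v) for v in c)
                for c in brute_force_maximal_cliques(G)
                if any(types[v] == "trait" for v in c)
                and all(G.degree(v) > 0 for v in c)
            }
            assert got == expect
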