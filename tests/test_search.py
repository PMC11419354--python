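import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bapdeconf import (
    DirectedAcyclicGraph,
    SearchConfig,
    dsep_search,
    fisher_z_test,
    glasso_search,
    partial_correlation,
    random_dag,
    shipley_basis_set,
    shrink_covariance,
    sparsity_index,
    validate_bap,
)
from bapdeconf.search import DegenerateDataError, default_glasso_rho


class TestBasisSet:
    def test_chain(self, chain_dag):
        assert shipley_basis_set(chain_dag) == [("c", "a", frozenset({"b"}))]

    def test_collider_has_empty_cond(self):
        g = DirectedAcyclicGraph(["a", "b", "c"], [("a", "c"), ("b", "c")])
        assert shipley_basis_set(g) == [("b", "a", frozenset())]

    def test_diamond(self, diamond_dag):
        got = {(j, k): cond for j, k, cond in shipley_basis_set(diamond_dag)}
        assert got == {("d", "a"): {"b", "c"}, ("c", "b"): {"a"}}

    @given(seed=st.integers(0, 10_000))
    def test_count_equals_model_df(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 15))
        m = int(rng.integers(0, p * (p - 1) // 2 + 1))
        g = random_dag(p, m, seed)
        assert len(shipley_basis_set(g)) == len(g.missing_edges())


class TestSparsityIndex:
    @pytest.mark.parametrize(
        "n, p, expected", [(224, 109, 3), (1, 3, 0), (400, 190, 3)]
    )
    def test_values(self, n, p, expected):
        assert sparsity_index(n, p) == expected

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sparsity_index(0, 10)


class TestPartialCorrelation:
    def test_empty_cond_is_pearson(self, gaussian_frame):
        r = partial_correlation(gaussian_frame, "w", "x")
        expected = np.corrcoef(gaussian_frame["w"], gaussian_frame["x"])[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_residual_and_precision_routes_agree(self, gaussian_frame):
        r1 = partial_correlation(gaussian_frame, "w", "z", ["x", "y"], "residual")
        r2 = partial_correlation(gaussian_frame, "w", "z", ["x", "y"], "precision")
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_degenerate_regression_errors(self, gaussian_frame):
        df = gaussian_frame.copy()
        df["w2"] = 2.0 * df["w"]  # w is an exact function of the cond set
        with pytest.raises(DegenerateDataError):
            partial_correlation(df, "w", "x", ["w2"])


class TestFisherZ:
    def test_zero_correlation(self):
        z, p = fisher_z_test(0.0, 100, 0)
        assert z == 0.0 and p == 1.0

    def test_frozen_example(self):
        # r=0.5, n=100, no conditioning: z = atanh(0.5) * sqrt(97)
        z, p = fisher_z_test(0.5, 100, 0)
        assert z == pytest.approx(5.4100, abs=5e-4)
        assert p == pytest.approx(6.3e-8, rel=0.05)

    @given(r=st.floats(-0.999, 0.999))
    def test_sign_matches_r(self, r):
        z, p = fisher_z_test(r, 50, 2)
        assert math.copysign(1, z) == math.copysign(1, r) or r == 0
        assert 0 <= p <= 1

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="insufficient"):
            fisher_z_test(0.3, 5, 3)

    def test_perfect_correlation_flagged(self):
        with pytest.warns(UserWarning):
            z, p = fisher_z_test(1.0, 100, 0)
        assert p == 0.0 and math.isinf(z)


class TestShrinkCovariance:
    def test_large_n_close_to_sample(self, rng):
        X = rng.standard_normal((5000, 4)) @ np.diag([1.0, 2.0, 0.5, 1.5])
        S = np.cov(X.T)
        Ssh = shrink_covariance(X)
        assert np.abs(Ssh - S).max() < 0.05

    def test_high_dim_positive_definite(self, rng):
        X = rng.standard_normal((10, 50))
        Ssh = shrink_covariance(X)
        assert np.linalg.eigvalsh(Ssh).min() > 0

    def test_off_diagonals_shrunk_toward_zero(self, rng):
        X = rng.standard_normal((15, 8))
        S = np.cov(X.T)
        Ssh = shrink_covariance(X)
        off = ~np.eye(8, dtype=bool)
        assert np.all(np.abs(Ssh[off]) <= np.abs(S[off]) + 1e-12)

    def test_constant_column_named(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(DegenerateDataError, match="b"):
            shrink_covariance(df)


class TestDsepSearch:
    def _simulate_chain_with_conf(self, n, rho_ac, seed):
        # a -> b -> c, plus an error covariance between a and c
        rng = np.random.default_rng(seed)
        psi = np.array([[1.0, 0.0, rho_ac], [0.0, 1.0, 0.0], [rho_ac, 0.0, 1.0]])
        E = rng.multivariate_normal(np.zeros(3), psi, size=n)
        a = E[:, 0]
        b = 0.8 * a + E[:, 1]
        c = 0.8 * b + E[:, 2]
        return pd.DataFrame({"a": a, "b": b, "c": c})

    def test_power_injected_covariance_selected(self, chain_dag):
        data = self._simulate_chain_with_conf(2000, 0.6, seed=4)
        table, selected = dsep_search(chain_dag, data, SearchConfig())
        assert selected == {("a", "c")}
        assert table.n_selected == 1

    def test_null_chain_nothing_selected(self, chain_dag):
        data = self._simulate_chain_with_conf(500, 0.0, seed=5)
        table, selected = dsep_search(chain_dag, data, SearchConfig())
        assert table.fisher_df == 2 * table.n_performed
        rec = table.records[0]
        assert rec.p_adj >= rec.p - 1e-15

    def test_selected_pairs_are_bow_free(self):
        g = random_dag(12, 20, seed=9)
        spec_data = pd.DataFrame(
            np.random.default_rng(0).standard_normal((200, 12)), columns=g.nodes
        )
        table, selected = dsep_search(g, spec_data)
        validate_bap(g, selected)  # must not raise

    def test_cmax_skips_and_excludes_from_correction(self, diamond_dag):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.standard_normal((100, 4)), columns=list("abcd"))
        table, _ = dsep_search(diamond_dag, data, SearchConfig(cmax=1))
        skipped = [r for r in table.records if r.skipped]
        performed = [r for r in table.records if not r.skipped]
        assert len(skipped) == 1 and skipped[0].pair == ("d", "a")
        assert table.fisher_df == 2 * len(performed)
        assert all(math.isnan(r.p_adj) for r in skipped)

    def test_alpha_zero_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            SearchConfig(alpha=0.0)


class TestGlassoSearch:
    def _toy(self, rho_ac=0.7, n=400, seed=0):
        g = DirectedAcyclicGraph(
            ["a", "b", "c", "d"], [("a", "b", 0.8), ("b", "c", 0.8)]
        )
        rng = np.random.default_rng(seed)
        psi = np.eye(4)
        psi[0, 3] = psi[3, 0] = rho_ac  # confounder on missing pair (a, d)
        E = rng.multivariate_normal(np.zeros(4), psi, size=n)
        B = g.coefficient_matrix()
        Y = E @ np.linalg.inv(np.eye(4) - B).T
        return g, pd.DataFrame(Y, columns=g.nodes)

    def test_huge_rho_selects_nothing(self):
        g, data = self._toy()
        selected, _ = glasso_search(g, data, rho=10.0)
        assert selected == frozenset()

    def test_identity_covariance_selects_nothing(self):
        g = DirectedAcyclicGraph(list("abcd"))
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.standard_normal((5000, 4)), columns=list("abcd"))
        selected, _ = glasso_search(g, data, rho=0.3)
        assert selected == frozenset()

    def test_strong_covariance_selected_dag_edges_zero(self):
        g, data = self._toy()
        selected, omega = glasso_search(g, data)
        assert ("a", "d") in selected
        idx = {v: i for i, v in enumerate(g.nodes)}
        for u, v, _ in g.edges:
            assert omega[idx[u], idx[v]] == 0.0

    def test_matches_sklearn_oracle_unconstrained(self, rng):
        from sklearn.covariance import graphical_lasso

        from bapdeconf.search import _glasso

        A = rng.standard_normal((400, 4)) @ np.array(
            [[1, 0, 0, 0], [0.5, 1, 0, 0], [0, 0.5, 1, 0], [0, 0, 0, 1.0]]
        )
        S = np.corrcoef(A.T)
        alpha = 0.2
        P = np.full((4, 4), alpha)
        np.fill_diagonal(P, 0.0)  # sklearn convention: diagonal unpenalized
        mine = _glasso(S, P, tol=1e-7)
        _, theirs = graphical_lasso(S, alpha=alpha, tol=1e-12, max_iter=2000)
        assert np.abs(mine - theirs).max() < 1e-4

    def test_default_rho_formula(self):
        assert default_glasso_rho(224, 109) == pytest.approx(
            math.sqrt(math.log(109) / 224)
        )
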