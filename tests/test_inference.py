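import numpy as np
import pandas as pd
import pytest

import beetlenet as bn
from beetlenet.errors import InferenceError, ValidationError
from beetlenet.inference import _fit_glasso, _support, default_lambda_grid


def _matrix(values: np.ndarray) -> bn.BiomassMatrix:
    df = pd.DataFrame(
        values, index=[f"s{i}" for i in range(values.shape[0])],
        columns=[f"sp{j}" for j in range(values.shape[1])],
    )
    return bn.BiomassMatrix(df, value_kind="biomass")


class TestNormalizeBiomass:
    def test_columns_autoscaled(self):
        rng = np.random.default_rng(0)
        norm = bn.normalize_biomass(_matrix(rng.lognormal(size=(30, 4))))
        assert np.allclose(norm.mean(), 0.0, atol=1e-10)
        assert np.allclose(norm.std(ddof=1), 1.0, atol=1e-10)

    def test_auto_pseudocount_is_half_min_positive(self):
        values = np.array([[0.0, 4.0], [2.0, 8.0], [6.0, 1.0]])
        norm = bn.normalize_biomass(_matrix(values))
        # independent recomputation: c = min positive / 2 = 0.5
        c = 0.5
        logged = np.log2(values + c)
        expected = (logged - logged.mean(0)) / logged.std(0, ddof=1)
        assert np.allclose(norm.values, expected)

    def test_zero_variance_column_dropped(self):
        values = np.array([[1.0, 3.0], [1.0, 5.0], [1.0, 2.0]])
        norm = bn.normalize_biomass(_matrix(values))
        assert list(norm.columns) == ["sp1"]

    def test_all_constant_is_error(self):
        with pytest.raises(InferenceError):
            bn.normalize_biomass(_matrix(np.ones((4, 3))))


class TestPearsonWithP:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        norm = bn.normalize_biomass(_matrix(rng.lognormal(size=(20, 3))))
        corr = bn.pearson_with_p(norm)
        assert np.allclose(np.diag(corr.r.values), 1.0)
        assert np.allclose(corr.r.values, corr.r.values.T)

    def test_orthogonal_patterns_r_zero_p_one(self):
        x = pd.DataFrame({"a": [1.0, 1.0, -1.0, -1.0], "b": [1.0, -1.0, 1.0, -1.0]})
        corr = bn.pearson_with_p(x)
        assert corr.r.at["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert corr.p.at["a", "b"] == pytest.approx(1.0)

    def test_perfect_correlation_p_zero(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        corr = bn.pearson_with_p(x)
        assert corr.r.at["a", "b"] == pytest.approx(1.0)
        assert corr.p.at["a", "b"] == 0.0

    def test_too_few_samples_is_error(self):
        with pytest.raises(InferenceError):
            bn.pearson_with_p(pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 1.0]}))

    def test_p_matches_permutation_estimate(self):
        # analytic t-test p vs a seeded permutation null for one pair, n = 20
        rng = np.random.default_rng(42)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        frame = pd.DataFrame({"a": x, "b": y})
        p_analytic = bn.pearson_with_p(frame).p.at["a", "b"]
        r_obs = abs(np.corrcoef(x, y)[0, 1])
        n_perm = 20000
        perm_rs = np.empty(n_perm)
        for k in range(n_perm):
            perm_rs[k] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = float(np.mean(np.abs(perm_rs) >= r_obs))
        mc_err = 4 * np.sqrt(max(p_perm, 1 / n_perm) / n_perm)
        assert p_analytic == pytest.approx(p_perm, abs=max(0.005, mc_err))


class TestGlasso:
    def test_independent_columns_give_empty_support(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        for lam in (0.2, 0.5):
            theta = _fit_glasso(np.eye(5), lam)
            assert not _support(theta).any()
        rho, stars = bn.glasso_partial_correlations(x, stars_subsamples=10, seed=0)
        off = rho.values[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_chain_precision_recovered(self):
        # 3-variable chain: partial(1,2) = 0.4, partial(1,3) = 0
        theta = np.array([[1.0, -0.4, 0.0], [-0.4, 1.0, -0.4], [0.0, -0.4, 1.0]])
        cov = np.linalg.inv(theta)
        rng = np.random.default_rng(8)
        x = rng.multivariate_normal(np.zeros(3), cov, size=4000)
        from beetlenet.inference import _partials_from_precision

        S = np.corrcoef(x, rowvar=False)
        rho = _partials_from_precision(_fit_glasso(S, 0.005))
        assert rho[0, 1] == pytest.approx(0.4, abs=0.05)
        assert abs(rho[0, 2]) < 0.05

    def test_edge_count_monotone_in_lambda(self, planted_500):
        _, matrix, _, _ = planted_500
        norm = bn.normalize_biomass(matrix)
        S = np.corrcoef(norm.values, rowvar=False)
        counts = []
        for lam in default_lambda_grid(S, points=8):
            theta = _fit_glasso(S, lam)
            counts.append(int(_support(theta).sum() // 2))
        # grid is decreasing, so counts must be non-decreasing
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_invalid_grid_rejected(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 3)), columns=list("abc"))
        with pytest.raises(ValidationError):
            bn.glasso_partial_correlations(x, lambda_grid=np.array([0.1, 0.2]))


class TestBuildNetwork:
    def test_zero_partials_give_edgeless_network(self):
        rng = np.random.default_rng(5)
        norm = bn.normalize_biomass(_matrix(rng.lognormal(size=(30, 4))))
        corr = bn.pearson_with_p(norm)
        rho = pd.DataFrame(np.eye(4), index=norm.columns, columns=norm.columns)
        net = bn.build_network(rho, corr)
        assert net.number_of_nodes() == 4
        assert net.number_of_edges() == 0

    def test_duplicate_columns_give_unit_edge(self):
        base = np.random.default_rng(6).lognormal(size=20)
        values = np.column_stack([base, base, np.random.default_rng(7).lognormal(size=20)])
        norm = bn.normalize_biomass(_matrix(values))
        corr = bn.pearson_with_p(norm)
        rho = pd.DataFrame(
            [[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]],
            index=norm.columns, columns=norm.columns,
        )
        net = bn.build_network(rho, corr)
        data = net.edges["sp0", "sp1"]
        assert data["pearson_r"] == pytest.approx(1.0)
        assert data["p"] == 0.0
        assert data["sign"] == 1

    def test_dimension_mismatch_is_error(self):
        rng = np.random.default_rng(5)
        norm = bn.normalize_biomass(_matrix(rng.lognormal(size=(30, 4))))
        corr = bn.pearson_with_p(norm)
        rho = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValidationError):
            bn.build_network(rho, corr)

    def test_edges_subset_of_significant_pearson_pairs(self, planted_500):
        _, matrix, _, _ = planted_500
        norm = bn.normalize_biomass(matrix)
        corr = bn.pearson_with_p(norm)
        rho, _ = bn.glasso_partial_correlations(norm, stars_subsamples=10, seed=2)
        net = bn.build_network(rho, corr, alpha=0.05)
        for u, v in net.edges:
            assert corr.p.at[u, v] <= 0.05


class TestInferenceInvariants:
    def test_sign_coherence_on_planted_data(self, planted_500):
        spec, matrix, _, truth = planted_500
        net, _ = bn.infer_network(matrix, seed=spec.seed, stars_subsamples=20)
        true_edges = {frozenset(e) for e in truth.edges}
        matches, considered = 0, 0
        for u, v, data in net.edges(data=True):
            if frozenset((u, v)) in true_edges:
                considered += 1
                planted_sign = np.sign(truth.partial_corr.at[u, v])
                if np.sign(data["pearson_r"]) == planted_sign:
                    matches += 1
        assert considered > 0
        assert matches / considered >= 0.9

    def test_permutation_null_yields_sparse_networks(self):
        # column-wise independent shuffles destroy all dependence; the
        # inferred edge count should stay below 5% of possible pairs
        p, n = 8, 60
        spec = bn.PlantedCommunitySpec(n_species=p, n_clusters=2, n_samples=n, seed=3)
        survey, _, _, _ = bn.make_planted_community(spec)
        matrix = bn.build_biomass_matrix(survey, value_kind="biomass")
        rng = np.random.default_rng(9)
        counts = []
        for _ in range(50):
            shuffled = matrix.values.apply(lambda col: rng.permutation(col.values))
            m = bn.BiomassMatrix(shuffled, value_kind="biomass")
            net, _ = bn.infer_network(
                m, seed=int(rng.integers(2**31)), stars_subsamples=10,
                lambda_grid=None,
            )
            counts.append(net.number_of_edges())
        assert np.mean(counts) <= 0.05 * p * (p - 1) / 2
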