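import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import beetlenet as bn
from beetlenet.errors import ValidationError


class TestShannon:
    def test_uniform_community_is_log_richness(self):
        assert bn.shannon_index([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_single_species_is_zero(self):
        assert bn.shannon_index([7]) == 0.0

    def test_zero_counts_ignored(self):
        assert bn.shannon_index([5, 0, 5]) == pytest.approx(np.log(2))

    def test_all_zero_is_error(self):
        with pytest.raises(ValidationError):
            bn.shannon_index([0, 0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 200), min_size=1, max_size=30).filter(lambda c: sum(c) > 0))
    def test_bounded_by_log_richness(self, counts):
        h = bn.shannon_index(counts)
        s = sum(1 for c in counts if c > 0)
        assert -1e-12 <= h <= np.log(s) + 1e-12


class TestDominance:
    def _matrix(self, totals: dict) -> bn.BiomassMatrix:
        df = pd.DataFrame([totals], index=["s1"]).astype(float)
        df.index.name = "sample_id"
        return bn.BiomassMatrix(df, value_kind="abundance")

    def test_two_species_shares(self):
        d = bn.dominance_table(self._matrix({"a": 30, "b": 70}))
        assert d["b"] == pytest.approx(70.0)
        assert d["a"] == pytest.approx(30.0)
        assert list(d.index) == ["b", "a"]  # sorted descending

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        d = bn.dominance_table(self._matrix({f"sp{i}": rng.integers(1, 99) for i in range(12)}))
        assert d.sum() == pytest.approx(100.0, abs=1e-9)


class TestGroupAggregate:
    @pytest.fixture
    def matrix_and_meta(self):
        values = pd.DataFrame(
            {"spA": [2.0, 4.0], "spB": [1.0, 0.0], "spC": [0.0, 3.0]},
            index=["s1", "s2"],
        )
        matrix = bn.BiomassMatrix(values, value_kind="abundance")
        meta = pd.DataFrame(
            {
                "species_id": ["spA", "spB", "spC"],
                "ecological_group": ["eurytope", "eurytope", "tyrphophile"],
                "functional_group": ["predator", "shredder", "predator"],
            }
        ).set_index("species_id", drop=False)
        return matrix, meta

    def test_single_group_equals_total(self, matrix_and_meta):
        matrix, meta = matrix_and_meta
        meta = meta.assign(ecological_group="eurytope")
        agg = bn.group_aggregate(matrix, meta, "ecological")
        assert agg.at["eurytope", "N"] == pytest.approx(matrix.values.values.sum())

    @pytest.mark.parametrize("grouping", ["ecological", "functional"])
    def test_groups_partition_total(self, matrix_and_meta, grouping):
        matrix, meta = matrix_and_meta
        agg = bn.group_aggregate(matrix, meta, grouping)
        assert agg["N"].sum() == pytest.approx(matrix.values.values.sum())

    def test_occurrence_mean_sd_hand_computed(self, matrix_and_meta):
        matrix, meta = matrix_and_meta
        agg = bn.group_aggregate(matrix, meta, "ecological")
        # eurytope occurrences: 2, 4 (spA), 1 (spB)
        cells = np.array([2.0, 4.0, 1.0])
        assert agg.at["eurytope", "mean"] == pytest.approx(cells.mean())
        assert agg.at["eurytope", "sd"] == pytest.approx(cells.std(ddof=1))
        assert agg.at["eurytope", "S"] == 2

    def test_unclassified_species_listed(self, matrix_and_meta):
        matrix, meta = matrix_and_meta
        with pytest.raises(ValidationError, match="spC"):
            bn.group_aggregate(matrix, meta.drop("spC"), "ecological")


class TestKruskalWallis:
    def test_hand_computed_two_groups(self):
        res = bn.kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.H == pytest.approx(3.857, abs=5e-4)
        assert res.df == 1

    def test_all_tied_gives_zero(self):
        res = bn.kruskal_wallis([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.H == 0.0
        assert res.p == 1.0

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_matches_scipy_reference(self, with_ties):
        rng = np.random.default_rng(11)
        if with_ties:
            values = rng.integers(0, 6, size=60).astype(float)
        else:
            values = rng.normal(size=60)
        groups = np.repeat(["a", "b", "c"], 20)
        res = bn.kruskal_wallis(values, groups)
        ref = stats.kruskal(values[groups == "a"], values[groups == "b"], values[groups == "c"])
        assert res.H == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_groups_equal_rank_sum_z_squared(self):
        # for k = 2, H equals the squared normal z of the rank-sum test
        rng = np.random.default_rng(5)
        values = rng.normal(size=30)
        groups = np.array(["a"] * 12 + ["b"] * 18)
        res = bn.kruskal_wallis(values, groups)
        n1, n2 = 12, 18
        ranks = stats.rankdata(values)
        w = ranks[groups == "a"].sum()
        z = (w - n1 * (n1 + n2 + 1) / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        assert res.H == pytest.approx(z**2, rel=1e-10)

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            bn.kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestPosthocMeanRanks:
    def test_identical_groups_adjusted_p_is_one(self):
        p = bn.posthoc_mean_ranks([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_separated_pair_has_smallest_p(self):
        values = np.concatenate([np.arange(10), np.arange(10) + 0.5, np.arange(10) + 40])
        groups = np.repeat(["a", "b", "c"], 10)
        p = bn.posthoc_mean_ranks(values, groups)
        assert p.loc["a", "c"] < p.loc["a", "b"]
        assert p.loc["b", "c"] < p.loc["a", "b"]

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=45)
        groups = np.repeat(["a", "b", "c"], 15)
        adjusted = bn.posthoc_mean_ranks(values, groups)
        n = len(values)
        ranks = stats.rankdata(values)
        for gi, gj in (("a", "b"), ("a", "c"), ("b", "c")):
            se = np.sqrt((n * (n + 1) / 12.0) * (1 / 15 + 1 / 15))
            z = abs(ranks[groups == gi].mean() - ranks[groups == gj].mean()) / se
            raw = 2 * stats.norm.sf(z)
            assert adjusted.loc[gi, gj] >= raw - 1e-15
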