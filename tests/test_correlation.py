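import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from grnsign.correlation import (
    all_possible_pairs,
    mann_whitney_u,
    pair_correlations,
)
from grnsign.expression import ExpressionCompendium
from grnsign.network import Edge, RegulatoryNetwork

from .conftest import small_compendium


def comp_from_rows(rows: dict[str, list[float]]) -> ExpressionCompendium:
    genes = list(rows)
    values = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(next(iter(rows.values()))))]).T
    meta = pd.DataFrame({"dataset": ["d0"] * values.shape[1],
                         "platform": ["microarray"] * values.shape[1]},
                        index=pd.Index(values.columns, name="sample"))
    return ExpressionCompendium(values, meta)


class TestPairCorrelations:
    def test_identical_profiles_correlate_to_one(self):
        comp = comp_from_rows({"tf": [1.0, 2.0, 3.0], "tg": [1.0, 2.0, 3.0]})
        net = RegulatoryNetwork(set(), [Edge("tf", "tg", 1)])
        s = pair_correlations(net, comp, include_all_possible=False)
        assert s.pairs["r"].tolist() == [pytest.approx(1.0)]

    def test_negated_profile_correlates_to_minus_one(self):
        comp = comp_from_rows({"tf": [1.0, 2.0, 3.0], "tg": [-1.0, -2.0, -3.0]})
        net = RegulatoryNetwork(set(), [Edge("tf", "tg", -1)])
        s = pair_correlations(net, comp, include_all_possible=False)
        assert s.pairs["r"].tolist() == [pytest.approx(-1.0)]

    def test_mc_is_mean_of_pair_correlations(self):
        rng = np.random.default_rng(0)
        comp = small_compendium(rng, n_genes=6)
        net = RegulatoryNetwork(set(), [Edge("g0", "g1", 1), Edge("g0", "g2", 1),
                                        Edge("g3", "g4", -1)])
        s = pair_correlations(net, comp, include_all_possible=False)
        assert s.mc["known_pairs"] == pytest.approx(s.pairs["r"].mean())
        assert s.n_pairs["known_pairs"] == 3

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(1)
        comp = small_compendium(rng, n_genes=12, per_dataset=10, n_datasets=2)
        edges = [Edge(f"g{i}", f"g{i+6}", 1) for i in range(6)]
        net = RegulatoryNetwork(set(), edges)
        sp = pair_correlations(net, comp, method="spearman", include_all_possible=False)
        ranked = comp.copy_with(pd.DataFrame(
            rankdata(comp.values.to_numpy(), axis=1),
            index=comp.values.index, columns=comp.values.columns))
        pe = pair_correlations(net, ranked, method="pearson", include_all_possible=False)
        np.testing.assert_allclose(sp.pairs["r"], pe.pairs["r"], atol=1e-12)

    def test_pearson_equals_spearman_on_monotone_linear_data(self):
        comp = comp_from_rows({"tf": [1.0, 2.0, 3.0, 4.0], "tg": [2.0, 4.0, 6.0, 8.0]})
        net = RegulatoryNetwork(set(), [Edge("tf", "tg", 1)])
        for m in ("pearson", "spearman"):
            s = pair_correlations(net, comp, method=m, include_all_possible=False)
            assert s.pairs["r"].tolist() == [pytest.approx(1.0)]

    def test_constant_profile_skipped_and_counted(self):
        comp = comp_from_rows({"tf": [1.0, 1.0, 1.0], "tg": [1.0, 2.0, 3.0]})
        net = RegulatoryNetwork(set(), [Edge("tf", "tg", 1)])
        s = pair_correlations(net, comp, include_all_possible=False)
        assert len(s.pairs) == 0
        assert s.n_skipped_constant == 1
        assert s.mc["known_pairs"] is None  # undefined, not 0

    def test_missing_gene_dropped_and_counted(self):
        comp = comp_from_rows({"tf": [1.0, 2.0, 3.0]})
        net = RegulatoryNetwork(set(), [Edge("tf", "ghost", 1)])
        s = pair_correlations(net, comp, include_all_possible=False)
        assert s.n_skipped_missing == 1 and len(s.pairs) == 0


class TestAllPossiblePairs:
    def test_counting_two_tfs_four_genes(self):
        rng = np.random.default_rng(0)
        comp = small_compendium(rng, n_genes=4)
        net = RegulatoryNetwork(set(), [Edge("g0", "g1", 1), Edge("g2", "g3", -1)])
        pairs = all_possible_pairs(net, comp)
        assert len(pairs) == 2 * 4 - 2  # self-pairs excluded
        assert pairs["known"].sum() == 2

    def test_empty_tf_set(self):
        rng = np.random.default_rng(0)
        comp = small_compendium(rng)
        assert len(all_possible_pairs(RegulatoryNetwork({"x"}, []), comp)) == 0

    def test_size_matches_brute_force(self):
        rng = np.random.default_rng(5)
        comp = small_compendium(rng, n_genes=7)
        net = RegulatoryNetwork(set(), [Edge("g0", "g1", 1), Edge("g1", "g2", -1),
                                        Edge("g5", "g0", 1)])
        tfs = {"g0", "g1", "g5"}
        expected = sum(1 for tf in tfs for g in comp.values.index if tf != g)
        assert len(all_possible_pairs(net, comp)) == expected


def brute_force_mw_p(x, y):
    """Exact two-sided p by enumerating value partitions and counting U as
    the number of (x_i > y_j) wins plus half-ties (pairwise counting, an
    independent route to U)."""
    def u_stat(a, b):
        return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0
                   for xi in a for yj in b)
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = u_stat(x, y)
    total = extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(a, b) - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


class TestMannWhitney:
    def test_disjoint_groups_exact(self):
        gc = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert gc.u == 0.0
        assert gc.p_value == pytest.approx(0.1)
        assert gc.method == "exact"

    def test_identical_groups(self):
        gc = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert gc.u == pytest.approx(16 / 2)
        assert gc.p_value == pytest.approx(1.0)

    def test_symmetry_complementary_u_same_p(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=5).tolist(), rng.normal(size=7).tolist()
        a, b = mann_whitney_u(x, y), mann_whitney_u(y, x)
        assert a.u + b.u == pytest.approx(len(x) * len(y))
        assert a.p_value == pytest.approx(b.p_value)

    def test_exact_matches_pairwise_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n1, n2 = rng.integers(1, 5, size=2)
            x = rng.integers(0, 5, size=n1).tolist()  # integer values force ties
            y = rng.integers(0, 5, size=n2).tolist()
            gc = mann_whitney_u(x, y)
            u_oracle, p_oracle = brute_force_mw_p(x, y)
            assert gc.u == pytest.approx(u_oracle)
            assert gc.p_value == pytest.approx(p_oracle)

    def test_normal_approximation_close_to_exact_and_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.normal(size=10).tolist()
            y = rng.normal(size=9).tolist()  # combined 19 > 16 -> normal branch
            gc = mann_whitney_u(x, y)
            assert gc.method == "normal"
            ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert gc.p_value == pytest.approx(ref.pvalue, abs=1e-9)
            exact = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert abs(gc.p_value - exact.pvalue) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
        with pytest.raises(ValueError):
            mann_whitney_u([1.0], [])
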