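"""Tests of limited-order partial correlations, NRR ranking and PR evaluation."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from oracles import nrr_bruteforce, partial_corr_residuals
from rewirescope import netinfer, simulate
from rewirescope.datatypes import GgmSpec, GoldStandardNetwork


def _gaussian(n, p, seed=0):
    return np.random.default_rng(seed).normal(size=(n, p))


class TestPartialCorrelation:
    def test_zeroth_order_equals_pearson(self):
        data = _gaussian(100, 4, seed=1)
        r0 = netinfer.partial_correlation(data, 0, 2)
        assert r0 == pytest.approx(float(np.corrcoef(data[:, 0], data[:, 2])[0, 1]))

    def test_identical_variables_have_unit_partial_correlation(self):
        data = _gaussian(50, 4, seed=2)
        data[:, 1] = data[:, 0]
        assert netinfer.partial_correlation(data, 0, 1, [2]) == pytest.approx(1.0)

    def test_matches_residual_regression_oracle(self):
        data = _gaussian(200, 6, seed=3)
        for Q in [(2,), (2, 3), (2, 3, 4, 5)]:
            mine = netinfer.partial_correlation(data, 0, 1, list(Q))
            ref = partial_corr_residuals(data, 0, 1, Q)
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_chain_mediator_explains_association_away(self):
        # i -- k -- j chain: conditioning on k leaves ~zero partial correlation
        spec = GgmSpec(p=3, edges=((0, 1), (1, 2)), magnitude=0.5, n=50_000)
        data = simulate.simulate_ggm(spec, seed=4)
        r = netinfer.partial_correlation(data, 0, 2, [1])
        assert abs(r) < 0.02
        # and the marginal correlation is clearly nonzero
        assert abs(netinfer.partial_correlation(data, 0, 2)) > 0.05

    def test_preconditions(self):
        data = _gaussian(10, 5, seed=5)
        with pytest.raises(ValueError):
            netinfer.partial_correlation(data, 0, 0)
        with pytest.raises(ValueError):
            netinfer.partial_correlation(data, 0, 1, [1])
        with pytest.raises(ValueError):
            netinfer.partial_correlation(data, 0, 1, list(range(2, 10)) + [11])


class TestNrrPair:
    def test_identical_variables_always_rejected(self):
        data = _gaussian(60, 5, seed=6)
        data[:, 1] = data[:, 0]
        for q in (1, 2):
            assert netinfer.nrr_pair(data, 0, 1, q=q, seed=0) == 0.0

    def test_exhaustive_order_one_equals_mean_of_individual_tests(self):
        # 4 variables: exactly two order-1 conditioning sets for a pair
        data = _gaussian(40, 4, seed=7)
        n = data.shape[0]
        df = n - 1 - 2
        tcrit = stats.t.ppf(0.975, df)
        outcomes = []
        for k in (2, 3):
            r = netinfer.partial_correlation(data, 0, 1, [k])
            t = abs(r) * math.sqrt(df / (1 - r * r))
            outcomes.append(t <= tcrit)
        assert netinfer.nrr_pair(data, 0, 1, q=1, seed=3) == pytest.approx(
            np.mean(outcomes)
        )

    def test_deterministic_given_seed_in_sampling_regime(self):
        data = _gaussian(80, 30, seed=8)
        a = netinfer.nrr_pair(data, 0, 1, q=5, n_subsets=20, seed=9)
        b = netinfer.nrr_pair(data, 0, 1, q=5, n_subsets=20, seed=9)
        assert a == b

    def test_order_bound_enforced(self):
        data = _gaussian(10, 20, seed=10)
        with pytest.raises(ValueError, match="n - 2"):
            netinfer.nrr_pair(data, 0, 1, q=8)


class TestAverageNrr:
    def test_single_order_equals_nrr_pair_when_exhaustive(self):
        data = _gaussian(50, 6, seed=11)
        table = netinfer.average_nrr(data, [(0, 1)], q_set=(2,), n_subsets=100, seed=12)
        direct = netinfer.nrr_pair(data, 0, 1, q=2, n_subsets=100, seed=99)
        assert table.table["avg_nrr"].iloc[0] == pytest.approx(direct)

    def test_q_set_order_invariance(self):
        data = _gaussian(60, 10, seed=13)
        pairs = [(0, 1), (0, 2)]
        a = netinfer.average_nrr(data, pairs, q_set=(1, 3, 5), n_subsets=10, seed=14)
        b = netinfer.average_nrr(data, pairs, q_set=(5, 1, 3), n_subsets=10, seed=14)
        assert a.table.equals(b.table)

    def test_invariant_under_affine_variable_rescaling(self):
        data = _gaussian(60, 8, seed=15)
        scaled = data.copy()
        scaled[:, 3] = 10.0 * scaled[:, 3] - 4.0
        pairs = [(0, 3), (1, 2)]
        a = netinfer.average_nrr(data, pairs, q_set=(1, 2), n_subsets=15, seed=16)
        b = netinfer.average_nrr(scaled, pairs, q_set=(1, 2), n_subsets=15, seed=16)
        np.testing.assert_allclose(a.table["avg_nrr"], b.table["avg_nrr"], atol=1e-12)

    def test_matches_bruteforce_on_exhaustive_small_p(self):
        spec = GgmSpec(p=6, edges=((0, 1), (0, 2), (3, 4)), magnitude=0.4, n=50)
        data = simulate.simulate_ggm(spec, seed=17)
        pairs = [(0, j) for j in range(1, 6)]
        table = netinfer.average_nrr(data, pairs, q_set=(1, 2, 3), n_subsets=10_000, seed=0)
        for (i, j), row in table.table.iterrows():
            expect = np.mean([nrr_bruteforce(data, i, j, q) for q in (1, 2, 3)])
            assert row["avg_nrr"] == pytest.approx(expect, abs=1e-12)

    def test_true_edges_rank_above_non_edges(self):
        # planted GGM: direct partners keep low average NRR
        genes = [f"y{i:02d}" for i in range(30)]
        gold = simulate.simulate_gold_network(30, 5, max_degree=6, seed=18, genes=genes)
        gidx = {g: i for i, g in enumerate(genes)}
        spec = GgmSpec(
            p=30,
            edges=tuple((gidx[r], gidx[t]) for r, t, _, _ in gold.edges),
            magnitude=0.35,
            n=200,
        )
        data = simulate.simulate_ggm(spec, seed=19)
        regs = sorted(gidx[r] for r in gold.regulators)
        pairs = [(i, j) for i in regs for j in range(30) if j != i]
        table = netinfer.average_nrr(
            data, pairs, q_set=(1, 5, 10), n_subsets=50, seed=20, variables=genes
        )
        gold_pairs = {frozenset((r, t)) for r, t, _, _ in gold.edges}
        ranks = table.table["rank"]
        true_ranks = [
            ranks[(r, g)] for r, g in table.table.index if frozenset((r, g)) in gold_pairs
        ]
        other = [
            ranks[(r, g)] for r, g in table.table.index if frozenset((r, g)) not in gold_pairs
        ]
        assert np.median(true_ranks) < np.median(other)

    def test_power_increases_with_sample_size(self):
        # more samples -> more rejections on true edges -> lower average NRR
        edges = ((0, 5), (1, 6), (2, 7), (3, 8), (4, 9))
        means = []
        for n in (50, 100, 200):
            vals = []
            for seed in range(20):
                spec = GgmSpec(p=10, edges=edges, magnitude=0.35, n=n)
                data = simulate.simulate_ggm(spec, seed=1000 + seed)
                t = netinfer.average_nrr(
                    data, list(edges), q_set=(1, 3), n_subsets=30, seed=seed
                )
                vals.append(t.table["avg_nrr"].mean())
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            netinfer.average_nrr(_gaussian(20, 5, seed=21), [], q_set=(1,))


def _ranking_from_pairs(pairs):
    """A minimal NRRTable with the given (regulator, gene) order."""
    import pandas as pd

    table = pd.DataFrame(
        {"avg_nrr": np.linspace(0.0, 0.9, len(pairs)), "rank": np.arange(1, len(pairs) + 1)},
        index=pd.MultiIndex.from_tuples(pairs, names=["regulator", "gene"]),
    )
    return netinfer.NRRTable(table=table, q_set=(1,))


def _gold(edges, regulators=None):
    regulators = regulators or {r for r, _ in edges}
    return GoldStandardNetwork(
        regulators=frozenset(regulators),
        edges=tuple((r, t, 1, 1.0) for r, t in edges),
    )


class TestPrecisionRecall:
    def test_perfect_ranking_reaches_100_100(self):
        edges = [("a", "b"), ("a", "c"), ("d", "e")]
        curve = netinfer.precision_recall(_ranking_from_pairs(edges), _gold(edges))
        last = curve.points.iloc[-1]
        assert last["precision"] == pytest.approx(100.0)
        assert last["recall"] == pytest.approx(100.0)

    def test_hand_enumerated_curve(self):
        # gold edges at ranks 1 and 3 of 4; all endpoints eligible
        ranked = [("a", "b"), ("a", "c"), ("c", "d"), ("a", "d")]
        gold = _gold([("a", "b"), ("c", "d")], regulators={"a", "c"})
        curve = netinfer.precision_recall(_ranking_from_pairs(ranked), gold)
        p = curve.points.set_index("k")
        assert p.loc[2, "precision"] == pytest.approx(50.0)
        assert p.loc[2, "recall"] == pytest.approx(50.0)
        assert p.loc[4, "precision"] == pytest.approx(50.0)
        assert p.loc[4, "recall"] == pytest.approx(100.0)

    def test_ineligible_edge_leaves_precision_unchanged(self):
        gold = _gold([("a", "b")])
        base = netinfer.precision_recall(_ranking_from_pairs([("a", "b")]), gold)
        # "z" appears in no gold interaction: the extra prediction is skipped
        ext = netinfer.precision_recall(
            _ranking_from_pairs([("a", "b"), ("a", "z")]), gold
        )
        assert ext.points["precision"].iloc[-1] == base.points["precision"].iloc[-1]

    def test_undirected_matching(self):
        gold = _gold([("a", "b")])
        curve = netinfer.precision_recall(_ranking_from_pairs([("b", "a")]), gold)
        assert curve.points["tp"].iloc[-1] == 1

    def test_random_ranking_precision_matches_gold_density(self):
        # expected precision of a random ranking = gold density among eligible
        rng = np.random.default_rng(22)
        nodes = [f"n{i}" for i in range(10)]
        gold_edges = [("n0", f"n{i}") for i in range(1, 6)] + [("n6", "n7"), ("n6", "n8")]
        gold = _gold(gold_edges, regulators={"n0", "n6"})
        all_pairs = [(r, t) for r in ("n0", "n6") for t in nodes if t != r]
        density = 100.0 * len(gold_edges) / len(all_pairs)
        finals = []
        for _ in range(100):
            perm = [all_pairs[k] for k in rng.permutation(len(all_pairs))]
            c = netinfer.precision_recall(_ranking_from_pairs(perm), gold)
            finals.append(c.points["precision"].iloc[4])  # precision at k=5
        se = math.sqrt(density * (100 - density) / 5) / math.sqrt(100)
        assert np.mean(finals) == pytest.approx(density, abs=4 * se)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError, match="empty gold"):
            netinfer.precision_recall(
                _ranking_from_pairs([("a", "b")]),
                GoldStandardNetwork(regulators=frozenset(), edges=()),
            )


class TestNetworkAtPrecision:
    def test_perfect_prefix_returned_at_100(self):
        edges = [(f"r{i}", f"t{i}") for i in range(5)]
        gold = _gold(edges)
        ranking = _ranking_from_pairs(edges)
        curve = netinfer.precision_recall(ranking, gold)
        net = netinfer.network_at_precision(curve, ranking, 100.0)
        assert net.edges == edges

    def test_connected_components_are_modules(self):
        edges = [("a", "b"), ("b", "c"), ("d", "e")]
        gold = _gold(edges, regulators={"a", "b", "d"})
        ranking = _ranking_from_pairs(edges)
        curve = netinfer.precision_recall(ranking, gold)
        net = netinfer.network_at_precision(curve, ranking, 50.0)
        assert net.n_modules == 2
        assert sorted(map(sorted, net.modules)) == [["a", "b", "c"], ["d", "e"]]

    def test_unreachable_precision_raises(self):
        gold = _gold([("a", "b")])
        ranking = _ranking_from_pairs([("a", "c")])  # eligible? c not in gold
        curve = netinfer.precision_recall(_ranking_from_pairs([("a", "b")]), gold)
        # precision 100 everywhere here; ask for an impossible >100
        with pytest.raises(ValueError, match="never reached"):
            netinfer.network_at_precision(curve, ranking, 101.0)
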