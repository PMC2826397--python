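import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from dreambench.consensus_community import (
    classify_topologies,
    contingency_ratios,
    fisher_exact_two_sided,
    identifiability,
    ks_two_sample,
    random_community_reference,
    rank_sum_consensus,
    systematic_fp_analysis,
)
from dreambench.formats import GoldNetwork, PredictionList, ValidationError

from conftest import random_prediction


class TestRankSumConsensus:
    def test_hand_sum(self):
        e1, e2, e3 = ("a", "b"), ("b", "a"), ("a", "c")
        l1 = PredictionList(edges=(e1, e2, e3))
        l2 = PredictionList(edges=(e2, e1, e3))
        cons = rank_sum_consensus([l1, l2], universe=None)
        # sums over {a,b,c} universe (R=6): e1=3, e2=3, e3=6; rest unsubmitted
        assert cons.edges[0] == e1  # lexicographic tie-break beats e2
        assert cons.edges[1] == e2
        assert cons.edges[2] == e3

    def test_identical_lists(self, small_gold):
        rng = np.random.default_rng(0)
        pred = random_prediction(small_gold, rng)
        cons = rank_sum_consensus([pred, pred, pred], universe=small_gold)
        assert cons.edges == pred.edges

    def test_perfect_plus_reversed_pure_tiebreak(self, small_gold):
        rng = np.random.default_rng(1)
        pred = random_prediction(small_gold, rng)
        rev = PredictionList(edges=pred.edges[::-1])
        cons = rank_sum_consensus([pred, rev], universe=small_gold)
        assert cons.edges == tuple(sorted(small_gold.all_pairs()))

    def test_too_few_lists(self, small_gold):
        rng = np.random.default_rng(2)
        with pytest.raises(ValidationError, match="at least 2"):
            rank_sum_consensus([random_prediction(small_gold, rng)])

    def test_truncated_expected_rank(self, small_gold):
        # a list containing only one edge: that edge gets rank 1, all others
        # (k_t+1+R)/2 = (2+12)/2 = 7 from that list
        e = sorted(small_gold.edges)[0]
        short = PredictionList(edges=(e,))
        rng = np.random.default_rng(3)
        full = random_prediction(small_gold, rng)
        cons = rank_sum_consensus([short, full], universe=small_gold)
        assert len(cons) == small_gold.n_pairs
        # edge e has sum rank 1 + rank_full(e) <= 13; every other edge has
        # sum 7 + rank_full >= 8, so e is never last
        assert cons.edges.index(e) < small_gold.n_pairs - 1


class TestIdentifiability:
    def test_zero_teams(self, small_gold):
        hist = identifiability([], small_gold, cutoff=6)
        assert hist.bins == {0: small_gold.n_edges}

    def test_all_perfect(self, small_gold, perfect_prediction):
        hist = identifiability(
            [perfect_prediction] * 4, small_gold, cutoff=small_gold.n_edges
        )
        assert hist.bins == {4: small_gold.n_edges}

    def test_bins_sum_to_p(self, small_gold):
        rng = np.random.default_rng(0)
        preds = [random_prediction(small_gold, rng) for _ in range(5)]
        hist = identifiability(preds, small_gold)
        assert sum(hist.bins.values()) == small_gold.n_edges

    def test_cutoff_bound(self, small_gold):
        with pytest.raises(ValidationError, match="cutoff"):
            identifiability([], small_gold, cutoff=small_gold.n_pairs + 1)

    def test_random_teams_match_binomial(self):
        # per-edge votes for random teams ~ Binomial(n_teams, cutoff / R)
        rng = np.random.default_rng(4)
        n_teams, votes_all = 6, []
        for net_seed in range(10):
            nodes = [f"N{i}" for i in range(6)]
            pairs = [(a, b) for a in nodes for b in nodes if a != b]
            edge_idx = rng.choice(len(pairs), size=8, replace=False)
            gold = GoldNetwork.from_edges(
                {pairs[i] for i in edge_idx}, nodes=nodes
            )
            preds = [random_prediction(gold, rng) for _ in range(n_teams)]
            hist = identifiability(preds, gold, cutoff=2 * gold.n_edges, seed=1)
            votes_all.extend(hist.edge_votes())
        q = 16 / 30
        ref = stats.binom.rvs(n_teams, q, size=4000, random_state=5)
        d = stats.ks_2samp(votes_all, ref).statistic
        assert d < 0.1


class TestRandomCommunityReference:
    def test_bin_zero_fraction(self, small_gold):
        hists = random_community_reference(
            small_gold, n_teams=4, cutoff=3, n_reps=300, seed=0
        )
        frac0 = np.mean([h.bins.get(0, 0) / small_gold.n_edges for h in hists])
        expected = (1 - 3 / small_gold.n_pairs) ** 4
        se = np.std([h.bins.get(0, 0) / small_gold.n_edges for h in hists]) / np.sqrt(
            len(hists)
        )
        assert abs(frac0 - expected) < 3 * se + 1e-9

    def test_cutoff_r_all_in_top(self, small_gold):
        hists = random_community_reference(
            small_gold, n_teams=3, cutoff=small_gold.n_pairs, n_reps=5, seed=0
        )
        for h in hists:
            assert h.bins == {3: small_gold.n_edges}

    def test_seeded(self, small_gold):
        a = random_community_reference(small_gold, 3, 4, n_reps=5, seed=9)
        b = random_community_reference(small_gold, 3, 4, n_reps=5, seed=9)
        assert [h.bins for h in a] == [h.bins for h in b]


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_exact(self):
        d, p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0
        assert p == pytest.approx(2 / comb(6, 3))
        assert p == pytest.approx(0.1)

    def test_d_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            d, p = ks_two_sample(rng.normal(size=20), rng.normal(size=15))
            assert 0 <= d <= 1
            assert 0 < p <= 1

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            d, p = ks_two_sample(a, b)
            ref = stats.ks_2samp(a, b, method="exact")
            assert d == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestClassifyTopologies:
    def test_chain_shortcut(self):
        gold = GoldNetwork.from_edges(
            {("A", "B"), ("B", "C")}, nodes=["A", "B", "C"]
        )
        topo = classify_topologies(gold)
        assert topo.shortcut[("A", "C")]
        assert not topo.co_regulated[("A", "C")]

    def test_fan_co_regulation(self):
        gold = GoldNetwork.from_edges(
            {("A", "B"), ("A", "C")}, nodes=["A", "B", "C"]
        )
        topo = classify_topologies(gold)
        assert topo.co_regulated[("B", "C")]
        assert topo.co_regulated[("C", "B")]
        assert not topo.shortcut[("B", "C")]

    def test_disconnected_pair_generic(self):
        gold = GoldNetwork.from_edges(
            {("A", "B")}, nodes=["A", "B", "C", "D"]
        )
        topo = classify_topologies(gold)
        assert not topo.shortcut[("C", "D")]
        assert not topo.co_regulated[("C", "D")]

    def test_defined_for_all_negatives(self, small_gold):
        topo = classify_topologies(small_gold)
        assert set(topo.shortcut) == set(small_gold.negatives())


def fisher_oracle(table):
    """Independent oracle: hypergeometric enumeration, point-probability
    two-sided rule."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (
            comb(row1, x, exact=True)
            * comb(row2, col1 - x, exact=True)
            / comb(n, col1, exact=True)
        )

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_derived_example(self):
        assert fisher_exact_two_sided([[3, 1], [1, 3]]) == pytest.approx(
            fisher_oracle([[3, 1], [1, 3]])
        )
        assert fisher_exact_two_sided([[3, 1], [1, 3]]) == pytest.approx(
            0.485714285714, abs=1e-9
        )

    def test_oracle_equivalence_small_tables(self):
        # all 2x2 tables with total <= 12 (larger totals spot-checked below)
        for total in range(2, 13):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        if (a + b) == 0 or (c + d) == 0:
                            continue
                        if (a + c) == 0 or (b + d) == 0:
                            continue
                        table = [[a, b], [c, d]]
                        assert fisher_exact_two_sided(table) == pytest.approx(
                            fisher_oracle(table), abs=1e-10
                        ), table

    def test_oracle_equivalence_total_40(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cells = rng.multinomial(40, [0.25] * 4)
            table = [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
            if min(sum(table[0]), sum(table[1])) == 0:
                continue
            if min(table[0][0] + table[1][0], table[0][1] + table[1][1]) == 0:
                continue
            assert fisher_exact_two_sided(table) == pytest.approx(
                fisher_oracle(table), abs=1e-10
            )


class TestSystematicFP:
    def test_printed_ratios(self):
        r_sys, r_rare = contingency_ratios(((51, 47), (920, 8757)))
        assert round(r_sys, 2) == 1.09
        assert round(r_rare, 2) == 0.11

    def test_table_sums_to_negatives(self, small_gold):
        rng = np.random.default_rng(0)
        preds = [random_prediction(small_gold, rng) for _ in range(5)]
        result = systematic_fp_analysis(preds, small_gold, top_fraction=0.2)
        assert result.total == small_gold.n_negatives

    def test_tie_handling_flagged(self, small_gold):
        # identical teams vote identically: massive ties at the boundary
        rng = np.random.default_rng(1)
        pred = random_prediction(small_gold, rng)
        result = systematic_fp_analysis([pred] * 3, small_gold, top_fraction=0.1)
        assert result.n_systematic >= 1
        assert result.total == small_gold.n_negatives

    def test_fisher_p_valid(self, small_gold):
        rng = np.random.default_rng(2)
        preds = [random_prediction(small_gold, rng) for _ in range(4)]
        result = systematic_fp_analysis(preds, small_gold, top_fraction=0.25)
        assert 0 < result.fisher_p <= 1


class TestConsensusRobustness:
    def test_degrades_slower_than_worst(self):
        # one strong predictor plus progressively more random ones: the
        # consensus AUROC stays above the worst included individual's
        from dreambench.insilico_sim import SimulationConfig, generate_network
        from dreambench.network_score import auroc, confusion_curves

        rng = np.random.default_rng(0)
        margins = []
        for seed in range(20):
            cfg = SimulationConfig(n_nodes=8, n_edges=9, seed=seed, n_trajectories=0)
            net = generate_network(cfg)
            strong = PredictionList(
                edges=tuple(sorted(net.edges) + net.negatives())
            )
            weak = [random_prediction(net, rng) for _ in range(4)]
            members = [strong] + weak
            cons = rank_sum_consensus(members, universe=net)
            cons_auroc = auroc(confusion_curves(cons, net))
            worst = min(auroc(confusion_curves(m, net)) for m in members)
            margins.append(cons_auroc - worst)
        assert np.mean(margins) > 0.1
        assert np.min(margins) > -0.05
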