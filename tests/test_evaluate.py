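import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netgene.evaluate import (
    auprc,
    auroc,
    average_rank,
    bh_fdr,
    class_significance,
    competition_rank,
    edge_density,
    log2_prior_ratio,
    p_at_topk,
    property_performance_correlation,
    segregation,
    wilcoxon_signed_rank,
)
from netgene.exceptions import ValidationError
from netgene.network import GeneNetwork
from netgene.simulate import SimConfig, generate_planted_network

from conftest import random_network


def ranking(labels_in_order):
    """Scores/labels dicts for genes ranked in the given label order
    (distinct descending scores, so the order is the ranking)."""
    genes = [f"g{i:02d}" for i in range(len(labels_in_order))]
    scores = {g: 1.0 - 0.01 * i for i, g in enumerate(genes)}
    labels = {g: y for g, y in zip(genes, labels_in_order)}
    return scores, labels


def brute_force_ap(y):
    """Oracle: mean over positives of precision at each positive's rank."""
    hits = 0
    total = 0.0
    for rank, label in enumerate(y, start=1):
        if label == 1:
            hits += 1
            total += hits / rank
    return total / sum(y)


def brute_force_auroc(scores, labels):
    """Oracle: exhaustive positive-negative pair counting, ties half credit."""
    pos = [g for g, y in labels.items() if y == 1]
    neg = [g for g, y in labels.items() if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if scores[p] > scores[n]:
                total += 1.0
            elif scores[p] == scores[n]:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestRankingMetrics:
    def test_perfect_ranking_auprc_is_one(self):
        scores, labels = ranking([1, 1, 0, 0, 0])
        assert auprc(scores, labels) == 1.0

    def test_interleaved_ranking_hand_value(self):
        scores, labels = ranking([1, 0, 1, 0])
        assert auprc(scores, labels) == pytest.approx((1 / 2) * (1 + 2 / 3))

    def test_all_positives_last_closed_form(self):
        n = 7
        scores, labels = ranking([0] * (n - 1) + [1])
        assert auprc(scores, labels) == pytest.approx(1 / n)

    def test_score_ties_break_by_gene_id(self):
        scores = {"gA": 0.5, "gB": 0.5}
        labels = {"gA": 1, "gB": 0}
        assert auprc(scores, labels) == 1.0  # gA ranked first at equal score

    def test_single_class_rejected(self):
        scores, _ = ranking([1, 1])
        with pytest.raises(ValidationError):
            auprc(scores, {g: 1 for g in scores})

    def test_p_at_topk_hand_value(self):
        scores, labels = ranking([1, 0, 1, 0])
        assert p_at_topk(scores, labels, k=2) == 0.5

    def test_p_at_topk_defaults_to_positive_count(self):
        scores, labels = ranking([1, 0, 1, 0])
        assert p_at_topk(scores, labels) == 0.5  # K = 2 positives

    def test_p_at_topk_perfect(self):
        scores, labels = ranking([1, 1, 0, 0])
        assert p_at_topk(scores, labels) == 1.0

    def test_p_at_topk_k_too_large_rejected(self):
        scores, labels = ranking([1, 0])
        with pytest.raises(ValidationError):
            p_at_topk(scores, labels, k=3)

    def test_auroc_perfect_and_tied(self):
        scores, labels = ranking([1, 1, 0, 0])
        assert auroc(scores, labels) == 1.0
        flat = {g: 0.5 for g in scores}
        assert auroc(flat, labels) == 0.5

    def test_auroc_hand_value(self):
        scores, labels = ranking([1, 0, 1, 0])
        assert auroc(scores, labels) == pytest.approx(3 / 4)

    def test_all_metrics_match_enumeration_on_six_genes(self):
        """Exhaustive oracle across all rankings of 6 genes with 2 positives."""
        for pos_positions in itertools.combinations(range(6), 2):
            y = [1 if i in pos_positions else 0 for i in range(6)]
            scores, labels = ranking(y)
            assert auprc(scores, labels) == pytest.approx(brute_force_ap(y))
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels)
            )
            assert p_at_topk(scores, labels) == pytest.approx(sum(y[:2]) / 2)

    def test_auroc_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        scores = {g: float(rng.integers(0, 5)) for g in genes}  # many ties
        labels = {g: int(rng.random() < 0.4) for g in genes}
        labels[genes[0]], labels[genes[1]] = 1, 0  # ensure both classes
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels)
        )

    def test_random_ranking_mean_auprc_near_prior(self):
        """E[auPRC] under random ranking approaches the prior (the bias is
        O(1/n); at 1000 genes it sits inside +-0.01)."""
        rng = np.random.default_rng(42)
        n, n_pos = 1000, 250
        y0 = np.array([1] * n_pos + [0] * (n - n_pos))
        ranks = np.arange(1, n + 1)
        vals = np.empty(2000)
        for i in range(vals.size):
            y = rng.permutation(y0)
            vals[i] = ((np.cumsum(y) / ranks)[y == 1]).mean()
        assert abs(vals.mean() - n_pos / n) < 0.01


class TestLog2PriorRatio:
    def test_raw_equal_prior_is_zero(self):
        assert log2_prior_ratio(0.25, 0.25) == 0.0

    def test_perfect_metric_vs_quarter_prior(self):
        assert log2_prior_ratio(1.0, 0.25) == 2.0

    def test_zero_raw_maps_to_neg_inf(self):
        assert log2_prior_ratio(0.0, 0.25) == float("-inf")

    def test_perfect_ranking_equals_minus_log2_prior(self):
        prior = 0.2
        assert log2_prior_ratio(1.0, prior) == pytest.approx(-math.log2(prior))

    @pytest.mark.parametrize("prior", [0.0, 1.0, -0.5, 2.0])
    def test_invalid_prior_rejected(self, prior):
        with pytest.raises(ValidationError):
            log2_prior_ratio(0.5, prior)


class TestRanking:
    def test_competition_rank_with_tie(self):
        ranks = competition_rank({"A": 0.9, "B": 0.7, "C": 0.7, "D": 0.5})
        assert ranks == {"A": 1, "B": 2, "C": 2, "D": 4}

    def test_all_equal_all_rank_one(self):
        assert competition_rank({"A": 1.0, "B": 1.0, "C": 1.0}) == {
            "A": 1, "B": 1, "C": 1,
        }

    def test_strictly_decreasing(self):
        ranks = competition_rank({"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0})
        assert ranks == {"A": 1, "B": 2, "C": 3, "D": 4}

    def test_average_rank_mean(self):
        avg = average_rank([{"A": 1, "B": 2}, {"A": 3, "B": 2}])
        assert avg == {"A": 2.0, "B": 2.0}

    def test_average_rank_single_geneset(self):
        assert average_rank([{"A": 1, "B": 4}]) == {"A": 1.0, "B": 4.0}

    def test_average_rank_inconsistent_methods_rejected(self):
        with pytest.raises(ValidationError):
            average_rank([{"A": 1}, {"B": 1}])


def exact_signed_rank_oracle(diffs):
    """Independent oracle: enumerate all 2^n sign assignments of the ranks."""
    from scipy.stats import rankdata

    d = np.asarray([x for x in diffs if x != 0], float)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    p_low = (stats <= w_obs + 1e-12).mean()
    p_high = (stats >= w_obs - 1e-12).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_six_unanimous_pairs_exact_p(self):
        a = [5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        b = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(2 / 64)
        assert (res.n_a_wins, res.n_b_wins) == (6, 0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(0.3, 1.0, 10)
            b = rng.normal(0.0, 1.0, 10)
            res = wilcoxon_signed_rank(a, b)
            assert res.p_value == pytest.approx(exact_signed_rank_oracle(a - b))

    def test_matches_scipy_exact(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(11)
        a = rng.normal(0.5, 1.0, 14)
        b = rng.normal(0.0, 1.0, 14)
        expected = scipy_wilcoxon(a, b, method="exact").pvalue
        assert wilcoxon_signed_rank(a, b).p_value == pytest.approx(expected)

    def test_large_n_matches_scipy_approx(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(12)
        a = rng.normal(0.2, 1.0, 60)
        b = rng.normal(0.0, 1.0, 60)
        expected = scipy_wilcoxon(a, b, method="approx", correction=True).pvalue
        assert wilcoxon_signed_rank(a, b).p_value == pytest.approx(expected, rel=1e-6)

    def test_all_tied_flagged(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.all_tied and res.p_value == 1.0
        assert (res.n_a_wins, res.n_b_wins) == (0, 0)

    def test_swap_symmetry(self):
        a = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        b = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]
        r1 = wilcoxon_signed_rank(a, b)
        r2 = wilcoxon_signed_rank(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert (r1.n_a_wins, r1.n_b_wins) == (r2.n_b_wins, r2.n_a_wins)

    def test_zero_differences_excluded_from_ranking(self):
        # two tied pairs plus six increases: same p as the six alone
        a = [5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 1.0, 2.0]
        b = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 1.0, 2.0]
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(2 / 64)
        assert (res.n_a_wins, res.n_b_wins) == (6, 0)


class TestBhFdr:
    def test_textbook_example_all_converge(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_fdr([0.03]) == [0.03]

    def test_all_equal_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 20)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_fdr(p.tolist()) == pytest.approx(expected.tolist())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=15))
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_fdr(p)
        assert all(a >= r - 1e-12 for a, r in zip(adj, p))
        assert all(a <= 1.0 for a in adj)

    def test_monotone_in_rank_order(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 30)
        adj = np.array(bh_fdr(p.tolist()))
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestClassSignificance:
    def _table(self, sl_boost, n=20, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.1, 0.5, n)
        return {
            "SL-A": (base + sl_boost).tolist(),
            "SL-I": (base + sl_boost * 0.9).tolist(),
            "LP-A": base.tolist(),
            "LP-I": (base + 0.001).tolist(),
        }

    def test_total_sl_dominance_gives_class_verdict(self):
        verdict = class_significance(self._table(sl_boost=0.3))
        assert verdict.winner == "SL"
        assert verdict.win_fraction == 1.0

    def test_identical_methods_no_winner(self):
        vals = [0.2] * 10
        verdict = class_significance(
            {"SL-A": vals, "SL-I": vals, "LP-A": vals, "LP-I": vals}
        )
        assert verdict.winner is None
        assert verdict.win_fraction == 0.0

    def test_single_method_winner_not_bold_class(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 0.5, 20)
        noise = rng.normal(0, 0.05, 20)
        table = {
            "SL-A": (base + 0.3).tolist(),  # beats both LP methods
            "SL-I": (base + noise).tolist(),  # no systematic edge
            "LP-A": base.tolist(),
            "LP-I": (base - noise).tolist(),
        }
        verdict = class_significance(table)
        assert verdict.winner == "SL-A"

    def test_lp_class_can_win(self):
        table = self._table(sl_boost=0.3)
        flipped = {
            "LP-A": table["SL-A"], "LP-I": table["SL-I"],
            "SL-A": table["LP-A"], "SL-I": table["LP-I"],
        }
        verdict = class_significance(flipped)
        assert verdict.winner == "LP"
        assert verdict.win_fraction == 0.0

    def test_invariant_to_geneset_ordering(self):
        table = self._table(sl_boost=0.1, seed=4)
        perm = np.random.default_rng(2).permutation(20)
        shuffled = {m: [vals[i] for i in perm] for m, vals in table.items()}
        v1 = class_significance(table)
        v2 = class_significance(shuffled)
        assert v1.winner == v2.winner
        assert v1.win_fraction == pytest.approx(v2.win_fraction)
        for key in v1.adjusted_p_values:
            assert v1.adjusted_p_values[key] == pytest.approx(
                v2.adjusted_p_values[key]
            )

    def test_missing_method_rejected(self):
        with pytest.raises(ValidationError):
            class_significance({"SL-A": [0.1], "LP-A": [0.1]})


class TestGenesetNetworkProperties:
    def test_clique_density_is_one(self):
        genes = ["a", "b", "c", "d"]
        net = GeneNetwork.from_edges(
            [(u, v, 1.0) for i, u in enumerate(genes) for v in genes[i + 1:]]
        )
        assert edge_density(net, set(genes)) == 1.0

    def test_internally_disconnected_geneset_density_zero(self):
        net = GeneNetwork.from_edges([("a", "x", 1.0), ("b", "x", 1.0)])
        assert edge_density(net, {"a", "b"}) == 0.0

    def test_density_needs_two_members(self):
        net = GeneNetwork.from_edges([("a", "b", 1.0)])
        with pytest.raises(ValidationError):
            edge_density(net, {"a"})

    def test_planted_module_density_tracks_p_within(self):
        """Density of a 30-node module generated at p_within=0.3 lands within
        +-0.05 of 0.3 (binomial concentration), for 5 seeds."""
        for seed in range(5):
            cfg = SimConfig(
                n_genes=100, n_modules=1, module_size_range=(30, 30),
                p_within=0.3, p_between=0.0, seed=seed,
            )
            net, coll = generate_planted_network(cfg)
            d = edge_density(net, coll.sets["M00"])
            assert abs(d - 0.3) < 0.05

    def test_isolated_clique_segregation_one(self):
        genes = ["a", "b", "c"]
        net = GeneNetwork.from_edges(
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0), ("x", "y", 1.0)]
        )
        assert segregation(net, set(genes)) == 1.0

    def test_star_leaves_segregation_zero(self):
        net = GeneNetwork.from_edges(
            [("hub", leaf, 1.0) for leaf in ("l1", "l2", "l3")]
        )
        assert segregation(net, {"l1", "l2", "l3"}) == 0.0

    def test_no_incident_edges_rejected(self):
        net = GeneNetwork.from_edges([("a", "b", 1.0)], extra_nodes=["z"])
        with pytest.raises(ValidationError):
            segregation(net, {"z"})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_segregation_bounded_by_one(self, seed):
        net = random_network(20, 0.3, seed)
        rng = np.random.default_rng(seed)
        members = set(rng.choice(net.nodes, size=8, replace=False))
        assert 0.0 <= segregation(net, members) <= 1.0


class TestPropertyCorrelation:
    def test_monotone_pair_is_one(self):
        x = list(range(12))
        y = [v**2 for v in x]
        rho, (lo, hi) = property_performance_correlation(x, y)
        assert rho == 1.0

    def test_anti_monotone_pair_is_minus_one(self):
        x = list(range(12))
        y = [-v for v in x]
        rho, _ = property_performance_correlation(x, y)
        assert rho == -1.0

    def test_independent_pairs_near_zero(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rho, _ = property_performance_correlation(
                rng.normal(size=200), rng.normal(size=200), n_boot=50, seed=seed
            )
            hits += abs(rho) < 0.2
        assert hits >= 19

    def test_constant_input_flagged_as_nan(self):
        rho, (lo, hi) = property_performance_correlation(
            [1.0] * 12, list(range(12))
        )
        assert math.isnan(rho) and math.isnan(lo)

    def test_bootstrap_interval_brackets_estimate(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = x + rng.normal(scale=0.5, size=50)
        rho, (lo, hi) = property_performance_correlation(x, y, seed=1)
        assert lo <= rho <= hi
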