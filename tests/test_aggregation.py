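import itertools

import numpy as np
import pytest

from mecorank.aggregation import condorcet_aggregate, pairwise_winner, select_top_k
from mecorank.propagation import Config

from conftest import make_voter


def brute_force_tally(rankings, genes, delta):
    """Exhaustive pairwise tabulation, independent of the vectorized path.

    For every unordered pair (lexicographic call order) the per-voter winner
    is collected via pairwise_winner; A beats B overall iff strictly more
    voters prefer A. Returns gene -> wins - losses.
    """
    tally = {g: 0 for g in genes}
    for a, b in itertools.combinations(sorted(genes), 2):
        votes_a = sum(1 for r in rankings if pairwise_winner(a, b, r, delta) == a)
        votes_b = len(rankings) - votes_a
        if votes_a > votes_b:
            tally[a] += 1
            tally[b] -= 1
        elif votes_b > votes_a:
            tally[b] += 1
            tally[a] -= 1
    return tally


def random_voters(rng, n_genes, n_voters):
    genes = [f"g{i}" for i in range(n_genes)]
    voters = []
    for v in range(n_voters):
        scores = {g: float(rng.integers(0, 5)) for g in genes}  # ties likely
        mutated = {g for g in genes if rng.random() < 0.4}
        voters.append(make_voter(f"P{v}", scores, mutated))
    return genes, voters


class TestPairwiseWinner:
    def test_mutation_penalty_flips_a_score_gap(self):
        # mutated 0.90 beats unmutated 1.00 at delta 0.85
        voter = make_voter("P", {"A": 0.90, "B": 1.00, "z": 0.0}, mutated={"A"})
        assert pairwise_winner("A", "B", voter, delta=0.85) == "A"

    def test_tie_falls_to_second_argument(self):
        voter = make_voter("P", {"A": 0.5, "B": 0.5, "z": 0.0}, mutated=set())
        # normalized scores tie exactly -> "otherwise" branch
        assert pairwise_winner("A", "B", voter, delta=0.85) == "B"

    def test_tie_with_both_mutated(self):
        voter = make_voter("P", {"A": 0.5, "B": 0.5, "z": 0.0}, mutated={"A", "B"})
        assert pairwise_winner("A", "B", voter, delta=0.85) == "B"

    def test_unranked_gene_has_rank_zero(self):
        voter = make_voter("P", {"A": 0.2, "z": 0.0}, mutated=set())
        assert pairwise_winner("A", "QQQ", voter, delta=0.85) == "A"


class TestCondorcetAggregate:
    def test_single_voter_all_mutated_preserves_score_order(self):
        voter = make_voter("P", {"a": 3.0, "b": 1.0, "c": 2.0}, mutated={"a", "b", "c"})
        agg = condorcet_aggregate([voter], Config())
        assert agg.genes == ["a", "c", "b"]

    def test_condorcet_winner_ranks_first(self):
        # gene "w" preferred to every other gene by a majority of voters
        voters = [
            make_voter("P1", {"w": 5.0, "a": 1.0, "b": 2.0, "z": 0.0}, {"w"}),
            make_voter("P2", {"w": 4.0, "a": 3.0, "b": 1.0, "z": 0.0}, {"w"}),
            make_voter("P3", {"w": 0.5, "a": 5.0, "b": 4.0, "z": 0.0}, set()),
        ]
        agg = condorcet_aggregate(voters, Config())
        assert agg.genes[0] == "w"

    def test_hand_written_table_matches_brute_force(self):
        voters = [
            make_voter("P1", {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}, {"a", "c"}),
            make_voter("P2", {"a": 1.0, "b": 4.0, "c": 3.0, "d": 2.0}, {"b"}),
            make_voter("P3", {"a": 2.0, "b": 1.0, "c": 4.0, "d": 3.0}, {"c", "d"}),
        ]
        agg = condorcet_aggregate(voters, Config())
        expected = brute_force_tally(voters, ["a", "b", "c", "d"], 0.85)
        got = dict(zip(agg.table["gene"], agg.table["copeland"]))
        assert got == expected

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n_genes = int(rng.integers(2, 11))
            n_voters = int(rng.integers(1, 11))
            genes, voters = random_voters(rng, n_genes, n_voters)
            agg = condorcet_aggregate(voters, Config())
            expected = brute_force_tally(voters, genes, 0.85)
            got = dict(zip(agg.table["gene"], agg.table["copeland"]))
            assert got == expected

    def test_tally_conservation(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            genes, voters = random_voters(rng, int(rng.integers(2, 12)), 5)
            agg = condorcet_aggregate(voters, Config())
            assert agg.table["copeland"].sum() == 0

    def test_voter_permutation_invariance(self):
        rng = np.random.default_rng(17)
        genes, voters = random_voters(rng, 8, 7)
        a1 = condorcet_aggregate(voters, Config())
        a2 = condorcet_aggregate(voters[::-1], Config())
        assert a1.genes == a2.genes
        assert list(a1.table["copeland"]) == list(a2.table["copeland"])

    def test_no_penalty_identical_voters_reproduce_common_order(self):
        scores = {"a": 0.9, "b": 0.7, "c": 0.4, "d": 0.1}
        voters = [make_voter(f"P{i}", scores, mutated=set()) for i in range(4)]
        agg = condorcet_aggregate(voters, Config(delta=1.0))
        assert agg.genes == ["a", "b", "c", "d"]

    def test_single_candidate(self):
        voter = make_voter("P", {"only": 1.0}, mutated={"only"})
        with pytest.warns(UserWarning):  # all-equal normalization warning
            agg = condorcet_aggregate([voter], Config())
        assert agg.genes == ["only"]
        assert list(agg.table["copeland"]) == [0]

    def test_candidate_pool_restriction(self):
        voters = [
            make_voter("P1", {"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.0}, set()),
            make_voter("P2", {"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0}, set()),
        ]
        agg = condorcet_aggregate(voters, Config(candidate_pool=2))
        assert set(agg.genes) == {"a", "b", "c", "d"}  # union of both voters' top 2

    def test_requires_at_least_one_voter(self):
        with pytest.raises(ValueError, match="at least one voter"):
            condorcet_aggregate([], Config())


class TestSelectTopK:
    def test_prefix(self):
        voters = [make_voter("P", {"a": 5.0, "b": 4.0, "c": 3.0, "d": 2.0, "e": 1.0}, set())]
        agg = condorcet_aggregate(voters, Config())
        assert select_top_k(agg, 3) == agg.genes[:3]

    def test_k_clamped_to_gene_count(self):
        voters = [make_voter("P", {"a": 2.0, "b": 1.0, "z": 0.0}, set())]
        agg = condorcet_aggregate(voters, Config())
        assert select_top_k(agg, 100) == agg.genes

    def test_nonpositive_k_rejected(self):
        voters = [make_voter("P", {"a": 1.0, "z": 0.0}, set())]
        agg = condorcet_aggregate(voters, Config())
        with pytest.raises(ValueError, match="positive"):
            select_top_k(agg, 0)
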