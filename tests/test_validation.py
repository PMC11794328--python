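"""Gold-standard and literature validation under degree-preserving
randomization."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drugeff import (
    ContractError,
    CooccurrenceRecord,
    GoldStandard,
    OverlapScore,
    ScoredPairList,
    cooccurrence_pvalue,
    literature_overlap,
    overlap_ratio,
    randomize_links,
    restrict_to_gold_universe,
)
from drugeff.fixtures import reference_oracle


def _spl(pairs):
    return ScoredPairList(tuple(
        OverlapScore(h, d, 10, 1, 1, 1, 1.0, 0.0) for h, d in pairs))


def degrees(pairs):
    return (Counter(h for h, _ in pairs), Counter(d for _, d in pairs))


def enumerate_configurations(pairs):
    """Independent oracle: all simple bipartite pair sets with the same
    per-phenotype and per-drug degree sequences, by recursive assignment."""
    hdeg, ddeg = degrees(pairs)
    hs = sorted(hdeg)
    ds = sorted(ddeg)
    configs = []

    def rec(i, remaining, acc):
        if i == len(hs):
            configs.append(frozenset(acc))
            return
        h = hs[i]
        avail = [d for d in ds if remaining[d] > 0]
        for combo in itertools.combinations(avail, hdeg[h]):
            for d in combo:
                remaining[d] -= 1
            rec(i + 1, remaining, acc + [(h, d) for d in combo])
            for d in combo:
                remaining[d] += 1

    rec(0, dict(ddeg), [])
    return configs


class TestRestrictToGoldUniverse:
    GOLD = GoldStandard(frozenset({("HP:0000001", "d1"),
                                   ("HP:0000002", "d2")}))

    def test_unseen_entities_removed(self):
        pred = _spl([("HP:0000001", "d1"), ("HP:0000001", "d9"),
                     ("HP:0000009", "d1")])
        out = restrict_to_gold_universe(pred, self.GOLD)
        assert out.pair_set() == {("HP:0000001", "d1")}

    def test_identity_within_universe(self):
        pred = _spl([("HP:0000001", "d1"), ("HP:0000002", "d2")])
        out = restrict_to_gold_universe(pred, self.GOLD)
        assert out.pair_set() == pred.pair_set()

    def test_membership_is_per_entity_not_per_pair(self):
        pred = _spl([("HP:0000001", "d2")])  # both seen, never together
        out = restrict_to_gold_universe(pred, self.GOLD)
        assert out.pair_set() == {("HP:0000001", "d2")}

    def test_empty_gold_rejected(self):
        with pytest.raises(ContractError):
            restrict_to_gold_universe(_spl([("HP:0000001", "d1")]),
                                      GoldStandard(frozenset()))


class TestRandomizeLinks:
    def test_degree_conservation_on_example(self):
        pairs = {("h1", "d1"), ("h1", "d2"), ("h2", "d1")}
        out = randomize_links(pairs, seed=3)
        assert degrees(out) == degrees(pairs)

    @given(st.sets(st.tuples(st.sampled_from("abcdef"),
                             st.sampled_from("uvwxyz")),
                   min_size=1, max_size=15),
           st.integers(0, 1000))
    def test_degree_multisets_always_preserved(self, pairs, seed):
        out = randomize_links(pairs, seed)
        assert degrees(out) == degrees(pairs)
        assert len(out) == len(pairs)

    def test_complete_bipartite_forced_to_identity(self):
        pairs = set(itertools.product(["h1", "h2"], ["d1", "d2"]))
        assert randomize_links(pairs, seed=0) == pairs

    def test_two_configurations_sampled_uniformly(self):
        """With pairs {(h1,d1),(h2,d2)} exactly two configurations exist;
        over many seeds the gold overlap must average 0.5 within 3 standard
        errors."""
        pairs = {("h1", "d1"), ("h2", "d2")}
        gold = {("h1", "d1")}
        hits = [len(randomize_links(pairs, seed) & gold)
                for seed in range(1000)]
        mean = np.mean(hits)
        se = np.std(hits, ddof=1) / math.sqrt(len(hits))
        assert abs(mean - 0.5) <= 3 * se

    def test_deterministic_given_seed(self):
        pairs = {(f"h{i}", f"d{(i * 3) % 7}") for i in range(7)}
        assert randomize_links(pairs, 42) == randomize_links(pairs, 42)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            randomize_links(set(), 0)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """On a small pair set, the sampled mean gold-overlap agrees with
        the average over all degree-preserving configurations."""
        pairs = {("h1", "d1"), ("h1", "d2"), ("h2", "d3"),
                 ("h3", "d1"), ("h3", "d3"), ("h4", "d2")}
        gold = {("h1", "d1"), ("h2", "d3"), ("h3", "d2")}
        configs = enumerate_configurations(pairs)
        exact = np.mean([len(c & gold) for c in configs])
        hits = [len(randomize_links(pairs, seed) & gold)
                for seed in range(1000)]
        se = np.std(hits, ddof=1) / math.sqrt(len(hits))
        assert abs(np.mean(hits) - exact) <= 3 * se


class TestOverlapRatio:
    def test_confirmed_counts_intersection(self):
        gold = GoldStandard(frozenset({("HP:0000001", "d1"),
                                       ("HP:0000002", "d2")}))
        pred = _spl([("HP:0000001", "d1"), ("HP:0000002", "d1")])
        rep = overlap_ratio(pred, gold, n_replicates=10, seed=5)
        assert rep.confirmed == 1

    def test_gold_disjoint_gives_zero_confirmed(self):
        gold = GoldStandard(frozenset({("HP:0000009", "d9")}))
        pred = _spl([("HP:0000001", "d1"), ("HP:0000002", "d2")])
        rep = overlap_ratio(pred, gold, n_replicates=10, seed=5)
        assert rep.confirmed == 0

    def test_zero_random_mean_reports_inf_sentinel(self):
        # rigid 1x2 predicted set never overlaps the disjoint gold
        gold = GoldStandard(frozenset({("HP:0000009", "d9")}))
        pred = _spl([("HP:0000001", "d1"), ("HP:0000001", "d2")])
        rep = overlap_ratio(pred, gold, n_replicates=10, seed=5)
        assert rep.confirmed == 0 and math.isinf(rep.ratio)

    def test_bitwise_reproducible(self):
        gold = GoldStandard(frozenset({("HP:0000001", "d1")}))
        pred = _spl([(f"HP:000000{i}", f"d{j}")
                     for i in range(1, 5) for j in (i, (i % 4) + 1)])
        a = overlap_ratio(pred, gold, n_replicates=25, seed=11)
        b = overlap_ratio(pred, gold, n_replicates=25, seed=11)
        assert a == b

    def test_planted_predictions_beat_random(self, default_universe):
        """Predictions containing the planted pairs overlap the gold
        standard more than their degree-preserving shuffles."""
        uni = default_universe
        from drugeff import run_protein_chain
        pred = run_protein_chain(uni.annotations, uni.activities, [0.0],
                                 pheno_gene_threshold=0.0)[0.0]
        restricted = restrict_to_gold_universe(pred, uni.gold)
        rep = overlap_ratio(restricted, uni.gold, n_replicates=100, seed=1)
        assert rep.ratio > 1


class TestCooccurrence:
    @pytest.mark.parametrize("n_total,n_drug,n_hpo,n_both,expected", [
        (10, 3, 3, 0, 1.0),
        (10, 3, 3, 2, 22 / 120),
        (100, 10, 10, 10, 1 / math.comb(100, 10)),
    ])
    def test_known_values(self, n_total, n_drug, n_hpo, n_both, expected):
        rec = CooccurrenceRecord("d", "HP:0000001", n_drug, n_hpo, n_both,
                                 n_total)
        assert cooccurrence_pvalue(rec) == pytest.approx(expected, rel=1e-9)

    def test_matches_enumeration_oracle(self):
        rec = CooccurrenceRecord("d", "HP:0000001", 5, 4, 2, 11)
        assert cooccurrence_pvalue(rec) == pytest.approx(
            float(reference_oracle(2, 4, 5, 11)), rel=1e-12)

    @pytest.mark.parametrize("kwargs", [
        dict(n_drug=3, n_hpo=3, n_both=4, n_total=10),
        dict(n_drug=11, n_hpo=3, n_both=1, n_total=10),
        dict(n_drug=3, n_hpo=3, n_both=-1, n_total=10),
    ])
    def test_inconsistent_counts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CooccurrenceRecord("d", "HP:0000001", **kwargs)


class TestLiteratureOverlap:
    def _rec(self, h, d, n_both):
        return CooccurrenceRecord(d, h, 200, 200, n_both, 1_000_000)

    def test_no_significant_comentions_confirms_nothing(self):
        pred = _spl([("HP:0000001", "d1"), ("HP:0000002", "d2")])
        comentions = [self._rec("HP:0000001", "d1", 0)]
        rep = literature_overlap(pred, comentions, n_replicates=10, seed=3)
        assert rep.confirmed == 0

    def test_comention_set_equal_to_predictions(self):
        pairs = [("HP:0000001", "d1"), ("HP:0000002", "d2"),
                 ("HP:0000003", "d3")]
        comentions = [self._rec(h, d, 30) for h, d in pairs]
        rep = literature_overlap(_spl(pairs), comentions,
                                 n_replicates=10, seed=3)
        assert rep.confirmed == len(pairs)

    def test_planted_fixture_beats_random(self, default_universe):
        uni = default_universe
        from drugeff import run_protein_chain
        pred = run_protein_chain(uni.annotations, uni.activities, [0.0],
                                 pheno_gene_threshold=0.0)[0.0]
        rep = literature_overlap(pred, uni.comentions,
                                 n_replicates=100, seed=2)
        assert rep.confirmed >= len(uni.planted_pairs)
        assert rep.ratio > 1
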