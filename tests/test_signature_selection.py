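import numpy as np
import pandas as pd
import pytest

from reosig import (
    DirectedPairSet,
    SimulationConfig,
    build_candidate_list,
    delta_avg_rank,
    find_reversed_pairs,
    gene_frequencies,
    generate_two_class,
    scan_odd_sizes,
    select_signature,
    within_sample_ranks,
)

from _oracles import delta_avg_rank_oracle, ranks_oracle, vote_oracle
from conftest import make_matrix, random_matrix


def pairset(*pairs):
    return DirectedPairSet(frozenset(pairs))


class TestFindReversedPairs:
    def test_definition(self):
        assert find_reversed_pairs(pairset(("a", "b")), pairset(("b", "a"))) == {("a", "b")}

    def test_no_reversal_when_sets_equal(self):
        s = pairset(("a", "b"), ("c", "d"))
        assert find_reversed_pairs(s, s) == frozenset()

    def test_antisymmetric_under_class_swap(self):
        c1 = pairset(("a", "b"), ("c", "d"), ("e", "f"))
        c2 = pairset(("b", "a"), ("c", "d"), ("f", "e"))
        fwd = find_reversed_pairs(c1, c2)
        rev = find_reversed_pairs(c2, c1)
        assert {(b, a) for a, b in fwd} == rev

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            find_reversed_pairs(DirectedPairSet(frozenset()), pairset(("a", "b")))


class TestWithinSampleRanks:
    def test_simple_ordering(self):
        m = make_matrix([[2.0], [5.0], [3.0]])
        assert list(within_sample_ranks(m)["s0"]) == [1.0, 3.0, 2.0]

    def test_ties_get_average_rank(self):
        m = make_matrix([[1.0], [1.0], [9.0]])
        assert list(within_sample_ranks(m)["s0"]) == [1.5, 1.5, 3.0]

    def test_matches_counting_oracle(self, rng):
        m = random_matrix(rng, 10, 5, ties=True)
        ranks = within_sample_ranks(m)
        for col in m.sample_ids:
            expected = ranks_oracle(m.data[col].to_dict())
            for g in m.gene_ids:
                assert ranks.loc[g, col] == expected[g]


class TestDeltaAvgRank:
    def test_hand_computed_example(self):
        ranks1 = pd.DataFrame({"n1": [1, 3], "n2": [2, 5]}, index=["i", "j"], dtype=float)
        ranks2 = pd.DataFrame({"m1": [4, 1]}, index=["i", "j"], dtype=float)
        # (|1-3| + |2-5| + |4-1|) / 3
        assert delta_avg_rank(("i", "j"), ranks1, ranks2) == pytest.approx(8 / 3)

    def test_constant_gap_returns_the_constant(self):
        ranks1 = pd.DataFrame({"a": [1, 4], "b": [2, 5]}, index=["i", "j"], dtype=float)
        ranks2 = pd.DataFrame({"c": [3, 6]}, index=["i", "j"], dtype=float)
        assert delta_avg_rank(("i", "j"), ranks1, ranks2) == 3.0

    def test_missing_gene_is_hard_error(self):
        r = pd.DataFrame({"a": [1, 2]}, index=["i", "j"], dtype=float)
        with pytest.raises(KeyError):
            delta_avg_rank(("i", "z"), r, r)

    def test_matches_raw_expression_oracle(self, rng):
        m1 = random_matrix(rng, 8, 4, ties=True)
        m2 = random_matrix(rng, 8, 3, ties=True)
        got = delta_avg_rank(("g1", "g5"), within_sample_ranks(m1), within_sample_ranks(m2))
        assert got == pytest.approx(delta_avg_rank_oracle(("g1", "g5"), m1.data, m2.data))

    def test_invariant_to_monotone_transform(self, rng):
        import reosig

        m1 = random_matrix(rng, 9, 5)
        m2 = random_matrix(rng, 9, 4)
        base = delta_avg_rank(("g0", "g8"), within_sample_ranks(m1), within_sample_ranks(m2))
        w1 = reosig.apply_monotone_distortion(m1, "exp")
        w2 = reosig.apply_monotone_distortion(m2, "affine_positive", seed=3)
        warped = delta_avg_rank(("g0", "g8"), within_sample_ranks(w1), within_sample_ranks(w2))
        assert warped == base


class TestBuildCandidateList:
    def test_singleton(self):
        out = build_candidate_list({("a", "b")}, delta={("a", "b"): 1.0})
        assert out == [("a", "b")]

    def test_frequency_then_max_delta(self):
        reversed_pairs = {("x", "h1"), ("x", "h2"), ("y", "h3")}
        freq = {"x": 3, "y": 2, "z": 1}
        delta = {("x", "h1"): 5.0, ("x", "h2"): 9.0, ("y", "h3"): 4.0}
        out = build_candidate_list(reversed_pairs, freq=freq, delta=delta)
        assert out[:2] == [("x", "h2"), ("y", "h3")]

    def test_duplicate_pair_skipped_not_replaced(self):
        # c tops the frequency list and claims (a, c); gene a's best pair is
        # then already taken, so a contributes nothing and b adds its own.
        reversed_pairs = {("a", "c"), ("b", "c")}
        delta = {("a", "c"): 5.0, ("b", "c"): 3.0}
        out = build_candidate_list(reversed_pairs, delta=delta)
        assert out == [("a", "c"), ("b", "c")]

    def test_deterministic_lexicographic_tie_breaks(self):
        reversed_pairs = {("b", "z"), ("a", "z")}
        delta = {("b", "z"): 2.0, ("a", "z"): 2.0}
        out = build_candidate_list(reversed_pairs, delta=delta)
        # z (freq 2) first: equal deltas and partner frequencies, so the
        # lexicographically smaller partner wins
        assert out[0] == ("a", "z")

    def test_gene_frequencies_counts_both_positions(self):
        freq = gene_frequencies({("a", "b"), ("a", "c")})
        assert freq == {"a": 2, "b": 1, "c": 1}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_candidate_list(set(), delta={})


class TestScanOddSizes:
    def test_perfectly_separable_chooses_one_pair(self):
        t1 = make_matrix([[9.0, 8.0], [1.0, 2.0]], genes=["a", "b"])
        t2 = make_matrix([[1.0, 2.0], [9.0, 8.0]], genes=["a", "b"])
        res = scan_odd_sizes([("a", "b")], t1, t2, max_n=1)
        assert res.chosen_n == 1
        assert res.accuracy == (100.0,)

    def test_accuracy_curve_matches_vote_oracle(self):
        cfg = SimulationConfig(
            n_genes=80, n_class1=15, n_class2=15, n_reversed=5,
            rank_gap=10.0, noise_sd=0.4, seed=42,
        )
        t1, t2, planted = generate_two_class(cfg)
        candidates = sorted(planted)
        res = scan_odd_sizes(candidates, t1, t2, max_n=5)
        for n, acc in zip(res.sizes, res.accuracy):
            correct = 0
            for m, own in ((t1, 1), (t2, 2)):
                for sid in m.sample_ids:
                    votes, n_eval = vote_oracle(m.sample(sid).to_dict(), candidates[:n])
                    pred = 1 if votes > n_eval / 2 else 2
                    correct += pred == own
            assert acc == pytest.approx(100.0 * correct / 30)

    def test_chosen_n_is_odd_bounded_and_maximal(self, rng):
        cfg = SimulationConfig(
            n_genes=60, n_class1=10, n_class2=10, n_reversed=4,
            rank_gap=8.0, noise_sd=0.5, seed=7,
        )
        t1, t2, planted = generate_two_class(cfg)
        res = scan_odd_sizes(sorted(planted), t1, t2, max_n=3)
        assert res.chosen_n % 2 == 1 and res.chosen_n <= 3
        assert res.chosen_accuracy == max(res.accuracy)

    def test_validation(self, tiny):
        with pytest.raises(ValueError):
            scan_odd_sizes([], tiny, tiny, max_n=1)
        with pytest.raises(ValueError):
            scan_odd_sizes([("g0", "g1")], tiny, tiny, max_n=2)
        with pytest.raises(ValueError):
            scan_odd_sizes([("g0", "g1")], tiny, tiny, max_n=3)


class TestSelectSignature:
    def test_end_to_end_recovers_planted_signature(self):
        cfg = SimulationConfig(n_genes=100, n_class1=25, n_class2=25, n_reversed=3, seed=5)
        m1, m2, planted = generate_two_class(cfg)
        sig, scan, table = select_signature([m1], [m2], class1_label="A", class2_label="B")
        assert set(table[["gene_high", "gene_low"]].itertuples(index=False, name=None)) == planted
        assert set(sig.pairs) <= planted
        assert scan.chosen_accuracy == 100.0

    def test_multi_dataset_training_uses_characteristic_sets(self):
        from reosig import apply_monotone_distortion

        cfg = SimulationConfig(n_genes=80, n_class1=12, n_class2=12, n_reversed=2, seed=1)
        m1a, m2a, planted = generate_two_class(cfg)
        # a second "laboratory": same biology, monotonically distorted scale
        m1b = apply_monotone_distortion(m1a, "affine_positive", seed=9)
        m2b = apply_monotone_distortion(m2a, "rank_preserving_spline", seed=9)
        sig, scan, _ = select_signature([m1a, m1b], [m2a, m2b])
        assert set(sig.pairs) <= planted
        assert scan.chosen_accuracy == 100.0
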