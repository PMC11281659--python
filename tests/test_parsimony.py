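"""Parsimony engine tests; oracles are exhaustive enumeration and brute-force
minimization over internal state assignments."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldchron.parsimony import (
    ParsimonyError,
    ParsimonyScorer,
    bootstrap_support,
    branch_swap_search,
    char_max_steps,
    char_min_steps,
    exhaustive_search,
    g1_statistic,
    mp_search,
    ordered_char_length,
    retention_index,
    sample_lengths,
    skewness_g1,
    stepwise_addition,
    tree_length,
)
from foldchron.trees import UnrootedTree, enumerate_topologies, random_topology
from tests.conftest import make_cm


def quartet(split_pair):
    """The quartet topology whose internal split is split_pair vs the rest."""
    pair = frozenset(split_pair)
    comp = frozenset("abcd") - pair
    return next(
        t
        for t in enumerate_topologies(["a", "b", "c", "d"])
        if t.splits() & {pair, comp}
    )


def brute_quartet(states, S=24):
    """Oracle: minimize over both internal node states of ((a,b),(c,d))."""
    a, b, c, d = states
    return min(
        abs(a - x) + abs(b - x) + abs(x - y) + abs(c - y) + abs(d - y)
        for x in range(S)
        for y in range(S)
    )


class TestOrderedCharLength:
    def test_two_leaves(self):
        t = UnrootedTree.from_pair("a", "b")
        assert ordered_char_length(t, {"a": 3, "b": 9}) == 6

    def test_quartet_brute_force(self):
        t = quartet(("c", "d"))
        got = ordered_char_length(t, {"a": 0, "b": 2, "c": 5, "d": 5})
        assert got == brute_quartet((0, 2, 5, 5)) == 5

    def test_all_equal(self):
        t = quartet(("c", "d"))
        assert ordered_char_length(t, {l: 7 for l in "abcd"}) == 0

    def test_missing_leaf_state_errors(self):
        t = UnrootedTree.from_pair("a", "b")
        with pytest.raises(ParsimonyError, match="no state entry"):
            ordered_char_length(t, {"a": 1})

    def test_missing_as_any(self):
        t = quartet(("c", "d"))
        assert ordered_char_length(t, {"a": 0, "b": "any", "c": 5, "d": 5}) == 5

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(0, 23)] * 4))
    def test_quartet_matches_brute_force(self, states):
        t = quartet(("c", "d"))
        mapping = dict(zip("abcd", states))
        assert ordered_char_length(t, mapping) == brute_quartet(states)


class TestTreeLength:
    def test_additivity_single_char(self, cm_factory):
        cm = cm_factory([[0], [2], [5], [5]], labels=list("abcd"))
        t = quartet(("c", "d"))
        assert tree_length(t, cm) == ordered_char_length(
            t, {"a": 0, "b": 2, "c": 5, "d": 5}
        )

    def test_duplicated_character_doubles(self, cm_factory):
        cm1 = cm_factory([[0], [2], [5], [5]], labels=list("abcd"))
        cm2 = cm_factory([[0, 0], [2, 2], [5, 5], [5, 5]], labels=list("abcd"))
        t = quartet(("c", "d"))
        assert tree_length(t, cm2) == 2 * tree_length(t, cm1)

    def test_quartet_two_chars(self, cm_factory):
        cm = cm_factory([[0, 1], [2, 1], [5, 1], [5, 1]], labels=list("abcd"))
        assert tree_length(quartet(("c", "d")), cm) == 5

    def test_taxon_mismatch(self, cm_factory):
        cm = cm_factory([[0], [1], [2]], labels=["a", "b", "x"])
        t = UnrootedTree.from_triplet("a", "b", "c")
        with pytest.raises(ParsimonyError, match="mismatch"):
            tree_length(t, cm)

    def test_root_invariance(self, cm_factory):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            cm = make_cm(rng.integers(0, 15, size=(n, 4)), labels)
            t = random_topology(labels, rng)
            scorer = ParsimonyScorer(cm)
            lengths = {scorer.length(t, root=r) for r in t.adj}
            assert len(lengths) == 1

    def test_additivity_concatenation(self, cm_factory):
        rng = np.random.default_rng(1)
        labels = list("abcde")
        m1 = rng.integers(0, 10, size=(5, 3))
        m2 = rng.integers(0, 10, size=(5, 2))
        t = random_topology(labels, rng)
        total = tree_length(t, make_cm(np.hstack([m1, m2]), labels))
        assert total == tree_length(t, make_cm(m1, labels)) + tree_length(
            t, make_cm(m2, labels)
        )

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(2)
        labels = list("abcde")
        states = rng.integers(0, 12, size=(5, 3))
        t = random_topology(labels, rng)
        L1 = tree_length(t, make_cm(states, labels))
        perm = [3, 1, 4, 0, 2]
        relabeled = t.copy()
        mapping = {labels[i]: labels[perm[i]] for i in range(5)}
        relabeled.labels = {
            n: mapping[l] for n, l in relabeled.labels.items()
        }
        permuted = np.empty_like(states)
        for i in range(5):
            permuted[perm[i]] = states[i]
        assert tree_length(relabeled, make_cm(permuted, labels)) == L1


class TestMinMaxSteps:
    def test_examples(self):
        assert char_min_steps([0, 2, 5, 5]) == 5
        assert char_max_steps([0, 2, 5, 5]) == 8  # min_z sum|x-z| at z in 2..5
        assert char_min_steps([7, 7]) == 0
        assert char_max_steps([7, 7]) == 0
        assert char_min_steps([0, 7]) == 7
        assert char_max_steps([0, 7]) == 7

    def test_all_missing_errors(self):
        with pytest.raises(ParsimonyError):
            char_min_steps(["any", "any"])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 23), min_size=2, max_size=8))
    def test_bounds_bracket_observed(self, states):
        labels = [f"t{i}" for i in range(len(states))]
        if len(states) < 3:
            t = UnrootedTree.from_pair(*labels)
        else:
            t = random_topology(labels, np.random.default_rng(0))
        obs = ordered_char_length(t, dict(zip(labels, states)))
        assert char_min_steps(states) <= obs <= char_max_steps(states)


class TestRetentionIndex:
    def test_perfect_fit(self, cm_factory):
        cm = cm_factory([[0], [0], [9], [9]], labels=list("abcd"))
        assert retention_index(quartet(("a", "b")), cm) == 1.0

    def test_worst_fit(self, cm_factory):
        cm = cm_factory([[0], [2], [0], [2]], labels=list("abcd"))
        assert retention_index(quartet(("a", "b")), cm) == 0.0

    def test_mixture(self, cm_factory):
        cm = cm_factory([[0, 0], [2, 2], [5, 0], [5, 2]], labels=list("abcd"))
        # g,s,m per char: (8,5,5) and (4,4,2) -> RI = (12-9)/(12-7) = 0.6
        assert retention_index(quartet(("c", "d")), cm) == pytest.approx(0.6)

    def test_no_signal_errors(self, cm_factory):
        cm = cm_factory([[3], [3], [3], [3]], labels=list("abcd"))
        with pytest.raises(ParsimonyError, match="no retention signal"):
            retention_index(quartet(("c", "d")), cm)


class TestStepwiseAddition:
    def test_three_taxa(self, cm_factory):
        cm = cm_factory([[0], [1], [2]])
        t = stepwise_addition(cm)
        assert sorted(t.leaf_labels) == ["t0", "t1", "t2"]

    def test_groups_low_states(self, cm_factory):
        cm = cm_factory([[0, 0], [0, 0], [9, 9], [9, 9]], labels=list("abcd"))
        t = stepwise_addition(cm)
        assert frozenset({"c", "d"}) in t.splits() or frozenset({"a", "b"}) in t.splits()
        assert tree_length(t, cm) == 18  # vs 27 for the alternatives

    def test_deterministic(self, cm_factory):
        cm = cm_factory(np.random.default_rng(0).integers(0, 9, size=(6, 3)))
        a = stepwise_addition(cm, seed=7, addition_order="random")
        b = stepwise_addition(cm, seed=7, addition_order="random")
        assert a.topology_key() == b.topology_key()

    def test_too_few_taxa(self, cm_factory):
        with pytest.raises(ParsimonyError):
            stepwise_addition(cm_factory([[0], [1]]))


class TestBranchSwap:
    def test_optimal_unchanged(self, cm_factory):
        cm = cm_factory([[0], [0], [9], [9]], labels=list("abcd"))
        t = quartet(("a", "b"))
        out = branch_swap_search(t, cm, moves="NNI")
        assert out.topology_key() == t.topology_key()

    @pytest.mark.parametrize("moves", ["NNI", "SPR"])
    def test_recovers_quartet(self, cm_factory, moves):
        cm = cm_factory([[0, 0], [0, 0], [9, 9], [9, 9]], labels=list("abcd"))
        bad = quartet(("a", "c"))
        out = branch_swap_search(bad, cm, moves=moves)
        assert frozenset({"a", "b"}) in out.splits() or frozenset({"c", "d"}) in out.splits()

    def test_never_lengthens(self, cm_factory):
        rng = np.random.default_rng(3)
        cm = make_cm(rng.integers(0, 10, size=(6, 4)))
        t = random_topology(cm.taxon_ids, rng)
        before = tree_length(t, cm)
        for moves in ("NNI", "SPR"):
            assert tree_length(branch_swap_search(t, cm, moves=moves), cm) <= before


class TestMPSearch:
    def test_reproducible(self, cm_factory):
        cm = cm_factory([[0, 0], [0, 1], [9, 8], [9, 9]], labels=list("abcd"))
        r1 = mp_search(cm, n_replicates=3, seed=5, n_random_trees_g1=5)
        r2 = mp_search(cm, n_replicates=3, seed=5, n_random_trees_g1=5)
        assert r1.length == r2.length
        assert [t.topology_key() for t in r1.best_trees] == [
            t.topology_key() for t in r2.best_trees
        ]

    @pytest.mark.parametrize("trial", range(10))
    def test_oracle_equivalence(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 8))
        k = int(rng.integers(1, 7))
        cm = make_cm(rng.integers(0, 10, size=(n, k)))
        _, exact = exhaustive_search(cm)
        res = mp_search(
            cm, n_replicates=8, seed=trial, moves="SPR", n_random_trees_g1=3
        )
        assert res.length == exact

    def test_duplicate_taxa_are_sisters(self):
        rng = np.random.default_rng(9)
        states = rng.integers(0, 10, size=(5, 4))
        states[1] = states[0]  # t1 duplicates t0
        cm = make_cm(states)
        trees, _ = exhaustive_search(cm)
        pair = frozenset({"t0", "t1"})
        comp = frozenset(cm.taxon_ids) - pair
        assert any(t.splits() & {pair, comp} for t in trees)


class TestG1:
    def test_symmetric_sample(self):
        assert skewness_g1([1, 2, 3]) == pytest.approx(0.0)

    def test_positive_sample(self):
        assert skewness_g1([0, 0, 10]) == pytest.approx(0.7071, abs=1e-4)

    def test_reproducible(self, cm_factory):
        cm = cm_factory(np.random.default_rng(0).integers(0, 9, size=(6, 3)))
        assert g1_statistic(cm, 20, seed=4) == g1_statistic(cm, 20, seed=4)

    def test_zero_variance_errors(self):
        with pytest.raises(ParsimonyError, match="degenerate"):
            skewness_g1([5, 5, 5])

    def test_min_trees(self, cm_factory):
        cm = cm_factory([[0], [1], [2], [3]])
        with pytest.raises(ParsimonyError):
            g1_statistic(cm, 2, seed=0)


class TestBootstrap:
    def test_unanimous_support(self, cm_factory):
        cm = cm_factory([[0, 0], [0, 0], [9, 9], [9, 9]], labels=list("abcd"))
        out = bootstrap_support(cm, n_replicates=20, seed=0)
        assert len(out) == 1
        assert out[0].support == 1.0
        assert out[0].bipartition in (frozenset({"a", "b"}), frozenset({"c", "d"}))

    def test_single_replicate_support_binary(self, cm_factory):
        rng = np.random.default_rng(0)
        cm = make_cm(rng.integers(0, 9, size=(5, 4)))
        out = bootstrap_support(cm, n_replicates=1, seed=3)
        assert all(b.support in (0.0, 1.0) for b in out)

    def test_clean_five_taxon_signal(self):
        # every character supports ((a,b),(c,d),e)-style structure
        states = np.array(
            [[0, 0], [1, 1], [8, 8], [9, 9], [5, 5]]
        )
        cm = make_cm(states, labels=list("abcde"))
        out = bootstrap_support(cm, n_replicates=50, seed=1)
        strong = {b.bipartition for b in out if b.support >= 0.95}
        assert frozenset({"c", "d"}) in strong
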