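"""Tree handling, the Wagner parsimony DP against exhaustive enumeration,
branch-event classification, and event summaries."""

import itertools
import random

import pytest

from tapscan.phylo import (
    WagnerConfig,
    classify_branch_events,
    parse_newick,
    prune_tree_to_species,
    read_count_matrix,
    summarize_events,
    wagner_reconstruct,
)
from tapscan.simulate import gen_count_evolution

from conftest import enumerate_tree_shapes, exhaustive_wagner

PENALTIES = [(1.0, 1.0), (2.0, 1.0), (0.5, 1.0)]


def leaf_labels(tree):
    return [l.taxon.label for l in tree.leaf_node_iter()]


class TestNewick:
    def test_basic_rooted_tree(self):
        tree = parse_newick("((A,B),C);")
        assert sorted(leaf_labels(tree)) == ["A", "B", "C"]
        assert len(tree.seed_node.child_nodes()) == 2

    def test_polytomy_accepted(self):
        tree = parse_newick("(A,B,C);")
        assert len(tree.seed_node.child_nodes()) == 3

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("((A,B)")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("((A,A),C);")


class TestPrune:
    def test_unary_suppression(self):
        pruned = prune_tree_to_species(parse_newick("((A,B),C);"), {"A", "C"})
        assert sorted(leaf_labels(pruned)) == ["A", "C"]
        assert len(pruned.seed_node.child_nodes()) == 2
        assert all(len(n.child_nodes()) != 1 for n in pruned.preorder_node_iter())

    def test_prune_to_all_leaves_is_identity(self):
        tree = parse_newick("((A,B),(C,(D,E)));")
        pruned = prune_tree_to_species(tree, {"A", "B", "C", "D", "E"})
        assert pruned.as_string(schema="newick") == tree.as_string(schema="newick")

    def test_mapping_substitutes_closest_relative(self):
        tree = parse_newick("((A,B),C);")
        pruned = prune_tree_to_species(tree, {"X", "C"}, mapping={"X": "A"})
        assert sorted(leaf_labels(pruned)) == ["C", "X"]

    def test_unmatched_species_without_mapping_fails(self):
        with pytest.raises(ValueError, match="not found"):
            prune_tree_to_species(parse_newick("((A,B),C);"), {"A", "Z"})

    def test_colliding_mapping_rejected(self):
        tree = parse_newick("((A,B),C);")
        with pytest.raises(ValueError, match="same leaf"):
            prune_tree_to_species(tree, {"X", "Y"}, mapping={"X": "A", "Y": "A"})


class TestCountMatrix:
    def test_reads_tsv(self):
        df = read_count_matrix("family\tA\tB\nWRKY\t3\t0\nGRAS\t1\t2\n")
        assert df.loc["WRKY", "A"] == 3 and df.shape == (2, 2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            read_count_matrix("family\tA\nWRKY\t-1\n")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            read_count_matrix("family\tA\nWRKY\t1\nWRKY\t2\n")


class TestWagnerSmall:
    def test_constant_leaves_zero_cost(self):
        tree = parse_newick("((A,B),(C,D));")
        counts, cost = wagner_reconstruct(tree, dict.fromkeys("ABCD", 3))
        assert cost == 0 and set(counts.values()) == {3}

    def test_symmetric_minimum_cost_one(self):
        tree = parse_newick("((A,B),C);")
        _, cost = wagner_reconstruct(tree, {"A": 0, "B": 1, "C": 1})
        assert cost == exhaustive_wagner(tree, {"A": 0, "B": 1, "C": 1}, 1, 1) == 1

    def test_asymmetric_cost_matches_enumeration(self):
        tree = parse_newick("((A,B),C);")
        lc = {"A": 0, "B": 1, "C": 1}
        cfg = WagnerConfig(gain_penalty=2.0, loss_penalty=1.0)
        counts, cost = wagner_reconstruct(tree, lc, cfg)
        assert cost == exhaustive_wagner(tree, lc, 2.0, 1.0)

    def test_smallest_count_tie_rule(self):
        # two leaves 0 and 1: parent 0 and 1 are co-optimal under (1,1)
        tree = parse_newick("(A,B);")
        counts, cost = wagner_reconstruct(tree, {"A": 0, "B": 1})
        assert cost == 1
        assert counts[tree.seed_node] == 0

    def test_missing_leaf_count_raises(self):
        with pytest.raises(KeyError):
            wagner_reconstruct(parse_newick("(A,B);"), {"A": 1})


class TestWagnerExhaustive:
    @pytest.mark.parametrize("gain,loss", PENALTIES)
    @pytest.mark.parametrize("n_leaves", [2, 3, 4])
    def test_dp_equals_enumeration_small_trees_all_counts(self, n_leaves, gain, loss):
        cfg = WagnerConfig(gain_penalty=gain, loss_penalty=loss)
        for nwk in enumerate_tree_shapes(n_leaves):
            tree = parse_newick(nwk)
            labels = leaf_labels(tree)
            for vec in itertools.product(range(4), repeat=n_leaves):
                lc = dict(zip(labels, vec))
                _, cost = wagner_reconstruct(tree, lc, cfg)
                assert cost == pytest.approx(
                    exhaustive_wagner(tree, lc, gain, loss)
                ), f"{nwk} {lc} ({gain},{loss})"

    @pytest.mark.parametrize("gain,loss", PENALTIES)
    @pytest.mark.parametrize("n_leaves", [5, 6])
    def test_dp_equals_enumeration_sampled_counts(self, n_leaves, gain, loss):
        rng = random.Random(97 + n_leaves)
        cfg = WagnerConfig(gain_penalty=gain, loss_penalty=loss)
        for nwk in enumerate_tree_shapes(n_leaves):
            tree = parse_newick(nwk)
            labels = leaf_labels(tree)
            for _ in range(12):
                lc = {l: rng.randrange(4) for l in labels}
                _, cost = wagner_reconstruct(tree, lc, cfg)
                assert cost == pytest.approx(
                    exhaustive_wagner(tree, lc, gain, loss)
                ), f"{nwk} {lc} ({gain},{loss})"

    def test_penalty_scaling_leaves_reconstruction_unchanged(self):
        rng = random.Random(5)
        tree = parse_newick("((A,(B,C)),(D,E));")
        for _ in range(20):
            lc = {l: rng.randrange(4) for l in leaf_labels(tree)}
            base, _ = wagner_reconstruct(tree, lc, WagnerConfig(2.0, 1.0))
            scaled, _ = wagner_reconstruct(tree, lc, WagnerConfig(6.0, 3.0))
            assert base == scaled


class TestBranchEvents:
    @pytest.mark.parametrize(
        "parent,child,expected",
        [
            (0, 2, "gain"),
            (0, 1, "gain"),
            (3, 0, "loss"),
            (1, 2, "expansion"),
            (3, 1, "contraction"),
            (1, 1, "none"),
            (0, 0, "none"),
        ],
    )
    def test_definitions(self, parent, child, expected):
        assert classify_branch_events(parent, child) == expected


class TestSummarize:
    def test_all_zero_matrix_no_events(self):
        tree = parse_newick("((A,B),C);")
        matrix = read_count_matrix("family\tA\tB\tC\nF1\t0\t0\t0\n")
        table = summarize_events(tree, matrix)
        assert table.events == []
        assert table.grand_totals == {
            "gain": 0, "loss": 0, "expansion": 0, "contraction": 0,
        }

    def test_constant_counts_no_events(self):
        tree = parse_newick("((A,B),C);")
        matrix = read_count_matrix("family\tA\tB\tC\nF1\t2\t2\t2\n")
        assert summarize_events(tree, matrix).events == []

    def test_single_gain_locates_branch(self):
        tree = parse_newick("((A,B),(C,D));")
        matrix = read_count_matrix("family\tA\tB\tC\tD\nF1\t1\t1\t0\t0\n")
        table = summarize_events(tree, matrix)
        assert len(table.events) == 1
        ev = table.events[0]
        assert ev.event == "gain" and ev.child_count == 1

    def test_totals_permutation_invariant_in_family_order(self):
        tree = parse_newick("((A,B),(C,D));")
        text = "family\tA\tB\tC\tD\nF1\t1\t1\t0\t0\nF2\t2\t0\t1\t1\nF3\t3\t3\t3\t1\n"
        m1 = read_count_matrix(text)
        m2 = m1.iloc[[2, 0, 1]]
        t1, t2 = summarize_events(tree, m1), summarize_events(tree, m2)
        assert t1.grand_totals == t2.grand_totals
        assert t1.node_totals.equals(t2.node_totals)

    def test_gain_and_expansion_mutually_exclusive_per_branch(self):
        tree = parse_newick("((A,(B,C)),(D,E));")
        matrix, _ = gen_count_evolution(
            tree, 1, 0.1, 0.1, 0.1, 0.1, seed=2, n_families=50
        )
        table = summarize_events(tree, matrix)
        seen = {}
        for ev in table.events:
            key = (ev.node, ev.family)
            assert key not in seen
            seen[key] = ev.event


class TestEventRecovery:
    def test_low_rate_totals_match_recorded_truth(self):
        tree = parse_newick(
            "(((A,B),(C,(D,E))),((F,G),(H,(I,(J,K)))),L);"
        )
        matrix, history = gen_count_evolution(
            tree, 2, 0.02, 0.02, 0.02, 0.02,
            seed=42, n_families=200, max_events_per_family=1,
        )
        assert history.events, "simulation produced no events"
        table = summarize_events(tree, matrix)
        assert table.grand_totals == history.event_totals()

    def test_low_rate_gain_regime_recovered(self):
        # families absent at the root can only be gained
        tree = parse_newick("(((A,B),(C,(D,E))),((F,G),(H,I)));")
        matrix, history = gen_count_evolution(
            tree, 0, 0.04, 0.0, 0.0, 0.0,
            seed=7, n_families=150, max_events_per_family=1,
        )
        totals = history.event_totals()
        assert totals["gain"] > 0
        table = summarize_events(tree, matrix)
        assert table.grand_totals == totals

    def test_forced_loss_on_terminal_branch(self):
        tree = parse_newick("((A,B),C);")
        matrix, history = gen_count_evolution(tree, 2, 0, 1.0, 0, 0, seed=0)
        # p_loss = 1 kills the family on the first branch below the root
        assert any(ev[2] == "loss" for ev in history.events)
        assert (matrix.to_numpy() == 0).all()

    def test_zero_rates_keep_root_count_everywhere(self):
        tree = parse_newick("((A,B),C);")
        matrix, history = gen_count_evolution(tree, 3, 0, 0, 0, 0, seed=1, n_families=5)
        assert (matrix.to_numpy() == 3).all()
        assert history.events == []
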