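import itertools
import random

import pytest

from motifarch.errors import InputError
from motifarch.phylo import (
    Node,
    count_gain_loss,
    default_tree,
    dollo_count,
    fitch_reconstruct,
    read_states_tsv,
    read_tree,
    resolve_states,
)


def brute_min_changes(root, tip_states):
    """Exhaustive enumeration over all internal (and unknown-tip) labelings."""
    internals = [n for n in root.postorder() if not n.is_leaf]
    leaves = root.leaves()
    unknowns = [l for l in leaves if tip_states.get(l.name) is None]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internals) + len(unknowns)):
        st = {}
        for node, s in zip(internals, assign[: len(internals)]):
            st[id(node)] = s
        for leaf, s in zip(unknowns, assign[len(internals) :]):
            st[id(leaf)] = s
        for leaf in leaves:
            state = tip_states.get(leaf.name)
            if state is not None:
                st[id(leaf)] = state
        changes = sum(
            st[id(p)] != st[id(c)] for p in root.preorder() for c in p.children
        )
        if best is None or changes < best:
            best = changes
    return best


def random_tree(names, rng):
    nodes = [Node(n) for n in names]
    counter = [0]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        parent = Node(f"I{counter[0]}", [a, b])
        counter[0] += 1
        nodes.append(parent)
    return nodes[0]


class TestFitch:
    def test_balanced_split_one_change(self):
        root = read_tree("((a,b),(c,d));", is_path=False)
        result = fitch_reconstruct(root, {"a": 1, "b": 1, "c": 0, "d": 0})
        assert result.change_count == 1

    def test_alternating_two_changes(self):
        root = read_tree("((a,b),(c,d));", is_path=False)
        result = fitch_reconstruct(root, {"a": 1, "b": 0, "c": 1, "d": 0})
        assert result.change_count == 2

    def test_constant_character_zero_changes(self):
        root = read_tree("((a,(b,e)),(c,d));", is_path=False)
        states = {n: 1 for n in "abcde"}
        assert fitch_reconstruct(root, states).change_count == 0

    def test_missing_tip_strict_vs_lenient(self):
        root = read_tree("((a,b),(c,d));", is_path=False)
        states = {"a": 1, "b": 1, "c": 0}
        with pytest.raises(InputError):
            fitch_reconstruct(root, states, strict=True)
        assert fitch_reconstruct(root, states).change_count == 1

    def test_too_few_known_states(self):
        root = read_tree("((a,b),(c,d));", is_path=False)
        with pytest.raises(InputError):
            fitch_reconstruct(root, {"a": 1})

    def test_matches_brute_force_on_random_trees(self):
        rng = random.Random(42)
        for case in range(200):
            n = rng.randint(2, 8)
            names = [f"t{i}" for i in range(n)]
            root = random_tree(names, rng)
            states = {}
            for name in names:
                states[name] = rng.choice([0, 1, 1, 0, None])
            if sum(1 for v in states.values() if v is not None) < 2:
                states[names[0]] = 0
                states[names[-1]] = 1
            result = fitch_reconstruct(root, states)
            assert result.change_count == brute_min_changes(root, states), (
                root.to_newick(),
                states,
            )


class TestGainLoss:
    def test_single_gain_in_derived_clade(self):
        root = read_tree(
            "(((Hymenoptera,Diptera),Hemiptera),Crustacea);", is_path=False
        )
        states = {"Hymenoptera": 1, "Diptera": 1, "Hemiptera": 0, "Crustacea": 0}
        events, node_states, total = count_gain_loss(root, states)
        assert total == 1
        kinds = [e.kind for e in events]
        assert kinds == ["gain"]
        assert node_states[id(root)] == 0

    def test_all_present_no_events(self):
        root = read_tree("((a,b),(c,d));", is_path=False)
        states = {n: 1 for n in "abcd"}
        events, node_states, total = count_gain_loss(root, states)
        assert events == [] and total == 0
        assert node_states[id(root)] == 1

    def test_two_events_under_any_policy(self):
        root = read_tree("((a,b),(c,d));", is_path=False)
        states = {"a": 1, "b": 0, "c": 1, "d": 0}
        for policy in ("prefer_absence", "prefer_presence"):
            events, _, total = count_gain_loss(root, states, policy)
            assert len(events) == total == 2

    def test_events_always_sum_to_change_count(self):
        rng = random.Random(7)
        for _ in range(100):
            n = rng.randint(3, 8)
            names = [f"t{i}" for i in range(n)]
            root = random_tree(names, rng)
            states = {name: rng.choice([0, 1]) for name in names}
            for policy in ("prefer_absence", "prefer_presence"):
                events, _, total = count_gain_loss(root, states, policy)
                assert len(events) == total

    def test_bad_policy_rejected(self):
        root = read_tree("((a,b),(c,d));", is_path=False)
        result = fitch_reconstruct(root, {"a": 1, "b": 1, "c": 0, "d": 0})
        with pytest.raises(InputError):
            resolve_states(result, "prefer_chaos")


class TestDollo:
    def test_single_origin_no_losses(self):
        root = read_tree(
            "(((Hymenoptera,Diptera),Hemiptera),Crustacea);", is_path=False
        )
        states = {"Hymenoptera": 1, "Diptera": 1, "Hemiptera": 0, "Crustacea": 0}
        assert dollo_count(root, states) == (1, 0)

    def test_gain_then_loss(self):
        root = read_tree("(((a,b),c),d);", is_path=False)
        states = {"a": 1, "b": 0, "c": 1, "d": 0}
        gains, losses = dollo_count(root, states)
        assert gains == 1 and losses == 1

    def test_absent_everywhere(self):
        root = read_tree("((a,b),(c,d));", is_path=False)
        assert dollo_count(root, {n: 0 for n in "abcd"}) == (0, 0)


class TestTrees:
    def test_polytomy_resolved_deterministically(self):
        t1 = read_tree("(a,b,c,d);", is_path=False)
        t2 = read_tree("(a,b,c,d);", is_path=False)
        assert t1.to_newick() == t2.to_newick()
        for node in t1.postorder():
            assert node.is_leaf or len(node.children) == 2

    def test_default_tree_tips(self):
        root = default_tree()
        tips = {n.name for n in root.leaves()}
        assert {"Diptera", "Hymenoptera", "Heteroptera", "Crustacea"} <= tips

    def test_unparseable_tree(self):
        with pytest.raises(InputError):
            read_tree("((a,b;", is_path=False)

    def test_newick_comments(self):
        root = read_tree("((a,b),c);", is_path=False)
        comments = {id(root): "state=1"}
        out = root.to_newick(comments)
        assert out.endswith("[&&NHX:state=1];")


def test_read_states_tsv(tmp_path):
    p = tmp_path / "states.tsv"
    p.write_text("taxon\tKRRW\tSRICH\nDiptera\t1\t1\nCrustacea\t0\t?\n")
    table = read_states_tsv(str(p))
    assert table["KRRW"] == {"Diptera": 1, "Crustacea": 0}
    assert table["SRICH"] == {"Diptera": 1, "Crustacea": None}
    bad = tmp_path / "bad.tsv"
    bad.write_text("taxon\tKRRW\nDiptera\t2\n")
    with pytest.raises(InputError):
        read_states_tsv(str(bad))
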