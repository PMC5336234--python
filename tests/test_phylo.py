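"""Parsimony, tree search, NJ, bootstrap, consensus and monophyly.

Fitch lengths are validated against a brute-force oracle that minimizes
over every assignment of states to internal nodes; the heuristic search is
validated against exhaustive enumeration of all unrooted six-taxon
topologies.
"""

import itertools

import numpy as np
import pytest

from conftest import PROTOSTOMES, REFERENCE_TOPOLOGY, VERTEBRATE_GROUPS
from rptp.phylo import (CharacterMatrix, GroupDefinition, bootstrap,
                        fitch_length, is_monophyletic, majority_consensus,
                        nj_tree, p_distance_matrix, search_parsimony)
from rptp.simulate import additive_distance_matrix
from rptp.tree import Clade, Tree, read_newick


# ------------------------------------------------------------- oracles

def brute_force_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Minimum changes over all internal-node state assignments."""
    states = sorted({c for r in matrix.rows for c in r} - {"?", "-"})
    leaf_state = dict(zip(matrix.labels, matrix.rows))
    total = 0
    for site in range(matrix.n_sites):
        internals = [n for n in tree.postorder() if not n.is_leaf]
        best = None
        for combo in itertools.product(states, repeat=len(internals)):
            assign = {id(n): s for n, s in zip(internals, combo)}
            cost = 0
            for node in tree.postorder():
                if node.is_leaf:
                    continue
                for ch in node.children:
                    if ch.is_leaf:
                        s = leaf_state[ch.label][site]
                        if s in ("?", "-"):
                            continue
                    else:
                        s = assign[id(ch)]
                    cost += s != assign[id(node)]
            best = cost if best is None else min(best, cost)
        total += best
    return total


def all_topologies(labels: list[str]):
    """Every unrooted binary topology, by inserting each successive leaf on
    every edge of every partial tree (yields (2n-5)!! trees)."""
    def _copy(n):
        return Clade(n.label, n.length, n.support, [_copy(c) for c in n.children])

    def _edges(root):
        out = []

        def walk(n):
            for c in n.children:
                out.append(c)
                walk(c)
        walk(root)
        return out

    def _replace(root, target, new):
        if root is target:
            return new
        return Clade(root.label, root.length, root.support,
                     [_replace(c, target, new) for c in root.children])

    def grow(base: Clade, rest: list[str]):
        if not rest:
            yield base
            return
        leaf = rest[0]
        for child in _edges(base):
            joint = Clade(children=[_copy(child), Clade(label=leaf)])
            # _replace is non-destructive: shares untouched subtrees
            yield from grow(_replace(base, child, joint), rest[1:])

    a, b, c = labels[:3]
    start = Clade(children=[Clade(label=a), Clade(label=b), Clade(label=c)])
    yield from (Tree(t) for t in grow(start, labels[3:]))


def random_matrix(rng, labels, n_sites=30, n_states=4):
    alphabet = "ACGT"[:n_states]
    rows = ["".join(alphabet[i] for i in rng.integers(0, n_states, n_sites))
            for _ in labels]
    return CharacterMatrix(list(labels), rows)


# ---------------------------------------------------------------- Fitch

class TestFitchLength:
    def test_identical_rows_cost_zero(self):
        m = CharacterMatrix(list("abcd"), ["ACGT"] * 4)
        assert fitch_length(read_newick("((a,b),(c,d));"), m) == 0

    def test_four_taxon_hand_case(self):
        m = CharacterMatrix(["t1", "t2", "t3", "t4"], ["A", "A", "B", "B"])
        assert fitch_length(read_newick("((t1,t2),(t3,t4));"), m) == 1
        assert fitch_length(read_newick("((t1,t3),(t2,t4));"), m) == 2

    def test_matches_brute_force_on_random_six_leaf_matrices(self):
        rng = np.random.default_rng(2024)
        labels = list("abcdef")
        topos = list(all_topologies(labels))
        for rep in range(20):
            m = random_matrix(rng, labels, n_sites=8, n_states=3)
            tree = topos[int(rng.integers(len(topos)))]
            assert fitch_length(tree, m) == brute_force_length(tree, m)

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(5)
        labels = list("abcdef")
        m = random_matrix(rng, labels)
        t1 = read_newick("((a,b),((c,d),(e,f)));")
        t2 = read_newick("(((a,b),(c,d)),e,f);")
        t3 = read_newick("(c,d,((e,f),(a,b)));")
        lengths = {fitch_length(t, m) for t in (t1, t2, t3)}
        assert len(lengths) == 1

    def test_missing_states_cost_nothing(self):
        m = CharacterMatrix(list("abcd"), ["A", "?", "B", "?"])
        assert fitch_length(read_newick("((a,b),(c,d));"), m) == 1


# --------------------------------------------------------------- search

class TestSearchParsimony:
    def test_finds_global_optimum_on_six_taxa(self):
        rng = np.random.default_rng(99)
        labels = list("abcdef")
        topos = list(all_topologies(labels))
        assert len(topos) == 105
        for rep in range(10):
            m = random_matrix(rng, labels, n_sites=20)
            opt = min(fitch_length(t, m) for t in topos)
            _, found = search_parsimony(m, n_starts=5,
                                        seed=int(rng.integers(2**31)))
            assert found == opt

    def test_recovers_generating_topology_on_clean_data(self, family_zero_rate):
        """Homoplasy-free characters: clades differ only by their planted
        group characters, so the planted topology's groups are recovered."""
        rows = {}
        groups = "BJHOQ"
        # five two-taxon groups with group-specific shared states
        for gi, g in enumerate(groups):
            for t in range(2):
                key = f"{g}{t}"
                shared = ["A" if i == gi else "C" for i in range(5)]
                private = ["G" if i == 2 * gi + t else "T" for i in range(10)]
                rows[key] = "".join(shared + private)
        m = CharacterMatrix(list(rows), list(rows.values()))
        tree, _ = search_parsimony(m, n_starts=5, seed=0)
        for g in groups:
            mono, _ = is_monophyletic(
                tree, GroupDefinition(g, frozenset({f"{g}0", f"{g}1"})))
            assert mono

    def test_more_starts_never_worse(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, list("abcdefgh"), n_sites=25)
        _, l1 = search_parsimony(m, n_starts=1, seed=3)
        _, l20 = search_parsimony(m, n_starts=20, seed=3)
        assert l20 <= l1

    def test_returned_length_matches_returned_tree(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, list("abcdefg"))
        tree, length = search_parsimony(m, n_starts=3, seed=4)
        assert fitch_length(tree, m) == length

    def test_fewer_than_four_taxa_warns(self):
        m = CharacterMatrix(list("abc"), ["A", "A", "C"])
        with pytest.warns(UserWarning):
            tree, _ = search_parsimony(m, seed=0)
        assert sorted(tree.leaf_labels()) == ["a", "b", "c"]


# ------------------------------------------------------------------- NJ

class TestNeighborJoining:
    def test_recovers_additive_trees_exactly(self):
        rng = np.random.default_rng(77)
        for rep in range(10):
            # random topology with random positive branch lengths
            labels = [f"t{i}" for i in range(7)]
            newick = _random_tree_newick(rng, labels)
            true = read_newick(newick)
            lab, D = additive_distance_matrix(true)
            est = nj_tree(lab, D)
            assert est.bipartitions() == true.bipartitions()
            lab2, D2 = additive_distance_matrix(est)
            assert lab2 == lab
            np.testing.assert_allclose(D2, D, atol=1e-9)

    def test_two_leaf_distance(self):
        t = nj_tree(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        _, D = additive_distance_matrix(t)
        assert D[0, 1] == pytest.approx(3.0)


def _random_tree_newick(rng, labels):
    nodes = [f"{l}:{rng.uniform(0.1, 2.0):.3f}" for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.3f}")
    return "(" + ",".join(f"{n}" for n in nodes) + ");"


# ------------------------------------------------------------ bootstrap

class TestBootstrap:
    def test_single_replicate_supports_are_0_or_100(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, list("abcdef"), n_sites=15)
        t = bootstrap(m, n_reps=1, seed=5)
        sups = [n.support for n in t.postorder()
                if not n.is_leaf and n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_one_column_matrix_resamples_itself(self):
        m = CharacterMatrix(list("abcd"), ["A", "A", "B", "B"])
        t = bootstrap(m, n_reps=10, seed=1)
        sups = [n.support for n in t.postorder() if n.support is not None]
        assert all(s == 100.0 for s in sups)

    def test_structured_clades_get_high_support(self, family):
        """Long internal branches in the generating tree: every planted
        group should be recovered at >= 95% support."""
        doms = dict(family.ptp_domains())
        from rptp.msa import progressive_align
        from rptp.records import ProteinRecord
        msa = progressive_align([ProteinRecord(l, s) for l, s in doms.items()])
        cm = CharacterMatrix.from_msa(msa)
        t = bootstrap(cm, n_reps=100, seed=9, method="nj")
        sups = {}
        leaves = frozenset(cm.labels)
        ref = min(leaves)
        for n in t.postorder():
            if not n.is_leaf and n is not t.root and n.support is not None:
                side = frozenset(n.leaf_labels())
                if ref in side:
                    side = leaves - side
                sups[side] = n.support
        for g in family.groups:
            if len(g.members) < 2:
                continue
            side = frozenset(g.members)
            if ref in side:
                side = leaves - side
            assert sups.get(side, 0.0) >= 95.0, g.name

    def test_supports_converge_across_seeds(self, family):
        doms = dict(family.ptp_domains())
        from rptp.msa import progressive_align
        from rptp.records import ProteinRecord
        msa = progressive_align([ProteinRecord(l, s) for l, s in doms.items()])
        cm = CharacterMatrix.from_msa(msa)

        def group_supports(seed):
            t = bootstrap(cm, n_reps=200, seed=seed, method="nj")
            leaves = frozenset(cm.labels)
            ref = min(leaves)
            out = {}
            for n in t.postorder():
                if not n.is_leaf and n.support is not None and n is not t.root:
                    side = frozenset(n.leaf_labels())
                    if ref in side:
                        side = leaves - side
                    out[side] = n.support
            return out

        s1, s2 = group_supports(21), group_supports(22)
        for g in family.groups:
            if len(g.members) < 2:
                continue
            side = frozenset(g.members)
            if min(cm.labels) in side:
                side = frozenset(cm.labels) - side
            assert abs(s1.get(side, 0) - s2.get(side, 0)) <= 5

    def test_reproducible_by_seed(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, list("abcdef"), n_sites=20)
        assert bootstrap(m, 20, seed=6).to_newick() == \
            bootstrap(m, 20, seed=6).to_newick()


# ------------------------------------------------------------ monophyly

class TestMonophyly:
    def test_whole_leafset_is_monophyletic(self):
        t = read_newick("((A,B),(C,D));")
        g = GroupDefinition("all", frozenset("ABCD"))
        assert is_monophyletic(t, g) == (True, 4)

    def test_four_taxon_cases(self):
        t = read_newick("((A,B),(C,D));")
        assert is_monophyletic(t, GroupDefinition("g", frozenset("AB")))[0]
        mono, size = is_monophyletic(t, GroupDefinition("g", frozenset("AC")))
        # smallest unrooted bipartition side containing {A, C} is e.g. {A,C,D}
        assert not mono and size == 3

    def test_unknown_member_rejected(self):
        from rptp.errors import ValidationError
        t = read_newick("((A,B),(C,D));")
        with pytest.raises(ValidationError):
            is_monophyletic(t, GroupDefinition("g", frozenset("AZ")))

    def test_reference_topology_group_statements(self):
        """On the reported backbone topology: each vertebrate R3 group is
        monophyletic, PTPRJ+PTPRH form a clade, and protostomes are
        monophyletic."""
        t = read_newick(REFERENCE_TOPOLOGY)
        for name, members in VERTEBRATE_GROUPS.items():
            assert is_monophyletic(
                t, GroupDefinition(name, frozenset(members)))[0], name
        jh = VERTEBRATE_GROUPS["PTPRJ"] | VERTEBRATE_GROUPS["PTPRH"]
        assert is_monophyletic(t, GroupDefinition("JH", frozenset(jh)))[0]
        assert is_monophyletic(
            t, GroupDefinition("protostomes", frozenset(PROTOSTOMES)))[0]


class TestConsensus:
    def test_identical_trees_full_support(self):
        trees = [read_newick("((a,b),(c,d),e);") for _ in range(4)]
        cons = majority_consensus(trees)
        sups = [n.support for n in cons.postorder() if n.support is not None]
        assert sups and all(s == 100.0 for s in sups)
        assert cons.bipartitions() == trees[0].bipartitions()

    def test_majority_split_kept_minority_dropped(self):
        t1 = read_newick("((a,b),(c,d),e);")
        t2 = read_newick("((a,b),(c,e),d);")
        t3 = read_newick("((a,b),(d,e),c);")
        cons = majority_consensus([t1, t2, t3])
        assert frozenset("cd") not in cons.bipartitions() \
            or frozenset("ab") in cons.bipartitions()
        sides = cons.bipartitions()
        assert any(s in (frozenset("ab"), frozenset("cde")) for s in sides)


class TestPDistance:
    def test_identical_rows_zero(self):
        m = CharacterMatrix(["a", "b"], ["ACGT", "ACGT"])
        assert p_distance_matrix(m)[0, 1] == 0.0

    def test_missing_excluded_from_denominator(self):
        m = CharacterMatrix(["a", "b"], ["A?GT", "ACGA"])
        assert p_distance_matrix(m)[0, 1] == pytest.approx(1 / 3)
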