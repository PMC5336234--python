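"""Tree inference and clade tests: Fitch parsimony with random-addition +
NNI search, neighbor joining, nonparametric bootstrap, majority-rule
consensus, and monophyly testing of predefined groups.

Parsimony uses the classic two-state-set Fitch pass, vectorized over sites
with bitmasks, on trees rooted along the edge next to the first leaf (the
length is invariant to that choice).  Gaps are treated as missing data by
default ('?' semantics); a flag turns the gap into a 21st state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .records import Msa
from .tree import Clade, Tree

MISSING = "?"


# ----------------------------------------------------- character matrix

@dataclass
class CharacterMatrix:
    """Aligned discrete characters for a set of taxa.

    ``rows`` are equal-length state strings (one character per site);
    '?' is missing.  With ``gap_as_state`` False (default) the alignment
    gap '-' is also treated as missing.
    """

    labels: list[str]
    rows: list[str]
    gap_as_state: bool = False

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValidationError("labels/rows mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate labels")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValidationError("rows have unequal lengths")
        states = sorted({c for r in self.rows for c in r} - {MISSING}
                        - (set() if self.gap_as_state else {"-"}))
        if len(states) > 31:
            raise ValidationError("more than 31 distinct states")
        self._states = states
        self._full = (1 << len(states)) - 1 if states else 0

    @classmethod
    def from_msa(cls, msa: Msa, gap_as_state: bool = False) -> "CharacterMatrix":
        return cls(list(msa.labels), list(msa.rows), gap_as_state)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def masks(self) -> np.ndarray:
        """(n_taxa, n_sites) uint32 bitmasks; missing = all states."""
        idx = {s: i for i, s in enumerate(self._states)}
        out = np.empty((len(self.rows), self.n_sites), dtype=np.uint32)
        for t, row in enumerate(self.rows):
            for j, c in enumerate(row):
                if c in idx:
                    out[t, j] = 1 << idx[c]
                else:  # '?' or gap-as-missing
                    out[t, j] = self._full
        return out


@dataclass(frozen=True)
class GroupDefinition:
    """A named set of leaf labels whose monophyly is to be tested."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"group {self.name!r} is empty")


# ----------------------------------------- adjacency form + Fitch engine

def _tree_to_adj(tree: Tree, labels: list[str]
                 ) -> tuple[dict[int, list[int]], int]:
    """Tree -> unrooted adjacency with leaves 0..n-1 in ``labels`` order.
    Degree-2 nodes (e.g. a rooted tree's root) are suppressed."""
    index = {l: i for i, l in enumerate(labels)}
    adj: dict[int, list[int]] = {i: [] for i in range(len(labels))}
    counter = [len(labels)]

    def walk(node: Clade) -> int:
        if node.is_leaf:
            if node.label not in index:
                raise ValidationError(f"leaf {node.label!r} not in matrix labels")
            return index[node.label]
        kids = [walk(c) for c in node.children]
        if len(kids) == 1:
            return kids[0]
        me = counter[0]
        counter[0] += 1
        adj[me] = []
        for k in kids:
            adj[me].append(k)
            adj[k].append(me)
        return me

    top = walk(tree.root)
    # suppress a degree-2 top node left by rooted input
    if len(adj[top]) == 2:
        a, b = adj[top]
        adj[a] = [x for x in adj[a] if x != top] + [b]
        adj[b] = [x for x in adj[b] if x != top] + [a]
        del adj[top]
    return adj, counter[0]


def _adj_to_tree(adj: dict[int, list[int]], labels: list[str]) -> Tree:
    """Adjacency -> Tree rooted at the internal node next to leaf 0
    (or at leaf 0's unique neighbor chain for tiny trees)."""
    if len(adj) == 1:
        return Tree(Clade(label=labels[0]))
    if len(adj) == 2:
        return Tree(Clade(children=[Clade(label=labels[0]), Clade(label=labels[1])]))
    root = adj[0][0]

    def build(node: int, parent: int) -> Clade:
        if node < len(labels):
            return Clade(label=labels[node])
        return Clade(children=[build(c, node) for c in adj[node] if c != parent])

    children = [build(c, root) for c in adj[root]]
    return Tree(Clade(children=children))


def _fitch_adj(adj: dict[int, list[int]], n_leaves: int, masks: np.ndarray,
               weights: np.ndarray | None = None) -> float:
    """Weighted Fitch length of an unrooted binary tree in adjacency form."""
    n_sites = masks.shape[1]
    changes = np.zeros(n_sites, dtype=np.int64)
    if len(adj) <= 2:
        return 0.0
    # root along the edge next to the smallest leaf present (partial trees
    # during stepwise addition need not contain leaf 0)
    root_leaf = min(k for k in adj if k < n_leaves)
    start = adj[root_leaf][0]
    order: list[tuple[int, int]] = []
    stack = [(start, root_leaf)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        if node >= n_leaves:
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
    node_mask: dict[int, np.ndarray] = {}
    for node, parent in reversed(order):
        if node < n_leaves:
            node_mask[node] = masks[node]
            continue
        kids = [node_mask[c] for c in adj[node] if c != parent]
        m = kids[0]
        for k in kids[1:]:
            inter = m & k
            zero = inter == 0
            changes += zero
            m = np.where(zero, m | k, inter)
        node_mask[node] = m
    inter = node_mask[start] & masks[root_leaf]
    changes = changes + (inter == 0)
    if weights is None:
        return float(changes.sum())
    return float((changes * weights).sum())


def fitch_length(tree: Tree, matrix: CharacterMatrix,
                 weights: np.ndarray | None = None) -> float:
    """Parsimony length of ``tree`` under Fitch counting.

    Missing states (and gaps, unless ``gap_as_state``) can take any value
    at no cost.  The length is invariant under re-rooting.
    """
    labels = list(matrix.labels)
    if set(tree.leaf_labels()) != set(labels):
        raise ValidationError("tree leaves do not match matrix labels")
    adj, _ = _tree_to_adj(tree, labels)
    return _fitch_adj(adj, len(labels), matrix.masks(), weights)


# ----------------------------------------------------------- tree search

def _stepwise_addition(order: list[int], adj_template: None, n_leaves: int,
                       masks: np.ndarray, weights: np.ndarray | None
                       ) -> dict[int, list[int]]:
    """Random-addition-sequence starting tree: greedily insert each taxon on
    the edge minimizing Fitch length (first-best on ties, deterministic)."""
    a, b, c = order[:3]
    center = n_leaves
    adj: dict[int, list[int]] = {a: [center], b: [center], c: [center],
                                 center: [a, b, c]}
    next_id = n_leaves + 1
    for leaf in order[3:]:
        edges = sorted((min(u, v), max(u, v))
                       for u in adj for v in adj[u] if u < v)
        best = None
        for (u, v) in edges:
            w = next_id
            adj[u] = [x if x != v else w for x in adj[u]]
            adj[v] = [x if x != u else w for x in adj[v]]
            adj[w] = [u, v, leaf]
            adj[leaf] = [w]
            length = _fitch_adj(adj, n_leaves, masks, weights)
            if best is None or length < best[0]:
                best = (length, u, v)
            # undo
            del adj[w], adj[leaf]
            adj[u] = [x if x != w else v for x in adj[u]]
            adj[v] = [x if x != w else u for x in adj[v]]
        _, u, v = best
        w = next_id
        next_id += 1
        adj[u] = [x if x != v else w for x in adj[u]]
        adj[v] = [x if x != u else w for x in adj[v]]
        adj[w] = [u, v, leaf]
        adj[leaf] = [w]
    return adj


def _nni_neighbors(adj: dict[int, list[int]], n_leaves: int):
    """Yield (edge, swap) descriptors for every NNI move."""
    for u in adj:
        if u < n_leaves:
            continue
        for v in adj[u]:
            if v < n_leaves or v < u:
                continue
            us = [x for x in adj[u] if x != v]
            vs = [x for x in adj[v] if x != u]
            # swapping us[1]<->vs[0] and us[1]<->vs[1] covers both topologies
            yield (u, v, us[1], vs[0])
            yield (u, v, us[1], vs[1])


def _apply_swap(adj, u, v, x, y):
    """Swap subtree x (neighbor of u) with subtree y (neighbor of v)."""
    adj[u] = [y if t == x else t for t in adj[u]]
    adj[v] = [x if t == y else t for t in adj[v]]
    adj[x] = [v if t == u else t for t in adj[x]]
    adj[y] = [u if t == v else t for t in adj[y]]


def _nni_hillclimb(adj: dict[int, list[int]], n_leaves: int, masks: np.ndarray,
                   weights: np.ndarray | None) -> tuple[dict, float]:
    """Best-improvement NNI until no move shortens the tree."""
    length = _fitch_adj(adj, n_leaves, masks, weights)
    improved = True
    while improved:
        improved = False
        best_move, best_len = None, length
        for (u, v, x, y) in _nni_neighbors(adj, n_leaves):
            _apply_swap(adj, u, v, x, y)
            l = _fitch_adj(adj, n_leaves, masks, weights)
            _apply_swap(adj, u, v, y, x)  # undo
            if l < best_len:
                best_len, best_move = l, (u, v, x, y)
        if best_move is not None:
            _apply_swap(adj, *best_move)
            length = best_len
            improved = True
    return adj, length


def search_parsimony(matrix: CharacterMatrix, n_starts: int = 10,
                     seed: int | None = None,
                     weights: np.ndarray | None = None,
                     keep_all: bool = False
                     ) -> tuple[Tree, float] | tuple[list[Tree], float]:
    """Heuristic maximum-parsimony search.

    Random stepwise addition (``n_starts`` independent addition orders)
    followed by best-improvement NNI hill climbing.  Deterministic for a
    given seed.  With ``keep_all`` every distinct equally-best topology
    found is returned (for strict/majority consensus reporting).
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 4:
        warnings.warn("fewer than 4 taxa: returning the star tree")
        star = Tree(Clade(children=[Clade(label=l) for l in labels]))
        return ([star], 0.0) if keep_all else (star, fitch_length(star, matrix))
    masks = matrix.masks()
    rng = np.random.default_rng(seed)
    best_len = None
    best: dict[frozenset, Tree] = {}
    for _ in range(n_starts):
        order = [int(i) for i in rng.permutation(n)]
        adj = _stepwise_addition(order, None, n, masks, weights)
        adj, length = _nni_hillclimb(adj, n, masks, weights)
        if best_len is None or length < best_len - 1e-9:
            best_len = length
            best = {}
        if abs(length - best_len) <= 1e-9:
            t = _adj_to_tree(adj, labels)
            best.setdefault(frozenset(t.bipartitions()), t)
    trees = [t for _, t in sorted(best.items(), key=lambda kv: kv[1].to_newick())]
    if keep_all:
        return trees, best_len
    return trees[0], best_len


# ------------------------------------------------------ neighbor joining

def nj_tree(labels: list[str], dist: np.ndarray) -> Tree:
    """Neighbor joining on a distance matrix; deterministic tie-breaks
    (minimum Q, then lexicographically smallest label pair).

    On an exactly additive matrix this reconstructs the generating topology
    and its path-length metric.
    """
    if len(labels) < 2:
        raise ValidationError("nj_tree needs >= 2 taxa")
    dist = np.asarray(dist, dtype=float)
    nodes: dict[str, Clade] = {l: Clade(label=l) for l in labels}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if a != b:
                d[(a, b)] = float(dist[i, j])
    active = sorted(labels)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[(a, b)] - r[a] - r[b]
                if best is None or (q, a, b) < best:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[(a, b)] - la
        nodes[a].length, nodes[b].length = la, lb
        new = f"({a},{b})"
        nodes[new] = Clade(children=[nodes[a], nodes[b]])
        for c in active:
            if c not in (a, b):
                dn = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
                d[(new, c)] = d[(c, new)] = dn
        active = sorted([c for c in active if c not in (a, b)] + [new])
    if len(active) == 2:
        a, b = active
        nodes[a].length = d[(a, b)]
        nodes[b].length = 0.0
        return Tree(Clade(children=[nodes[a], nodes[b]]))
    a, b, c = active
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    return Tree(Clade(children=[nodes[a], nodes[b], nodes[c]]))


def p_distance_matrix(matrix: CharacterMatrix,
                      weights: np.ndarray | None = None) -> np.ndarray:
    """Pairwise proportion of differing sites (both states present)."""
    rows = matrix.rows
    n = len(rows)
    L = matrix.n_sites
    w = np.ones(L) if weights is None else np.asarray(weights, dtype=float)
    arr = np.array([[ord(c) for c in r] for r in rows])
    missing = {ord(MISSING)} | (set() if matrix.gap_as_state else {ord("-")})
    valid = ~np.isin(arr, list(missing))
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            tot = (w * both).sum()
            diff = (w * (both & (arr[i] != arr[j]))).sum()
            out[i, j] = out[j, i] = diff / tot if tot else 0.0
    return out


# -------------------------------------------------------------- consensus

def majority_consensus(trees: list[Tree], min_freq: float = 0.5) -> Tree:
    """Majority-rule consensus with split frequencies (%) as supports."""
    if not trees:
        raise ValidationError("no trees to summarize")
    leaves = frozenset(trees[0].leaf_labels())
    for t in trees[1:]:
        if frozenset(t.leaf_labels()) != leaves:
            raise ValidationError("trees have different leaf sets")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.bipartitions():
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    keep = [(s, c / n) for s, c in counts.items() if c / n > min_freq]
    keep.sort(key=lambda sc: (-len(sc[0]), sorted(sc[0])))

    root = Clade(children=[Clade(label=l) for l in sorted(leaves)])
    clade_of: list[tuple[set, Clade]] = [(set(leaves), root)]
    for s, freq in keep:
        parent_set, parent = min(
            ((cs, cn) for cs, cn in clade_of if s <= cs),
            key=lambda t: len(t[0]))
        inside = [ch for ch in parent.children
                  if set(ch.leaf_labels()) <= s]
        if not inside or set().union(*(set(c.leaf_labels()) for c in inside)) != s:
            continue  # incompatible with a previously placed split
        new = Clade(children=inside, support=round(100.0 * freq, 1))
        parent.children = [ch for ch in parent.children if ch not in inside]
        parent.children.append(new)
        clade_of.append((set(s), new))
    return Tree(root)


# -------------------------------------------------------------- bootstrap

def bootstrap(matrix: CharacterMatrix, n_reps: int, seed: int | None = None,
              method: str = "parsimony", n_starts: int = 2) -> Tree:
    """Nonparametric bootstrap: resample sites with replacement, re-infer a
    tree per replicate, and return the majority-rule consensus with split
    frequencies (0-100) as supports."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if method not in ("parsimony", "nj"):
        raise ValidationError(f"unknown bootstrap method {method!r}")
    rng = np.random.default_rng(seed)
    L = matrix.n_sites
    labels = list(matrix.labels)
    reps: list[Tree] = []
    for _ in range(n_reps):
        counts = np.bincount(rng.integers(0, L, size=L), minlength=L)
        if method == "parsimony":
            t, _ = search_parsimony(matrix, n_starts=n_starts,
                                    seed=int(rng.integers(2 ** 31)),
                                    weights=counts)
        else:
            t = nj_tree(labels, p_distance_matrix(matrix, weights=counts))
        reps.append(t)
    return majority_consensus(reps, min_freq=0.0 if n_reps == 1 else 0.5)


def split_supports(trees: list[Tree]) -> dict[frozenset, float]:
    """Frequency (%) of every split across a set of trees."""
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.bipartitions():
            counts[s] = counts.get(s, 0) + 1
    return {s: 100.0 * c / len(trees) for s, c in counts.items()}


# -------------------------------------------------------------- monophyly

def is_monophyletic(tree: Tree, group: GroupDefinition
                    ) -> tuple[bool, int]:
    """Does an edge bipartition isolate exactly the group?

    Returns (monophyletic, size of the smallest clade containing the group).
    Tested on the unrooted tree, so a group equal to all leaves, or to the
    complement of a single-edge side, is monophyletic.
    """
    leaves = frozenset(tree.leaf_labels())
    unknown = group.members - leaves
    if unknown:
        raise ValidationError(f"group {group.name!r}: unknown members {sorted(unknown)}")
    members = frozenset(group.members)
    if members == leaves:
        return True, len(leaves)
    if len(members) == 1:
        return True, 1
    sides: set[frozenset] = set()
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = frozenset(node.leaf_labels())
        sides.add(side)
        sides.add(leaves - side)
    mono = members in sides
    containing = [s for s in sides if members <= s]
    smallest = min((len(s) for s in containing), default=len(leaves))
    return mono, min(smallest, len(leaves))
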