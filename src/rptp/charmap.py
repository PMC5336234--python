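"""Join structural character tables to tree leaves and reconstruct
ancestral discrete states by Fitch parsimony.

`annotate_tree` produces the long-format (leaf, character, value) table
behind a characters-on-the-tree panel plus a Newick string with NHX-style
comment annotations.  `fitch_ancestral` reports ancestral states as *sets*
— when several states are equally parsimonious at a node, all are kept
rather than forcing an arbitrary resolution.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .errors import ValidationError
from .tree import Clade, Tree

MISSING = "?"


def annotate_tree(tree: Tree, chars: pd.DataFrame
                  ) -> tuple[pd.DataFrame, str, list[str]]:
    """Attach a character table (indexed by leaf label) to a tree.

    Returns (long-format table, NHX-annotated Newick, list of character
    table labels absent from the tree).  Leaves missing from the table get
    '?' for every character, with a warning; extra table rows are reported,
    not fatal.  Topology is never altered.
    """
    leaves = tree.leaf_labels()
    extra = sorted(set(chars.index) - set(leaves))
    rows = []
    for leaf in leaves:
        if leaf in chars.index:
            for col in chars.columns:
                v = chars.loc[leaf, col]
                rows.append((leaf, col, MISSING if pd.isna(v) else v))
        else:
            warnings.warn(f"leaf {leaf!r} has no character row")
            for col in chars.columns:
                rows.append((leaf, col, MISSING))
    table = pd.DataFrame(rows, columns=["leaf", "character", "value"])

    def fmt(node: Clade) -> str:
        if node.is_leaf:
            s = node.label or ""
            if node.label in chars.index:
                kv = ":".join(
                    f"{c}={chars.loc[node.label, c]}" for c in chars.columns)
                s += f"[&&NHX:{kv}]"
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                s += f"{node.support:g}"
        if node.length is not None:
            s += f":{node.length:g}"
        return s

    return table, fmt(tree.root) + ";", extra


def fitch_ancestral(tree: Tree, character: dict[str, str]
                    ) -> tuple[set[str], list[tuple[frozenset[str], set[str]]], int]:
    """Set-valued Fitch ancestral reconstruction of one discrete character.

    ``character`` maps each leaf label to its state ('?' allowed).  Returns
    (root state set, per-node sets as (clade leafset, state set) pairs in
    postorder, parsimony change count).  The change count equals the Fitch
    length of the same single-column matrix and is invariant under
    re-rooting.
    """
    leaves = set(tree.leaf_labels())
    missing_leaves = leaves - set(character)
    if missing_leaves:
        raise ValidationError(f"no state for leaves {sorted(missing_leaves)}")
    states = sorted(set(character.values()) - {MISSING})
    full = set(states)
    changes = 0
    up: dict[int, set[str]] = {}

    order = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(order)}
    for node in order:
        if node.is_leaf:
            s = character[node.label]
            up[id(node)] = full.copy() if s == MISSING else {s}
        else:
            acc = up[id(node.children[0])]
            for ch in node.children[1:]:
                inter = acc & up[id(ch)]
                if inter:
                    acc = inter
                else:
                    acc = acc | up[id(ch)]
                    changes += 1
            up[id(node)] = acc

    down: dict[int, set[str]] = {id(tree.root): up[id(tree.root)]}
    for node in reversed(order):  # preorder-ish: parents before children
        for ch in node.children:
            parent_final = down[id(node)]
            inter = parent_final & up[id(ch)]
            down[id(ch)] = inter if inter else up[id(ch)]

    per_node = [(frozenset(n.leaf_labels()), down[id(n)]) for n in order]
    return down[id(tree.root)], per_node, changes
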