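"""Shared helpers over dendropy trees: labels, clades, splits, path lengths."""

from __future__ import annotations

from typing import Iterable

import dendropy


def tip_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [tip_label(n) for n in tree.leaf_node_iter()]


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def node_tipsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Map every node to the frozenset of tip labels below it (postorder)."""
    out: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset([tip_label(node)])
        else:
            s: set[str] = set()
            for ch in node.child_nodes():
                s |= out[ch]
            out[node] = frozenset(s)
    return out


def clade_sets(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Rooted clades (tip-label sets of internal nodes, root included)."""
    tips = node_tipsets(tree)
    return {s for n, s in tips.items() if not n.is_leaf()}


def splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Unrooted bipartitions as canonical tip-label sets.

    Each internal edge induces a split; the canonical representative is the
    side NOT containing the lexicographically smallest tip, so rooted and
    unrooted versions of the same topology compare equal.
    """
    all_tips = frozenset(leaf_labels(tree))
    anchor = min(all_tips)
    tips = node_tipsets(tree)
    out: set[frozenset[str]] = set()
    for node, below in tips.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = below if anchor not in below else all_tips - below
        if 1 < len(side) < len(all_tips) - 1:
            out.add(side)
    return out


def path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Tip-to-tip path lengths (keys are sorted label pairs)."""
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            key = tuple(sorted((t1.label, t2.label)))
            out[key] = pdm.patristic_distance(t1, t2)
    return out


class SpeciesIndex:
    """Constant-time-ish LCA and subtree queries over a rooted species tree."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.node_of: dict[str, dendropy.Node] = {}
        self.depth: dict[dendropy.Node, int] = {}
        self.parent: dict[dendropy.Node, dendropy.Node | None] = {}
        for node in tree.preorder_node_iter():
            label = tip_label(node)
            if label is not None:
                self.node_of[label] = node
            par = node.parent_node
            self.parent[node] = par
            self.depth[node] = 0 if par is None else self.depth[par] + 1
        self.tipsets = node_tipsets(tree)

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a is not b:
            a = self.parent[a]
            b = self.parent[b]
        return a

    def lca_of(self, labels: Iterable[str]) -> dendropy.Node:
        nodes = [self.node_of[l] for l in labels]
        cur = nodes[0]
        for n in nodes[1:]:
            cur = self.lca(cur, n)
        return cur
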