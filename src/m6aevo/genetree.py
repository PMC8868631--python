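"""Distance-based gene-tree inference: Poisson distances, neighbor joining,
nonparametric bootstrap support and midpoint rooting.

Neighbor joining with a nonparametric bootstrap stands in for full
maximum-likelihood tree search: the downstream reconciliation needs a
supported topology, which NJ provides with a provable guarantee — on an
additive (tree-metric) distance matrix it returns the generating topology
and branch lengths exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .msa import GAP, Alignment, TrimmedAlignment
from .trees import splits, tip_label


def poisson_distance(p: float) -> float:
    """Poisson-corrected evolutionary distance ``d = -ln(1 - p)`` from an
    observed proportion ``p`` of differing sites.  ``p >= 1`` is saturated
    and raises."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 1:
        raise ValueError("saturated distance: p >= 1")
    return float(-np.log1p(-p))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances with taxon ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")

    @classmethod
    def from_alignment(cls, aln, saturation_cap: float = 0.99) -> "DistanceMatrix":
        """Pairwise Poisson distances from an alignment.

        ``p`` is computed over columns where both rows hold letters; it is
        capped just below 1 (``saturation_cap``) so saturated pairs stay
        finite rather than aborting the whole matrix.
        """
        rows = aln.rows
        ids = list(aln.ids)
        n = len(ids)
        arr = np.array([list(r) for r in rows])
        gaps = arr == GAP
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                shared = ~(gaps[i] | gaps[j])
                total = int(shared.sum())
                if total == 0:
                    p = saturation_cap
                else:
                    p = float((arr[i][shared] != arr[j][shared]).sum() / total)
                    p = min(p, saturation_cap)
                d = poisson_distance(p)
                values[i, j] = values[j, i] = d
        return cls(ids, values)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in self.values[i]) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(header, np.array(rows, dtype=float))


def _min_tip(node: dendropy.Node, cache: dict) -> str:
    return cache[node]


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Q-matrix ties are broken by the lexicographically smallest pair of
    cluster representative labels (the smallest tip label in each cluster),
    so the agglomeration order is platform-independent.  Negative branch
    lengths are clamped to zero with the deficit moved onto the sister
    branch.  The returned tree is unrooted (the seed node is the final
    three-way join, or the two-taxon edge split in half).
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for label in dm.ids:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=label)
        nodes.append(node)
        reps.append(label)
    D = dm.values.astype(float).copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                key = (q, *sorted((reps[active[ai]], reps[active[aj]])))
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        ni.edge.length = li
        nj.edge.length = lj
        parent.add_child(ni)
        parent.add_child(nj)
        # distances from the new cluster to the rest
        new_d = {}
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_d[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        for k, v in new_d.items():
            D[i, k] = D[k, i] = max(v, 0.0)
        active = [k for k in active if k != j]

    seed = dendropy.Node()
    if len(active) == 2:
        i, j = active
        d = D[i, j]
        nodes[i].edge.length = d / 2
        nodes[j].edge.length = d / 2
        seed.add_child(nodes[i])
        seed.add_child(nodes[j])
    else:
        i, j, k = active
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            nodes[idx].edge.length = max(ln, 0.0)
            seed.add_child(nodes[idx])
    tree.seed_node = seed
    return tree


def set_supports(tree: dendropy.Tree, value: float) -> None:
    """Assign a uniform support value to every internal non-root node."""
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.parent_node is not None:
            node.support = value
            node.label = f"{value:g}"


def bootstrap_support(
    aln: TrimmedAlignment | Alignment,
    replicates: int = 1000,
    seed: int | None = None,
    saturation_cap: float = 0.99,
) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap supports.

    Alignment columns are resampled with replacement ``replicates`` times;
    NJ is recomputed on each resample; the support of an internal branch of
    the original tree is the fraction of replicate trees containing its
    bipartition.  Supports are stored on ``node.support`` and mirrored into
    ``node.label``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = aln.alignment if isinstance(aln, TrimmedAlignment) else aln
    if base.length < 2:
        raise ValueError("alignment must have >= 2 columns")
    rng = np.random.default_rng(seed)
    dm = DistanceMatrix.from_alignment(base, saturation_cap)
    tree = neighbor_joining(dm)
    from .trees import node_tipsets

    all_tips = frozenset(base.ids)
    anchor = min(all_tips)
    counts: dict[frozenset, int] = {s: 0 for s in splits(tree)}

    arr = np.array([list(r) for r in base.rows])
    ids = list(base.ids)
    for _ in range(replicates):
        cols = rng.integers(0, base.length, size=base.length)
        rep_aln = Alignment(ids, ["".join(row) for row in arr[:, cols]])
        rep_tree = neighbor_joining(DistanceMatrix.from_alignment(rep_aln, saturation_cap))
        rep_splits = splits(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1

    tipsets = node_tipsets(tree)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = tipsets[node]
        side = below if anchor not in below else all_tips - below
        if side in counts:
            sup = counts[side] / replicates
        else:
            sup = 1.0  # trivial split (single tip on one side)
        node.support = sup
        node.label = f"{sup:.3f}"
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of its longest tip-to-tip path.

    Operates on a clone; supports riding on nodes are preserved where the
    corresponding edge survives rerooting.
    """
    from .trees import leaf_labels, node_tipsets

    def node_support(node):
        sup = getattr(node, "support", None)
        if sup is not None:
            return float(sup)
        try:
            return float(node.label)
        except (TypeError, ValueError):
            return None

    all_tips = frozenset(leaf_labels(tree))
    anchor = min(all_tips)

    def canonical(side: frozenset) -> frozenset:
        return side if anchor not in side else all_tips - side

    # record split -> support on the unrooted tree, reassign after rerooting
    # (node-attached supports do not survive the edge remapping)
    sup_by_split = {}
    tipsets = node_tipsets(tree)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = node_support(node)
        if sup is not None:
            sup_by_split[canonical(tipsets[node])] = sup

    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=False)
    tipsets = node_tipsets(rooted)
    for node in rooted.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = canonical(tipsets[node])
        # splits absent from the map are trivial (one tip vs rest): certain
        sup = sup_by_split.get(side, 1.0)
        node.support = sup
        node.label = f"{sup:.3f}"
    return rooted
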