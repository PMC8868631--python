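"""Synthetic evolutionary histories with ground truth.

Everything downstream (screening, alignment, trees, reconciliation, motif
and structure analysis) is exercised on gene families generated here, where
the true history — duplications, losses, horizontal transfers, the true
gene tree, the embedded motifs, the rigid motion between structure pairs —
is known exactly.

The gene-family process is a branchwise birth–death–transfer model: each
gene lineage travelling along a species-tree branch experiences duplication
(rate ``dup_rate``), loss (``loss_rate``) and transfer-out (``transfer_rate``)
as independent Poisson processes per unit branch length; a transfer copies
the lineage onto a uniformly chosen contemporaneous recipient branch
(additive transfer — the donor keeps its copy).  Sequences then evolve down
the true gene tree under uniform 20-letter replacement, which has the
closed-form expected difference proportion
``p(t) = (19/20) * (1 - exp(-(20/19) t))`` used as an oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .homolog import AMINO_ACIDS, ProteinRecord
from .structure import CaTrace
from .trees import tip_label

SUPERGROUPS = (
    "Bacteria",
    "Archaea",
    "Discoba",
    "Metamonada",
    "SAR",
    "Archaeplastida",
    "Amorphea",
)

#: Supergroup composition of the default 88-taxon panel.
DEFAULT_PANEL_COUNTS: dict[str, int] = {
    "Bacteria": 17,
    "Archaea": 6,
    "Discoba": 7,
    "Metamonada": 2,
    "SAR": 14,
    "Archaeplastida": 6,
    "Amorphea": 36,
}


@dataclass
class SpeciesTree:
    """A rooted, ultrametric species tree whose tips carry supergroup labels."""

    tree: dendropy.Tree
    supergroup_of: dict[str, str]

    def __post_init__(self) -> None:
        tips = {tip_label(n) for n in self.tree.leaf_node_iter()}
        missing = tips - set(self.supergroup_of)
        if missing:
            raise ValueError(f"tips without a supergroup: {sorted(missing)}")
        for node in self.tree.preorder_node_iter():
            if node.edge.length is not None and node.edge.length < 0:
                raise ValueError("negative branch length in species tree")

    @property
    def taxa(self) -> list[str]:
        return [tip_label(n) for n in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        from .trees import write_newick

        return write_newick(self.tree)

    def write_map_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\tsupergroup\n")
            for t in self.taxa:
                fh.write(f"{t}\t{self.supergroup_of[t]}\n")

    def supergroup_clade_parents(self) -> dict[str, dendropy.Node]:
        """Parent node of each supergroup's clade root (None for the root).

        Two supergroups are 'sisters' iff their clade roots share a parent;
        non-sister supergroups count as distantly related for xenology.
        """
        from .trees import node_tipsets

        tipsets = node_tipsets(self.tree)
        out: dict[str, dendropy.Node] = {}
        groups = set(self.supergroup_of.values())
        for sg in groups:
            members = {t for t, g in self.supergroup_of.items() if g == sg}
            # smallest clade containing all members
            best = None
            for node, below in tipsets.items():
                if members <= below and (best is None or len(below) < len(tipsets[best])):
                    best = node
            out[sg] = best.parent_node
        return out


@dataclass
class EvolParams:
    """Rates and shapes of the simulated gene-family process.

    Rates are events per unit branch length (branch lengths are in expected
    substitutions/site, tree height 1 by construction).  ``motifs`` is a
    list of ``(pattern_string, start)`` pairs: literal residue strings
    written into the root sequence at 0-based ``start`` and held invariant
    during sequence evolution.
    """

    dup_rate: float = 0.0
    loss_rate: float = 0.0
    transfer_rate: float = 0.0
    root_copies: int = 1
    seq_length: int = 300
    subst_rate: float = 0.3
    motifs: list[tuple[str, int]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.dup_rate, self.loss_rate, self.transfer_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.root_copies < 1:
            raise ValueError("root_copies must be >= 1")
        for motif, start in self.motifs:
            if start < 0 or start + len(motif) > self.seq_length:
                raise ValueError(f"motif {motif!r} at {start} outside sequence")
            if len(motif) >= self.seq_length:
                raise ValueError("sequence length must exceed longest motif")


@dataclass(frozen=True)
class Event:
    """One event of a family's true history.

    ``branch`` and ``recipient`` identify species-tree branches by the label
    of the branch's child node (tips by taxon id, internal nodes ``n1``…).
    ``recipient`` is set for transfers only.
    """

    kind: str  # gain | duplication | loss | transfer
    branch: str
    time: float
    recipient: str | None = None


@dataclass
class TrueHistory:
    events: list[Event]

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    @property
    def transfers(self) -> list[Event]:
        return [e for e in self.events if e.kind == "transfer"]

    @property
    def losses(self) -> list[Event]:
        return [e for e in self.events if e.kind == "loss"]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "kind": e.kind,
                    "branch": e.branch,
                    "recipient": e.recipient or "",
                    "time": e.time,
                }
                for e in self.events
            ],
            columns=["kind", "branch", "recipient", "time"],
        )


@dataclass
class SimulatedFamily:
    """A gene family with its complete ground truth."""

    name: str
    records: list[ProteinRecord]
    tip_map: dict[str, str]  # sequence id -> taxon
    history: TrueHistory
    gene_tree: dendropy.Tree | None  # None when the family went extinct
    species_tree: SpeciesTree
    #: gene-tree tips descended from each transfer event, in event order
    transfer_descendants: list[list[str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# species panel


def simulate_species_panel(
    counts_per_supergroup: Mapping[str, int], seed: int
) -> SpeciesTree:
    """Random ultrametric species panel with one clade per supergroup.

    Within each supergroup, tips are joined in random order; the supergroup
    clades are then joined in random order to form the backbone.  Node
    depths are drawn uniformly between parent depth and the tips, so the
    tree is ultrametric with height 1 (branch lengths in expected
    substitutions/site).  Deterministic for a given seed.
    """
    if not counts_per_supergroup:
        raise ValueError("counts map must be non-empty")
    if any(c < 1 for c in counts_per_supergroup.values()):
        raise ValueError("all supergroup counts must be >= 1")
    rng = np.random.default_rng(seed)

    def join_random(items: list) -> object:
        items = list(items)
        while len(items) > 1:
            i, j = sorted(rng.choice(len(items), size=2, replace=False))
            b = items.pop(j)
            a = items.pop(i)
            items.append((a, b))
        return items[0]

    clades = []
    supergroup_of: dict[str, str] = {}
    for sg, count in counts_per_supergroup.items():
        names = [f"{sg}_{i + 1:02d}" for i in range(count)]
        for name in names:
            supergroup_of[name] = sg
        clades.append(join_random(names))
    topology = join_random(clades)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    counter = [0]

    def build(struct, parent_depth: float | None) -> dendropy.Node:
        node = dendropy.Node()
        if isinstance(struct, str):
            node.taxon = tns.new_taxon(label=struct)
            depth = 1.0
        else:
            counter[0] += 1
            node.label = f"n{counter[0]}"
            if parent_depth is None:
                depth = 0.0  # the root defines time zero
            else:
                depth = parent_depth + rng.uniform(0.2, 0.8) * (1.0 - parent_depth)
            for child_struct in struct:
                child = build(child_struct, depth)
                node.add_child(child)
        node.depth = depth
        node.edge.length = depth - (parent_depth or 0.0)
        return node

    root = build(topology, None)
    root.edge.length = None
    tree.seed_node = root
    return SpeciesTree(tree, supergroup_of)


def default_panel(seed: int = 88) -> SpeciesTree:
    """The bundled default panel: 88 taxa across the seven supergroups."""
    return simulate_species_panel(DEFAULT_PANEL_COUNTS, seed)


# ---------------------------------------------------------------------------
# gene-family simulation


class _GeneLineage:
    __slots__ = ("node", "sp_node", "time", "transfer_ids")

    def __init__(self, node, sp_node, time, transfer_ids):
        self.node = node  # dendropy node whose edge is being extended
        self.sp_node = sp_node  # species node at the END of the current branch
        self.time = time  # current absolute time along the species tree
        self.transfer_ids = transfer_ids  # indices of transfer events above


def _species_times(sp: SpeciesTree) -> dict[dendropy.Node, float]:
    times: dict[dendropy.Node, float] = {}
    for node in sp.tree.preorder_node_iter():
        par = node.parent_node
        t0 = 0.0 if par is None else times[par]
        times[node] = t0 + (node.edge.length or 0.0)
    return times


def simulate_family(
    tree: SpeciesTree, params: EvolParams, seed: int, name: str = "fam"
) -> SimulatedFamily:
    """Run the birth–death–transfer gene process along the species tree.

    The family is gained at the species root with ``params.root_copies``
    copies.  Returns the surviving gene tree (unary nodes suppressed, branch
    lengths in time units), per-tip species assignments, and the full event
    history.  An empty family (all copies lost) is a legal outcome.

    Sequences are placeholders until :func:`evolve_sequences` runs; records
    are created there.
    """
    rng = np.random.default_rng(seed)
    sp_times = _species_times(tree)
    sp_root = tree.tree.seed_node
    events: list[Event] = []
    root_label = tip_label(sp_root) or "root"
    events.append(Event("gain", root_label, 0.0))

    # Branches alive at time t: species nodes whose edge interval contains t.
    branch_nodes = [n for n in tree.tree.preorder_node_iter() if n.parent_node is not None]

    def alive_at(t: float, exclude) -> list[dendropy.Node]:
        out = []
        for n in branch_nodes:
            t1 = sp_times[n]
            t0 = sp_times[n.parent_node]
            if t0 <= t < t1 and n is not exclude:
                out.append(n)
        return out

    gene_root = dendropy.Node()
    gene_root.age_time = 0.0
    tip_counter: dict[str, int] = {}
    tip_map: dict[str, str] = {}
    tns = dendropy.TaxonNamespace()
    transfer_tipsets: dict[int, list[str]] = {}

    stack: list[_GeneLineage] = []

    def spawn(parent_node, sp_node, t):
        child = dendropy.Node()
        child.start_time = t
        parent_node.add_child(child)
        return child

    # seed copies: each root copy descends into the species root's children
    def start_copy(parent_gene_node):
        for sp_child in sp_root.child_nodes():
            child = spawn(parent_gene_node, sp_child, 0.0)
            stack.append(_GeneLineage(child, sp_child, 0.0, ()))
        parent_gene_node.kind = "speciation"

    if params.root_copies == 1:
        start_copy(gene_root)
    else:
        gene_root.kind = "duplication"
        for _ in range(params.root_copies):
            copy_node = spawn(gene_root, sp_root, 0.0)
            copy_node.kind = "speciation"
            start_copy(copy_node)

    total_rate = params.dup_rate + params.loss_rate + params.transfer_rate
    while stack:
        lin = stack.pop()
        node, sp_node, t = lin.node, lin.sp_node, lin.time
        t_end = sp_times[sp_node]
        while True:
            dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if t + dt >= t_end:
                break
            t += dt
            u = rng.uniform(0, total_rate)
            branch_label = tip_label(sp_node)
            if u < params.dup_rate:
                events.append(Event("duplication", branch_label, t))
                node.kind = "duplication"
                node.end_time = t
                left = spawn(node, sp_node, t)
                right = spawn(node, sp_node, t)
                stack.append(_GeneLineage(right, sp_node, t, lin.transfer_ids))
                node, lin = left, _GeneLineage(left, sp_node, t, lin.transfer_ids)
            elif u < params.dup_rate + params.loss_rate:
                events.append(Event("loss", branch_label, t))
                node.kind = "loss"
                node.end_time = t
                node = None
                break
            else:
                recipients = alive_at(t, exclude=sp_node)
                if not recipients:
                    continue  # nowhere to go; transfer aborted silently
                rec = recipients[int(rng.integers(len(recipients)))]
                ev_idx = len(events)
                events.append(
                    Event("transfer", branch_label, t, recipient=tip_label(rec))
                )
                transfer_tipsets[ev_idx] = []
                node.kind = "transfer"
                node.end_time = t
                stay = spawn(node, sp_node, t)
                moved = spawn(node, rec, t)
                stack.append(
                    _GeneLineage(moved, rec, t, lin.transfer_ids + (ev_idx,))
                )
                node, lin = stay, _GeneLineage(stay, sp_node, t, lin.transfer_ids)
        if node is None:
            continue
        node.end_time = t_end
        if sp_node.is_leaf():
            taxon = tip_label(sp_node)
            k = tip_counter.get(taxon, 0) + 1
            tip_counter[taxon] = k
            seq_id = f"{name}|{taxon}|{k}"
            node.taxon = tns.new_taxon(label=seq_id)
            node.kind = "tip"
            tip_map[seq_id] = taxon
            for ti in lin.transfer_ids:
                transfer_tipsets[ti].append(seq_id)
        else:
            node.kind = "speciation"
            for sp_child in sp_node.child_nodes():
                child = spawn(node, sp_child, t_end)
                stack.append(_GeneLineage(child, sp_child, t_end, lin.transfer_ids))

    gene_tree = _prune_gene_tree(gene_root, tns)
    transfer_descendants = [
        transfer_tipsets[i]
        for i, e in enumerate(events)
        if e.kind == "transfer"
    ]
    return SimulatedFamily(
        name=name,
        records=[],
        tip_map=tip_map,
        history=TrueHistory(events),
        gene_tree=gene_tree,
        species_tree=tree,
        transfer_descendants=transfer_descendants,
    )


def _prune_gene_tree(gene_root: dendropy.Node, tns) -> dendropy.Tree | None:
    """Drop extinct subtrees and suppress unary nodes; compute branch lengths
    from node times.  Internal nodes keep their event ``kind``."""

    def survives(node) -> bool:
        if getattr(node, "kind", None) == "tip":
            return True
        return any(survives(c) for c in node.child_nodes())

    def rebuild(node, start_time: float):
        kids = [c for c in node.child_nodes() if survives(c)]
        if getattr(node, "kind", None) == "tip":
            new = dendropy.Node()
            new.taxon = node.taxon
            new.kind = "tip"
            new.edge.length = node.end_time - start_time
            return new
        if len(kids) == 1:
            return rebuild(kids[0], start_time)
        new = dendropy.Node()
        new.kind = node.kind
        t = getattr(node, "end_time", 0.0)
        new.edge.length = t - start_time
        for c in kids:
            new.add_child(rebuild(c, t))
        return new

    if not survives(gene_root):
        return None
    root = rebuild(gene_root, 0.0)
    if root.is_leaf():
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = root
        return tree
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    root.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# sequence evolution


def _random_root_sequence(params: EvolParams, rng) -> tuple[str, np.ndarray]:
    aas = np.array(list(AMINO_ACIDS))
    seq = aas[rng.integers(20, size=params.seq_length)]
    frozen = np.zeros(params.seq_length, dtype=bool)
    for motif, start in params.motifs:
        for k, c in enumerate(motif):
            seq[start + k] = c
            frozen[start + k] = True
    return "".join(seq), frozen


def evolve_sequences(
    family: SimulatedFamily, params: EvolParams, seed: int
) -> SimulatedFamily:
    """Evolve sequences down the true gene tree by uniform 20-letter replacement.

    Substitution events per branch are Poisson with mean
    ``subst_rate * branch_length * n_mutable_sites``; each event rewrites a
    uniformly chosen mutable site with one of the 19 other residues.  Motif
    columns are frozen.  Fills ``family.records`` in place and returns the
    family.
    """
    if family.gene_tree is None:
        family.records = []
        return family
    for motif, start in params.motifs:
        if start < 0 or start + len(motif) > params.seq_length:
            raise ValueError(f"motif {motif!r} at {start} out of range")
    rng = np.random.default_rng(seed)
    root_seq, frozen = _random_root_sequence(params, rng)
    mutable = np.flatnonzero(~frozen)
    aas = AMINO_ACIDS

    seqs: dict[int, str] = {}
    records: list[ProteinRecord] = []
    for node in family.gene_tree.preorder_node_iter():
        if node.parent_node is None:
            seq = root_seq
        else:
            parent_seq = seqs[id(node.parent_node)]
            brlen = node.edge.length or 0.0
            n_events = rng.poisson(params.subst_rate * brlen * len(mutable))
            chars = list(parent_seq)
            for _ in range(n_events):
                site = int(mutable[rng.integers(len(mutable))])
                old = chars[site]
                choices = aas.replace(old, "")
                chars[site] = choices[int(rng.integers(19))]
            seq = "".join(chars)
        seqs[id(node)] = seq
        if node.is_leaf() and node.taxon is not None:
            sid = node.taxon.label
            records.append(ProteinRecord(sid, family.tip_map[sid], seq))
    family.records = records
    return family


# ---------------------------------------------------------------------------
# toy structures


def simulate_structure_pair(
    n_atoms: int,
    rotation: Sequence[float],
    translation: Sequence[float],
    noise_sd: float,
    seed: int,
) -> tuple[CaTrace, CaTrace]:
    """A CA trace and its rigid motion plus isotropic Gaussian noise.

    The base trace is a smooth random chain with 3.8 Å steps (consecutive-CA
    geometry).  The second trace is ``R @ x + t`` with ``R`` from intrinsic
    x-y-z Euler angles (radians), plus N(0, noise_sd^2) on every coordinate.
    """
    if n_atoms < 3:
        raise ValueError("superposition needs >= 3 atoms")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    coords = [np.zeros(3)]
    for _ in range(n_atoms - 1):
        direction = direction + 0.6 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords.append(coords[-1] + 3.8 * direction)
    xyz_a = np.array(coords)
    R = Rotation.from_euler("xyz", list(rotation)).as_matrix()
    xyz_b = xyz_a @ R.T + np.asarray(translation, dtype=float)
    if noise_sd > 0:
        xyz_b = xyz_b + rng.normal(scale=noise_sd, size=xyz_b.shape)
    res_names = ["ALA"] * n_atoms
    numbers = list(range(1, n_atoms + 1))
    return (
        CaTrace("A", res_names, numbers, xyz_a),
        CaTrace("B", list(res_names), list(numbers), xyz_b),
    )
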