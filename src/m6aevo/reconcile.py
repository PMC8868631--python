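"""Gene-tree / species-tree reconciliation and gain–loss inference.

The core is classical LCA reconciliation: each gene-tree internal node maps
to the LCA of its descendants' species; a node is a duplication iff it maps
to the same species node as one of its children, otherwise a speciation.
Orthologue/paralogue/xenologue labels for tip pairs follow from the event
at their gene-tree LCA.  Xenologues (horizontal transfers) are called from
taxonomic misplacement: a supergroup-uniform group of tips nested, with
strong support, inside a clade whose other members all belong to a single
distantly related (non-sister) supergroup.  Family origins and losses come
from Dollo parsimony on the presence/absence matrix, with reported losses
restricted to lineage-specific ones — uniformly absent subtrees whose
sister retains the gene — so that patchy absences caused by e.g. incomplete
genomes are not over-interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .homolog import ProteinRecord
from .synthetic import SpeciesTree
from .trees import SpeciesIndex, node_tipsets, tip_label

ABSENT, PRESENT, XENOLOG_PRESENT = 0, 1, 2


@dataclass
class ReconciliationResult:
    gene_tree: dendropy.Tree
    #: event label ("speciation" | "duplication") per internal node
    node_events: dict[dendropy.Node, str]
    #: species-tree node each gene-tree node maps to
    species_map: dict[dendropy.Node, dendropy.Node]
    tip_map: dict[str, str]

    @property
    def duplication_count(self) -> int:
        return sum(1 for v in self.node_events.values() if v == "duplication")

    @property
    def speciation_count(self) -> int:
        return sum(1 for v in self.node_events.values() if v == "speciation")


@dataclass(frozen=True)
class XenologCall:
    tip: str
    recipient_supergroup: str
    donor_supergroup: str
    support: float


@dataclass
class EventSummary:
    """Per-family evolutionary events inferred from tree + landscape."""

    family: str
    gain_branch: str | None
    losses: list[str] = field(default_factory=list)  # lineage-specific, by branch
    candidate_losses: list[str] = field(default_factory=list)  # all Dollo losses
    duplications: int = 0
    transfers: list[XenologCall] = field(default_factory=list)


def lca_reconcile(
    gene_tree: dendropy.Tree,
    species_tree: SpeciesTree,
    tip_map: Mapping[str, str],
) -> ReconciliationResult:
    """LCA-map a rooted gene tree onto the species tree.

    Raises if any gene tip lacks a species mapping or maps to a taxon not
    on the species tree.
    """
    index = SpeciesIndex(species_tree.tree)
    species_map: dict[dendropy.Node, dendropy.Node] = {}
    node_events: dict[dendropy.Node, str] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = tip_label(node)
            taxon = tip_map.get(label)
            if taxon is None or taxon not in index.node_of:
                raise ValueError(f"gene tip {label!r} has no species mapping")
            species_map[node] = index.node_of[taxon]
        else:
            children = node.child_nodes()
            cur = species_map[children[0]]
            for ch in children[1:]:
                cur = index.lca(cur, species_map[ch])
            species_map[node] = cur
            if any(species_map[ch] is cur for ch in children):
                node_events[node] = "duplication"
            else:
                node_events[node] = "speciation"
    return ReconciliationResult(gene_tree, node_events, species_map, dict(tip_map))


def classify_pairs(
    recon: ReconciliationResult,
    xenolog_tips: Iterable[str] = (),
) -> pd.DataFrame:
    """Classify every tip pair as ortholog / paralog / xenolog.

    The label is paralog if the pair's gene-tree LCA is a duplication node,
    ortholog if a speciation; any pair touching a xenologue-flagged tip is
    a xenolog pair.
    """
    xeno = set(xenolog_tips)
    tree = recon.gene_tree
    tips = [n for n in tree.leaf_node_iter()]
    # ancestor sets for pairwise LCA
    parents: dict[dendropy.Node, dendropy.Node | None] = {}
    depth: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        parents[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1

    def lca(a, b):
        while depth[a] > depth[b]:
            a = parents[a]
        while depth[b] > depth[a]:
            b = parents[b]
        while a is not b:
            a, b = parents[a], parents[b]
        return a

    rows = []
    for i, t1 in enumerate(tips):
        for t2 in tips[i + 1 :]:
            l1, l2 = tip_label(t1), tip_label(t2)
            if l1 in xeno or l2 in xeno:
                relation = "xenolog"
            else:
                anc = lca(t1, t2)
                relation = (
                    "paralog"
                    if recon.node_events.get(anc) == "duplication"
                    else "ortholog"
                )
            rows.append({"tip1": l1, "tip2": l2, "relation": relation})
    return pd.DataFrame(rows, columns=["tip1", "tip2", "relation"])


def _node_support(node: dendropy.Node) -> float | None:
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def detect_xenologs(
    gene_tree: dendropy.Tree,
    species_tree: SpeciesTree,
    tip_map: Mapping[str, str],
    support_threshold: float = 0.8,
) -> list[XenologCall]:
    """Call horizontally transferred tips from taxonomic misplacement.

    For each tip, take the maximal surrounding clade G whose tips all share
    the tip's supergroup, then the smallest ancestor clade C with at least
    3 tips and at least one tip outside G.  The tip is a xenologue iff all
    members of C outside G belong to supergroups different from the tip's,
    C's support is at least ``support_threshold``, and the donor (the
    majority supergroup among those outside members) is distantly related —
    its supergroup clade is not sister to the recipient's on the species
    tree.  With G a single tip this is exactly the "odd tip inside a
    well-supported foreign clade" rule; allowing |G| > 1 covers transfers
    whose descendants speciated after arrival.

    Two further conditions separate transfer from loss artifacts.  The
    outside members of C must all belong to one supergroup (a mixed outside
    context is ordinary deep species-tree structure, not a donor clade).
    And the group must break the foreign context rather than merely sit
    beside it: either the outside members are non-monophyletic, or the
    clade above C adds further donor-supergroup tips, or the group's taxa
    carry extra copies elsewhere in the gene tree.  A native group stranded
    by losses — concordantly sister to an intact foreign clade — satisfies
    none of these and is not called.

    Detection iterates to a fixpoint: called tips are masked out and the
    scan repeats, so two transfers that landed next to each other (each
    polluting the other's context) are peeled one at a time.

    Requires support values on internal nodes (``node.support`` or numeric
    ``node.label``); raises if any internal node lacks one.
    """
    for node in gene_tree.preorder_node_iter():
        if not node.is_leaf() and node.parent_node is not None:
            if _node_support(node) is None:
                raise ValueError("gene tree carries internal nodes without support")
    calls: dict[str, XenologCall] = {}
    while True:
        new = _detect_xenologs_once(
            gene_tree, species_tree, tip_map, support_threshold, set(calls)
        )
        added = [c for c in new if c.tip not in calls]
        if not added:
            break
        for c in added:
            calls[c.tip] = c
    return sorted(calls.values(), key=lambda c: c.tip)


def _detect_xenologs_once(
    gene_tree: dendropy.Tree,
    species_tree: SpeciesTree,
    tip_map: Mapping[str, str],
    support_threshold: float,
    masked: set[str],
) -> list[XenologCall]:
    """One scan of the misplacement rule, ignoring ``masked`` tips."""
    sg_of_taxon = species_tree.supergroup_of
    clade_parents = species_tree.supergroup_clade_parents()
    raw_tipsets = node_tipsets(gene_tree)
    tipsets = {
        node: frozenset(t for t in s if t not in masked)
        for node, s in raw_tipsets.items()
    }
    all_clades = set(tipsets.values())
    calls: list[XenologCall] = []
    for tip_node in gene_tree.leaf_node_iter():
        label = tip_label(tip_node)
        if label in masked:
            continue
        sg = sg_of_taxon[tip_map[label]]
        # maximal same-supergroup surrounding clade G
        g_node = tip_node
        while g_node.parent_node is not None:
            parent = g_node.parent_node
            parent_sgs = {sg_of_taxon[tip_map[t]] for t in tipsets[parent]}
            if parent_sgs == {sg}:
                g_node = parent
            else:
                break
        group = tipsets[g_node]
        # smallest enclosing clade C with >= 3 tips and an outside member
        c_node = g_node.parent_node
        while c_node is not None and (
            len(tipsets[c_node]) < 3 or tipsets[c_node] == group
        ):
            c_node = c_node.parent_node
        if c_node is None:
            continue
        others = tipsets[c_node] - group
        other_sgs = [sg_of_taxon[tip_map[t]] for t in sorted(others)]
        if sg in other_sgs:
            continue
        if len(set(other_sgs)) != 1:
            # a multi-supergroup context is ordinary deep species-tree
            # structure, not a donor clade the tip is nested in
            continue
        support = _node_support(c_node) if c_node.parent_node is not None else 1.0
        if support is None:
            raise ValueError("internal node without support value")
        if support < support_threshold:
            continue
        donor = other_sgs[0]
        if donor == sg:
            continue
        # distantly related = supergroup clades are not sisters
        if clade_parents.get(donor) is not None and clade_parents.get(
            donor
        ) is clade_parents.get(sg):
            continue
        # the group must break the foreign context, not just be sister to it:
        # (a) the outside members are non-monophyletic (G sits inside them),
        # (b) the clade above C adds further donor tips (nested in a larger
        #     donor clade), or (c) G's taxa have extra copies elsewhere in
        #     the gene tree (a displaced second copy).  A native group
        # stranded by losses satisfies none of these.
        others_monophyletic = frozenset(others) in all_clades
        c_tips = tipsets[c_node]
        parent_adds_donor = parent_adds_own = False
        if c_node.parent_node is not None:
            added = tipsets[c_node.parent_node] - c_tips
            # purely donor-supergroup context above C = nested inside a
            # larger donor clade; a mixed addition is just deeper structure
            parent_adds_donor = bool(added) and all(
                sg_of_taxon[tip_map[t]] == donor for t in added
            )
            # reconnecting purely with its own supergroup just above C means
            # the group is in place (e.g. the donor-side copy of a transfer)
            parent_adds_own = bool(added) and all(
                sg_of_taxon[tip_map[t]] == sg for t in added
            )
        g_taxa = {tip_map[t] for t in group}
        o_taxa = {tip_map[t] for t in others}
        outside_taxa = {tip_map[t] for t in tipsets[gene_tree.seed_node] - c_tips}
        # asymmetric extra copies: G's taxa recur elsewhere while the
        # context's taxa do not — a displaced duplicate, not a deep
        # paralogous block (where both sides recur)
        g_copies_outside = (
            bool(g_taxa & outside_taxa)
            and not (o_taxa & outside_taxa)
            and not parent_adds_own
        )
        if others_monophyletic and not parent_adds_donor and not g_copies_outside:
            continue
        calls.append(XenologCall(label, sg, donor, support))
    return calls


def build_presence_absence(
    retained: Mapping[str, Sequence[ProteinRecord]],
    species_tree: SpeciesTree,
    xenolog_taxa: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Taxa × families landscape matrix (0 absent, 1 present, 2 xenolog-present).

    Rows follow the species-tree tip order; a cell is present iff at least
    one retained record of that family belongs to the taxon, and
    xenolog-present where the family's xenologue calls flag the taxon.
    """
    taxa = species_tree.taxa
    taxon_set = set(taxa)
    xenolog_taxa = xenolog_taxa or {}
    data = {}
    for family, records in retained.items():
        col = {t: ABSENT for t in taxa}
        for rec in records:
            if rec.species not in taxon_set:
                raise ValueError(
                    f"record {rec.id!r} has unknown taxon {rec.species!r}"
                )
            col[rec.species] = PRESENT
        for t in xenolog_taxa.get(family, ()):
            if col.get(t) == PRESENT:
                col[t] = XENOLOG_PRESENT
        data[family] = [col[t] for t in taxa]
    return pd.DataFrame(data, index=taxa, columns=list(retained.keys()))


def infer_gains_losses(
    pam: pd.DataFrame,
    species_tree: SpeciesTree,
    max_loss_internal_nodes: int = 1,
) -> dict[str, EventSummary]:
    """Dollo gain and lineage-specific losses per family.

    The gain is the single Dollo origin: the MRCA of all natively present
    tips (xenolog-present cells are excluded, so one transferred copy does
    not drag the family's origin towards the root).  Candidate losses are
    the maximal uniformly-absent subtrees under the gain node; reported
    losses are those whose subtree contains at most
    ``max_loss_internal_nodes`` internal nodes (terminal branches and small
    absent clades), i.e. confined lineage-specific absences whose sister
    retains the gene.
    """
    tree_taxa = set(species_tree.taxa)
    if set(pam.index) != tree_taxa:
        raise ValueError("matrix taxa do not match species tree tips")
    index = SpeciesIndex(species_tree.tree)
    tipsets = index.tipsets
    out: dict[str, EventSummary] = {}
    for family in pam.columns:
        col = pam[family]
        native = {t for t in pam.index if col[t] == PRESENT}
        if not native:
            out[family] = EventSummary(family, None)
            continue
        gain_node = index.lca_of(sorted(native))
        gain_label = tip_label(gain_node) or "root"

        candidate: list[dendropy.Node] = []

        def collect(node):
            below = tipsets[node]
            if not (below & native):
                candidate.append(node)  # maximal absent subtree
                return
            for ch in node.child_nodes():
                collect(ch)

        for ch in gain_node.child_nodes():
            collect(ch)

        def n_internal(node) -> int:
            return sum(
                1
                for d in node.preorder_iter()
                if not d.is_leaf()
            )

        candidate_labels = sorted(_branch_label(n) for n in candidate)
        reported = sorted(
            _branch_label(n)
            for n in candidate
            if n_internal(n) <= max_loss_internal_nodes
        )
        out[family] = EventSummary(
            family,
            gain_branch=gain_label,
            losses=reported,
            candidate_losses=candidate_labels,
        )
    return out


def _branch_label(node: dendropy.Node) -> str:
    return tip_label(node)


def landscape_to_tsv(pam: pd.DataFrame, path) -> None:
    pam.to_csv(path, sep="\t", index_label="taxon")


def events_to_tsv(summaries: Mapping[str, EventSummary], path) -> None:
    rows = []
    for fam, s in summaries.items():
        rows.append(
            {
                "family": fam,
                "gain_branch": s.gain_branch or "",
                "losses": ",".join(s.losses),
                "candidate_losses": ",".join(s.candidate_losses),
                "duplications": s.duplications,
                "transfers": ",".join(c.tip for c in s.transfers),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
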