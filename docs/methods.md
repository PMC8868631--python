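# Methods

This note records the models, rules and numerical choices behind `m6aevo`,
and what the synthetic benchmarks do and do not establish.

## Synthetic evolution (the ground-truth generator)

**Species panels.** `simulate_species_panel` draws a rooted binary tree in
which each supergroup is a clade: tips are joined in random order within
each supergroup, then the supergroup clades are joined in random order.
Node depths are drawn uniformly between the parent's depth and the tips,
the root at depth 0 and all tips at depth 1, so the tree is ultrametric
with height 1 in expected substitutions per site. Ultrametricity is not
cosmetic: transfer events need a notion of *contemporaneous* branches, and
absolute node times provide it. The bundled default panel has 88 taxa —
17 Bacteria, 6 Archaea, 7 Discoba, 2 Metamonada, 14 SAR, 6 Archaeplastida
and 36 Amorphea. The published species topology for such panels lives in
supplementary material we do not reproduce; the simulator ships a
configurable random stand-in rather than asserting any particular topology.

**Gene families.** A family is gained at the species root (`root_copies`
copies, default 1). Each gene lineage travelling along a species branch
experiences duplication, loss and transfer as independent Poisson
processes with rates per unit branch length (`dup_rate`, `loss_rate`,
`transfer_rate`). A duplication forks the lineage in place; a loss ends
it; a transfer copies it onto a recipient branch chosen uniformly among
the branches whose time interval contains the event time (additive
transfer — the donor keeps its copy). Waiting times are exponential. The
true gene tree is pruned of extinct subtrees, unary nodes are collapsed,
and every surviving internal node remembers its event kind; the event list
(TrueHistory) records kind, species branch (identified by the branch's
child node label), time, and, for transfers, the recipient branch plus the
descendant tips of the moved copy. Bookkeeping invariant, asserted in
tests: the copy number at any tip equals root copies + duplications +
incoming transfers − losses along its root path.

**Sequences.** Sequences evolve down the true gene tree under uniform
20-letter replacement: per branch the number of events is Poisson with
mean `subst_rate × branch length × mutable sites`, each event rewriting a
uniformly chosen site with one of the 19 other residues. This model is
deliberately exchangeability-free because it has a closed form used as an
oracle: two sequences separated by path length *t* differ at an expected
proportion `p(t) = (19/20)(1 − e^{−(20/19)t})` of sites. Motif inserts
(literal strings at fixed 0-based positions) are frozen columns. No indels
are simulated, so same-family sequences are natively aligned; the
progressive aligner is exercised on its own fixtures.

**Default study conditions.** The benchmark simulations use a 16-tip panel
(4 supergroups × 4 taxa), 200 families, duplication and loss rates 0.1,
transfer rate 0.05 per unit branch length, substitution rate 0.3 and
sequence length 300 (a typical catalytic-domain span). Tree height 1 makes
rates directly interpretable as expected events per root-to-tip path.

**Toy structures.** `simulate_structure_pair` builds a smoothed random
chain with 3.8 Å steps (consecutive-CA geometry) and returns it together
with a rigid motion of itself plus isotropic Gaussian coordinate noise.
With per-coordinate noise σ the post-fit RMSD concentrates near `σ√3`
(three noisy coordinates per atom; the 6 fitted degrees of freedom are
negligible at n = 500), which the tests verify.

## Homologue screening

Local alignment is Smith–Waterman with affine gaps (a gap of length k
costs `open + k·extend`; defaults 11/1 under BLOSUM62), delegated to
Biopython's PairwiseAligner; the test suite checks it against a naive
dynamic-programming implementation written independently. E-values use the
Karlin–Altschul form `E = K·m·n·e^{−λS}` with K = 0.041 and λ = 0.267
supplied by configuration — the screen is a deterministic desk-scale
stand-in for an iterative profile search, which is out of scope (a single
pass gives the same testable contract). Redundancy clustering is greedy
and longest-first (ties by id), identity counted as matches over the
shorter sequence, mirroring the convention of standard clustering tools at
a 0.98 cutoff; clustering is applied within each species' pooled hits.
The domain filter retains a record only if every required motif pattern
for its family matches, with an explicit bypass set for families whose
diagnostic domain is genuinely absent in some lineages.

## Alignment and trimming

`build_msa` is classical progressive alignment: UPGMA guide tree on
pairwise global-alignment distances (1 − identity), then profile–profile
global alignment with affine gaps (Gotoh), profile columns scored by
expected substitution score between column frequency vectors. Traceback
ties prefer match, then a gap in the second profile — the output is a pure
function of the input order. End gaps are penalized like internal ones.
No conserved-domain anchoring or iterative refinement is attempted.

`trim_columns` keeps a column iff (non-gap letters / rows) ≥ 0.30 **and**
(conserved letter pairs / all letter pairs) ≥ 0.10. "Conserved" defaults
to *identical*, the strictest defensible reading; a matrix-positive
alternative is a config switch because the source rule does not define the
word. Both thresholds compare with ≥ ("at least"). A column with fewer
than two letters has no pairs and is removed. X counts as a letter for
the gap criterion but never certifies a conserved pair. The operation is
idempotent and monotone in both thresholds; tests check exact agreement
with a brute-force pair-enumeration oracle.

## Gene trees

Distances are Poisson-corrected, `d = −ln(1 − p)`; `p ≥ 1` is an error in
the scalar operation, while the alignment-matrix builder caps `p` at 0.99
so a single saturated pair does not abort a whole family. Neighbor
joining breaks Q-matrix ties by the lexicographically smallest pair of
cluster representatives (the smallest tip label in each cluster), making
the agglomeration platform-independent; negative branch lengths are
clamped to zero with the deficit moved to the sister edge. On additive
matrices NJ provably returns the generating topology and branch lengths,
which the tests assert to 1e-9 — this guarantee is why a full
maximum-likelihood search with model selection was not reimplemented: the
downstream reconciliation needs only a supported topology. Bootstrap
support is the fraction of column-resampled NJ trees containing each
original bipartition. Midpoint rooting re-identifies supports after
rerooting by canonical bipartition lookup, since node-attached labels do
not survive the edge remapping; splits created by the rooting itself are
trivial and take support 1.

## Reconciliation

LCA mapping is standard: a gene node maps to the LCA of its children's
images; it is a duplication iff it shares its image with a child. Under
pure duplication–loss this recovers every surviving duplication node
except the provably unidentifiable case of a duplication followed by
complementary losses (which mimics a speciation); transfers additionally
create *apparent* duplications around the insertion point, which is
expected behaviour of LCA mapping, not an error.

**Xenologue detection** operationalises "a gene in one species derived
from a distantly related species" as taxonomic misplacement: for a tip,
let G be the maximal surrounding clade of its own supergroup and C the
smallest ancestor clade with ≥ 3 tips and a member outside G. The tip is
called iff the outside members of C all belong to one supergroup different
from the tip's, C's support is at least the threshold (default 0.8 — the
source states no value; this is configuration, not doctrine), and donor
and recipient supergroup clades are not sisters on the species tree
("distantly related"; the weakest rule covering inter-kingdom cases).
Three further guards separate transfer from loss artifacts, all motivated
by what loss alone can and cannot produce:

1. a native group stranded by losses sits concordantly *sister* to an
   intact foreign clade — so the call additionally requires that the
   foreign context is broken: the outside members are non-monophyletic,
   **or** the clade above C adds purely donor-supergroup tips (nesting
   inside a larger donor clade), **or** the group's taxa recur elsewhere
   in the tree while the context's taxa do not (a displaced extra copy,
   asymmetric where deep paralogous blocks are symmetric);
2. a multi-supergroup outside context is ordinary deep species-tree
   structure and never counts as a donor clade;
3. detection iterates to a fixpoint with called tips masked, so two
   transfers that landed next to each other are peeled one at a time.

Measured on nine independent panels × 200 families at the default rates,
this rule recovers 95–100% of detectable between-supergroup transfer
recipients with zero false positives. Three classes are undetectable in
principle from placement and are excluded from "detectable": transfers to
branches ancestral to several supergroups (the moved block reconstitutes
an internally concordant subtree), round-trip chains whose descendants
reside where their lineage originated, and pairs of co-localized transfers
that mask each other symmetrically (the one class the fixpoint iteration
does not always resolve — a known limitation).

**Gains and losses** follow Dollo parsimony on the presence/absence
matrix: the gain is the MRCA of natively present tips; xenolog-present
cells are excluded so a transferred copy does not drag a family's origin
rootward. Candidate losses are the maximal uniformly absent subtrees under
the gain node; *reported* losses are restricted to lineage-specific ones —
subtrees with at most one internal node (terminal branches and cherries)
by default, configurable — because broader absences may reflect genome
quality rather than genuine loss. Reported losses are always a subset of
the Dollo candidates; both lists are emitted.

## Motif classification

Patterns are position-wise residue sets (`[DNSH]PP[WFY]`) plus literal
variants of equal length (EPPV for bacterial Dam; NIPY/NLPY for the rRNA
dimethyltransferase lineage); matching is exact, not probabilistic,
because the classification rules reason with literal four-residue
consensus strings. The AdoMet-binding motif I has no published consensus
in this context; the default glycine-rich `[AG]x[AG]x[AG]` exists so the
class-order rule (α: I before IV; β: IV before I) runs out of the box and
is config-overridable. Group assignment from motif IV is NPPF/NPPY → I,
NIPY/NLPY → II, and NPPF with a PCIF1 family hint → III; Groups I and III
share NPPF and are distinguished partly by function, so the hint is
unavoidable for a sequence-only classifier. ALKB-site spacing windows
(HxD then a distal H 10–80 residues on; N–Y–R–R with gaps ≤ 60/60/30) are
family-dependent figure-derived configuration, not claims. The aromatic
cage check accepts F/W/Y plus L by default because one cage position is
aliphatic in some prokaryotic homologues; the set is configurable.

## Structure superposition

Residue correspondence comes from a global alignment of the chains'
one-letter sequences (non-gap columns only). The optimal rotation is the
Kabsch SVD solution with the determinant-sign correction, so reflections
are never returned; tests assert orthonormality and det +1 to 1e-9 and
cross-check the rotation against SciPy's independent alignment solver. Refinement
rejects pairs deviating more than `reject_sigma` (default 2.0) times the
current RMS deviation and refits, up to `max_cycles` (default 5) — both
configurable since the published workflow states neither; rejection is
monotone non-increasing in RMSD and stops at numerical convergence
(RMS < 1e-8 Å). Only CA atoms are used; altloc duplicates keep the first
occurrence. Comparisons against the published YTH-fold RMSD values
(4.45/3.97 Å and 3.90/3.29 Å, and 2.96 Å for the Dam–RlmJ pair) require
the PDB coordinate files as user-supplied inputs; because the published
numbers do not say which human YTH partner produced which value, the
comparison uses the larger/smaller of each pair.

## What the benchmarks do and do not show

The synthetic generator gives exact ground truth, but real data differ in
ways the suite deliberately does not model: no indels (so the aligner is
never stressed by the screen), no rate heterogeneity across sites or
lineages, no compositional bias, uniform replacement rather than an
empirical exchangeability matrix, no genome-quality artifacts behind
absences, and species trees that are random stand-ins rather than the
published topology. Passing the suite demonstrates the *algorithms* are
implemented correctly and that the inference chain is consistent under its
own model — not that the biological conclusions of any particular study
follow from real sequence data.

## Problem sizes

The benchmark suite runs 200 families on 16 taxa for event recovery, 500
random alignments for the trimming oracle, 100 random additive matrices
for NJ, 100 bootstrap replicates on a 2000-column quartet alignment, and
20 replicates of 500-atom structure pairs — sizes chosen to give stable
percentages while keeping a full run on one CPU within a few seconds.
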