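"""Homologue screening: local alignment, E-values, redundancy clustering, domain filtering.

This module is the desk-scale counterpart of a similarity search against a
protein database: candidate homologues of a query set are collected by
optimal local alignment under an affine-gap scoring scheme, ranked by a
Karlin–Altschul E-value, de-duplicated by greedy identity clustering, and
finally filtered for the catalytic/domain motifs that define each family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a species assignment.

    ``species`` is a taxon identifier matching a tip of the species tree the
    downstream reconciliation uses.
    """

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residues {sorted(bad)} "
                "(allowed: 20 amino acids + X)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap protein scoring with Karlin–Altschul statistics.

    A gap of length ``k`` costs ``gap_open + k * gap_extend`` (BLAST
    convention).  ``ka_k`` and ``ka_lambda`` parameterise the E-value
    formula ``E = K * m * n * exp(-lambda * S)``; they are supplied by
    configuration rather than estimated from data, so the screen is
    deterministic.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_k: float = 0.041
    ka_lambda: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.ka_k <= 0 or self.ka_lambda <= 0:
            raise ValueError("Karlin-Altschul parameters must be > 0")

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)

    def make_aligner(self, mode: str = "local") -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self.matrix
        # Biopython charges open_gap_score for the first gap residue, so the
        # BLAST-style total cost open + k*extend maps to these two numbers.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        aligner.mode = mode
        return aligner


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise alignment hit (1-based inclusive span coordinates)."""

    query: str
    subject: str
    score: float
    evalue: float | None
    pident: float
    qstart: int
    qend: int
    sstart: int
    send: int


HIT_COLUMNS = [
    "query",
    "subject",
    "species",
    "score",
    "evalue",
    "pident",
    "qstart",
    "qend",
    "sstart",
    "send",
]


def local_align(a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme) -> AlignmentHit:
    """Optimal local (Smith–Waterman) alignment of two protein records.

    Returns the best local score under ``scheme``, percent identity over the
    aligned columns and the 1-based inclusive coordinates of the aligned
    spans.  A score of 0 (no positive-scoring pair) yields an empty span.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    aligner = scheme.make_aligner("local")
    alns = aligner.align(a.sequence.upper(), b.sequence.upper())
    score = float(alns.score)
    if score <= 0 or len(alns) == 0:
        return AlignmentHit(a.id, b.id, 0.0, None, 0.0, 0, 0, 0, 0)
    best = alns[0]
    qblocks, sblocks = best.aligned
    matches = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        columns += qe - qs
        for i in range(qe - qs):
            if a.sequence[qs + i].upper() == b.sequence[ss + i].upper():
                matches += 1
    pident = 100.0 * matches / columns if columns else 0.0
    return AlignmentHit(
        query=a.id,
        subject=b.id,
        score=score,
        evalue=None,
        pident=pident,
        qstart=int(qblocks[0][0]) + 1,
        qend=int(qblocks[-1][1]),
        sstart=int(sblocks[0][0]) + 1,
        send=int(sblocks[-1][1]),
    )


def estimate_evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expected number of chance hits: ``K m n exp(-lambda S)``."""
    if score < 0:
        raise ValueError("score must be >= 0")
    if m < 1 or n < 1:
        raise ValueError("sequence/database lengths must be >= 1")
    return float(scheme.ka_k * m * n * np.exp(-scheme.ka_lambda * score))


def screen_homologs(
    queries: Sequence[ProteinRecord],
    database: Sequence[ProteinRecord],
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Screen a database for homologues of the queries.

    Every (query, subject) pair whose local alignment attains an E-value
    below ``e_cutoff`` contributes one row; a subject is a candidate
    homologue if it passes against at least one query.  Rows are pooled by
    species (sorted by species, then E-value) so per-species redundancy
    removal can run downstream.
    """
    if not queries or not database:
        raise ValueError("queries and database must be non-empty")
    scheme = scheme or ScoringScheme()
    db_length = sum(len(r) for r in database)
    rows = []
    for subject in database:
        for query in queries:
            hit = local_align(query, subject, scheme)
            if hit.score <= 0:
                continue
            ev = estimate_evalue(hit.score, len(query), db_length, scheme)
            if ev < e_cutoff:
                rows.append(
                    {
                        "query": query.id,
                        "subject": subject.id,
                        "species": subject.species,
                        "score": hit.score,
                        "evalue": ev,
                        "pident": hit.pident,
                        "qstart": hit.qstart,
                        "qend": hit.qend,
                        "sstart": hit.sstart,
                        "send": hit.send,
                    }
                )
    table = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if not table.empty:
        table = table.sort_values(
            ["species", "evalue", "subject", "query"], kind="mergesort"
        ).reset_index(drop=True)
    return table


def pairwise_identity(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Fraction of identical residues over a global alignment, divided by the
    length of the shorter sequence (the convention of greedy identity
    clustering tools)."""
    scheme = scheme or ScoringScheme()
    aligner = scheme.make_aligner("global")
    alns = aligner.align(a.upper(), b.upper())
    best = alns[0]
    qblocks, sblocks = best.aligned
    matches = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        for i in range(qe - qs):
            if a[qs + i].upper() == b[ss + i].upper():
                matches += 1
    return matches / min(len(a), len(b))


def cluster_redundant(
    records: Sequence[ProteinRecord],
    identity_cutoff: float = 0.98,
    scheme: ScoringScheme | None = None,
) -> list[ProteinRecord]:
    """Greedy longest-first redundancy removal at an identity cutoff.

    Records are visited longest-first (equal lengths broken by id); each one
    either joins an existing representative at identity >= ``identity_cutoff``
    or founds a new cluster.  Returns the representatives in visiting order,
    so the operation is deterministic and idempotent.
    """
    if not records:
        raise ValueError("no records to cluster")
    scheme = scheme or ScoringScheme()
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[ProteinRecord] = []
    for rec in ordered:
        placed = False
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence, scheme) >= identity_cutoff:
                placed = True
                break
        if not placed:
            reps.append(rec)
    return reps


def _pattern_to_regex(pattern: str) -> re.Pattern:
    """Compile a bracket-class motif string such as ``[DNSH]PP[WFY]``."""
    return re.compile(pattern)


def filter_by_domain(
    hits: pd.DataFrame,
    records: Sequence[ProteinRecord],
    required_motifs: Mapping[str, Iterable[str]],
    bypass_families: Iterable[str] = (),
    family_of: Mapping[str, str] | None = None,
) -> list[ProteinRecord]:
    """Retain records whose sequence carries every motif required for its family.

    A record's family defaults to the id of its best (lowest-E-value) query
    in ``hits``; pass ``family_of`` to override.  Families in
    ``bypass_families`` are retained unconditionally — the escape hatch for
    families whose diagnostic domain is genuinely missing in some lineages
    (the ZC3H13 situation).
    """
    bypass = set(bypass_families)
    if family_of is None:
        if hits.empty:
            raise ValueError("no hits to derive family assignments from")
        best = hits.sort_values("evalue", kind="mergesort").drop_duplicates("subject")
        family_of = dict(zip(best["subject"], best["query"]))
    retained = []
    for rec in records:
        fam = family_of.get(rec.id)
        if fam is None:
            continue
        if fam in bypass:
            retained.append(rec)
            continue
        if fam not in required_motifs:
            raise ValueError(
                f"family {fam!r} has neither required motifs nor a bypass entry"
            )
        patterns = [_pattern_to_regex(p) for p in required_motifs[fam]]
        if all(p.search(rec.sequence.upper()) for p in patterns):
            retained.append(rec)
    return retained


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records from FASTA; species parsed from ``id|species|n``
    style ids when present, else taken from the description's second token."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        species = parts[1] if len(parts) >= 2 else (
            rec.description.split()[1] if len(rec.description.split()) > 1 else "unknown"
        )
        records.append(ProteinRecord(rec.id, species, str(rec.seq)))
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
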