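"""Progressive multiple alignment and column trimming.

The aligner is a classical progressive scheme: a UPGMA guide tree from
pairwise global-alignment distances, then profile–profile global alignment
with affine gaps at each internal node.  Trimming applies a two-part
column-retention rule: a column survives only if at least ``min_nongap`` of
its rows are letters AND at least ``min_conserved_pairs`` of its letter
pairs are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy

from .homolog import ProteinRecord, ScoringScheme, pairwise_identity

GAP = "-"


@dataclass
class Alignment:
    """A multiple sequence alignment: ordered ids and equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    def ungapped(self, idx: int) -> str:
        return self.rows[idx].replace(GAP, "")

    def take_columns(self, indices: Sequence[int]) -> "Alignment":
        idx = list(indices)
        return Alignment(
            list(self.ids), ["".join(row[i] for i in idx) for row in self.rows]
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq))
        return cls(ids, rows)


@dataclass
class TrimmedAlignment:
    """An alignment restricted to retained columns of a source alignment.

    ``retained_columns`` are 0-based, strictly increasing indices into the
    source alignment, kept for provenance.
    """

    alignment: Alignment
    retained_columns: list[int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.retained_columns, self.retained_columns[1:])):
            raise ValueError("retained columns must be strictly increasing")
        if len(self.retained_columns) != self.alignment.length:
            raise ValueError("retained column count does not match alignment length")

    @property
    def ids(self) -> list[str]:
        return self.alignment.ids

    @property
    def rows(self) -> list[str]:
        return self.alignment.rows

    def write_columns_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("retained_column\n")
            for c in self.retained_columns:
                fh.write(f"{c}\n")


# ---------------------------------------------------------------------------
# progressive alignment


def _matrix_array(scheme: ScoringScheme) -> tuple[np.ndarray, dict[str, int]]:
    mat = scheme.matrix
    alphabet = str(mat.alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    return np.asarray(mat), index


def _profile(rows: list[str], index: dict[str, int]) -> np.ndarray:
    """Column frequency profile over the scoring alphabet (gaps excluded,
    frequencies normalised by the number of rows so gapped columns are
    down-weighted)."""
    n_alpha = len(index)
    length = len(rows[0])
    prof = np.zeros((length, n_alpha))
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                prof[j, index.get(c.upper(), index.get("X", 0))] += 1.0
    return prof / len(rows)


def _align_profiles(
    rows1: list[str],
    rows2: list[str],
    scheme: ScoringScheme,
    mat: np.ndarray,
    index: dict[str, int],
) -> tuple[list[str], list[str]]:
    """Global affine-gap (Gotoh) alignment of two alignment profiles.

    Match scores are expected substitution scores between column profiles.
    Ties in the traceback prefer match, then a gap in the second profile;
    this makes the result independent of hash ordering.
    """
    p1 = _profile(rows1, index)
    p2 = _profile(rows2, index)
    L1, L2 = p1.shape[0], p2.shape[0]
    S = p1 @ mat @ p2.T  # (L1, L2) expected column-pair scores

    go = -(scheme.gap_open + scheme.gap_extend)
    ge = -scheme.gap_extend
    NEG = -1e30
    M = np.full((L1 + 1, L2 + 1), NEG)
    X = np.full((L1 + 1, L2 + 1), NEG)  # gap in rows2 (consume rows1)
    Y = np.full((L1 + 1, L2 + 1), NEG)  # gap in rows1 (consume rows2)
    M[0, 0] = 0.0
    for i in range(1, L1 + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, L2 + 1):
        Y[0, j] = go + ge * (j - 1)
    for i in range(1, L1 + 1):
        Si = S[i - 1]
        for j in range(1, L2 + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + Si[j - 1]
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
    # traceback
    i, j = L1, L2
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    path: list[int] = []
    while i > 0 or j > 0:
        path.append(state)
        if state == 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:
            opts = [M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go]
            state = int(np.argmax(opts))
            i -= 1
        else:
            opts = [M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge]
            state = int(np.argmax(opts))
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    path.reverse()
    out1 = [[] for _ in rows1]
    out2 = [[] for _ in rows2]
    i = j = 0
    for state in path:
        if state == 0:
            for k, row in enumerate(rows1):
                out1[k].append(row[i])
            for k, row in enumerate(rows2):
                out2[k].append(row[j])
            i += 1
            j += 1
        elif state == 1:
            for k, row in enumerate(rows1):
                out1[k].append(row[i])
            for k in range(len(rows2)):
                out2[k].append(GAP)
            i += 1
        else:
            for k in range(len(rows1)):
                out1[k].append(GAP)
            for k, row in enumerate(rows2):
                out2[k].append(row[j])
            j += 1
    return ["".join(r) for r in out1], ["".join(r) for r in out2]


def build_msa(records: Sequence[ProteinRecord], scheme: ScoringScheme | None = None) -> Alignment:
    """Progressive multiple alignment of protein records.

    Guide tree: UPGMA on pairwise distances ``1 - identity`` from global
    alignments.  Merge order follows the guide tree bottom-up; each merge is
    a profile–profile Gotoh alignment.  Deterministic for a fixed input
    order of equal-distance records (scipy's linkage tie-breaking is itself
    deterministic).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to align")
    scheme = scheme or ScoringScheme()
    mat, index = _matrix_array(scheme)
    n = len(records)
    if n == 2:
        r1, r2 = _align_profiles(
            [records[0].sequence], [records[1].sequence], scheme, mat, index
        )
        return Alignment([records[0].id, records[1].id], [r1[0], r2[0]])

    dists = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(records[i].sequence, records[j].sequence, scheme)
            dists[i, j] = dists[j, i] = d
    condensed = dists[np.triu_indices(n, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([records[i].id], [records[i].sequence]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(linkage):
        ids1, rows1 = clusters.pop(int(a))
        ids2, rows2 = clusters.pop(int(b))
        new1, new2 = _align_profiles(rows1, rows2, scheme, mat, index)
        clusters[n + step] = (ids1 + ids2, new1 + new2)
    ids, rows = clusters.popitem()[1]
    order = {rec.id: k for k, rec in enumerate(records)}
    paired = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    return Alignment([p[0] for p in paired], [p[1] for p in paired])


# ---------------------------------------------------------------------------
# trimming


def _column_passes(
    column: str,
    min_nongap: float,
    min_conserved_pairs: float,
    conserved: str,
    mat: np.ndarray | None,
    index: dict[str, int] | None,
) -> bool:
    n = len(column)
    letters = [c for c in column if c != GAP]
    if len(letters) / n < min_nongap:
        return False
    k = len(letters)
    if k < 2:
        return False  # fewer than two letters: no pairs, fails by convention
    total_pairs = k * (k - 1) // 2
    conserved_pairs = 0
    for i in range(k):
        for j in range(i + 1, k):
            a, b = letters[i].upper(), letters[j].upper()
            if a == "X" or b == "X":
                continue  # unknown residues never certify conservation
            if conserved == "identity":
                if a == b:
                    conserved_pairs += 1
            else:  # matrix-positive
                if mat[index[a], index[b]] > 0:
                    conserved_pairs += 1
    return conserved_pairs / total_pairs >= min_conserved_pairs


def trim_columns(
    aln: Alignment,
    min_nongap: float = 0.30,
    min_conserved_pairs: float = 0.10,
    conserved: str = "identity",
    scheme: ScoringScheme | None = None,
) -> TrimmedAlignment:
    """Trim alignment columns by the dual retention rule.

    A column is kept iff its non-gap fraction is at least ``min_nongap``
    (default 30%) and the fraction of conserved letter pairs among all
    letter pairs in the column is at least ``min_conserved_pairs`` (default
    10%).  ``conserved`` is ``"identity"`` (default: a pair is conserved iff
    the two residues are identical and neither is X) or ``"positive"``
    (substitution-matrix score > 0).  Columns with fewer than two letters
    have no pairs and are removed.
    """
    if aln.n < 2:
        raise ValueError("trimming requires >= 2 rows")
    if conserved not in ("identity", "positive"):
        raise ValueError("conserved must be 'identity' or 'positive'")
    mat = index = None
    if conserved == "positive":
        mat, index = _matrix_array(scheme or ScoringScheme())
    kept = [
        i
        for i in range(aln.length)
        if _column_passes(
            aln.column(i), min_nongap, min_conserved_pairs, conserved, mat, index
        )
    ]
    return TrimmedAlignment(aln.take_columns(kept), kept)
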