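"""CA-trace superposition: PDB parsing, Kabsch fitting with outlier
rejection, and pairwise RMSD matrices.

Residue correspondence between two chains comes from a global alignment of
their one-letter sequences; the optimal least-squares rotation is then the
Kabsch solution (SVD with a determinant correction that forbids
reflections), refined by cycles that reject pairs deviating more than
``reject_sigma`` times the current RMS deviation and refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .homolog import ScoringScheme

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class CaTrace:
    """Ordered CA coordinates of one chain."""

    chain_id: str
    res_names: list[str]
    res_numbers: list[int]
    coords: np.ndarray  # (n, 3) in Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.coords) < 3:
            raise ValueError("a CA trace needs >= 3 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def sequence(self) -> str:
        return "".join(_THREE_TO_ONE.get(r.upper(), "X") for r in self.res_names)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CaTrace":
        return CaTrace(
            self.chain_id,
            list(self.res_names),
            list(self.res_numbers),
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
        )

    def to_pdb(self) -> str:
        lines = []
        for i, (name, num, (x, y, z)) in enumerate(
            zip(self.res_names, self.res_numbers, self.coords), start=1
        ):
            lines.append(
                f"ATOM  {i:5d}  CA  {name:>3s} {self.chain_id}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3,3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å over retained pairs
    n_pairs: int  # pairs retained after rejection
    cycles: int  # rejection cycles actually run
    rmsd_history: list[float] = None  # RMSD after each fit, initial first


def parse_structure(pdb_text: str, chain: str) -> CaTrace:
    """Extract the CA trace of one chain from PDB-format text.

    Altloc duplicates keep the first occurrence; residue names and author
    numbering are preserved in file order.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    model = structure[0]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise ValueError(f"chain {chain!r} not found")
    names, numbers, coords = [], [], []
    for residue in target:
        for atom in residue:
            if atom.name == "CA":
                names.append(residue.name)
                numbers.append(residue.seqid.num)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                break  # first altloc only
    if len(coords) < 3:
        raise ValueError(f"chain {chain!r} has fewer than 3 CA atoms")
    return CaTrace(chain, names, numbers, np.array(coords))


def kabsch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit mapping points ``a`` onto ``b``.

    Returns ``(R, t, rmsd)`` with ``R @ a_i + t ≈ b_i``; ``R`` is a proper
    rotation (reflections are excluded via the determinant sign correction).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    P, Q = a - ca, b - cb
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (a @ R.T + t) - b
    rmsd = float(np.sqrt((diff**2).sum() / len(a)))
    return R, t, rmsd


def _correspondence(a: CaTrace, b: CaTrace, scheme: ScoringScheme) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs of corresponding residues from a global sequence alignment."""
    aligner = scheme.make_aligner("global")
    alns = aligner.align(a.sequence, b.sequence)
    best = alns[0]
    ia, ib = [], []
    for (qs, qe), (ss, se) in zip(*best.aligned):
        ia.extend(range(qs, qe))
        ib.extend(range(ss, se))
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def superpose(
    a: CaTrace,
    b: CaTrace,
    scheme: ScoringScheme | None = None,
    max_cycles: int = 5,
    reject_sigma: float = 2.0,
) -> SuperpositionResult:
    """Superpose two CA traces with iterative outlier rejection.

    Correspondence comes from global sequence alignment (non-gap columns
    only); each cycle refits on the retained pairs and drops pairs whose
    deviation exceeds ``reject_sigma`` times the current RMS deviation.
    Stops when no pair is rejected or ``max_cycles`` is reached.  Raises if
    fewer than 3 pairs remain at any stage.
    """
    scheme = scheme or ScoringScheme()
    ia, ib = _correspondence(a, b, scheme)
    if len(ia) < 3:
        raise ValueError("fewer than 3 corresponding residue pairs")
    keep = np.ones(len(ia), dtype=bool)
    cycles = 0
    R, t, rmsd = kabsch(a.coords[ia], b.coords[ib])
    history = [float(rmsd)]
    for _ in range(max_cycles):
        dev = np.linalg.norm(
            (a.coords[ia[keep]] @ R.T + t) - b.coords[ib[keep]], axis=1
        )
        scale = np.sqrt((dev**2).mean())  # RMS deviation of retained pairs
        if scale < 1e-8:  # already at numerical convergence; nothing to reject
            break
        bad = dev > reject_sigma * scale
        if not bad.any():
            break
        new_keep = keep.copy()
        new_keep[np.flatnonzero(keep)[bad]] = False
        if new_keep.sum() < 3:
            raise ValueError("outlier rejection left fewer than 3 pairs")
        keep = new_keep
        cycles += 1
        R, t, rmsd = kabsch(a.coords[ia[keep]], b.coords[ib[keep]])
        history.append(float(rmsd))
    return SuperpositionResult(R, t, float(rmsd), int(keep.sum()), cycles, history)


def rmsd_matrix(
    traces: list[CaTrace],
    scheme: ScoringScheme | None = None,
    max_cycles: int = 5,
    reject_sigma: float = 2.0,
) -> np.ndarray:
    """All-against-all superposition RMSDs (symmetric, zero diagonal)."""
    if len(traces) < 2:
        raise ValueError("need >= 2 traces")
    n = len(traces)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = superpose(traces[i], traces[j], scheme, max_cycles, reject_sigma)
            out[i, j] = out[j, i] = res.rmsd
    return out
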