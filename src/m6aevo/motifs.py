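"""Catalytic-motif detection and classification.

Three signature systems are covered, each used as evolutionary evidence in
the analysis of RNA N6-adenosine modification machinery:

* Rossmann-fold MTase motifs — the catalytic motif IV consensus
  ``[DNSH]PP[WFY]`` with family variants (``EPPV`` of bacterial Dam,
  ``NIPY``/``NLPY`` of the rRNA dimethyltransferase lineage), the
  glycine-rich AdoMet-binding motif I, the class call (α: motif order I→IV;
  β: IV→I) and the Group I/II/III assignment of motif IV variants.
* ALKB-family dioxygenase sites — the HxD…H iron-binding triad and the
  N…Y…R…R α-ketoglutarate pocket, matched with configurable spacing
  windows (spacings vary by family and are configuration, not doctrine).
* The YTH/McrB-N aromatic cage — three alignment columns that must hold
  bulky hydrophobics for the domain to grip a methylated base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .msa import GAP, Alignment

_CLASS_RE = re.compile(r"\[([A-Z]+)\]|([A-Z])")


@dataclass
class MotifPattern:
    """A position-wise residue-set pattern plus literal variants.

    ``positions`` holds one allowed-residue set per position (parsed from
    strings like ``[DNSH]PP[WFY]``); ``variants`` are whole literal strings
    of the same length that also count as matches (e.g. ``EPPV``).
    """

    name: str
    positions: list[frozenset[str]]
    variants: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("pattern needs at least one position")
        k = len(self.positions)
        for v in self.variants:
            if len(v) != k:
                raise ValueError(f"variant {v!r} length != pattern length {k}")

    @classmethod
    def from_string(cls, name: str, pattern: str, variants: Iterable[str] = ()) -> "MotifPattern":
        any_residue = frozenset("ACDEFGHIKLMNPQRSTVWYX")
        positions = []
        for grp, single in _CLASS_RE.findall(pattern.upper()):
            allowed = frozenset(grp) if grp else frozenset(single)
            # X denotes "any residue" in the pattern mini-language
            positions.append(any_residue if "X" in allowed else allowed)
        return cls(name, positions, list(variants))

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, seq: str, i: int) -> str | None:
        """Matched substring if the pattern or a variant matches at 0-based ``i``."""
        k = len(self.positions)
        window = seq[i : i + k].upper()
        if len(window) < k:
            return None
        if all(c in allowed for c, allowed in zip(window, self.positions)):
            return window
        if window in (v.upper() for v in self.variants):
            return window
        return None


@dataclass(frozen=True)
class MotifHit:
    pattern: str
    variant: str
    start: int  # 1-based
    match: str


def scan_motif(seq: str, pattern: MotifPattern) -> list[MotifHit]:
    """All non-overlapping matches of a pattern (or its variants), left to right."""
    if not seq:
        raise ValueError("empty sequence")
    hits: list[MotifHit] = []
    i = 0
    k = len(pattern)
    while i <= len(seq) - k:
        m = pattern.matches_at(seq, i)
        if m is not None:
            hits.append(MotifHit(pattern.name, m, i + 1, m))
            i += k
        else:
            i += 1
    return hits


#: Default AdoMet-binding motif I: a glycine-rich consensus.  The exact
#: motif I definition is configurable; this default exists so the class
#: order rule (alpha: I before IV) can run out of the box.
DEFAULT_MOTIF_I = MotifPattern.from_string("motif_I", "[AG][X][AG][X][AG]")

DEFAULT_MOTIF_IV = MotifPattern.from_string(
    "motif_IV", "[DNSH]PP[WFY]", variants=["EPPV", "NIPY", "NLPY"]
)


def classify_mtase_class(
    seq: str,
    motif_I: MotifPattern | None = None,
    motif_IV: MotifPattern | None = None,
) -> str:
    """Methyltransferase class from catalytic motif order.

    ``alpha`` if the first AdoMet-binding motif (I) precedes the first
    catalytic motif (IV); ``beta`` for the reverse order; ``unknown`` when
    either motif is absent.
    """
    motif_I = motif_I or DEFAULT_MOTIF_I
    motif_IV = motif_IV or DEFAULT_MOTIF_IV
    hits_I = scan_motif(seq, motif_I)
    hits_IV = scan_motif(seq, motif_IV)
    if not hits_I or not hits_IV:
        return "unknown"
    return "alpha" if hits_I[0].start < hits_IV[0].start else "beta"


_GROUP_I = {"NPPF", "NPPY"}
_GROUP_II = {"NIPY", "NLPY"}


def classify_mtase_group(hit: MotifHit, family_hint: str | None = None) -> str:
    """Evolutionary group of an N6mA-MTase from its motif IV variant.

    NPPF/NPPY → Group I (ncRNA MTases of the RlmJ/METTL5/METTL16 lineage);
    NIPY/NLPY → Group II (the ErmAM/RsmA/DIMT1L/TFB2M lineage); NPPF with a
    PCIF1 family hint → Group III (the motif alone cannot separate Groups I
    and III — the distinction is partly functional, hence the hint).
    """
    variant = hit.variant.upper()
    if variant == "NPPF" and family_hint is not None and family_hint.upper() == "PCIF1":
        return "III"
    if variant in _GROUP_I:
        return "I"
    if variant in _GROUP_II:
        return "II"
    return "none"


def check_alkbh_sites(
    seq: str,
    fe_distal_gap: tuple[int, int] = (10, 80),
    akg_gaps: Sequence[tuple[int, int]] = ((1, 60), (1, 60), (1, 30)),
) -> tuple[bool, bool, dict]:
    """Detect ALKB-family metal and cofactor binding sites.

    Iron site: an ``H-x-D`` pair followed by a distal H whose offset from
    the D lies within ``fe_distal_gap``.  α-KG site: residues N, Y, R, R in
    order, with each inter-residue gap inside the corresponding window of
    ``akg_gaps``.  Windows are family-dependent configuration.  Returns
    ``(fe_site, akg_site, positions)`` with 1-based positions of the first
    satisfying arrangement.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    fe_pos = None
    for i in range(len(s) - 2):
        if s[i] == "H" and s[i + 2] == "D":
            lo, hi = fe_distal_gap
            for j in range(i + 2 + lo, min(i + 2 + hi, len(s) - 1) + 1):
                if s[j] == "H":
                    fe_pos = (i + 1, i + 3, j + 1)
                    break
            if fe_pos:
                break

    akg_pos = None
    targets = "NYRR"
    def search(idx: int, level: int, acc: tuple) -> tuple | None:
        if level == 4:
            return acc
        lo, hi = (0, len(s)) if level == 0 else akg_gaps[level - 1]
        start = idx + lo if level else 0
        stop = min(idx + hi, len(s) - 1) if level else len(s) - 1
        for j in range(start, stop + 1):
            if s[j] == targets[level]:
                got = search(j, level + 1, acc + (j + 1,))
                if got:
                    return got
        return None

    akg_pos = search(-1, 0, ())
    positions = {"fe": fe_pos, "akg": akg_pos}
    return fe_pos is not None, akg_pos is not None, positions


def check_aromatic_cage(
    aln: Alignment,
    cage_columns: Sequence[int],
    allowed: frozenset[str] | set[str] = frozenset("FWYL"),
) -> dict[str, bool]:
    """Per-sequence aromatic-cage check over three alignment columns.

    A sequence passes iff all three cage columns hold residues from
    ``allowed`` (default F/W/Y plus L, since one cage position is aliphatic
    in some prokaryotic homologues); a gap at any cage column fails.
    """
    if len(cage_columns) != 3:
        raise ValueError("exactly 3 cage columns required")
    for c in cage_columns:
        if c < 0 or c >= aln.length:
            raise ValueError(f"cage column {c} out of range")
    allowed_upper = {a.upper() for a in allowed}
    out = {}
    for sid, row in zip(aln.ids, aln.rows):
        out[sid] = all(
            row[c] != GAP and row[c].upper() in allowed_upper for c in cage_columns
        )
    return out
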