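"""Pipeline configuration: thresholds, inputs, motif patterns, seeds."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .motifs import MotifPattern


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run.

    Thresholds default to the analysis parameter set: E-value cutoff 0.05,
    redundancy identity 0.98, column retention 0.30 non-gap / 0.10
    conserved pairs, 1000 bootstrap replicates, xenologue support 0.8.
    """

    # inputs (None -> simulate a demo panel instead of ingesting files)
    fasta: str | None = None
    species_map: str | None = None
    species_tree: str | None = None
    pdb_files: list[str] = field(default_factory=list)
    pdb_chains: list[str] = field(default_factory=list)

    # thresholds
    e_cutoff: float = 0.05
    identity_cutoff: float = 0.98
    trim_min_nongap: float = 0.30
    trim_min_conserved_pairs: float = 0.10
    bootstrap_replicates: int = 1000
    xenolog_support: float = 0.8

    # simulation (used when no input FASTA is given)
    n_families: int = 4
    n_taxa_per_group: int = 4
    dup_rate: float = 0.1
    loss_rate: float = 0.1
    transfer_rate: float = 0.05
    subst_rate: float = 0.2
    seq_length: int = 300

    motif_file: str | None = None
    seed: int = 0
    out_dir: str = "m6aevo_run"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.e_cutoff <= 0:
            raise ValueError("e_cutoff must be > 0")
        if not 0 < self.identity_cutoff <= 1:
            raise ValueError("identity_cutoff must be in (0, 1]")
        for name in ("trim_min_nongap", "trim_min_conserved_pairs", "xenolog_support"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required (stochastic stages are enabled)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def load_motif_config(path: str | None = None) -> dict:
    """Load motif patterns; falls back to the packaged defaults."""
    if path is None:
        text = resources.files("m6aevo").joinpath("data/motifs.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out = {
        "motif_I": MotifPattern.from_string(
            "motif_I", raw["motif_I"]["pattern"], raw["motif_I"].get("variants", [])
        ),
        "motif_IV": MotifPattern.from_string(
            "motif_IV", raw["motif_IV"]["pattern"], raw["motif_IV"].get("variants", [])
        ),
        "alkbh": {
            "fe_distal_gap": tuple(raw["alkbh"]["fe_distal_gap"]),
            "akg_gaps": [tuple(g) for g in raw["alkbh"]["akg_gaps"]],
        },
        "aromatic_cage": frozenset(raw["aromatic_cage"]["allowed"]),
    }
    return out
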