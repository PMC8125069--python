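"""Run configuration: every threshold the pipeline honours, in one place.

Defaults follow the conventions of the effector-survey literature: families
at a 40 % identity cutoff, toxin-domain homologs at >= 40 % identity over
>= 90 aligned residues, VgrG homologs over >= 300, counted VgrG members
longer than 500 aa, immunity homologs at >= 40 % identity over >= 90 % of
the reference, structural-gene homologs at 40 % identity / 70 % reference
coverage, and operon-scale immunity proximity (<= 200 bp, same strand).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


class ConfigError(ValueError):
    """Raised for out-of-range or unknown configuration values."""


@dataclass
class RunConfig:
    # clustering
    cluster_identity: float = 0.40
    # toxin-domain homolog recovery
    toxin_min_identity: float = 0.40
    toxin_min_aln_len: int = 90
    # VgrG
    vgrg_min_aln_len: int = 300
    vgrg_min_member_len: int = 500
    truncation_fraction: float = 0.5
    # immunity cooccurrence
    immunity_min_identity: float = 0.40
    immunity_min_ref_coverage: float = 0.90
    max_intergenic: int = 200
    require_same_strand: bool = True
    # T6SS inventory
    t6ss_min_identity: float = 0.40
    t6ss_min_coverage: float = 0.70
    locus_max_gap: int = 10_000
    contig_end_margin: int = 0
    # Rhs splitting
    dpxg_window: int = 100
    core_min_len: int = 150
    min_toxin_len: int = 30
    # motif calibration
    motif_fpr: float = 0.001
    motif_n_decoys: int = 1000
    # alignment scoring
    substitution: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    # run control
    seed: int = 0
    threads: int = 1  # results are thread-count invariant

    def __post_init__(self) -> None:
        for name in ("cluster_identity", "toxin_min_identity",
                     "immunity_min_identity", "t6ss_min_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name}={v} outside (0, 1]")
        for name in ("immunity_min_ref_coverage", "t6ss_min_coverage",
                     "truncation_fraction", "motif_fpr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name}={v} outside (0, 1]")
        for name in ("toxin_min_aln_len", "vgrg_min_aln_len",
                     "vgrg_min_member_len", "max_intergenic",
                     "locus_max_gap", "contig_end_margin", "dpxg_window",
                     "core_min_len", "min_toxin_len", "motif_n_decoys",
                     "gap_open", "gap_extend"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path | None) -> RunConfig:
    """Read a YAML config, or return the documented defaults."""
    if path is None:
        return RunConfig()
    return RunConfig.from_yaml(path)
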