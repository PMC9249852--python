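"""Run configuration: one declarative YAML file, validated defaults."""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run, with their defaults.

    Thresholds mirror the published analysis: consensus peaks are summit
    +/- 250 bp windows, loci are scored over a 100-bp center window,
    signal matrices span +/- 1 kb in 20-bp bins, differential loci need
    peak support in >= 2 of 4 experiments at FDR < 0.05, common loci
    support in >= 3 of 4 at raw p > 0.1, differential accessibility adds
    |log2 fold| > 1, affinity-track values below 1e-4 are ignored, and
    motif tables report the ten strongest hits.
    """

    # input paths (any may be None when the corresponding stage is not run)
    genome_fasta: str | None = None
    peak_files: list[str] = field(default_factory=list)
    coverage_files: dict[str, str] = field(default_factory=dict)
    counts_file: str | None = None
    gtf_file: str | None = None
    psam_files: list[str] = field(default_factory=list)
    selex_r0: str | None = None
    selex_r1: str | None = None

    # parameters
    affinity_threshold: float = 1e-4
    flank: int = 50
    summit_halfwidth: int = 250
    matrix_halfwidth: int = 1000
    matrix_binsize: int = 20
    fdr_differential: float = 0.05
    p_common: float = 0.1
    min_overlap_differential: int = 2
    min_overlap_common: int = 3
    lfc_accessibility: float = 1.0
    top_n_motifs: int = 10
    selex_k: int = 7
    selex_reads: int = 50_000
    rng_seed: int = 0

    def __post_init__(self):
        checks = [
            (0 < self.affinity_threshold < 1, "affinity_threshold in (0,1)"),
            (self.flank > 0, "flank > 0"),
            (self.summit_halfwidth > 0, "summit_halfwidth > 0"),
            (self.matrix_halfwidth > 0 and self.matrix_binsize > 0
             and (2 * self.matrix_halfwidth) % self.matrix_binsize == 0,
             "matrix_binsize must divide 2*matrix_halfwidth"),
            (0 < self.fdr_differential < 1, "fdr_differential in (0,1)"),
            (0 < self.p_common < 1, "p_common in (0,1)"),
            (self.min_overlap_differential >= 1, "min_overlap_differential >= 1"),
            (self.min_overlap_common >= 1, "min_overlap_common >= 1"),
            (self.lfc_accessibility >= 0, "lfc_accessibility >= 0"),
            (self.top_n_motifs >= 1, "top_n_motifs >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
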