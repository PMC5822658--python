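"""Run configuration: every tunable of every stage, with the published
thresholds as defaults (E-value 1e-3, 60-kb merge, 40-kb flank, >=8 of 13
core genes, subtype identity 0.90, within-subtype check 0.95, R = 2,
1000 bootstraps)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # global
    seed: int = 1
    species_id: str = "synthetic_species"
    # synthetic genome
    simulate: bool = True
    n_contigs: int = 1
    contig_length: int = 1_000_000
    gc: float = 0.45
    n_host_genes: int = 20
    host_gene_length: int = 1500
    # element
    transposase_placement: str = "internal"  # internal | edge | absent
    tir_length: int = 13
    spacer_length: int = 150
    # copies: list of [n_copies, between_divergence, within_divergence]
    subtype_spec: list = field(default_factory=lambda: [[5, 0.17, 0.02], [5, 0.17, 0.02]])
    degrade: list = field(default_factory=list)
    insertion_min_separation: int = 2000
    # reads (mean_depth = 0 skips the copy-number stage)
    mean_depth: float = 30.0
    read_length: int = 100
    error_rate: float = 0.002
    # search
    evalue: float = 1e-3
    word_size: int = 4
    gap_open: float = -11.0
    gap_extend: float = -1.0
    x_drop: float = 20.0
    ungapped_trigger: float = 30.0
    # loci / classification
    merge_distance: int = 60_000
    flank: int = 40_000
    min_genes: int = 8
    # subtypes
    subtype_identity: float = 0.90
    within_subtype_identity: float = 0.95
    # divergence / phylogenetics
    ts_tv_bias: float = 2.0
    n_bootstrap: int = 1000
    run_phylo: bool = True
    # annotation
    orf_min_length_aa: int = 100
    intact_fraction: float = 0.8
    tir_min_len: int = 10
    tir_max_len: int = 40
    tir_max_mismatch: int = 1
    # mapping
    seed_kmer: int = 21
    max_mismatches: int = 4
    copy_number_bootstrap: int = 200
    # inputs for non-simulated runs
    genome_fasta: str | None = None
    queries_fasta: str | None = None
    host_bed: str | None = None
    reads_fastq: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def search_params(self):
        from .search import SearchParams

        return SearchParams(
            word_size=self.word_size,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            x_drop=self.x_drop,
            evalue_keep=self.evalue,
            ungapped_trigger=self.ungapped_trigger,
        )
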