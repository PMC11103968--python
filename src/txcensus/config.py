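"""Pipeline configuration.

Every threshold used by the filter cascades, the activation test, the
enrichment analyses and the entity association lives here, with defaults set
to the values the analysis was designed around.  A config can be loaded from
a YAML file; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Config:
    # small-variant filter cascade (somatic + rare germline)
    max_gnomad_af: float = 0.0005       # population MAF above this -> common germline, dropped
    min_vaf: float = 0.1                # low-VAF excess attributed to shearing artifacts
    # recurrence-analysis refinement (applied on top of the cascade above)
    recurrence_min_vaf: float = 0.15
    recurrence_min_reads: int = 20
    # structural variants
    sv_min_paired_reads: int = 3
    sv_max_recurrent_entities: int = 4  # >=4 myeloid AND >=4 lymphatic -> dropped
    # variant-category classifiers
    promoter_window_bp: int = 2000      # strict: |pos - TSS| < window
    splice_affecting_min_score: float = 0.2
    vep_splice_terms: tuple[str, ...] = (
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
    )
    coding_utr_consequences: tuple[str, ...] = (
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "coding_sequence_variant",
    )
    coding_impacts: tuple[str, ...] = ("HIGH", "MODERATE", "LOW")
    # expression units and gene partition
    fpkm_expressed_threshold: float = 1.0
    common_gene_sample_fraction: float = 0.05
    # NB-act
    nbact_baseline_fpkm: float = 1.0
    nbact_dispersion: float = 0.02
    nbact_fdr: float = 0.05
    nbact_adjust_scope: str = "global"  # "global" (all rare-gene x sample tests) or "per_sample"
    # outlier callers consumed downstream
    outlier_fdr: float = 0.05
    # enrichment
    top_k_per_sample: int = 3
    recurrence_bins: tuple[int, ...] = (1, 5)  # strata: 1, 2-5, >5
    # whether library size is the supplied per-sample total or the column sum
    # over annotated genes (the unit definition admits both readings)
    library_size_from: str = "supplied"  # or "annotated"
    # entity association
    association_fdr: float = 0.05
    # variance components: include residual in the normalisation?
    include_residual: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.nbact_fdr < 1:
            raise ValueError("nbact_fdr must be in (0, 1)")
        if self.nbact_dispersion <= 0:
            raise ValueError("nbact_dispersion must be positive")
        if self.nbact_baseline_fpkm <= 0:
            raise ValueError("nbact_baseline_fpkm must be positive")
        if self.library_size_from not in ("supplied", "annotated"):
            raise ValueError("library_size_from must be 'supplied' or 'annotated'")
        if self.nbact_adjust_scope not in ("global", "per_sample"):
            raise ValueError("nbact_adjust_scope must be 'global' or 'per_sample'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


DEFAULT_CONFIG = Config()
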