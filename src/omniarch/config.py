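"""Configuration objects for the synthetic benchmark and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

__all__ = ["SyntheticConfig", "PipelineConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic gene universe and its derived datasets.

    The defaults describe the benchmark conditions the package is calibrated
    on: a universe of 2,200 genes with 200 core genes, a signature panel of
    1,000 perturbagens in which 30% of perturbagens shift core-gene
    expression by 0.5 Z-score units (random sign) and 5% double the
    core-gene standard deviation, plus SNP, network, annotation and
    interaction-triple layers with planted ground truth.

    All randomness flows from ``seed`` through named sub-streams, so a fixed
    seed gives byte-identical serialized outputs.
    """

    # gene universe
    n_genes: int = 2200
    n_core: int = 200
    n_hsp: int = 10
    frac_excluded: float = 0.1       # genes with consensus score 1..10
    frac_omim: float = 0.5           # fraction of core genes carrying an OMIM label
    n_tissues: int = 6
    relevant_tissues: Sequence[int] = (0, 1)
    core_expression_shift: float = 1.0   # standardized shift in relevant tissues
    expression_base: float = 6.0
    tss_core_mean: float = 8.0
    tss_background_mean: float = 4.0

    # genome layout (one synthetic chromosome, bp)
    gene_length: int = 2000
    ld_block_size: int = 20_000
    snp_window: int = 10_000

    # SNP table
    n_snps: int = 100
    n_decoy_proximity: int = 3
    n_decoy_ld: int = 3

    # perturbation panel
    n_perturbagens: int = 1000
    frac_discriminative: float = 0.3
    mean_shift_delta: float = 0.5    # Z-score units
    frac_variance: float = 0.05
    variance_factor: float = 2.0     # SD ratio applied to core-gene entries

    # interaction triples
    n_triples_per_class: int = 50
    triple_dim: int = 50
    triple_noise_sd: float = 0.1
    suppression_coeff: float = 0.2
    synergy_coeff: float = 2.0
    neomorph_noise_frac: float = 0.9
    class_group_assoc: float = 0.9   # P(suppression/neomorph triple is core-core)

    # multi-modal network
    n_edges: int = 4000
    degree_elevation: float = 3.0    # expected-degree factor for core genes

    # annotations
    n_terms: int = 30
    n_enriched_terms: int = 5
    include_exact_core_term: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        self.relevant_tissues = tuple(int(t) for t in self.relevant_tissues)
        self.validate()

    def validate(self) -> None:
        c = self
        if c.n_core + c.n_hsp > c.n_genes:
            raise ConfigurationError(
                f"n_core + n_hsp = {c.n_core + c.n_hsp} exceeds n_genes = {c.n_genes}"
            )
        for name in ("frac_excluded", "frac_omim", "frac_discriminative",
                     "frac_variance", "neomorph_noise_frac", "class_group_assoc"):
            v = getattr(c, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} = {v} not in [0, 1]")
        if c.variance_factor <= 1.0:
            raise ConfigurationError("variance_factor must be > 1")
        if c.suppression_coeff <= 0 or c.suppression_coeff >= 1:
            raise ConfigurationError("suppression_coeff must lie in (0, 1)")
        if c.synergy_coeff <= 1:
            raise ConfigurationError("synergy_coeff must be > 1")
        if c.n_tissues < 1 or (c.relevant_tissues and max(c.relevant_tissues) >= c.n_tissues):
            raise ConfigurationError("relevant_tissues indices must be < n_tissues")
        # the in-LD-block decoy SNP needs room inside a block beyond the
        # proximity window of the block's own gene body
        if c.ld_block_size <= c.gene_length + c.snp_window + 2:
            raise ConfigurationError(
                "ld_block_size must exceed gene_length + snp_window + 2"
            )
        if c.triple_dim < 3:
            raise ConfigurationError("triple_dim must be >= 3")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["relevant_tissues"] = list(self.relevant_tissues)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration: one synthetic config plus the
    per-stage analysis parameters and stage toggles."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: Sequence[str] = (
        "simulate", "classify", "hsp", "enrich", "perturb",
        "overlap", "interact", "netstats",
    )
    # analysis parameters
    hsp_z_threshold: float = 5.0
    hsp_window: int = 10_000
    hsp_p_cut: float = 5e-8
    alpha: float = 0.05
    percentile: float = 0.5
    n_rand: int = 1000
    n_random_controls: int = 20
    topk: Sequence[int] = (100, 500)
    restart: float = 0.15
    importance_threshold: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.topk = tuple(int(k) for k in self.topk)
        known = {"simulate", "classify", "hsp", "enrich", "perturb",
                 "overlap", "interact", "netstats"}
        unknown = set(self.stages) - known
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        d["stages"] = list(self.stages)
        d["topk"] = list(self.topk)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
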