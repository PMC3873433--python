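"""Pipeline configuration: a YAML mapping validated into dataclasses.

Unknown keys are rejected so typos fail loudly rather than silently
running with defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .gxe import DEFAULT_MODEL_IDS
from .riskscore import DEFAULT_N_GRID, TRAIT_SIGNS
from .syndata import SimConfig


@dataclass
class PipelineConfig:
    # input paths (any may be None when a stage is run standalone)
    genotypes: dict[str, str] = field(default_factory=dict)   # cohort name -> path
    phenotypes: dict[str, str] = field(default_factory=dict)
    gene_sets: str | None = None
    esnp_map: str | None = None
    outdir: str = "results"

    # QC thresholds
    max_snp_missing: float = 0.02
    min_maf: float = 0.02
    min_hwe_p: float = 1e-4
    min_sample_call_rate: float = 0.98
    pca_sd_threshold: float = 3.0

    # association / meta
    binary_covariates: list[str] = field(default_factory=lambda: ["age", "smoke", "pc1", "pc2", "pc3"])
    quant_covariates: list[str] = field(default_factory=lambda: ["age", "smoke"])
    effective_n: str = "total"          # or "binary"
    genome_wide_p: float = 5e-8
    suggestive_p: float = 5e-6

    # SSEA
    ssea_mode: str = "two_sample"       # or "uniform"
    ssea_permutations: int = 10_000
    ssea_min_set_size: int = 5

    # GxE
    gxe_env: str = "alcohol"
    gxe_threshold: float = 1e-9
    gxe_model_ids: dict[int, list[str]] = field(
        default_factory=lambda: {i: list(v) for i, v in DEFAULT_MODEL_IDS.items()}
    )

    # risk score
    score_n_grid: list[int] = field(default_factory=lambda: list(DEFAULT_N_GRID))
    trait_signs: dict[str, int] = field(default_factory=lambda: dict(TRAIT_SIGNS))

    # simulation + global seed
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.max_snp_missing <= 1 and 0 <= self.min_maf <= 0.5):
            raise ValueError("QC thresholds out of range")
        if not (0 <= self.min_hwe_p <= 1 and 0 <= self.min_sample_call_rate <= 1):
            raise ValueError("QC thresholds out of range")
        if self.effective_n not in ("total", "binary"):
            raise ValueError("effective_n must be 'total' or 'binary'")
        if self.ssea_mode not in ("two_sample", "uniform"):
            raise ValueError("ssea_mode must be 'two_sample' or 'uniform'")
        for p in (self.genome_wide_p, self.suggestive_p, self.gxe_threshold):
            if not (0 < p < 1):
                raise ValueError("p-value thresholds must be in (0, 1)")
        self.sim.validate()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys at both levels."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_raw = raw.pop("sim", {})
    sim_known = {f.name for f in fields(SimConfig)}
    sim_unknown = set(sim_raw) - sim_known
    if sim_unknown:
        raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
    sim = SimConfig(**{k: tuple(v) if k == "maf_range" else v for k, v in sim_raw.items()})
    cfg = PipelineConfig(sim=sim, **raw)
    if "seed" in raw:
        cfg.sim.seed = cfg.seed
    cfg.validate()
    return cfg
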