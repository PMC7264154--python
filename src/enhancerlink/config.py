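"""Typed, validated pipeline configuration.

A YAML config supplies input paths and analysis thresholds; every
threshold defaults to the published analysis values (promoter window
3000/1000 bp, enhancer widening 10 kb, interaction filter at 5 CPM and
2-fold over expected, differential FDR 0.01, LD r^2 0.8 within +-1 Mb,
eQTL FDR 0.2, SNP QC at 10% missingness / imputation R2 0.4 / HWE 1e-6,
15 hidden factors, 500 top features for ordination). Unknown keys and
out-of-range values are rejected with named errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_RANGES = {
    "promoter_up": (1, 1_000_000),
    "promoter_down": (1, 1_000_000),
    "widen": (0, 10_000_000),
    "min_ave_cpm": (0.0, 1e9),
    "min_fold": (1.0, 1e6),
    "de_fdr": (0.0, 1.0),
    "interaction_fdr": (0.0, 1.0),
    "ld_r2": (0.0, 1.0),
    "ld_window": (0, 1e9),
    "eqtl_fdr": (0.0, 1.0),
    "max_missing": (0.0, 1.0),
    "min_imp_r2": (0.0, 1.0),
    "hwe_alpha": (0.0, 1.0),
    "hidden_k": (0, 10_000),
    "mds_top_k": (1, 10_000_000),
    "seed": (0, 2**31 - 1),
}

_PATH_KEYS = (
    "tss", "k27ac_peaks", "k4me1_peaks", "k4me3_peaks",
    "gene_counts", "peak_counts", "design",
    "interactions", "interaction_design",
    "index_snps", "genotypes",
    "cohort_expression", "cohort_covariates",
    "phenotype_expression", "phenotype_panel",
)


@dataclass
class PipelineConfig:
    """All input paths and thresholds for one pipeline run."""

    paths: dict[str, str] = field(default_factory=dict)
    contrast: dict[str, float] = field(
        default_factory=lambda: {"Treatment": 1.0, "Control": -1.0}
    )
    interaction_contrast: dict[str, float] = field(
        default_factory=lambda: {"cond2": 1.0, "cond1": -1.0}
    )
    treatment: str = "Treatment"
    phenotype_group: str = "CD_muscle"
    promoter_up: int = 3000
    promoter_down: int = 1000
    widen: int = 10_000
    min_ave_cpm: float = 5.0
    min_fold: float = 2.0
    de_fdr: float = 0.01
    interaction_fdr: float = 0.05
    ld_r2: float = 0.8
    ld_window: int = 1_000_000
    eqtl_fdr: float = 0.2
    max_missing: float = 0.10
    min_imp_r2: float = 0.4
    hwe_alpha: float = 1e-6
    hidden_k: int = 15
    mds_top_k: int = 500
    adjust_group: bool = True   # drop for the no-BMI-adjustment sensitivity run
    seed: int = 0

    def __post_init__(self) -> None:
        for key, (lo, hi) in _RANGES.items():
            val = getattr(self, key)
            if not (lo <= val <= hi):
                raise ConfigError(f"{key}={val!r} outside valid range [{lo}, {hi}]")
        unknown_paths = set(self.paths) - set(_PATH_KEYS)
        if unknown_paths:
            raise ConfigError(f"unknown path keys: {sorted(unknown_paths)}")

    def path(self, key: str) -> Path:
        if key not in self.paths:
            raise ConfigError(f"config is missing required path {key!r}")
        p = Path(self.paths[key])
        if not p.exists():
            raise ConfigError(f"path {key!r} does not exist: {p}")
        return p


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load and validate a config mapping or YAML file."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
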