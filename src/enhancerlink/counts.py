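"""Count matrices, TMM library normalization, CPM and FDR helpers.

TMM (trimmed mean of M-values) corrects library-size-normalised counts for
compositional differences between libraries: for each library versus a
reference, per-feature log-ratios (M) are doubly trimmed on M and on
average abundance (A), and a precision-weighted mean of the surviving M
values gives the log2 scaling factor. Factors are rescaled to geometric
mean 1 so effective library size = lib_size * factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DesignSpec",
    "tmm_factors",
    "cpm",
    "ave_log_cpm",
    "bh_adjust",
]


@dataclass
class CountMatrix:
    """Non-negative integer counts, features x samples."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class DesignSpec:
    """Per-sample group/block factors and a contrast over group levels.

    The model is a means parameterisation ``~0 + group (+ block)``; the
    contrast maps group levels to weights that must sum to zero, e.g.
    ``{"P5_Palmitate": 0.5, "P6_Palmitate": 0.5, "P5_Control": -0.5,
    "P6_Control": -0.5}``.
    """

    sample_ids: list[str]
    group: list[str]
    contrast: dict[str, float]
    block: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.group) != len(self.sample_ids):
            raise ValueError("one group level required per sample")
        if self.block is not None and len(self.block) != len(self.sample_ids):
            raise ValueError("one block level required per sample")
        if abs(sum(self.contrast.values())) > 1e-9:
            raise ValueError("contrast weights must sum to 0")
        unknown = set(self.contrast) - set(self.group)
        if unknown:
            raise ValueError(f"contrast names unknown group levels: {sorted(unknown)}")

    @property
    def group_levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g)
        return list(seen)

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Full-rank design: one indicator per group level, block levels
        beyond the first as additive effects."""
        levels = self.group_levels
        cols = [np.asarray([g == lv for g in self.group], float) for lv in levels]
        names = [f"group:{lv}" for lv in levels]
        if self.block is not None:
            blevels = sorted(set(self.block))
            for bl in blevels[1:]:
                cols.append(np.asarray([b == bl for b in self.block], float))
                names.append(f"block:{bl}")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"design is rank deficient (columns {names}); "
                "group and block factors are confounded"
            )
        return X, names

    def contrast_vector(self) -> np.ndarray:
        _, names = self.design_matrix()
        return np.asarray(
            [self.contrast.get(n.removeprefix("group:"), 0.0) if n.startswith("group:") else 0.0
             for n in names]
        )


@dataclass
class NormalizationFactors:
    factors: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, float)
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Log2 TMM factor of one library against the reference."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        raise ValueError("library shares no expressed features with the reference")
    p_obs, p_ref = obs[ok] / n_obs, ref[ok] / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M under binomial sampling
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    if np.allclose(M, M[0]):
        return float(M[0])
    n = M.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    from scipy.stats import rankdata

    rm, ra = rankdata(M), rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizationFactors:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference library is the one whose 75th-percentile CPM is closest
    to the mean of those percentiles across libraries.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample in count matrix")
    q75 = np.quantile(counts / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    log_f = np.array(
        [
            0.0
            if j == ref_idx
            else _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(counts.shape[1])
        ]
    )
    f = 2.0 ** log_f
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationFactors(f, list(cm.sample_ids))


def cpm(
    cm: CountMatrix,
    nf: NormalizationFactors | None = None,
    log: bool = False,
    prior: float = 0.5,
) -> np.ndarray:
    """(log2) counts per million on TMM-effective library sizes.

    For ``log=True`` the pseudo-count is scaled per library by effective
    library size relative to the mean, and the library size is inflated by
    twice the scaled prior, so a zero count maps to the same value in every
    library.
    """
    factors = np.ones(len(cm.sample_ids)) if nf is None else nf.factors
    eff = cm.lib_sizes * factors
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    if not log:
        return cm.counts / eff * 1e6
    prior_j = prior * eff / eff.mean()
    return np.log2((cm.counts + prior_j) / (eff + 2 * prior_j) * 1e6)


def ave_log_cpm(cm: CountMatrix, nf: NormalizationFactors | None = None,
                prior: float = 2.0) -> np.ndarray:
    """Per-feature average abundance: log2 CPM of the mean normalised count.

    Counts are rescaled to a common (mean effective) library size before
    averaging, with a pseudo-count so all-zero features stay finite.
    """
    factors = np.ones(len(cm.sample_ids)) if nf is None else nf.factors
    eff = cm.lib_sizes * factors
    mean_lib = eff.mean()
    scaled = cm.counts / eff * mean_lib
    return np.log2((scaled.mean(axis=1) + prior) / (mean_lib + 2 * prior) * 1e6)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
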