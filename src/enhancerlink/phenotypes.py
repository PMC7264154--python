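"""Spearman correlation of gene expression against phenotype panels.

Emulates the genetic-reference-population analysis: each candidate gene's
expression across strains is rank-correlated with every phenotype in a
panel (48 metabolic traits by default), separately per grouping key (diet
x tissue), and p-values are Benjamini-Hochberg adjusted within each
(gene, group) block of panel correlations. Stars annotate FDR < 0.2 /
0.1 / 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts import bh_adjust

__all__ = ["PhenotypePanel", "spearman", "panel_correlate"]

STAR_THRESHOLDS = ((0.05, "***"), (0.1, "**"), (0.2, "*"))


@dataclass
class PhenotypePanel:
    """Phenotype values per strain, with a grouping key (e.g. diet_tissue).

    ``values`` is strains x phenotypes and may contain NaN; each
    correlation needs >= 3 complete pairs.
    """

    strain_ids: list[str]
    phenotype_names: list[str]
    values: pd.DataFrame
    group: str

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("grouping key must be non-empty")
        if list(self.values.index) != list(self.strain_ids) or list(
            self.values.columns
        ) != list(self.phenotype_names):
            raise ValueError("values frame must be indexed by strains x phenotypes")


def _exact_spearman_p(rho: float, rx: np.ndarray, ry: np.ndarray) -> float:
    """Exact two-sided permutation p for small n (enumerates all pairings)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rhos = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> dict:
    """Spearman rank correlation with average ranks for ties.

    Missing pairs are dropped. The p-value uses the t approximation, or an
    exact permutation enumeration for n <= ``exact_max_n``. Fewer than 3
    complete pairs or a constant vector yields an untestable result.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return {"rho": np.nan, "p": np.nan, "n": int(n), "testable": False}
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_spearman_p(rho, rx, ry)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return {"rho": rho, "p": p, "n": int(n), "testable": True}


def _stars(fdr: float) -> str:
    for cut, mark in STAR_THRESHOLDS:
        if fdr < cut:
            return mark
    return ""


def panel_correlate(
    expr: pd.DataFrame,
    panels: list[PhenotypePanel],
) -> pd.DataFrame:
    """Correlate each gene with each phenotype, FDR-adjusted per panel.

    ``expr`` is genes x strains. For every (gene, panel) the full set of
    panel correlations is computed and BH-adjusted together, mirroring the
    per-diet/per-tissue adjustment of the published analysis; groups never
    influence each other's FDR.
    """
    rows = []
    for panel in panels:
        strains = [s for s in panel.strain_ids if s in expr.columns]
        if not strains:
            raise ValueError(f"no overlapping strains for group {panel.group!r}")
        vals = panel.values.loc[strains]
        for gene in expr.index:
            e = expr.loc[gene, strains].to_numpy(float)
            block = []
            for pheno in panel.phenotype_names:
                r = spearman(e, vals[pheno].to_numpy(float))
                block.append((gene, pheno, panel.group, r["rho"], r["p"], r["n"],
                              r["testable"]))
            bdf = pd.DataFrame(
                block, columns=["gene", "phenotype", "group", "rho", "p", "n", "testable"]
            )
            fdr = np.full(len(bdf), np.nan)
            ok = bdf["testable"].to_numpy()
            if ok.any():
                fdr[ok] = bh_adjust(bdf.loc[ok, "p"].to_numpy())
            bdf["fdr"] = fdr
            bdf["stars"] = ["" if not np.isfinite(q) else _stars(q) for q in fdr]
            rows.append(bdf)
    return pd.concat(rows, ignore_index=True)


def rho_matrix(table: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Heatmap-ready phenotype x group matrix of rho values for one gene."""
    sub = table[table["gene"] == gene]
    return sub.pivot(index="phenotype", columns="group", values="rho")
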