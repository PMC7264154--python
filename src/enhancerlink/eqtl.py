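"""cis-eQTL testing of pre-specified SNP-gene pairs with hierarchical
Bonferroni-BH eGene calling.

The workflow follows the standard small-cohort design: genotype QC
(missingness, imputation quality, Hardy-Weinberg equilibrium), hidden
expression factors (principal axes of covariate-residualised,
standardised expression, standing in for PEER), rank-based inverse normal
transform of covariate-adjusted residuals, per-pair ordinary least
squares of transformed expression on allele dosage, and a two-level
multiple-testing correction: Bonferroni over each gene's SNPs followed by
Benjamini-Hochberg across genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .counts import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "CovariateSet",
    "hwe_chi2_p",
    "snp_qc",
    "hidden_factors",
    "int_residuals",
    "test_pairs",
    "hierarchical_correct",
    "EqtlResult",
]


@dataclass
class GenotypeMatrix:
    """SNP x individual dosages in [0, 2] (NaN = missing) with QC metadata."""

    snp_ids: list[str]
    individual_ids: list[str]
    dosages: np.ndarray
    imputation_r2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        if self.dosages.shape != (len(self.snp_ids), len(self.individual_ids)):
            raise ValueError("dosage matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.nansum(bad) > 0:
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [s for s, k in zip(self.snp_ids, keep) if k],
            list(self.individual_ids),
            self.dosages[keep],
            None if self.imputation_r2 is None else self.imputation_r2[keep],
        )


@dataclass
class CovariateSet:
    """Known covariates plus hidden factors, aligned to individuals."""

    individual_ids: list[str]
    known: pd.DataFrame                       # e.g. age, group (0/1)
    factors: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def design(self) -> np.ndarray:
        """Intercept + known covariates + hidden factors."""
        parts = [np.ones((len(self.individual_ids), 1))]
        if not self.known.empty:
            parts.append(self.known.to_numpy(float))
        if self.factors.size:
            parts.append(self.factors)
        return np.column_stack(parts)


def hwe_chi2_p(dosages: np.ndarray) -> float:
    """Hardy-Weinberg 1-df chi-square p from hard-called genotypes.

    Dosages are rounded to {0, 1, 2}; the test compares observed genotype
    counts with those expected at the sample allele frequency.
    """
    d = np.asarray(dosages, float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return np.nan
    g = np.clip(np.round(d), 0, 2).astype(int)
    n = g.size
    counts = np.bincount(g, minlength=3).astype(float)
    p = (2 * counts[2] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([q * q, 2 * p * q, p * p]) * n
    stat = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, df=1))


def snp_qc(
    gm: GenotypeMatrix,
    max_missing: float = 0.10,
    min_imp_r2: float = 0.4,
    hwe_alpha: float = 1e-6,
) -> GenotypeMatrix:
    """Keep SNPs with missingness < ``max_missing``, imputation R2 >
    ``min_imp_r2`` and no significant Hardy-Weinberg deviation."""
    miss_ok = gm.missingness < max_missing
    if gm.imputation_r2 is not None:
        imp_ok = gm.imputation_r2 > min_imp_r2
    else:
        imp_ok = np.ones(len(gm.snp_ids), bool)
    hwe_p = np.array([hwe_chi2_p(row) for row in gm.dosages])
    hwe_ok = ~(hwe_p < hwe_alpha)  # NaN (monomorphic/empty) passes
    keep = miss_ok & imp_ok & hwe_ok
    if not keep.any():
        raise ValueError("no SNPs survive QC")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("snp_qc removed %d of %d SNPs", n_drop, len(keep))
    return gm.subset(keep)


def _residualize(Y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of each row of Y on the column space of design."""
    beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    return Y - (design @ beta).T


def hidden_factors(
    expr: np.ndarray,
    covariates: CovariateSet,
    k: int = 15,
) -> np.ndarray:
    """Top-k principal axes of covariate-residualised, per-gene
    standardised expression (individuals x k, orthonormal columns).

    A PCA-based stand-in for PEER-style hidden-factor estimation; the
    residualisation makes the factors orthogonal to known covariates'
    fitted effects by construction.
    """
    n_ind = expr.shape[1]
    n_known = covariates.design().shape[1]
    if k >= n_ind - n_known:
        raise ValueError(f"k={k} too large for {n_ind} individuals and "
                         f"{n_known} known covariate columns")
    if k == 0:
        return np.empty((n_ind, 0))
    resid = _residualize(expr, covariates.design())
    sd = resid.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    Z = (resid - resid.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    factors = vt[:k].T
    for j in range(k):  # deterministic sign
        nz = np.flatnonzero(np.abs(factors[:, j]) > 1e-12)
        if nz.size and factors[nz[0], j] < 0:
            factors[:, j] = -factors[:, j]
    return factors


def int_residuals(expr: np.ndarray, covariates: CovariateSet) -> np.ndarray:
    """Rank-based inverse normal transform of expression residuals.

    Per gene: residualise on the covariate design (including hidden
    factors), rank with average ranks for ties, and map rank r to
    Phi^-1((r - 0.5) / n). Constant genes come back all-zero with a
    warning.
    """
    design = covariates.design()
    resid = _residualize(expr, design)
    n = resid.shape[1]
    out = np.empty_like(resid)
    for i, row in enumerate(resid):
        if np.allclose(row, row[0]):
            warnings.warn(f"gene row {i} is constant after residualisation; INT set to 0")
            out[i] = 0.0
            continue
        r = stats.rankdata(row, method="average")
        out[i] = stats.norm.ppf((r - 0.5) / n)
    return out


def test_pairs(
    pairs: pd.DataFrame,
    gm: GenotypeMatrix,
    transformed: np.ndarray,
    gene_ids: list[str],
) -> pd.DataFrame:
    """OLS of transformed expression on dosage for pre-specified pairs.

    ``pairs`` has columns snp, gene. Individuals with missing dosage are
    dropped per pair; monomorphic SNPs are flagged untestable (beta/se/p
    NaN). Returns one row per pair with beta, se, p, n and testable.
    """
    snp_row = {s: i for i, s in enumerate(gm.snp_ids)}
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    rows = []
    for snp, gene in pairs[["snp", "gene"]].itertuples(index=False):
        si, gi = snp_row.get(snp), gene_row.get(gene)
        if si is None or gi is None:
            rows.append((snp, gene, np.nan, np.nan, np.nan, 0, False))
            continue
        g = gm.dosages[si]
        y = transformed[gi]
        ok = np.isfinite(g)
        g, y = g[ok], y[ok]
        n = g.size
        if n < 3 or g.std() == 0:
            rows.append((snp, gene, np.nan, np.nan, np.nan, n, False))
            continue
        gc = g - g.mean()
        yc = y - y.mean()
        sxx = (gc**2).sum()
        beta = float((gc * yc).sum() / sxx)
        resid = yc - beta * gc
        df = n - 2
        s2 = float((resid**2).sum() / df)
        se = float(np.sqrt(s2 / sxx))
        if se == 0:
            p = 0.0
        else:
            p = float(2 * stats.t.sf(abs(beta / se), df))
        rows.append((snp, gene, beta, se, p, n, True))
    return pd.DataFrame(rows, columns=["snp", "gene", "beta", "se", "p", "n", "testable"])


@dataclass
class EqtlResult:
    """Per-pair effects and per-gene hierarchical correction."""

    pairs: pd.DataFrame   # snp, gene, beta, se, p, n, testable, snp_significant
    genes: pd.DataFrame   # gene, n_snps, min_p, bonferroni_p, bh_q, egene
    fdr: float


def hierarchical_correct(pair_results: pd.DataFrame, fdr: float = 0.2) -> EqtlResult:
    """Bonferroni within gene, Benjamini-Hochberg across genes.

    Per gene g with m_g testable SNPs: bonferroni_p = min(1, m_g * min p).
    BH step-up across the gene-level p-values gives bh_q; eGenes have
    bh_q < ``fdr``. Within eGenes, a SNP is reported significant when its
    raw p clears the per-gene Bonferroni share of the BH cut
    (k * fdr / (G * m_g), k = number of eGenes).
    """
    tested = pair_results[pair_results["testable"]]
    if tested.empty:
        genes = pd.DataFrame(columns=["gene", "n_snps", "min_p", "bonferroni_p", "bh_q", "egene"])
        out = pair_results.copy()
        out["snp_significant"] = False
        return EqtlResult(out, genes, fdr)
    per_gene = (
        tested.groupby("gene")
        .agg(n_snps=("p", "size"), min_p=("p", "min"))
        .reset_index()
    )
    per_gene["bonferroni_p"] = np.minimum(1.0, per_gene["n_snps"] * per_gene["min_p"])
    per_gene["bh_q"] = bh_adjust(per_gene["bonferroni_p"].to_numpy())
    per_gene["egene"] = per_gene["bh_q"] < fdr
    n_genes = len(per_gene)
    n_egenes = int(per_gene["egene"].sum())
    gene_cut = n_egenes * fdr / n_genes if n_genes else 0.0

    info = per_gene.set_index("gene")
    out = pair_results.copy()
    sig = []
    for row in out.itertuples(index=False):
        if not row.testable or row.gene not in info.index or not info.loc[row.gene, "egene"]:
            sig.append(False)
        else:
            m_g = info.loc[row.gene, "n_snps"]
            sig.append(bool(row.p <= gene_cut / m_g))
    out["snp_significant"] = sig
    return EqtlResult(out, per_gene, fdr)
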