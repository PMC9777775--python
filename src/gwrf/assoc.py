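"""Association stage: per-SNP regression, GATES gene p-values, PCA covariates.

Given a continuous phenotype (here, a summary of the selected fused
features), each SNP dosage column is tested by ordinary least squares with
covariates (age, sex, education and k genotype principal components for
population stratification). Per-gene evidence is combined with GATES — the
extended Simes procedure: with the gene's SNP p-values sorted ascending,

    P_gene = min_j  m_e * p_(j) / m_e(j)

where m_e(j) is the effective number of independent tests among the top j
SNPs, computed from the eigenvalues lambda_i of their correlation matrix as
m_e(j) = j - sum_i [lambda_i > 1](lambda_i - 1). The SNP p-value
correlation is approximated from the dosage correlation matrix, by default
through the even polynomial map of the method's defining reference (which
keeps the null calibrated under LD); the raw dosage correlation is
available as a cruder alternative. Gene-level multiplicity is handled by
Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "AssocResult",
    "GeneResult",
    "pca_covariates",
    "snp_regression",
    "run_gwas",
    "gates_gene_p",
    "select_pca_count",
    "bonferroni",
]


@dataclass
class AssocResult:
    """Per-SNP OLS results for one phenotype."""

    snp_p: np.ndarray
    betas: np.ndarray
    covariate_spec: list[str]
    constant_snps: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.snp_p = np.asarray(self.snp_p, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.snp_p) != len(self.betas):
            raise ValueError("snp_p and betas must have equal length")
        if ((self.snp_p <= 0) | (self.snp_p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")


@dataclass
class GeneResult:
    """GATES gene-level p-value with its effective number of tests."""

    gene_p: float
    m_e: float
    corrected_p: float
    gene_id: str | None = None


def pca_covariates(dosages: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of the column-standardised dosages.

    Signs are fixed so each component's largest-magnitude loading is
    positive, making the scores reproducible across runs and platforms.
    """
    x = np.asarray(dosages, dtype=float)
    n, p = x.shape
    if not (1 <= k <= min(n, p)):
        raise ValueError(f"k must lie in [1, {min(n, p)}], got {k}")
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant columns carry no stratification signal
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def snp_regression(
    dosage_col: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """OLS of phenotype on dosage + covariates + intercept.

    Returns ``(beta, p)`` with a two-sided t-test p-value for the dosage
    coefficient. A constant dosage column is untestable and yields
    ``(0.0, 1.0)``.
    """
    g = np.asarray(dosage_col, dtype=float).ravel()
    y = np.asarray(phenotype, dtype=float).ravel()
    n_cov = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    if len(g) < n_cov + 3:
        raise ValueError("too few participants for the requested covariates")
    if np.ptp(g) == 0:
        return 0.0, 1.0
    cols = [g] if covariates is None else [g, np.asarray(covariates, dtype=float).reshape(len(g), -1)]
    design = sm.add_constant(np.column_stack(cols), prepend=False)
    fit = sm.OLS(y, design).fit()
    p = float(fit.pvalues[0])
    return float(fit.params[0]), max(p, np.finfo(float).tiny)


def run_gwas(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> AssocResult:
    """Per-SNP :func:`snp_regression` over every dosage column."""
    x = np.asarray(dosages, dtype=float)
    betas = np.empty(x.shape[1])
    pvals = np.empty(x.shape[1])
    constant = np.zeros(x.shape[1], dtype=bool)
    for j in range(x.shape[1]):
        constant[j] = np.ptp(x[:, j]) == 0
        betas[j], pvals[j] = snp_regression(x[:, j], phenotype, covariates)
    return AssocResult(
        snp_p=pvals,
        betas=betas,
        covariate_spec=list(covariate_names or []),
        constant_snps=constant,
    )


def _pvalue_correlation(r: np.ndarray) -> np.ndarray:
    """Approximate p-value correlation from genotype correlation.

    Polynomial fit from the GATES reference, applied to |r| (two-sided
    p-values make the relation even in r); exactly collinear SNPs
    (|r| = 1) have identical p-values, so their entry is pinned at 1.
    """
    a = np.abs(r)
    rp = (0.2982 * a**6 - 0.0127 * a**5 + 0.0588 * a**4
          + 0.0099 * a**3 + 0.6281 * a**2 - 0.0009 * a)
    rp[a >= 1.0 - 1e-12] = 1.0
    return rp


def _effective_tests(corr: np.ndarray) -> float:
    """m_e = m - sum over eigenvalues > 1 of (lambda - 1), clipped to >= 1."""
    lam = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    m = corr.shape[0]
    m_e = m - float(np.sum(np.clip(lam - 1.0, 0.0, None)))
    return float(np.clip(m_e, 1.0, m))


def gates_gene_p(
    snp_ps: np.ndarray,
    dosage_block: np.ndarray,
    gene_id: str | None = None,
    n_genes: int = 1,
    pvalue_corr: str = "polynomial",
) -> GeneResult:
    """GATES (extended Simes) gene-level p-value.

    ``snp_ps`` are the gene's per-SNP p-values and ``dosage_block`` the
    matching dosage columns, used to approximate the p-value correlation:
    ``pvalue_corr="polynomial"`` (default) maps the dosage correlation
    through the reference polynomial, ``"genotype"`` uses it directly.
    With independent SNPs this reduces to the Simes statistic
    ``min_j m * p_(j) / j``; with perfectly correlated SNPs m_e = 1 and the
    gene p-value is the minimum SNP p-value.
    """
    p = np.asarray(snp_ps, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(dosage_block, dtype=float))
    if x.shape[1] != len(p):
        raise ValueError(f"{len(p)} p-values but {x.shape[1]} dosage columns")
    if len(p) == 0:
        raise ValueError("need at least one SNP p-value")
    m = len(p)
    if m == 1:
        gp = float(p[0])
        return GeneResult(gene_p=gp, m_e=1.0, corrected_p=bonferroni(gp, n_genes), gene_id=gene_id)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    corr = np.clip((z.T @ z) / x.shape[0], -1.0, 1.0)
    if pvalue_corr == "polynomial":
        corr = _pvalue_correlation(corr)
    elif pvalue_corr != "genotype":
        raise ValueError("pvalue_corr must be 'polynomial' or 'genotype'")
    np.fill_diagonal(corr, 1.0)
    corr = corr[np.ix_(order, order)]
    m_e_total = _effective_tests(corr)
    gene_p = np.inf
    for j in range(1, m + 1):
        m_e_j = _effective_tests(corr[:j, :j])
        gene_p = min(gene_p, m_e_total * p_sorted[j - 1] / m_e_j)
    gene_p = float(np.clip(gene_p, np.finfo(float).tiny, 1.0))
    return GeneResult(
        gene_p=gene_p,
        m_e=m_e_total,
        corrected_p=bonferroni(gene_p, n_genes),
        gene_id=gene_id,
    )


def select_pca_count(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    candidate_gene_cols: np.ndarray,
    k_range: range = range(1, 21),
) -> int:
    """Number of PCs minimising the candidate gene's GATES p-value.

    For each k in ``k_range`` the candidate gene's SNPs are re-tested with
    base covariates plus k genotype PCs; the k giving the smallest gene
    p-value wins (ties to the smallest k).
    """
    cols = np.asarray(candidate_gene_cols, dtype=int)
    if len(cols) < 1:
        raise ValueError("candidate gene must have at least one SNP")
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    best_k, best_p = None, np.inf
    for k in ks:
        pcs = pca_covariates(dosages, k)
        cov = pcs if covariates is None else np.column_stack([np.asarray(covariates), pcs])
        res = run_gwas(np.asarray(dosages)[:, cols], phenotype, cov)
        gene_p = gates_gene_p(res.snp_p, np.asarray(dosages)[:, cols]).gene_p
        if gene_p < best_p:  # strict: ties keep the smaller, earlier k
            best_k, best_p = k, gene_p
    return int(best_k)


def bonferroni(p: float, n_tests: int) -> float:
    """min(1, n_tests * p)."""
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(min(1.0, n_tests * p))
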