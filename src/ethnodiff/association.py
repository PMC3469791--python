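"""Case-control association testing under an additive genetic model.

Each SNP is tested by unconditional logistic regression of case status on
allele dosage (0/1/2 copies of the coded allele) plus covariates, typically
principal components computed from the genotype matrix to adjust for
population stratification. Effects are reported as per-allele odds ratios
with Wald 95% confidence intervals; one-sided p-values follow a
prespecified direction hypothesis (here, that the allele enriched in the
comparison populations is protective).

Also provided: conditional testing (adding another SNP's dosage as a
covariate, to ask whether a signal is separate from a known hit) and
pairwise linkage-disequilibrium estimation (D', r^2) via EM haplotype
frequency estimation from unphased genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotypes import GenotypeMatrix, PhenotypeTable

__all__ = [
    "AssociationResult",
    "fit_additive_logistic",
    "code_minor_allele",
    "compute_stratification_pcs",
    "conditional_test",
    "estimate_ld",
]

_Z975 = stats.norm.ppf(0.975)
_SEPARATION_BETA = 15.0  # |log-OR| beyond this is treated as (quasi-)separation


@dataclass
class AssociationResult:
    """Per-SNP additive logistic-regression estimate.

    ``p_one_sided`` halves the two-sided Wald p when the estimated effect
    direction matches ``hypothesized_sign`` (sign of beta expected under
    the study hypothesis for the coded allele), else 1 - p_two/2. With no
    hypothesis stated it is left None.
    """

    snp_id: str
    beta: float
    se: float
    n_used: int
    converged: bool = True
    coded_allele: Optional[str] = None
    hypothesized_sign: Optional[int] = None

    @property
    def or_hat(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> Tuple[float, float]:
        return (
            float(np.exp(self.beta - _Z975 * self.se)),
            float(np.exp(self.beta + _Z975 * self.se)),
        )

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 else np.nan

    @property
    def p_two_sided(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    @property
    def p_one_sided(self) -> Optional[float]:
        if self.hypothesized_sign is None:
            return None
        if np.sign(self.beta) == self.hypothesized_sign or self.beta == 0:
            return self.p_two_sided / 2.0
        return 1.0 - self.p_two_sided / 2.0


def _fit_logit(y: np.ndarray, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Logit MLE via statsmodels; returns (beta, se, converged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception:
            return np.full(X.shape[1], np.nan), np.full(X.shape[1], np.nan), False
    converged = bool(res.mle_retvals.get("converged", True))
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        converged = False
    if np.any(np.abs(params[1:]) > _SEPARATION_BETA):
        converged = False
    return params, bse, converged


def fit_additive_logistic(
    dosage: np.ndarray,
    phenotype: PhenotypeTable,
    covariates: Optional[np.ndarray] = None,
    snp_id: str = "",
    coded_allele: Optional[str] = None,
    hypothesized_sign: Optional[int] = None,
) -> AssociationResult:
    """Per-allele log-odds of disease from an additive logistic model.

    Samples with a missing dosage are dropped for this SNP. Requires at
    least one case and one control among the complete observations and a
    non-constant dosage. Non-convergence or separation is flagged on the
    result rather than raised.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = phenotype.status.astype(float)
    if covariates is None and len(phenotype.covariates):
        covariates = phenotype.covariates.to_numpy(dtype=float)
    keep = ~np.isnan(dosage)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(dosage):
            covariates = covariates.T
        keep &= ~np.isnan(covariates).any(axis=1)
    d, yk = dosage[keep], y[keep]
    if yk.sum() < 1 or (1 - yk).sum() < 1:
        raise ValueError(f"SNP {snp_id or '?'}: need at least one case and one control")
    if np.ptp(d) == 0:
        raise ValueError(f"SNP {snp_id or '?'}: constant dosage")
    cols = [np.ones_like(d), d]
    if covariates is not None:
        cols.extend(covariates[keep].T)
    X = np.column_stack(cols)
    params, bse, converged = _fit_logit(yk, X)
    return AssociationResult(
        snp_id=snp_id,
        beta=float(params[1]),
        se=float(bse[1]),
        n_used=int(keep.sum()),
        converged=converged,
        coded_allele=coded_allele,
        hypothesized_sign=hypothesized_sign,
    )


def code_minor_allele(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Re-code every SNP so dosage counts the minor allele.

    Minor status is determined in the full sample; an exact 0.5 tie keeps
    the lexicographically smaller allele label as coded.
    """
    freq = geno.coded_allele_freq()
    coded = list(geno.coded_alleles) if geno.coded_alleles else ["A"] * geno.n_snps
    other = list(geno.other_alleles) if geno.other_alleles else ["B"] * geno.n_snps
    dosages = geno.dosages.copy()
    for i in range(geno.n_snps):
        flip = freq[i] > 0.5 or (freq[i] == 0.5 and other[i] < coded[i])
        if flip:
            dosages[i] = 2.0 - dosages[i]
            coded[i], other[i] = other[i], coded[i]
    return GenotypeMatrix(
        snp_ids=list(geno.snp_ids),
        sample_ids=list(geno.sample_ids),
        dosages=dosages,
        coded_alleles=coded,
        other_alleles=other,
        chrom=list(geno.chrom) if geno.chrom else None,
        pos=geno.pos.copy() if geno.pos is not None else None,
    )


def compute_stratification_pcs(geno: GenotypeMatrix, k: int = 2) -> pd.DataFrame:
    """Sample principal components from standardized dosages.

    Missing dosages are mean-imputed per SNP; each SNP is centred by twice
    its allele frequency and scaled by sqrt(2 p (1-p)) (the EIGENSTRAT
    normalisation); zero-variance SNPs are excluded. Returns the top-k
    left-singular sample loadings as columns PC1..PCk (orthonormal).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = geno.dosages.copy()
    means = np.nanmean(d, axis=1)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(means, inds[0])
    p = means / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = (scale > 0) & (np.ptp(d, axis=1) > 0)
    if keep.sum() == 0:
        raise ValueError("no polymorphic SNPs available for PCA")
    z = (d[keep] - 2.0 * p[keep, None]) / scale[keep, None]
    # samples x snps, as in sample-covariance PCA
    u, s, _ = np.linalg.svd(z.T, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    return pd.DataFrame(
        u[:, :k], columns=[f"PC{j + 1}" for j in range(k)], index=geno.sample_ids
    )


def conditional_test(
    geno: GenotypeMatrix,
    target_snp: str,
    conditioning_snp: str,
    phenotype: PhenotypeTable,
    covariates: Optional[np.ndarray] = None,
    hypothesized_sign: Optional[int] = None,
) -> AssociationResult:
    """Association of the target SNP conditional on another SNP's dosage.

    The conditioning SNP enters the model as an extra covariate, so the
    reported p asks whether the target carries signal beyond it. Samples
    missing either dosage are dropped; identical dosage columns are
    rejected as collinear.
    """
    target = geno.dosage_of(target_snp)
    cond = geno.dosage_of(conditioning_snp)
    both = ~np.isnan(target) & ~np.isnan(cond)
    if np.array_equal(target[both], cond[both]):
        raise ValueError(
            f"dosages of {target_snp} and {conditioning_snp} are identical (collinear)"
        )
    extra = cond[:, None]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(target):
            covariates = covariates.T
        extra = np.column_stack([extra, covariates])
    return fit_additive_logistic(
        target,
        phenotype,
        covariates=extra,
        snp_id=target_snp,
        hypothesized_sign=hypothesized_sign,
    )


def _em_haplotype_freqs(counts: np.ndarray, tol: float = 1e-12, max_iter: int = 2000):
    """EM haplotype frequencies for two biallelic loci.

    ``counts[i, j]`` is the number of individuals with dosage i at locus 1
    and j at locus 2. Returns (p11, p10, p01, p00): frequencies of the four
    haplotypes, '1' meaning the coded allele at that locus.
    """
    n = counts.sum()
    if n == 0:
        raise ValueError("empty genotype table")
    # haplotype counts certain from unambiguous genotypes
    fixed11 = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    fixed10 = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    fixed01 = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    fixed00 = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    dbl_het = counts[1, 1]
    h = np.array([fixed11, fixed10, fixed01, fixed00], dtype=float) + dbl_het / 2.0
    p = h / h.sum()
    for _ in range(max_iter):
        denom = p[0] * p[3] + p[1] * p[2]
        alpha = 0.5 if denom == 0 else p[0] * p[3] / denom  # P(phase is 11/00)
        h = np.array(
            [
                fixed11 + dbl_het * alpha,
                fixed10 + dbl_het * (1 - alpha),
                fixed01 + dbl_het * (1 - alpha),
                fixed00 + dbl_het * alpha,
            ]
        )
        p_new = h / (2.0 * n)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    return tuple(p)


def estimate_ld(dosage1: np.ndarray, dosage2: np.ndarray) -> Tuple[float, float]:
    """(D', r^2) between two SNPs from unphased dosages.

    Haplotype frequencies are estimated by EM over the 3x3 genotype table
    (samples missing either dosage dropped); D = p11 - p1 p2, D' = |D| /
    Dmax with the standard sign-dependent Dmax, r^2 = D^2 / (p1 q1 p2 q2).
    Both are invariant to allele relabelling at either locus.
    """
    d1 = np.asarray(dosage1, dtype=float)
    d2 = np.asarray(dosage2, dtype=float)
    both = ~np.isnan(d1) & ~np.isnan(d2)
    d1, d2 = d1[both], d2[both]
    if len(d1) == 0:
        raise ValueError("no samples with both dosages observed")
    counts = np.zeros((3, 3), dtype=int)
    for i in range(3):
        for j in range(3):
            counts[i, j] = int(((d1 == i) & (d2 == j)).sum())
    p1 = d1.mean() / 2.0
    p2 = d2.mean() / 2.0
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("monomorphic SNP: LD undefined")
    p11, _, _, _ = _em_haplotype_freqs(counts)
    D = p11 - p1 * p2
    if D >= 0:
        dmax = min(p1 * (1 - p2), (1 - p1) * p2)
    else:
        dmax = min(p1 * p2, (1 - p1) * (1 - p2))
    d_prime = 0.0 if dmax == 0 else abs(D) / dmax
    r_squared = D * D / (p1 * (1 - p1) * p2 * (1 - p2))
    return float(min(d_prime, 1.0)), float(min(r_squared, 1.0))
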