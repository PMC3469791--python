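"""Fixed-effects inverse-variance meta-analysis with Cochran's Q.

Per-study log odds ratios beta_i with standard errors se_i are pooled as

    w_i = 1 / se_i^2
    beta_pooled = sum(w_i beta_i) / sum(w_i),   se_pooled = 1 / sqrt(sum w_i)

assuming one common underlying effect. Heterogeneity is assessed by
Cochran's Q = sum w_i (beta_i - beta_pooled)^2, chi-square with
(n_studies - 1) degrees of freedom under homogeneity. Studies whose data
are unavailable for a SNP are simply dropped before pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
from scipy import stats

__all__ = ["StudyEstimate", "MetaResult", "pool_fixed_effects", "se_from_ci"]

_Z975 = stats.norm.ppf(0.975)


def se_from_ci(or_hat: float, ci_low: float, ci_high: float) -> float:
    """Standard error of the log-OR from a two-sided 95% CI.

    se = (ln U - ln L) / (2 * 1.959964); requires 0 < L <= OR <= U with
    L < U strictly.
    """
    if not (0 < ci_low <= or_hat <= ci_high):
        raise ValueError("CI must satisfy 0 < low <= OR <= high")
    if ci_low == ci_high:
        raise ValueError("degenerate confidence interval")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * _Z975)


@dataclass
class StudyEstimate:
    """One study's log-OR and its standard error.

    Construct from a printed OR and CI via :meth:`from_or_ci` when raw
    estimates are unavailable.
    """

    study_label: str
    beta: float
    se: float
    n_cases: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")

    @classmethod
    def from_or_ci(
        cls,
        study_label: str,
        or_hat: float,
        ci_low: float,
        ci_high: float,
        n_cases: Optional[int] = None,
    ) -> "StudyEstimate":
        return cls(study_label, math.log(or_hat), se_from_ci(or_hat, ci_low, ci_high), n_cases)


@dataclass
class MetaResult:
    pooled_beta: float
    pooled_se: float
    n_studies: int
    q_stat: Optional[float] = None
    hypothesized_sign: Optional[int] = None

    @property
    def pooled_or(self) -> float:
        return float(np.exp(self.pooled_beta))

    @property
    def ci95(self) -> Tuple[float, float]:
        return (
            float(np.exp(self.pooled_beta - _Z975 * self.pooled_se)),
            float(np.exp(self.pooled_beta + _Z975 * self.pooled_se)),
        )

    @property
    def df(self) -> int:
        return self.n_studies - 1

    @property
    def p_het(self) -> Optional[float]:
        if self.q_stat is None or self.df < 1:
            return None
        return float(stats.chi2.sf(self.q_stat, self.df))

    @property
    def z(self) -> float:
        return self.pooled_beta / self.pooled_se

    @property
    def p_two_sided(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    @property
    def p_one_sided(self) -> Optional[float]:
        if self.hypothesized_sign is None:
            return None
        if np.sign(self.pooled_beta) == self.hypothesized_sign or self.pooled_beta == 0:
            return self.p_two_sided / 2.0
        return 1.0 - self.p_two_sided / 2.0


def pool_fixed_effects(
    estimates: Iterable[StudyEstimate],
    hypothesized_sign: Optional[int] = None,
) -> MetaResult:
    """Inverse-variance fixed-effects pooling of study log-ORs.

    With a single study the pooled estimate equals the input and Q is
    reported as not applicable (None). Estimates with non-finite standard
    errors are dropped.
    """
    kept: List[StudyEstimate] = [
        e for e in estimates if np.isfinite(e.beta) and np.isfinite(e.se) and e.se > 0
    ]
    if not kept:
        raise ValueError("no usable study estimates")
    betas = np.array([e.beta for e in kept])
    weights = np.array([1.0 / e.se**2 for e in kept])
    pooled = float(np.sum(weights * betas) / np.sum(weights))
    pooled_se = float(1.0 / np.sqrt(np.sum(weights)))
    if len(kept) == 1:
        return MetaResult(pooled, pooled_se, 1, None, hypothesized_sign)
    q = float(np.sum(weights * (betas - pooled) ** 2))
    return MetaResult(pooled, pooled_se, len(kept), q, hypothesized_sign)
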