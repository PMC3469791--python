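"""Genotypic-relative-risk to incidence-rate-ratio attribution.

A single biallelic locus with per-genotype relative risks (1, g1, g2) for
0/1/2 copies of the risk allele implies, under Hardy-Weinberg proportions,
a *normalized incidence rate* for a population with risk-allele frequency p:

    R(p) = q^2 * 1 + 2pq * g1 + p^2 * g2,      q = 1 - p.

The ratio R(p_A) / R(p_B) for two populations A and B is the incidence rate
ratio (IRR) attributable to the locus: the factor by which disease incidence
in A would exceed incidence in B if the locus were the only cause of the
difference and genotype fully determined relative risk.

Per-allele odds ratios from case-control studies are mapped onto a GRR model
by one of two scales:

* ``additive_risk``: g1 = OR, g2 = 1 + 2(OR - 1) — risk increments add per
  allele copy on the relative-risk scale.
* ``multiplicative``: g1 = OR, g2 = OR^2.

The additive scale is not invariant to which allele is labelled the risk
allele, so inputs are first oriented so the per-allele OR is >= 1
(frequencies complemented, OR reciprocated when OR < 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Tuple

import pandas as pd

__all__ = [
    "GRRModel",
    "IrrResult",
    "orient_to_risk_allele",
    "normalized_rate",
    "incidence_rate_ratio",
    "irr_surface",
]


@dataclass(frozen=True)
class GRRModel:
    """Genotypic relative risks for 0, 1 and 2 copies of the risk allele.

    ``g0`` is fixed at 1 (the reference genotype). Use the classmethods to
    derive ``g1``/``g2`` from a per-allele odds ratio on a named scale, or
    pass both explicitly.
    """

    g1: float
    g2: float
    scale: str = "explicit"
    g0: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        if not (self.g1 > 0 and self.g2 > 0):
            raise ValueError("genotypic relative risks must be positive")

    @classmethod
    def from_per_allele_or(cls, per_allele_or: float, scale: str = "additive_risk") -> "GRRModel":
        """Build a GRR model with heterozygote risk equal to the per-allele OR."""
        if per_allele_or <= 0:
            raise ValueError("per-allele odds ratio must be positive")
        if scale == "additive_risk":
            return cls(per_allele_or, 1.0 + 2.0 * (per_allele_or - 1.0), scale)
        if scale == "multiplicative":
            return cls(per_allele_or, per_allele_or**2, scale)
        raise ValueError(f"unknown GRR scale: {scale!r}")

    def risk(self, n_risk_alleles: int) -> float:
        return (self.g0, self.g1, self.g2)[n_risk_alleles]


@dataclass(frozen=True)
class IrrResult:
    """Risk-allele frequencies, per-group normalized rates and pairwise IRRs."""

    risk_allele_freqs: Mapping[str, float]
    normalized_rates: Mapping[str, float]
    irr: Mapping[Tuple[str, str], float]


def orient_to_risk_allele(
    ref_allele_freqs: Mapping[str, float], per_allele_or: float
) -> Tuple[dict, float]:
    """Re-express a locus so its per-allele odds ratio is >= 1.

    If the stated allele is protective (OR < 1) the *other* allele is the
    risk allele: frequencies are complemented and the OR reciprocated.
    Idempotent for OR >= 1.
    """
    if per_allele_or <= 0:
        raise ValueError("per-allele odds ratio must be positive")
    for group, freq in ref_allele_freqs.items():
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"frequency for group {group!r} outside [0, 1]: {freq}")
    if per_allele_or >= 1.0:
        return dict(ref_allele_freqs), per_allele_or
    return {g: 1.0 - f for g, f in ref_allele_freqs.items()}, 1.0 / per_allele_or


def normalized_rate(p_risk: float, grr: GRRModel) -> float:
    """HWE-weighted mean relative risk at risk-allele frequency ``p_risk``.

    R(p) = q^2 g0 + 2pq g1 + p^2 g2 with q = 1 - p. Proportional to
    population disease incidence under the single-locus model.
    """
    if not 0.0 <= p_risk <= 1.0:
        raise ValueError("risk-allele frequency outside [0, 1]")
    p, q = p_risk, 1.0 - p_risk
    return q * q * grr.g0 + 2.0 * p * q * grr.g1 + p * p * grr.g2


def incidence_rate_ratio(
    freqs_by_group: Mapping[str, float],
    per_allele_or: float,
    pair: Tuple[str, str],
    grr_scale: str = "additive_risk",
) -> float:
    """IRR between an ordered pair of groups attributable to one locus.

    ``freqs_by_group`` are frequencies of any consistently chosen allele;
    the computation first orients to the risk allele, so the result does not
    depend on the labelling.
    """
    a, b = pair
    for g in pair:
        if g not in freqs_by_group:
            raise KeyError(f"group {g!r} absent from frequency map")
    risk_freqs, oriented_or = orient_to_risk_allele(freqs_by_group, per_allele_or)
    grr = GRRModel.from_per_allele_or(oriented_or, grr_scale)
    return normalized_rate(risk_freqs[a], grr) / normalized_rate(risk_freqs[b], grr)


def attribute_irr(
    freqs_by_group: Mapping[str, float],
    per_allele_or: float,
    pairs: Iterable[Tuple[str, str]],
    grr_scale: str = "additive_risk",
) -> IrrResult:
    """Full attribution for one locus: oriented frequencies, rates, IRRs."""
    risk_freqs, oriented_or = orient_to_risk_allele(freqs_by_group, per_allele_or)
    grr = GRRModel.from_per_allele_or(oriented_or, grr_scale)
    rates = {g: normalized_rate(p, grr) for g, p in risk_freqs.items()}
    irrs = {}
    for a, b in pairs:
        if a not in rates or b not in rates:
            raise KeyError(f"pair ({a!r}, {b!r}) references unknown group")
        irrs[(a, b)] = rates[a] / rates[b]
    return IrrResult(risk_freqs, rates, irrs)


def irr_surface(
    grr_values: Sequence[GRRModel],
    freq_grid: Sequence[Tuple[float, float]],
) -> pd.DataFrame:
    """Evaluate the two-group IRR over a grid of GRR models and frequency pairs.

    ``freq_grid`` holds (p_group1, p_group2) risk-allele frequencies. Returns
    a tidy frame with one row per (GRR, frequency-pair) combination, suitable
    for contour/line plotting of the IRR landscape.
    """
    if not grr_values or not freq_grid:
        raise ValueError("grr_values and freq_grid must be nonempty")
    rows = []
    for grr, (p1, p2) in itertools.product(grr_values, freq_grid):
        rows.append(
            {
                "g1": grr.g1,
                "g2": grr.g2,
                "p_risk_group1": p1,
                "p_risk_group2": p2,
                "irr": normalized_rate(p1, grr) / normalized_rate(p2, grr),
            }
        )
    return pd.DataFrame(rows)
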