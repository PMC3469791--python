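"""Inter-group allele-frequency differences and candidate-SNP categories.

For each SNP the reference-allele frequency difference is taken between a
baseline group (Whites) and each of two comparison groups (East Asians,
Africans). When the two differences share a sign, their mean absolute value
places the SNP in one of three primary-hypothesis categories:

* HIGHEST  — mean difference >= 0.70
* HIGH     — 0.60 <= mean difference < 0.70
* MODERATE — 0.40 <= mean difference < 0.60

A secondary hypothesis captures loci differentiated against only one
comparison group: HIGHEST_LOW when exactly one absolute difference is
>= 0.70 while the other is < 0.40 (direction agreement not required).

Multiple-testing thresholds allocate a study-wide alpha (default 0.05)
equally across the four categories, then Bonferroni-correct within each
category: threshold = (alpha / 4) / n_category.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .panel import PopulationFrequencyRecord, PopulationPanel, pool_groups

__all__ = [
    "Category",
    "DifferenceProfile",
    "CategoryThresholds",
    "difference_profile",
    "categorize",
    "category_thresholds",
    "select_candidates",
]

DEFAULT_GROUP_ORDER = ("White", "EastAsian", "African")


class Category(str, enum.Enum):
    HIGHEST = "HIGHEST"
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    HIGHEST_LOW = "HIGHEST_LOW"
    NONE = "NONE"


@dataclass
class DifferenceProfile:
    """Pairwise reference-allele frequency differences for one SNP.

    ``d_we`` = baseline minus first comparison group (White - East Asian),
    ``d_wa`` = baseline minus second (White - African). ``mean_abs_diff``
    is defined only when both differences are nonzero and share a sign.
    """

    snp_id: str
    d_we: Optional[float] = None
    d_wa: Optional[float] = None
    usable: bool = True
    category: Category = Category.NONE

    @property
    def same_direction(self) -> bool:
        if not self.usable:
            return False
        return self.d_we * self.d_wa > 0

    @property
    def mean_abs_diff(self) -> Optional[float]:
        if not self.same_direction:
            return None
        return (abs(self.d_we) + abs(self.d_wa)) / 2.0


@dataclass
class CategoryThresholds:
    """Per-category Bonferroni thresholds under equal alpha allocation."""

    study_alpha: float
    counts: Dict[Category, int]
    thresholds: Dict[Category, float]

    @property
    def per_subgroup_alpha(self) -> float:
        return self.study_alpha / 4.0

    def threshold_for(self, category: Category) -> Optional[float]:
        return self.thresholds.get(category)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": c.value,
                "n_snps": self.counts.get(c, 0),
                "threshold": self.thresholds.get(c),
            }
            for c in (Category.HIGHEST, Category.HIGH, Category.MODERATE, Category.HIGHEST_LOW)
        ]
        return pd.DataFrame(rows)


def difference_profile(
    record: PopulationFrequencyRecord,
    group_order: Sequence[str] = DEFAULT_GROUP_ORDER,
) -> DifferenceProfile:
    """Signed frequency differences of the reference allele for one SNP.

    ``group_order`` names (baseline, comparison1, comparison2). A missing
    group frequency yields an unusable profile (category NONE downstream).
    """
    base, comp1, comp2 = group_order
    f_base = record.frequency(base)
    f_c1 = record.frequency(comp1)
    f_c2 = record.frequency(comp2)
    if f_base is None or f_c1 is None or f_c2 is None:
        return DifferenceProfile(snp_id=record.snp_id, usable=False)
    return DifferenceProfile(
        snp_id=record.snp_id,
        d_we=f_base - f_c1,
        d_wa=f_base - f_c2,
    )


def categorize(
    profile: DifferenceProfile,
    highest_min: float = 0.70,
    high_min: float = 0.60,
    moderate_min: float = 0.40,
) -> Category:
    """Assign a candidate category from a difference profile.

    Same-direction SNPs are classed by mean absolute difference (lower
    bounds closed, upper bounds open). Regardless of direction agreement, a
    SNP whose two absolute differences straddle the HIGHEST and Low bounds
    (one >= 0.70, the other < 0.40) is HIGHEST_LOW; when a same-direction
    SNP satisfies both readings the mean-difference category wins.
    """
    if not profile.usable:
        return Category.NONE
    abs_we, abs_wa = abs(profile.d_we), abs(profile.d_wa)
    highest_low = (abs_we >= highest_min) != (abs_wa >= highest_min) and min(abs_we, abs_wa) < moderate_min
    if profile.same_direction:
        m = profile.mean_abs_diff
        if m >= highest_min:
            return Category.HIGHEST
        if m >= high_min:
            return Category.HIGH
        if m >= moderate_min:
            return Category.MODERATE
        if highest_low:
            return Category.HIGHEST_LOW
        return Category.NONE
    if highest_low:
        return Category.HIGHEST_LOW
    return Category.NONE


def category_thresholds(
    counts: Mapping[Category, int], study_alpha: float = 0.05
) -> CategoryThresholds:
    """Per-category significance thresholds: (study_alpha / 4) / n_snps.

    The study-wide alpha is split equally over the four candidate
    categories, then Bonferroni-divided by each category's SNP count.
    Categories with zero SNPs receive no threshold.
    """
    if not 0 < study_alpha < 1:
        raise ValueError("study_alpha must lie in (0, 1)")
    clean: Dict[Category, int] = {}
    for cat, n in counts.items():
        cat = Category(cat)
        if cat is Category.NONE:
            continue
        if n < 0:
            raise ValueError(f"negative SNP count for {cat}")
        clean[cat] = int(n)
    per_subgroup = study_alpha / 4.0
    thresholds = {cat: per_subgroup / n for cat, n in clean.items() if n > 0}
    return CategoryThresholds(study_alpha=study_alpha, counts=clean, thresholds=thresholds)


def profile_panel(
    panel: PopulationPanel, group_order: Sequence[str] = DEFAULT_GROUP_ORDER
) -> List[DifferenceProfile]:
    """Difference profiles (with categories) for every SNP in a panel."""
    pooled = pool_groups(panel) if any(
        len(src) > 1 or g != src[0] for g, src in panel.group_definitions.items()
    ) else panel
    profiles = []
    for record in pooled.records:
        prof = difference_profile(record, group_order)
        prof.category = categorize(prof)
        profiles.append(prof)
    return profiles


def select_candidates(
    panel: PopulationPanel, group_order: Sequence[str] = DEFAULT_GROUP_ORDER
) -> List[DifferenceProfile]:
    """Profiles of SNPs falling in any candidate category (category != NONE)."""
    return [p for p in profile_panel(panel, group_order) if p.category is not Category.NONE]


def category_counts(profiles: Sequence[DifferenceProfile]) -> Dict[Category, int]:
    counts = {c: 0 for c in Category if c is not Category.NONE}
    for p in profiles:
        if p.category is not Category.NONE:
            counts[p.category] += 1
    return counts


def profiles_to_frame(profiles: Sequence[DifferenceProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [p.snp_id for p in profiles],
            "d_we": [p.d_we for p in profiles],
            "d_wa": [p.d_wa for p in profiles],
            "same_direction": [p.same_direction for p in profiles],
            "mean_abs_diff": [p.mean_abs_diff for p in profiles],
            "category": [p.category.value for p in profiles],
        }
    )


def format_threshold(threshold: float, sig_figs: int = 3) -> str:
    """Render a threshold at a fixed number of significant figures."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exponent = math.floor(math.log10(threshold))
    mantissa = round(threshold / 10**exponent, sig_figs - 1)
    if mantissa >= 10:  # rounding carried into the next decade
        mantissa /= 10
        exponent += 1
    return f"{mantissa:.{sig_figs - 1}f}e{exponent:+03d}"
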