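"""Synthetic multi-population panels and case-control cohorts.

The generator provides data with the statistical structure the analysis
assumes, so the whole pipeline is testable without external cohorts:

* **Allele frequencies** follow the Balding-Nichols model: each SNP has an
  ancestral frequency p drawn uniformly from a configurable range, and each
  population's frequency is Beta-distributed with mean p and variance
  F * p * (1 - p), where F is that population's differentiation parameter
  (an F_ST analogue). Loci are independent — no linkage disequilibrium.
* **Genotypes** are Hardy-Weinberg draws within each population, with
  missing-completely-at-random dropout.
* **Disease** follows a genotypic-relative-risk model: a subject's disease
  probability is a baseline risk multiplied, over each planted risk SNP, by
  the GRR of the subject's genotype (risks multiply across loci,
  i.e. loci act independently). Cases and controls are sampled from the
  population until the requested quotas are met; unplanted SNPs are null.

All randomness flows from one integer seed; each operation derives its own
named sub-stream, so panels, genotype matrices and cohorts are individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .genotypes import GenotypeMatrix, PhenotypeTable
from .irr import GRRModel
from .panel import GroupStats, PopulationFrequencyRecord, PopulationPanel

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "simulate_frequency_panel",
    "simulate_genotypes",
    "simulate_case_control",
    "empirical_incidence",
]

_STREAMS = {"panel": 0, "genotypes": 1, "case_control": 2, "incidence": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class PlantedEffect:
    """A causal SNP planted into the disease model.

    ``risk_allele`` names which allele carries risk: "A" (the panel's
    reference allele) or "B" (the other allele). ``per_allele_or`` maps to
    genotype relative risks on ``grr_scale`` (see :class:`GRRModel`).
    """

    snp_index: int
    per_allele_or: float
    risk_allele: str = "B"
    grr_scale: str = "multiplicative"

    def __post_init__(self) -> None:
        if self.per_allele_or <= 0:
            raise ValueError("per_allele_or must be positive")
        if self.risk_allele not in ("A", "B"):
            raise ValueError("risk_allele must be 'A' or 'B'")

    @property
    def grr(self) -> GRRModel:
        return GRRModel.from_per_allele_or(self.per_allele_or, self.grr_scale)


@dataclass
class SimulationConfig:
    """All knobs for one synthetic study.

    ``group_sizes`` gives diploid sample counts per population for genotype
    panels and the population mix for case-control sampling;
    ``fst_per_group`` the Balding-Nichols differentiation per population.
    """

    n_snps: int = 100
    group_sizes: Dict[str, int] = field(
        default_factory=lambda: {"White": 215, "EastAsian": 250, "African": 257}
    )
    fst_per_group: Dict[str, float] = field(
        default_factory=lambda: {"White": 0.15, "EastAsian": 0.15, "African": 0.15}
    )
    ancestral_freq_range: Tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    planted_snps: List[PlantedEffect] = field(default_factory=list)
    n_cases: int = 692
    n_controls: int = 3992
    baseline_risk: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not self.group_sizes or any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        for g, f in self.fst_per_group.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"F for group {g!r} must lie in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        idx = [e.snp_index for e in self.planted_snps]
        if len(set(idx)) != len(idx):
            raise ValueError("planted SNP indices must be distinct")
        if any(i < 0 or i >= self.n_snps for i in idx):
            raise ValueError("planted SNP index out of range")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case/control counts must be positive")
        if not 0.0 < self.baseline_risk < 1.0:
            raise ValueError("baseline_risk must lie in (0, 1)")
        max_risk = self.baseline_risk
        for e in self.planted_snps:
            max_risk *= max(e.grr.g1, e.grr.g2, 1.0)
        if max_risk > 1.0:
            raise ValueError(
                f"maximum genotype disease risk {max_risk:.3f} exceeds 1; "
                "lower baseline_risk or effect sizes"
            )

    @property
    def groups(self) -> List[str]:
        return list(self.group_sizes)


def simulate_frequency_panel(config: SimulationConfig) -> PopulationPanel:
    """Balding-Nichols reference-allele frequencies for every group.

    For ancestral frequency p and differentiation F the group frequency is
    Beta(p (1-F)/F, (1-p)(1-F)/F): mean p, variance F p (1-p). Deterministic
    given ``config.seed``. Frequencies are stored as pseudo-counts over a
    large fixed chromosome total so the count-based panel TSV round-trips
    (quantization 2.5e-6, negligible for every downstream computation).
    """
    pseudo_chroms = 200_000
    rng = _rng(config.seed, "panel")
    lo, hi = config.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=config.n_snps)
    freqs = {}
    for group in config.groups:
        f = config.fst_per_group.get(group)
        if f is None:
            raise ValueError(f"no F specified for group {group!r}")
        shape = (1.0 - f) / f
        freqs[group] = rng.beta(ancestral * shape, (1.0 - ancestral) * shape)
    records = []
    for i in range(config.n_snps):
        records.append(
            PopulationFrequencyRecord(
                snp_id=f"snp{i:05d}",
                chrom="1",
                pos=(i + 1) * 1000,
                reference_allele="A",
                other_allele="B",
                groups={
                    g: GroupStats(
                        ref_count=int(round(float(freqs[g][i]) * pseudo_chroms)),
                        total_alleles=pseudo_chroms,
                        call_rate=1.0,
                    )
                    for g in config.groups
                },
            )
        )
    return PopulationPanel(records=records, group_definitions={g: [g] for g in config.groups})


def _panel_freq_matrix(panel: PopulationPanel, groups: List[str]) -> np.ndarray:
    mat = np.empty((len(panel), len(groups)))
    for i, record in enumerate(panel.records):
        for j, g in enumerate(groups):
            f = record.frequency(g)
            if f is None:
                raise ValueError(f"panel lacks frequency for group {g!r} at {record.snp_id}")
            mat[i, j] = f
    return mat


def simulate_genotypes(
    panel: PopulationPanel, config: SimulationConfig
) -> Tuple[GenotypeMatrix, Dict[str, str]]:
    """HWE genotypes per group with MCAR missingness.

    Dosages count copies of the panel's reference allele. Returns the
    matrix and a sample-id -> group map.
    """
    rng = _rng(config.seed, "genotypes")
    groups = config.groups
    freq = _panel_freq_matrix(panel, groups)
    blocks, sample_ids, sample_groups = [], [], {}
    for j, g in enumerate(groups):
        n = config.group_sizes[g]
        blocks.append(rng.binomial(2, freq[:, j][:, None], size=(len(panel), n)).astype(float))
        for k in range(n):
            sid = f"{g}_{k:04d}"
            sample_ids.append(sid)
            sample_groups[sid] = g
    dosages = np.concatenate(blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    geno = GenotypeMatrix(
        snp_ids=panel.snp_ids,
        sample_ids=sample_ids,
        dosages=dosages,
        coded_alleles=[r.reference_allele for r in panel.records],
        other_alleles=[r.other_allele for r in panel.records],
        chrom=[r.chrom for r in panel.records],
        pos=np.array([r.pos for r in panel.records]),
    )
    return geno, sample_groups


def _risk_allele_freqs(panel: PopulationPanel, effect: PlantedEffect, groups) -> np.ndarray:
    record = panel.records[effect.snp_index]
    f = np.array([record.frequency(g) for g in groups], dtype=float)
    return f if effect.risk_allele == "A" else 1.0 - f


def _draw_cohort(
    panel: PopulationPanel,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_subjects: int,
):
    """Draw group labels, planted-SNP genotypes and disease status."""
    groups = config.groups
    sizes = np.array([config.group_sizes[g] for g in groups], dtype=float)
    group_idx = rng.choice(len(groups), size=n_subjects, p=sizes / sizes.sum())
    risk = np.full(n_subjects, config.baseline_risk)
    planted_geno = {}
    for effect in config.planted_snps:
        p_risk = _risk_allele_freqs(panel, effect, groups)[group_idx]
        geno = rng.binomial(2, p_risk)
        grr = effect.grr
        risk *= np.choose(geno, [1.0, grr.g1, grr.g2])
        planted_geno[effect.snp_index] = geno
    if np.any(risk > 1.0):
        raise ValueError("a subject's disease risk exceeds 1 under the planted model")
    disease = rng.random(n_subjects) < risk
    return group_idx, planted_geno, disease


def empirical_incidence(
    panel: PopulationPanel, config: SimulationConfig, n_subjects: int = 100_000
) -> Dict[str, float]:
    """Per-group disease rates in a simulated open cohort.

    Converges to the analytic incidence-rate model as ``n_subjects`` grows;
    used to validate the attribution calculation against the generative
    process.
    """
    rng = _rng(config.seed, "incidence")
    group_idx, _, disease = _draw_cohort(panel, config, rng, n_subjects)
    rates = {}
    for j, g in enumerate(config.groups):
        mask = group_idx == j
        if mask.sum() == 0:
            raise ValueError(f"no subjects drawn for group {g!r}")
        rates[g] = float(disease[mask].mean())
    return rates


def simulate_case_control(
    panel: PopulationPanel, config: SimulationConfig
) -> Tuple[GenotypeMatrix, PhenotypeTable]:
    """Sample cases and controls under the planted GRR disease model.

    Subjects are drawn from the group mixture until the case and control
    quotas fill. Genotypes at planted SNPs are generated before the disease
    draw (they determine risk); all other SNPs are null and are filled in
    afterwards from the subject's group frequencies, which is equivalent
    because they are independent of disease status.
    """
    rng = _rng(config.seed, "case_control")
    groups = config.groups
    need_cases, need_controls = config.n_cases, config.n_controls
    kept_group, kept_status = [], []
    kept_planted: Dict[int, list] = {e.snp_index: [] for e in config.planted_snps}
    # expected draws to fill the case quota, padded; loop guards shortfall
    batch = max(2000, int(need_cases / max(config.baseline_risk, 1e-6) * 1.3))
    max_draws = 200 * (need_cases + need_controls) / max(config.baseline_risk, 1e-6)
    drawn = 0
    while need_cases > 0 or need_controls > 0:
        if drawn > max_draws:
            raise RuntimeError("case/control quotas unreachable at this baseline risk")
        group_idx, planted_geno, disease = _draw_cohort(panel, config, rng, batch)
        drawn += batch
        take_case = np.flatnonzero(disease)[:need_cases]
        take_ctrl = np.flatnonzero(~disease)[:need_controls]
        take = np.concatenate([take_case, take_ctrl])
        need_cases -= len(take_case)
        need_controls -= len(take_ctrl)
        kept_group.extend(group_idx[take])
        kept_status.extend(disease[take].astype(int))
        for idx, geno in planted_geno.items():
            kept_planted[idx].extend(geno[take])
        batch = min(batch, 500_000)
    n_total = len(kept_status)
    group_idx = np.array(kept_group)
    status = np.array(kept_status)

    freq = _panel_freq_matrix(panel, groups)
    dosages = rng.binomial(2, freq[:, group_idx], size=(len(panel), n_total)).astype(float)
    for idx, geno in kept_planted.items():
        effect = next(e for e in config.planted_snps if e.snp_index == idx)
        geno = np.array(geno, dtype=float)
        # convert risk-allele copies back to reference-allele dosage
        dosages[idx] = geno if effect.risk_allele == "A" else 2.0 - geno
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    order = np.argsort(-status, kind="stable")  # cases first, deterministic
    dosages = dosages[:, order]
    group_idx = group_idx[order]
    status = status[order]
    sample_ids = [f"S{k:06d}" for k in range(n_total)]
    geno = GenotypeMatrix(
        snp_ids=panel.snp_ids,
        sample_ids=sample_ids,
        dosages=dosages,
        coded_alleles=[r.reference_allele for r in panel.records],
        other_alleles=[r.other_allele for r in panel.records],
        chrom=[r.chrom for r in panel.records],
        pos=np.array([r.pos for r in panel.records]),
    )
    phenotypes = PhenotypeTable(
        sample_ids=sample_ids,
        status=status,
        group=[groups[j] for j in group_idx],
    )
    return geno, phenotypes
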