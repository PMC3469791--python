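"""End-to-end discovery workflow orchestration.

Stages: frequency-panel QC -> candidate selection by inter-group allele
frequency differences -> category-allocated Bonferroni thresholds ->
additive logistic association with principal-component stratification
adjustment (one-sided p) -> comparison against category thresholds ->
gene-region follow-up of sub-threshold hits (all SNPs within a flank of any
gene containing a hit, regardless of frequency-difference category) ->
direction-consistency exclusion of genes whose follow-up signals point the
wrong way -> export of replication-format rows.

Every stage output is a pure function of the inputs and the configured
seed, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .association import (
    AssociationResult,
    code_minor_allele,
    compute_stratification_pcs,
    fit_additive_logistic,
)
from .genotypes import GenotypeMatrix, PhenotypeTable
from .panel import PopulationPanel, QcReport, apply_panel_qc, load_panel
from .selection import (
    Category,
    CategoryThresholds,
    DifferenceProfile,
    category_counts,
    category_thresholds,
    profile_panel,
    profiles_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRegion",
    "PipelineConfig",
    "DiscoveryReport",
    "read_bed",
    "expand_gene_regions",
    "direction_consistency_filter",
    "hypothesized_sign",
    "run_discovery_pipeline",
]


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval (1-based, inclusive) with a symmetric flank."""

    gene_label: str
    chrom: str
    start: int
    end: int
    flank: int = 5000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_label}: start > end")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start - self.flank <= pos <= self.end + self.flank


def read_bed(path, flank: int = 5000) -> List[GeneRegion]:
    """Parse gene intervals from BED (0-based half-open) into 1-based inclusive."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs chrom, start, end, name")
            chrom, start0, end0, name = fields[:4]
            regions.append(
                GeneRegion(
                    gene_label=name,
                    chrom=chrom,
                    start=int(start0) + 1,
                    end=int(end0),
                    flank=flank,
                )
            )
    return regions


@dataclass
class PipelineConfig:
    """Paths and tuning parameters for one discovery run."""

    panel_path: str
    genotypes_path: str
    phenotypes_path: str
    annotations_path: Optional[str] = None
    group_definitions: Optional[Dict[str, List[str]]] = None
    group_order: Tuple[str, str, str] = ("White", "EastAsian", "African")
    study_alpha: float = 0.05
    discovery_p_cut: float = 0.01
    replication_alpha: float = 0.05
    gene_flank: int = 5000
    k_pcs: int = 2
    callrate_min: float = 0.95
    hwe_alpha: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.discovery_p_cut < 1.0:
            raise ValueError("discovery_p_cut must lie in (0, 1)")
        if not 0.0 < self.study_alpha < 1.0:
            raise ValueError("study_alpha must lie in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "group_order" in raw:
            raw["group_order"] = tuple(raw["group_order"])
        return cls(**raw)


@dataclass
class DiscoveryReport:
    """Bundle of every stage's tabular output."""

    panel_qc: QcReport
    profiles: List[DifferenceProfile]
    thresholds: CategoryThresholds
    associations: pd.DataFrame
    gene_snps: Dict[str, List[str]]
    retained_genes: List[str]
    replication_export: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "panel_qc.json", "w") as fh:
            json.dump(self.panel_qc.to_dict(), fh, indent=2, sort_keys=True)
        profiles_to_frame(self.profiles).to_csv(
            outdir / "difference_profiles.tsv", sep="\t", index=False
        )
        self.thresholds.to_frame().to_csv(outdir / "thresholds.tsv", sep="\t", index=False)
        self.associations.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        with open(outdir / "gene_followup.json", "w") as fh:
            json.dump(
                {"gene_snps": self.gene_snps, "retained_genes": self.retained_genes},
                fh,
                indent=2,
                sort_keys=True,
            )
        self.replication_export.to_csv(
            outdir / "replication_export.tsv", sep="\t", index=False
        )


def expand_gene_regions(
    hits: Sequence[str],
    annotations: Sequence[GeneRegion],
    all_snps: PopulationPanel,
) -> Dict[str, List[str]]:
    """SNPs to follow up per gene containing a sub-threshold hit.

    For each gene harbouring at least one hit SNP (within the gene body or
    its flank), returns every panel SNP inside [start - flank, end + flank],
    regardless of whether those SNPs met the frequency-difference criteria.
    Hits falling in no annotated gene are skipped with a warning.
    """
    coords = {r.snp_id: (r.chrom, r.pos) for r in all_snps.records}
    hit_genes: List[GeneRegion] = []
    for snp in hits:
        if snp not in coords:
            logger.warning("hit SNP %s missing from panel; skipped", snp)
            continue
        chrom, pos = coords[snp]
        matched = [g for g in annotations if g.contains(chrom, pos)]
        if not matched:
            logger.warning("hit SNP %s lies in no annotated gene; skipped", snp)
        for g in matched:
            if g not in hit_genes:
                hit_genes.append(g)
    return {
        g.gene_label: [s for s, (c, p) in coords.items() if g.contains(c, p)]
        for g in hit_genes
    }


def hypothesized_sign(profile: DifferenceProfile, coded_is_reference: bool) -> Optional[int]:
    """Expected sign of the coded allele's log-OR under the study hypothesis.

    The hypothesis holds that the allele enriched in the comparison groups
    is protective — equivalently the baseline-group-enriched allele is the
    risk allele. The dominant pairwise difference decides which allele is
    baseline-enriched.
    """
    if not profile.usable or (profile.d_we == 0 and profile.d_wa == 0):
        return None
    dominant = profile.d_we if abs(profile.d_we) >= abs(profile.d_wa) else profile.d_wa
    ref_sign = 1 if dominant > 0 else -1  # +1: reference allele enriched in baseline
    return ref_sign if coded_is_reference else -ref_sign


def direction_consistency_filter(
    gene_results: Mapping[str, Sequence[AssociationResult]],
    p_cut: float = 0.01,
) -> List[str]:
    """Retain genes whose follow-up signals agree with the hypothesis.

    A gene is dropped when any of its follow-up SNPs is significant at
    ``p_cut`` (two-sided) with the comparison-group-enriched allele
    estimated as risk-increasing, i.e. the estimated effect direction
    contradicts the hypothesized one. Genes with no directional follow-up
    results pass through.
    """
    retained = []
    for gene, results in gene_results.items():
        inconsistent = any(
            r.hypothesized_sign is not None
            and r.p_two_sided < p_cut
            and np.sign(r.beta) == -r.hypothesized_sign
            for r in results
        )
        if inconsistent:
            logger.info("gene %s excluded: follow-up direction inconsistent", gene)
        else:
            retained.append(gene)
    return retained


def _associate(
    geno: GenotypeMatrix,
    phenotype: PhenotypeTable,
    pcs: Optional[pd.DataFrame],
    profiles_by_id: Mapping[str, DifferenceProfile],
    snp_ids: Sequence[str],
    provenance: Mapping[str, str],
    reference_alleles: Optional[Mapping[str, str]] = None,
) -> Tuple[pd.DataFrame, Dict[str, AssociationResult]]:
    rows, results = [], {}
    covar = pcs.to_numpy() if pcs is not None else None
    for snp in snp_ids:
        i = geno.snp_index(snp)
        prof = profiles_by_id.get(snp)
        sign = None
        if prof is not None:
            ref = reference_alleles.get(snp) if reference_alleles else None
            coded_is_ref = (
                geno.coded_alleles is None
                or ref is None
                or geno.coded_alleles[i] == ref
            )
            sign = hypothesized_sign(prof, coded_is_ref)
        try:
            res = fit_additive_logistic(
                geno.dosages[i],
                phenotype,
                covariates=covar,
                snp_id=snp,
                coded_allele=geno.coded_alleles[i] if geno.coded_alleles else None,
                hypothesized_sign=sign,
            )
        except ValueError as exc:
            logger.warning("association skipped for %s: %s", snp, exc)
            continue
        results[snp] = res
        ci_low, ci_high = res.ci95
        rows.append(
            {
                "snp_id": snp,
                "coded_allele": res.coded_allele,
                "n_used": res.n_used,
                "beta": res.beta,
                "se": res.se,
                "or": res.or_hat,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "p_two_sided": res.p_two_sided,
                "p_one_sided": res.p_one_sided,
                "converged": res.converged,
                "category": prof.category.value if prof is not None else Category.NONE.value,
                "provenance": provenance.get(snp, ""),
            }
        )
    columns = [
        "snp_id", "coded_allele", "n_used", "beta", "se", "or", "ci_low",
        "ci_high", "p_two_sided", "p_one_sided", "converged", "category",
        "provenance",
    ]
    return pd.DataFrame(rows, columns=columns), results


def run_discovery_pipeline(config: PipelineConfig) -> DiscoveryReport:
    """Execute the full discovery workflow from files on disk.

    Fails with a stage-labelled error if any stage's inputs are invalid.
    Deterministic given the configured seed.
    """
    rng_seed = config.seed  # reserved for stages with stochastic components

    try:
        panel = load_panel(
            config.panel_path, dialect="freq_tsv", group_definitions=config.group_definitions
        )
    except Exception as exc:
        raise RuntimeError(f"[panel-load] {exc}") from exc

    panel_qc, qc_report = None, None
    try:
        panel_qc, qc_report = apply_panel_qc(
            panel, callrate_min=config.callrate_min, hwe_alpha=config.hwe_alpha
        )
    except Exception as exc:
        raise RuntimeError(f"[panel-qc] {exc}") from exc

    try:
        profiles = profile_panel(panel_qc, config.group_order)
        profiles_by_id = {p.snp_id: p for p in profiles}
        counts = category_counts(profiles)
        thresholds = category_thresholds(counts, config.study_alpha)
    except Exception as exc:
        raise RuntimeError(f"[selection] {exc}") from exc

    try:
        geno = GenotypeMatrix.read_tsv(config.genotypes_path)
        phenotype = PhenotypeTable.read_tsv(config.phenotypes_path)
        if list(map(str, geno.sample_ids)) != list(map(str, phenotype.sample_ids)):
            raise ValueError("genotype and phenotype sample ids disagree")
        coords = {r.snp_id: r for r in panel_qc.records}
        geno.coded_alleles = [
            coords[s].reference_allele if s in coords else "A" for s in geno.snp_ids
        ]
        geno.other_alleles = [
            coords[s].other_allele if s in coords else "B" for s in geno.snp_ids
        ]
        geno = code_minor_allele(geno)
    except Exception as exc:
        raise RuntimeError(f"[genotype-load] {exc}") from exc

    try:
        pcs = compute_stratification_pcs(geno, k=config.k_pcs) if config.k_pcs > 0 else None
    except Exception as exc:
        raise RuntimeError(f"[stratification-pcs] {exc}") from exc

    candidate_ids = [
        p.snp_id
        for p in profiles
        if p.category is not Category.NONE and p.snp_id in set(geno.snp_ids)
    ]
    provenance = {s: f"category:{profiles_by_id[s].category.value}" for s in candidate_ids}
    try:
        ref_alleles = {r.snp_id: r.reference_allele for r in panel_qc.records}
        assoc_df, assoc_results = _associate(
            geno, phenotype, pcs, profiles_by_id, candidate_ids, provenance,
            reference_alleles=ref_alleles,
        )
    except Exception as exc:
        raise RuntimeError(f"[association] {exc}") from exc

    if len(assoc_df):
        assoc_df["threshold"] = [
            thresholds.threshold_for(Category(c)) for c in assoc_df["category"]
        ]
        assoc_df["significant"] = (
            assoc_df["p_one_sided"].notna()
            & assoc_df["threshold"].notna()
            & (assoc_df["p_one_sided"] < assoc_df["threshold"])
        )
    else:
        assoc_df["threshold"] = []
        assoc_df["significant"] = []

    gene_snps: Dict[str, List[str]] = {}
    retained_genes: List[str] = []
    followup_df = pd.DataFrame()
    if config.annotations_path is not None and len(assoc_df):
        try:
            annotations = read_bed(config.annotations_path, flank=config.gene_flank)
            hits = list(
                assoc_df.loc[
                    assoc_df["p_one_sided"].notna()
                    & (assoc_df["p_one_sided"] < config.discovery_p_cut),
                    "snp_id",
                ]
            )
            gene_snps = expand_gene_regions(hits, annotations, panel_qc)
            extra_ids = sorted(
                {
                    s
                    for snps in gene_snps.values()
                    for s in snps
                    if s in set(geno.snp_ids) and s not in set(candidate_ids)
                }
            )
            extra_prov = {}
            for gene, snps in gene_snps.items():
                for s in snps:
                    if s in extra_ids:
                        extra_prov[s] = f"gene_expansion:{gene}"
            followup_df, followup_results = _associate(
                geno, phenotype, pcs, profiles_by_id, extra_ids, extra_prov,
                reference_alleles=ref_alleles,
            )
            gene_results: Dict[str, List[AssociationResult]] = {}
            all_results = {**assoc_results, **followup_results}
            for gene, snps in gene_snps.items():
                gene_results[gene] = [all_results[s] for s in snps if s in all_results]
            retained_genes = direction_consistency_filter(
                gene_results, p_cut=config.discovery_p_cut
            )
        except Exception as exc:
            raise RuntimeError(f"[gene-followup] {exc}") from exc

    if len(followup_df):
        followup_df["threshold"] = np.nan
        followup_df["significant"] = False
        assoc_df = pd.concat([assoc_df, followup_df], ignore_index=True)

    retained_set = set(retained_genes)
    gene_of = {}
    for gene, snps in gene_snps.items():
        for s in snps:
            gene_of.setdefault(s, gene)
    replication_rows = []
    for _, row in assoc_df.iterrows():
        snp = row["snp_id"]
        in_retained_gene = gene_of.get(snp) in retained_set
        if row["p_one_sided"] is not None and not pd.isna(row["p_one_sided"]):
            if row["p_one_sided"] < config.discovery_p_cut and (
                not gene_snps or in_retained_gene or snp not in gene_of
            ):
                replication_rows.append(
                    {
                        "study": "discovery",
                        "snp_id": snp,
                        "gene": gene_of.get(snp, ""),
                        "or": row["or"],
                        "ci_low": row["ci_low"],
                        "ci_high": row["ci_high"],
                        "p_one_sided": row["p_one_sided"],
                    }
                )
    replication_export = pd.DataFrame(replication_rows)

    assoc_df = assoc_df.sort_values("snp_id", kind="stable").reset_index(drop=True)
    logger.info(
        "discovery pipeline: %d candidates, %d follow-up genes, %d retained",
        len(candidate_ids),
        len(gene_snps),
        len(retained_genes),
    )
    return DiscoveryReport(
        panel_qc=qc_report,
        profiles=profiles,
        thresholds=thresholds,
        associations=assoc_df,
        gene_snps=gene_snps,
        retained_genes=retained_genes,
        replication_export=replication_export,
    )
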