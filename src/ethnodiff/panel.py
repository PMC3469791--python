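"""Multi-population allele-frequency panels, ingestion and QC.

A :class:`PopulationPanel` holds per-SNP reference-allele frequencies for a
set of populations (e.g. the HapMap Phase III CEU/TSI/CHB/JPT/YRI/LWK
samples), optionally organised into pooled analysis groups (CEU+TSI as
Whites, CHB+JPT as East Asians, YRI+LWK as Africans). Pooling is by allele
*count*: pooled frequency = summed reference-allele counts over summed
chromosome counts, so larger source populations carry more weight.

QC mirrors standard frequency-panel hygiene: SNPs are dropped when a group
is missing data, when any group's call rate falls below a threshold
(default 95%), or when any source population departs from Hardy-Weinberg
equilibrium at an exact-test p-value below a threshold (default 1e-7).
Each SNP is attributed to the *first* failing filter in that order, so the
QC report partitions the input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GroupStats",
    "PopulationFrequencyRecord",
    "PopulationPanel",
    "QcReport",
    "hwe_test",
    "load_panel",
    "pool_groups",
    "apply_panel_qc",
    "apply_casecontrol_qc",
]


@dataclass
class GroupStats:
    """Per-population summary for one SNP."""

    ref_count: Optional[int] = None
    total_alleles: Optional[int] = None
    frequency: Optional[float] = None
    call_rate: Optional[float] = None
    hwe_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frequency is None and self.ref_count is not None and self.total_alleles:
            self.frequency = self.ref_count / self.total_alleles
        if self.frequency is not None and not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency outside [0, 1]: {self.frequency}")
        if self.call_rate is not None and not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"call rate outside [0, 1]: {self.call_rate}")

    @property
    def missing(self) -> bool:
        return self.frequency is None


@dataclass
class PopulationFrequencyRecord:
    """Reference-allele frequencies and QC metadata for one SNP."""

    snp_id: str
    chrom: str
    pos: int
    reference_allele: str
    other_allele: str
    groups: Dict[str, GroupStats] = field(default_factory=dict)

    def frequency(self, group: str) -> Optional[float]:
        stats = self.groups.get(group)
        return None if stats is None else stats.frequency


@dataclass
class PopulationPanel:
    """A set of frequency records plus the pooling structure.

    ``group_definitions`` maps an analysis-group label to the source
    populations pooled into it, e.g. ``{"White": ["CEU", "TSI"]}``. A panel
    whose records are already keyed by group labels uses the identity map.
    """

    records: List[PopulationFrequencyRecord]
    group_definitions: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_id(s) in panel: {dup[:5]}")
        if not self.group_definitions:
            pops = sorted({p for r in self.records for p in r.groups})
            self.group_definitions = {p: [p] for p in pops}

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> List[str]:
        return [r.snp_id for r in self.records]

    @property
    def groups(self) -> List[str]:
        return list(self.group_definitions)

    def record(self, snp_id: str) -> PopulationFrequencyRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "reference_allele": r.reference_allele,
                "other_allele": r.other_allele,
            }
            for pop, st in r.groups.items():
                row[f"{pop}:frequency"] = st.frequency
                row[f"{pop}:call_rate"] = st.call_rate
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        """Write the count-based frequency TSV dialect."""
        pops = sorted({p for r in self.records for p in r.groups})
        header = ["snp_id", "chrom", "pos", "reference_allele", "other_allele"]
        for p in pops:
            header += [f"{p}:ref_count", f"{p}:total_count"]
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for r in self.records:
                row = [r.snp_id, r.chrom, str(r.pos), r.reference_allele, r.other_allele]
                for p in pops:
                    st = r.groups.get(p)
                    if st is None or st.ref_count is None:
                        row += ["NA", "NA"]
                    else:
                        row += [str(st.ref_count), str(st.total_alleles)]
                fh.write("\t".join(row) + "\n")


@dataclass
class QcReport:
    """Exclusion tallies; one count per SNP, by first failing filter."""

    n_input: int = 0
    n_excluded_missing_source: int = 0
    n_excluded_callrate: int = 0
    n_excluded_hwe: int = 0
    n_excluded_sample: int = 0
    n_retained: int = 0

    def validate(self) -> None:
        total = (
            self.n_excluded_missing_source
            + self.n_excluded_callrate
            + self.n_excluded_hwe
            + self.n_retained
        )
        if total != self.n_input:
            raise AssertionError("QC counts do not partition the input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_missing_source": self.n_excluded_missing_source,
            "n_excluded_callrate": self.n_excluded_callrate,
            "n_excluded_hwe": self.n_excluded_hwe,
            "n_excluded_sample": self.n_excluded_sample,
            "n_retained": self.n_retained,
        }


def hwe_test(genotype_counts: Tuple[int, int, int]) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa). The p-value sums, over the
    distribution of heterozygote counts conditional on the observed allele
    counts under HWE, the probabilities of all configurations no more
    probable than the observed one (no mid-p correction). Follows the
    conditional-enumeration construction standard for SNP QC.
    """
    n_hom1, n_het, n_hom2 = (int(c) for c in genotype_counts)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("at least one observed genotype required")
    # rare allele count; heterozygote count shares its parity
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # log P(het = h | allele counts) up to a constant, via log-factorials
    lgam = math.lgamma
    def log_prob(h: int) -> float:
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * math.log(2.0)
            - lgam(h + 1)
            - lgam(hom_rare + 1)
            - lgam(hom_common + 1)
        )

    hs = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[(n_het - (n_rare % 2)) // 2]
    # tolerance guards ties against floating-point noise
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _freq_tsv_records(path) -> Tuple[List[PopulationFrequencyRecord], Dict[str, int]]:
    pop_sizes: Dict[str, int] = {}
    records = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#samples"):
                for tok in line.split()[1:]:
                    pop, _, size = tok.partition("=")
                    pop_sizes[pop] = int(size)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                base = ["snp_id", "chrom", "pos", "reference_allele", "other_allele"]
                if header[: len(base)] != base:
                    raise ValueError(f"{path}: unexpected freq TSV header")
                pops = []
                for col in header[len(base):: 2]:
                    pop, _, kind = col.partition(":")
                    if kind != "ref_count":
                        raise ValueError(f"{path}: bad per-population column {col!r}")
                    pops.append(pop)
                continue
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields")
            try:
                groups = {}
                for k, pop in enumerate(pops):
                    ref_s, tot_s = fields[5 + 2 * k], fields[6 + 2 * k]
                    if ref_s == "NA" or tot_s == "NA":
                        groups[pop] = GroupStats()
                        continue
                    ref, tot = int(ref_s), int(tot_s)
                    call_rate = None
                    if pop in pop_sizes and pop_sizes[pop] > 0:
                        call_rate = tot / (2 * pop_sizes[pop])
                    groups[pop] = GroupStats(ref_count=ref, total_alleles=tot, call_rate=call_rate)
                records.append(
                    PopulationFrequencyRecord(
                        snp_id=fields[0],
                        chrom=fields[1],
                        pos=int(fields[2]),
                        reference_allele=fields[3],
                        other_allele=fields[4],
                        groups=groups,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records, pop_sizes


def _records_from_genotypes(
    geno: GenotypeMatrix, sample_populations: Mapping[str, str]
) -> List[PopulationFrequencyRecord]:
    pops = sorted(set(sample_populations.values()))
    pop_cols = {
        p: [j for j, s in enumerate(geno.sample_ids) if sample_populations[str(s)] == p]
        for p in pops
    }
    coded = geno.coded_alleles or ["A"] * geno.n_snps
    other = geno.other_alleles or ["B"] * geno.n_snps
    chrom = geno.chrom or ["1"] * geno.n_snps
    pos = geno.pos if geno.pos is not None else np.arange(1, geno.n_snps + 1)
    records = []
    for i, snp in enumerate(geno.snp_ids):
        groups = {}
        for p in pops:
            d = geno.dosages[i, pop_cols[p]]
            called = d[~np.isnan(d)]
            n_attempted = len(d)
            if len(called) == 0:
                groups[p] = GroupStats(call_rate=0.0)
                continue
            counts = (
                int((called == 2).sum()),
                int((called == 1).sum()),
                int((called == 0).sum()),
            )
            groups[p] = GroupStats(
                ref_count=int(called.sum()),
                total_alleles=2 * len(called),
                call_rate=len(called) / n_attempted,
                hwe_p=hwe_test(counts),
            )
        records.append(
            PopulationFrequencyRecord(
                snp_id=str(snp),
                chrom=str(chrom[i]),
                pos=int(pos[i]),
                reference_allele=coded[i],
                other_allele=other[i],
                groups=groups,
            )
        )
    return records


def _vcf_records(path, sample_populations: Mapping[str, str]) -> List[PopulationFrequencyRecord]:
    # GT-only parse; cyvcf2 used when importable, plain-text fallback otherwise
    try:
        from cyvcf2 import VCF  # type: ignore

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
        for var in vcf:
            if len(var.ALT) != 1:
                logger.warning("skipping multi-allelic site %s", var.ID or var.POS)
                continue
            snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            chroms.append(str(var.CHROM))
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            dose = []
            for call in var.genotypes:  # [allele0, allele1, phased]
                a = call[:-1]
                if any(x < 0 for x in a):
                    dose.append(np.nan)
                else:
                    dose.append(float(sum(1 for x in a if x == 0)))  # REF copies
            rows.append(dose)
    except ImportError:
        samples, snp_ids, chroms, poss, refs, alts, rows = _parse_vcf_text(path)
    geno = GenotypeMatrix(
        snp_ids=snp_ids,
        sample_ids=samples,
        dosages=np.array(rows, dtype=float).reshape(len(snp_ids), len(samples)),
        coded_alleles=refs,
        other_alleles=alts,
        chrom=chroms,
        pos=np.array(poss),
    )
    return _records_from_genotypes(geno, sample_populations)


def _parse_vcf_text(path):
    samples: List[str] = []
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    gt_dose = {"0/0": 2.0, "0/1": 1.0, "1/0": 1.0, "1/1": 0.0,
               "0|0": 2.0, "0|1": 1.0, "1|0": 1.0, "1|1": 0.0}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: truncated VCF record")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                logger.warning("skipping multi-allelic site %s", vid)
                continue
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            dose = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx]
                dose.append(gt_dose.get(gt, np.nan))
            snp_ids.append(vid if vid != "." else f"{chrom}:{pos}")
            chroms.append(chrom)
            poss.append(int(pos))
            refs.append(ref)
            alts.append(alt)
            rows.append(dose)
    return samples, snp_ids, chroms, poss, refs, alts, rows


def load_panel(
    path,
    dialect: str = "freq_tsv",
    group_definitions: Optional[Mapping[str, Sequence[str]]] = None,
    sample_populations: Optional[Mapping[str, str]] = None,
) -> PopulationPanel:
    """Read a panel from disk.

    Dialects: ``freq_tsv`` (per-population allele counts), ``vcf``
    (GT-only v4.x; reference-allele frequencies computed by counting), and
    ``genotype_tsv`` (SNP x sample dosage matrix). The genotype dialects
    require ``sample_populations`` mapping sample id -> population label.
    """
    if dialect == "freq_tsv":
        records, _ = _freq_tsv_records(path)
    elif dialect == "vcf":
        if sample_populations is None:
            raise ValueError("vcf dialect requires sample_populations")
        records = _vcf_records(path, sample_populations)
    elif dialect == "genotype_tsv":
        if sample_populations is None:
            raise ValueError("genotype_tsv dialect requires sample_populations")
        geno = GenotypeMatrix.read_tsv(path)
        records = _records_from_genotypes(geno, sample_populations)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return PopulationPanel(
        records=records,
        group_definitions={g: list(p) for g, p in group_definitions.items()}
        if group_definitions
        else {},
    )


def pool_groups(panel: PopulationPanel) -> PopulationPanel:
    """Collapse source populations into their analysis groups.

    Pooled reference-allele count and chromosome total are sums over source
    populations (count weighting). Call rate pools as total called alleles
    over total attempted; the pooled record carries the *minimum* source HWE
    p-value, so a per-source HWE threshold applied after pooling is
    equivalent to applying it before. Idempotent on already-pooled panels.
    """
    pooled_records = []
    for r in panel.records:
        groups: Dict[str, GroupStats] = {}
        for glabel, sources in panel.group_definitions.items():
            stats = [r.groups.get(s) for s in sources]
            if any(s is None or s.missing for s in stats):
                groups[glabel] = GroupStats()
                continue
            have_counts = all(s.ref_count is not None for s in stats)
            if have_counts:
                ref = sum(s.ref_count for s in stats)
                tot = sum(s.total_alleles for s in stats)
            else:
                ref = tot = None
            call_rates = [s.call_rate for s in stats]
            if all(c is not None for c in call_rates) and have_counts:
                attempted = sum(s.total_alleles / s.call_rate for s in stats if s.call_rate > 0)
                call = tot / attempted if attempted else 0.0
            elif len(stats) == 1:
                call = stats[0].call_rate
            else:
                call = None
            hwe_ps = [s.hwe_p for s in stats if s.hwe_p is not None]
            freq = None
            if ref is None:
                freqs = [s.frequency for s in stats]
                freq = float(np.mean(freqs)) if len(stats) == 1 else None
            groups[glabel] = GroupStats(
                ref_count=ref,
                total_alleles=tot,
                frequency=freq,
                call_rate=min(1.0, call) if call is not None else None,
                hwe_p=min(hwe_ps) if hwe_ps else None,
            )
        pooled_records.append(
            PopulationFrequencyRecord(
                snp_id=r.snp_id,
                chrom=r.chrom,
                pos=r.pos,
                reference_allele=r.reference_allele,
                other_allele=r.other_allele,
                groups=groups,
            )
        )
    return PopulationPanel(
        records=pooled_records,
        group_definitions={g: [g] for g in panel.group_definitions},
    )


def apply_panel_qc(
    panel: PopulationPanel,
    callrate_min: float = 0.95,
    hwe_alpha: float = 1e-7,
) -> Tuple[PopulationPanel, QcReport]:
    """Exclude SNPs by availability, call rate, then HWE.

    A SNP must have data for every analysis group, call rate >= callrate_min
    in every group (after pooling), and exact-test HWE p >= hwe_alpha in
    every source population. Each SNP counts toward its first failing
    filter.
    """
    pooled = pool_groups(panel)
    report = QcReport(n_input=len(panel))
    kept = []
    for r, pr in zip(panel.records, pooled.records):
        group_stats = [pr.groups.get(g) for g in pooled.group_definitions]
        if any(s is None or s.missing for s in group_stats):
            report.n_excluded_missing_source += 1
            continue
        call_rates = [s.call_rate for s in group_stats if s.call_rate is not None]
        if any(c < callrate_min for c in call_rates):
            report.n_excluded_callrate += 1
            continue
        source_hwe = [
            st.hwe_p
            for src_list in panel.group_definitions.values()
            for src in src_list
            if (st := r.groups.get(src)) is not None and st.hwe_p is not None
        ]
        if any(p < hwe_alpha for p in source_hwe):
            report.n_excluded_hwe += 1
            continue
        report.n_retained += 1
        kept.append(r)
    report.validate()
    logger.info("panel QC: %s", report.to_dict())
    return (
        PopulationPanel(records=kept, group_definitions=dict(panel.group_definitions)),
        report,
    )


def apply_casecontrol_qc(
    genotypes: GenotypeMatrix,
    sample_groups: Mapping[str, str],
    control_groups: Optional[Iterable[str]] = None,
    sample_callrate_min: float = 0.98,
    control_hwe_alpha: float = 1e-5,
    max_group_missing: float = 0.05,
) -> Tuple[GenotypeMatrix, QcReport]:
    """QC for a case-control genotype matrix.

    First drops samples whose call rate falls below ``sample_callrate_min``;
    then drops SNPs that deviate from HWE among any control group
    (exact-test p < control_hwe_alpha) or that have more than
    ``max_group_missing`` missing data in any subject group.
    """
    groups = [sample_groups[str(s)] for s in genotypes.sample_ids]
    if control_groups is None:
        control_groups = {g for g in groups if "control" in g.lower()}
    control_groups = set(control_groups)

    keep_samples = [
        j for j, cr in enumerate(genotypes.sample_call_rate()) if cr >= sample_callrate_min
    ]
    n_samples_dropped = genotypes.n_samples - len(keep_samples)
    geno = genotypes.subset_samples(keep_samples)
    groups = [groups[j] for j in keep_samples]
    group_labels = sorted(set(groups))
    group_cols = {g: [j for j, lab in enumerate(groups) if lab == g] for g in group_labels}

    report = QcReport(n_input=geno.n_snps, n_excluded_sample=n_samples_dropped)
    keep_snps = []
    for i in range(geno.n_snps):
        row = geno.dosages[i]
        missing_by_group = {
            g: np.isnan(row[cols]).mean() for g, cols in group_cols.items() if cols
        }
        hwe_fail = False
        for g in control_groups & set(group_labels):
            d = row[group_cols[g]]
            d = d[~np.isnan(d)]
            if len(d) == 0:
                continue
            counts = (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
            if hwe_test(counts) < control_hwe_alpha:
                hwe_fail = True
                break
        if hwe_fail:
            report.n_excluded_hwe += 1
            continue
        if any(m > max_group_missing for m in missing_by_group.values()):
            report.n_excluded_missing_source += 1
            continue
        report.n_retained += 1
        keep_snps.append(i)
    report.validate()
    logger.info("case-control QC: %s", report.to_dict())
    return geno.subset_snps(keep_snps), report
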