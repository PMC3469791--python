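"""Panel ingestion, pooling, HWE exact test and QC filters."""

from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethnodiff.genotypes import GenotypeMatrix
from ethnodiff.panel import (
    GroupStats,
    PopulationPanel,
    apply_casecontrol_qc,
    apply_panel_qc,
    hwe_test,
    load_panel,
    pool_groups,
)

from conftest import make_panel, make_record


def hwe_exact_oracle(n_hom1, n_het, n_hom2):
    """Exact-integer enumeration of the conditional heterozygote
    distribution under HWE given the allele counts."""
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het
    weights = {}
    for het in range(n + 1):
        if (na - het) % 2 or het > na or het > 2 * n - na:
            continue
        h1 = (na - het) // 2
        h2 = n - het - h1
        if h1 < 0 or h2 < 0:
            continue
        weights[het] = (
            factorial(n) // (factorial(h1) * factorial(het) * factorial(h2))
        ) * 2**het
    total = sum(weights.values())
    obs = weights[n_het]
    return sum(w for w in weights.values() if w <= obs) / total


class TestHweTest:
    def test_perfect_hwe_is_nonsignificant(self):
        assert hwe_test((25, 50, 25)) > 0.9

    def test_complete_het_deficit_extreme(self):
        assert hwe_test((50, 0, 50)) < 1e-7

    def test_small_table_matches_enumeration(self):
        assert hwe_test((3, 4, 3)) == pytest.approx(hwe_exact_oracle(3, 4, 3), rel=1e-10)

    def test_matches_enumeration_for_all_tables_up_to_n20(self):
        for n in range(1, 21):
            for n1 in range(n + 1):
                for n2 in range(n - n1 + 1):
                    counts = (n1, n2, n - n1 - n2)
                    assert hwe_test(counts) == pytest.approx(
                        hwe_exact_oracle(*counts), rel=1e-9
                    ), counts

    def test_symmetric_in_homozygote_labels(self):
        assert hwe_test((7, 5, 2)) == pytest.approx(hwe_test((2, 5, 7)), rel=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((-1, 2, 3))


class TestLoadPanel:
    def test_freq_tsv_counts_to_frequencies(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\treference_allele\tother_allele\t"
            "CEU:ref_count\tCEU:total_count\n"
            "rs1\t1\t100\tA\tG\t12\t20\n"
            "rs2\t1\t200\tC\tT\t20\t20\n"
            "rs3\t1\t300\tG\tA\t0\t20\n"
        )
        panel = load_panel(path, dialect="freq_tsv")
        assert [r.frequency("CEU") for r in panel.records] == [0.6, 1.0, 0.0]

    def test_freq_tsv_samples_header_gives_call_rates(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "#samples CEU=10\n"
            "snp_id\tchrom\tpos\treference_allele\tother_allele\t"
            "CEU:ref_count\tCEU:total_count\n"
            "rs1\t1\t100\tA\tG\t9\t18\n"
        )
        panel = load_panel(path, dialect="freq_tsv")
        assert panel.records[0].groups["CEU"].call_rate == pytest.approx(0.9)

    def test_vcf_reference_frequency(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        panel = load_panel(
            path, dialect="vcf", sample_populations={"s1": "P", "s2": "P", "s3": "P"}
        )
        assert panel.records[0].frequency("P") == pytest.approx(0.5)

    def test_genotype_tsv_missingness_gives_call_rate(self, tmp_path):
        rng = np.random.default_rng(7)
        dos = rng.binomial(2, 0.4, size=(1, 100)).astype(float)
        dos[0, :5] = np.nan  # exactly 5% missing
        geno = GenotypeMatrix(["rs1"], [f"s{i}" for i in range(100)], dos)
        path = tmp_path / "geno.tsv"
        geno.write_tsv(path)
        panel = load_panel(
            path,
            dialect="genotype_tsv",
            sample_populations={f"s{i}": "P" for i in range(100)},
        )
        assert panel.records[0].groups["P"].call_rate == pytest.approx(0.95)

    def test_duplicate_snp_rejected(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\treference_allele\tother_allele\t"
            "CEU:ref_count\tCEU:total_count\n"
            "rs1\t1\t100\tA\tG\t1\t20\n"
            "rs1\t1\t100\tA\tG\t1\t20\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_panel(path, dialect="freq_tsv")

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\treference_allele\tother_allele\t"
            "CEU:ref_count\tCEU:total_count\n"
            "rs1\t1\t100\tA\tG\t1\n"
        )
        with pytest.raises(ValueError, match=":2"):
            load_panel(path, dialect="freq_tsv")


class TestPoolGroups:
    def _panel(self, counts_a, counts_b):
        rec = make_record("rs1", {"CEU": None, "TSI": None},
                          counts={"CEU": counts_a, "TSI": counts_b})
        return PopulationPanel(records=[rec], group_definitions={"White": ["CEU", "TSI"]})

    def test_count_weighted_pooling(self):
        pooled = pool_groups(self._panel((30, 100), (70, 100)))
        assert pooled.records[0].frequency("White") == pytest.approx(0.5)

    def test_identical_frequencies_unchanged(self):
        pooled = pool_groups(self._panel((40, 200), (20, 100)))
        assert pooled.records[0].frequency("White") == pytest.approx(0.2)

    def test_unequal_sizes_weighted_by_chromosome_count(self):
        # 0.2 at 2*113 chromosomes and 0.3 at 2*102: hand-summed pooling
        n1, n2 = 2 * 113, 2 * 102
        c1, c2 = round(0.2 * n1), round(0.3 * n2)
        pooled = pool_groups(self._panel((c1, n1), (c2, n2)))
        assert pooled.records[0].frequency("White") == pytest.approx((c1 + c2) / (n1 + n2))

    def test_idempotent_on_pooled_panel(self):
        once = pool_groups(self._panel((30, 100), (70, 100)))
        twice = pool_groups(once)
        assert twice.records[0].frequency("White") == once.records[0].frequency("White")
        assert twice.group_definitions == once.group_definitions

    def test_missing_source_flags_group_missing(self):
        rec = make_record("rs1", {"CEU": 0.4})
        rec.groups["TSI"] = GroupStats()  # no data
        panel = PopulationPanel([rec], group_definitions={"White": ["CEU", "TSI"]})
        assert pool_groups(panel).records[0].groups["White"].missing

    def test_carries_minimum_source_hwe(self):
        rec = make_record("rs1", {"CEU": None, "TSI": None},
                          counts={"CEU": (30, 100), "TSI": (60, 100)},
                          hwe_ps={"CEU": 1e-3, "TSI": 0.5})
        panel = PopulationPanel([rec], group_definitions={"White": ["CEU", "TSI"]})
        assert pool_groups(panel).records[0].groups["White"].hwe_p == pytest.approx(1e-3)


class TestApplyPanelQc:
    def test_one_group_below_callrate_excludes(self):
        rec = make_record("rs1", {"W": 0.5, "EA": 0.5, "AFR": 0.5},
                          call_rates={"W": 0.96, "EA": 0.94, "AFR": 0.99})
        kept, report = apply_panel_qc(PopulationPanel([rec]))
        assert len(kept) == 0 and report.n_excluded_callrate == 1

    def test_passing_snp_retained(self):
        rec = make_record("rs1", {"W": 0.5, "EA": 0.5, "AFR": 0.5},
                          call_rates={"W": 0.99, "EA": 0.98, "AFR": 0.99},
                          hwe_ps={"W": 0.3, "EA": 0.7, "AFR": 0.9})
        kept, report = apply_panel_qc(PopulationPanel([rec]))
        assert len(kept) == 1 and report.n_retained == 1

    def test_disjoint_failures_partition_input(self):
        records = []
        for i in range(10):
            call = 0.90 if i < 3 else 0.99          # 3 call-rate failures
            hwe = 1e-9 if 3 <= i < 5 else 0.5       # 2 HWE failures (disjoint)
            records.append(
                make_record(f"rs{i}", {"W": 0.5}, call_rates={"W": call},
                            hwe_ps={"W": hwe}, pos=100 * (i + 1))
            )
        kept, report = apply_panel_qc(PopulationPanel(records))
        assert report.n_excluded_callrate == 3
        assert report.n_excluded_hwe == 2
        assert report.n_retained == len(kept) == 5
        report.validate()

    def test_missing_group_counts_before_callrate(self):
        rec = make_record("rs1", {"W": 0.5})
        rec.groups["EA"] = GroupStats()
        kept, report = apply_panel_qc(PopulationPanel([rec]))
        assert report.n_excluded_missing_source == 1 and len(kept) == 0


class TestCaseControlQc:
    def _matrix(self, dosages, groups):
        n_snps, n_samples = dosages.shape
        geno = GenotypeMatrix(
            [f"rs{i}" for i in range(n_snps)],
            [f"s{j}" for j in range(n_samples)],
            dosages,
        )
        return geno, {f"s{j}": groups[j] for j in range(n_samples)}

    def test_low_callrate_sample_dropped(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.5, size=(100, 10)).astype(float)
        dos[:3, 0] = np.nan  # sample 0 call rate 97%
        geno, groups = self._matrix(dos, ["ctl_control"] * 10)
        kept, report = apply_casecontrol_qc(geno, groups)
        assert "s0" not in kept.sample_ids
        assert report.n_excluded_sample == 1

    def test_snp_with_group_missingness_dropped(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.5, size=(5, 100)).astype(float)
        group_a = [f"s{j}" for j in range(50)]
        dos[0, :3] = np.nan  # 6% missing within first group of 50
        geno, groups = self._matrix(dos, ["case_a"] * 50 + ["ctl_control"] * 50)
        kept, report = apply_casecontrol_qc(geno, groups, sample_callrate_min=0.0)
        assert "rs0" not in kept.snp_ids
        assert report.n_excluded_missing_source == 1

    def test_hwe_deviating_snp_dropped_in_controls(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.5, size=(3, 200)).astype(float)
        dos[1] = np.repeat([0.0, 2.0], 100)  # no heterozygotes at all
        geno, groups = self._matrix(dos, ["ctl_control"] * 200)
        kept, report = apply_casecontrol_qc(geno, groups)
        assert "rs1" not in kept.snp_ids and report.n_excluded_hwe == 1

    def test_clean_matrix_unchanged(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.5, size=(20, 100)).astype(float)
        geno, groups = self._matrix(dos, ["case_a"] * 50 + ["ctl_control"] * 50)
        kept, report = apply_casecontrol_qc(geno, groups)
        assert kept.n_snps == 20 and kept.n_samples == 100
        assert report.n_excluded_hwe == 0
        assert report.n_excluded_missing_source == 0
        assert report.n_excluded_sample == 0
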