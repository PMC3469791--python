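import numpy as np
import pytest

from ethnodiff.panel import GroupStats, PopulationFrequencyRecord, PopulationPanel


def make_record(snp_id, freqs, counts=None, call_rates=None, hwe_ps=None,
                chrom="1", pos=1000, ref="A", other="B"):
    """Build a frequency record from plain dicts keyed by group label."""
    groups = {}
    for g, f in freqs.items():
        kwargs = {}
        if counts and g in counts:
            kwargs["ref_count"], kwargs["total_alleles"] = counts[g]
        else:
            kwargs["frequency"] = f
        if call_rates and g in call_rates:
            kwargs["call_rate"] = call_rates[g]
        if hwe_ps and g in hwe_ps:
            kwargs["hwe_p"] = hwe_ps[g]
        groups[g] = GroupStats(**kwargs)
    return PopulationFrequencyRecord(
        snp_id=snp_id, chrom=chrom, pos=pos, reference_allele=ref,
        other_allele=other, groups=groups,
    )


def make_panel(freq_rows, **kwargs):
    """Panel from a list of (snp_id, {group: freq}) pairs."""
    records = [
        make_record(snp_id, freqs, pos=1000 * (i + 1))
        for i, (snp_id, freqs) in enumerate(freq_rows)
    ]
    return PopulationPanel(records=records, **kwargs)


@pytest.fixture
def three_group_panel():
    """Six SNPs spanning every candidate category plus NONE."""
    return make_panel([
        ("s_highest", {"White": 0.90, "EastAsian": 0.10, "African": 0.20}),  # mean 0.75
        ("s_high", {"White": 0.85, "EastAsian": 0.20, "African": 0.25}),     # mean 0.625
        ("s_moderate", {"White": 0.60, "EastAsian": 0.15, "African": 0.20}), # mean 0.425
        ("s_hilo", {"White": 0.80, "EastAsian": 0.05, "African": 0.70}),     # 0.75 / 0.10
        ("s_opposite", {"White": 0.50, "EastAsian": 0.10, "African": 0.90}), # opposite signs
        ("s_flat", {"White": 0.50, "EastAsian": 0.48, "African": 0.52}),
    ])


@pytest.fixture(scope="session")
def null_phenotype():
    """600 subjects, half cases, status independent of any genotype."""
    from ethnodiff.genotypes import PhenotypeTable

    n = 600
    return PhenotypeTable(
        sample_ids=[f"S{i}" for i in range(n)],
        status=np.array([1] * (n // 2) + [0] * (n // 2)),
    )
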