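"""Additive logistic association, PCs, conditional tests and LD."""

import numpy as np
import pytest
from scipy import optimize

from ethnodiff.association import (
    code_minor_allele,
    compute_stratification_pcs,
    conditional_test,
    estimate_ld,
    fit_additive_logistic,
    _em_haplotype_freqs,
)
from ethnodiff.genotypes import GenotypeMatrix, PhenotypeTable


def logistic_mle_oracle(dosage, status):
    """Direct likelihood maximization on (intercept, slope), independent of
    the fitting route used by the package."""

    def negloglik(params):
        b0, b1 = params
        eta = b0 + b1 * dosage
        return np.sum(np.log1p(np.exp(eta)) - status * eta)

    res = optimize.minimize(negloglik, x0=[0.0, 0.0], method="BFGS")
    return res.x[1]


def make_phen(status, **kwargs):
    status = np.asarray(status)
    return PhenotypeTable(
        sample_ids=[f"S{i}" for i in range(len(status))], status=status, **kwargs
    )


class TestFitAdditiveLogistic:
    def test_beta_matches_direct_likelihood_maximization(self):
        # collapsed 2x3 genotype table: counts per (status, dosage)
        table = {(0, 0): 120, (0, 1): 60, (0, 2): 20, (1, 0): 80, (1, 1): 70, (1, 2): 50}
        dosage, status = [], []
        for (s, d), n in table.items():
            dosage += [d] * n
            status += [s] * n
        dosage, status = np.array(dosage, float), np.array(status)
        res = fit_additive_logistic(dosage, make_phen(status))
        assert res.beta == pytest.approx(logistic_mle_oracle(dosage, status), abs=1e-6)
        assert res.converged

    def test_missing_dosages_dropped(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, 0.4, size=400).astype(float)
        dosage[:50] = np.nan
        status = rng.integers(0, 2, size=400)
        res = fit_additive_logistic(dosage, make_phen(status))
        assert res.n_used == 350

    def test_one_sided_p_follows_direction_hypothesis(self):
        rng = np.random.default_rng(1)
        dosage = rng.binomial(2, 0.4, size=600).astype(float)
        logit = -0.5 + 0.6 * dosage
        status = rng.random(600) < 1 / (1 + np.exp(-logit))
        phen = make_phen(status.astype(int))
        res_plus = fit_additive_logistic(dosage, phen, hypothesized_sign=+1)
        res_minus = fit_additive_logistic(dosage, phen, hypothesized_sign=-1)
        assert res_plus.p_one_sided == pytest.approx(res_plus.p_two_sided / 2)
        assert res_plus.p_one_sided + res_minus.p_one_sided == pytest.approx(1.0)

    def test_irrelevant_constant_covariate_changes_nothing(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.3, size=500).astype(float)
        status = rng.integers(0, 2, size=500)
        phen = make_phen(status)
        base = fit_additive_logistic(dosage, phen)
        noise = rng.normal(size=500)  # independent of everything
        with_cov = fit_additive_logistic(dosage, phen, covariates=noise[:, None])
        assert with_cov.beta == pytest.approx(base.beta, abs=0.05)

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_additive_logistic(np.ones(100), make_phen([1] * 50 + [0] * 50))

    def test_all_case_input_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="case and one control"):
            fit_additive_logistic(
                rng.binomial(2, 0.5, 50).astype(float), make_phen([1] * 50)
            )

    def test_separation_flagged_not_fatal(self):
        dosage = np.array([0.0] * 50 + [2.0] * 50)
        status = np.array([0] * 50 + [1] * 50)
        res = fit_additive_logistic(dosage, make_phen(status))
        assert not res.converged


class TestCodeMinorAllele:
    def test_major_coded_snp_flipped(self):
        dos = np.array([[2.0, 2.0, 1.0, 2.0]])
        geno = GenotypeMatrix(["rs1"], list("abcd"), dos, coded_alleles=["A"], other_alleles=["G"])
        coded = code_minor_allele(geno)
        assert coded.coded_alleles == ["G"]
        assert np.array_equal(coded.dosage_of("rs1"), 2.0 - dos[0])

    def test_minor_coded_snp_untouched(self):
        dos = np.array([[0.0, 1.0, 0.0, 0.0]])
        geno = GenotypeMatrix(["rs1"], list("abcd"), dos, coded_alleles=["A"], other_alleles=["G"])
        coded = code_minor_allele(geno)
        assert coded.coded_alleles == ["A"]
        assert np.array_equal(coded.dosage_of("rs1"), dos[0])

    def test_tie_broken_lexicographically(self):
        dos = np.array([[0.0, 2.0]])
        geno = GenotypeMatrix(["rs1"], list("ab"), dos, coded_alleles=["T"], other_alleles=["C"])
        assert code_minor_allele(geno).coded_alleles == ["C"]


class TestStratificationPcs:
    def _two_pop_matrix(self, f=0.1, n_snps=200, n_per_group=100, seed=0):
        rng = np.random.default_rng(seed)
        anc = rng.uniform(0.2, 0.8, n_snps)
        shape = (1 - f) / f
        freqs = rng.beta(anc[:, None] * shape, (1 - anc[:, None]) * shape, size=(n_snps, 2))
        dosages = np.concatenate(
            [
                rng.binomial(2, freqs[:, [0]], size=(n_snps, n_per_group)),
                rng.binomial(2, freqs[:, [1]], size=(n_snps, n_per_group)),
            ],
            axis=1,
        ).astype(float)
        labels = np.array([0] * n_per_group + [1] * n_per_group)
        geno = GenotypeMatrix(
            [f"rs{i}" for i in range(n_snps)],
            [f"s{j}" for j in range(2 * n_per_group)],
            dosages,
        )
        return geno, labels

    def test_pc1_separates_differentiated_groups(self):
        geno, labels = self._two_pop_matrix()
        pcs = compute_stratification_pcs(geno, k=2)
        r = np.corrcoef(pcs["PC1"], labels)[0, 1]
        assert abs(r) > 0.9

    def test_pcs_orthonormal(self):
        geno, _ = self._two_pop_matrix(seed=1)
        pcs = compute_stratification_pcs(geno, k=4).to_numpy()
        assert np.allclose(pcs.T @ pcs, np.eye(4), atol=1e-8)

    def test_zero_variance_snps_excluded(self):
        dosages = np.vstack([np.ones((5, 40)), np.random.default_rng(2).binomial(2, 0.5, (10, 40))]).astype(float)
        geno = GenotypeMatrix([f"rs{i}" for i in range(15)], [f"s{j}" for j in range(40)], dosages)
        pcs = compute_stratification_pcs(geno, k=2)  # must not fail on constant rows
        assert pcs.shape == (40, 2)

    def test_k_beyond_rank_rejected(self):
        geno, _ = self._two_pop_matrix(n_snps=3, n_per_group=5, seed=3)
        with pytest.raises(ValueError, match="rank"):
            compute_stratification_pcs(geno, k=9)


class TestConditionalTest:
    def _tagged_pair(self, seed, n=1500, d_prime=1.0):
        """Causal SNP + tag SNP on shared haplotypes; disease driven by the
        causal SNP only."""
        rng = np.random.default_rng(seed)
        p_causal, p_tag_given = 0.4, 0.9  # tag allele rides on the causal haplotype
        hap_c = rng.random((n, 2)) < p_causal
        hap_t = np.where(
            hap_c, rng.random((n, 2)) < p_tag_given, rng.random((n, 2)) < 0.05
        )
        causal = hap_c.sum(axis=1).astype(float)
        tag = hap_t.sum(axis=1).astype(float)
        logit = -1.0 + 0.7 * causal
        status = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        geno = GenotypeMatrix(
            ["tag", "causal"], [f"s{i}" for i in range(n)], np.vstack([tag, causal])
        )
        return geno, make_phen(status)

    def test_identical_columns_rejected(self):
        d = np.random.default_rng(0).binomial(2, 0.5, 100).astype(float)
        geno = GenotypeMatrix(["a", "b"], [f"s{i}" for i in range(100)], np.vstack([d, d]))
        with pytest.raises(ValueError, match="collinear"):
            conditional_test(geno, "a", "b", make_phen(np.tile([0, 1], 50)))

    def test_independent_target_keeps_its_signal(self):
        rng = np.random.default_rng(4)
        n = 1200
        target = rng.binomial(2, 0.4, n).astype(float)
        other = rng.binomial(2, 0.4, n).astype(float)
        logit = -0.8 + 0.5 * target
        status = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        geno = GenotypeMatrix(["t", "o"], [f"s{i}" for i in range(n)], np.vstack([target, other]))
        phen = make_phen(status)
        uncond = fit_additive_logistic(target, phen, snp_id="t")
        cond = conditional_test(geno, "t", "o", phen)
        assert cond.beta == pytest.approx(uncond.beta, abs=0.1)
        assert cond.p_two_sided < 1e-4

    def test_tagging_snp_loses_signal_when_conditioned(self):
        """Mirrors conditioning a tag SNP on the causal hit: the tag's
        conditional signal should disappear in most replicates."""
        nonsig = 0
        for rep in range(10):
            geno, phen = self._tagged_pair(seed=100 + rep)
            marginal = fit_additive_logistic(geno.dosage_of("tag"), phen, snp_id="tag")
            cond = conditional_test(geno, "tag", "causal", phen)
            assert marginal.p_two_sided < cond.p_two_sided  # conditioning absorbs signal
            if cond.p_two_sided > 0.05:
                nonsig += 1
        assert nonsig >= 9


class TestEstimateLd:
    def test_perfect_correlation(self):
        d = np.random.default_rng(0).binomial(2, 0.5, 500).astype(float)
        d_prime, r2 = estimate_ld(d, d)
        assert d_prime == pytest.approx(1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps_have_negligible_r2(self):
        rng = np.random.default_rng(5)
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.6, 10_000).astype(float)
        _, r2 = estimate_ld(a, b)
        assert r2 < 0.01

    def test_em_matches_direct_likelihood_maximization(self):
        counts = np.array([[20, 8, 2], [10, 25, 5], [3, 9, 18]])

        def negloglik(x):
            # softmax parametrization of the 3-simplex interior
            e = np.exp(np.append(x, 0.0))
            p = e / e.sum()  # p11, p10, p01, p00
            ll = 0.0
            cell = {
                (2, 2): p[0] ** 2, (2, 1): 2 * p[0] * p[1], (2, 0): p[1] ** 2,
                (1, 2): 2 * p[0] * p[2], (1, 1): 2 * (p[0] * p[3] + p[1] * p[2]),
                (1, 0): 2 * p[1] * p[3],
                (0, 2): p[2] ** 2, (0, 1): 2 * p[2] * p[3], (0, 0): p[3] ** 2,
            }
            for (i, j), prob in cell.items():
                ll += counts[i, j] * np.log(prob)
            return -ll

        best = optimize.minimize(negloglik, x0=np.zeros(3), method="Nelder-Mead",
                                 options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        e = np.exp(np.append(best.x, 0.0))
        p_oracle = e / e.sum()
        p_em = _em_haplotype_freqs(counts)
        assert np.allclose(p_em, p_oracle, atol=1e-6)

    def test_invariant_under_allele_relabeling(self):
        rng = np.random.default_rng(6)
        hap1 = rng.random((800, 2)) < 0.4
        hap2 = np.where(hap1, rng.random((800, 2)) < 0.8, rng.random((800, 2)) < 0.2)
        a = hap1.sum(axis=1).astype(float)
        b = hap2.sum(axis=1).astype(float)
        assert estimate_ld(a, b) == pytest.approx(estimate_ld(2 - a, b), abs=1e-9)
        assert estimate_ld(a, b) == pytest.approx(estimate_ld(a, 2 - b), abs=1e-9)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            estimate_ld(np.zeros(100), np.ones(100) * 2)
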