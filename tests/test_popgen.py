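import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rewardnet.popgen import (GenotypeTable, SNP, allele_frequencies,
                              call_rate_filter, case_control_association,
                              hwe_chisq, ld_pairwise, snp_screen,
                              _em_haplotype_freqs)
from rewardnet.simulate import LDBlock, SNPSpec, simulate_genotypes
from conftest import HA_COUNTS, HC_COUNTS


def make_table(calls: dict, risk: dict | None = None) -> GenotypeTable:
    df = pd.DataFrame(calls)
    snps = []
    for sid in df.columns:
        alleles = sorted(set("".join(g for g in df[sid] if g != "00")))
        snps.append(SNP(sid, allele_a=alleles[0], allele_b=alleles[1],
                        risk_allele=(risk or {}).get(sid, alleles[1])))
    return GenotypeTable(subjects=list(df.index), snps=snps, calls=df)


class TestCallRateFilter:
    def test_full_call_rate_unchanged(self):
        table = make_table({"rs1": pd.Series(["AA", "AG", "GG"], list("abc"))})
        filtered, report = call_rate_filter(table, 0.98)
        assert [s.snp_id for s in filtered.snps] == ["rs1"]
        assert report["kept"].all()

    def test_threshold_drop(self):
        calls = ["AA"] * 50 + ["AG"] * 47 + ["00"] * 3  # call rate 0.97
        idx = [f"s{i}" for i in range(100)]
        table = make_table({
            "rs1": pd.Series(calls, idx),
            "rs2": pd.Series(["AG"] * 100, idx),
        })
        filtered, report = call_rate_filter(table, 0.98)
        assert [s.snp_id for s in filtered.snps] == ["rs2"]
        assert not report.set_index("snp").loc["rs1", "kept"]

    def test_dropped_set_matches_recount_oracle(self):
        rng = np.random.default_rng(9)
        idx = [f"s{i}" for i in range(200)]
        calls = {}
        for k in range(8):
            g = np.where(rng.random(200) < 0.05, "00", "AG")
            calls[f"rs{k}"] = pd.Series(g, idx)
        table = make_table(calls)
        filtered, _ = call_rate_filter(table, 0.98)
        kept_oracle = {
            sid for sid, col in calls.items()
            if sum(v != "00" for v in col) / 200 > 0.98
        }
        assert {s.snp_id for s in filtered.snps} == kept_oracle


class TestHWE:
    def test_reproduces_case_group_p(self):
        _, p = hwe_chisq(HA_COUNTS)
        assert round(p, 2) == 0.92

    def test_reproduces_control_group_p(self):
        _, p = hwe_chisq(HC_COUNTS)
        assert round(p, 2) == 0.42

    def test_exact_hw_counts_give_zero(self):
        chi2, p = hwe_chisq((25, 50, 25))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_monomorphic_flagged(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_chisq((10, 0, 0))

    @given(st.tuples(st.integers(1, 500), st.integers(1, 500),
                     st.integers(1, 500)))
    @settings(max_examples=50, deadline=None)
    def test_chi2_nonnegative(self, counts):
        chi2, p = hwe_chisq(counts)
        assert chi2 >= 0
        assert 0 < p <= 1


class TestAlleleFrequencies:
    def test_printed_case_frequency(self):
        freq_a, freq_g = allele_frequencies(HA_COUNTS)
        assert round(freq_a, 2) == 0.44
        assert freq_a + freq_g == pytest.approx(1.0)

    @pytest.mark.parametrize("counts,expected", [
        ((7, 0, 0), 1.0), ((0, 9, 0), 0.5),
    ])
    def test_degenerate_counts(self, counts, expected):
        assert allele_frequencies(counts)[0] == pytest.approx(expected)


class TestCaseControlAssociation:
    def test_reproduces_printed_table(self):
        res = case_control_association(HA_COUNTS, HC_COUNTS)
        assert round(res.allelic_chi2, 2) == 11.28
        assert round(res.genotypic_chi2, 2) == 11.31
        assert round(res.odds_ratio, 2) == 0.84
        assert round(res.ci_lower, 2) == 0.76
        assert round(res.ci_upper, 2) == 0.93
        assert round(res.case_freq_a, 2) == 0.44
        assert res.allelic_p < 0.001

    def test_identical_distributions_null(self):
        res = case_control_association((30, 40, 30), (30, 40, 30))
        assert res.genotypic_chi2 == pytest.approx(0.0)
        assert res.allelic_chi2 == pytest.approx(0.0)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_lower < 1 < res.ci_upper

    def test_group_swap_inverts_odds_ratio(self):
        a, b = (30, 40, 30), (10, 60, 30)
        r1 = case_control_association(a, b)
        r2 = case_control_association(b, a)
        assert r1.odds_ratio == pytest.approx(1 / r2.odds_ratio)
        assert r1.allelic_chi2 == pytest.approx(r2.allelic_chi2)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            case_control_association((0, 0, 30), (0, 0, 40))


class TestLD:
    def test_duplicated_snp_column_perfect_ld(self):
        rng = np.random.default_rng(2)
        geno = rng.choice(["AA", "AG", "GG"], size=300, p=[0.36, 0.48, 0.16])
        idx = [f"s{i}" for i in range(300)]
        table = make_table({"rs1": pd.Series(geno, idx),
                            "rs2": pd.Series(geno, idx)})
        res = ld_pairwise(table, "rs1", "rs2")
        assert res.d_prime == pytest.approx(1.0, abs=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_independent_snps_near_zero(self):
        specs = [SNPSpec("rs1", 0.3), SNPSpec("rs2", 0.4, minor_allele="C",
                                              major_allele="T")]
        table = simulate_genotypes(5000, specs, seed=11)
        res = ld_pairwise(table, "rs1", "rs2")
        assert res.r_squared < 0.01

    def test_em_recovers_known_phase_truth(self):
        """Haplotypes AB=40, Ab=10, aB=10, ab=40 collapsed to genotypes."""
        rng = np.random.default_rng(0)
        haps = np.array([[1, 1]] * 40 + [[1, 0]] * 10
                        + [[0, 1]] * 10 + [[0, 0]] * 40)
        rng.shuffle(haps)
        g = haps[0::2] + haps[1::2]
        counts = np.zeros((3, 3))
        for a, b in g:
            counts[2 - a, 2 - b] += 1
        f, _, ll = _em_haplotype_freqs(counts, tol=1e-8, max_iter=1000)
        assert np.max(np.abs(f - np.array([0.4, 0.1, 0.1, 0.4]))) < 0.03
        # EM log-likelihood is non-decreasing across iterations
        assert np.all(np.diff(ll) >= -1e-10)

    def test_r2_bounded_by_dprime_squared(self):
        for seed in range(5):
            specs = [SNPSpec("rs1", 0.25), SNPSpec("rs2", 0.35)]
            table = simulate_genotypes(
                400, specs, [LDBlock(("rs1", "rs2"), 0.6)], seed=seed)
            res = ld_pairwise(table, "rs1", "rs2")
            assert 0 <= res.r_squared <= res.d_prime**2 + 1e-9
            assert 0 <= res.d_prime <= 1

    def test_nonconvergence_reported(self):
        rng = np.random.default_rng(4)
        geno = rng.choice(["AA", "AG", "GG"], size=200)
        idx = [f"s{i}" for i in range(200)]
        table = make_table({"rs1": pd.Series(geno, idx),
                            "rs2": pd.Series(rng.permutation(geno), idx)})
        with pytest.raises(RuntimeError, match="iterations"):
            ld_pairwise(table, "rs1", "rs2", max_iter=1)


class TestSNPScreen:
    def make_cohort(self, rng, n=200, beta_pooled=0.0, beta_hc_only=0.0):
        idx = [f"s{i}" for i in range(n)]
        groups = pd.Series(["HA"] * (n // 2) + ["HC"] * (n // 2), idx)
        dose = rng.binomial(2, 0.45, n).astype(float)
        geno = np.array(["AA", "AG", "GG"])[dose.astype(int)]
        table = make_table({"rs1": pd.Series(geno, idx)}, risk={"rs1": "G"})
        is_hc = (groups == "HC").to_numpy(dtype=float)
        y = pd.Series(
            0.5 + beta_pooled * dose + beta_hc_only * dose * is_hc
            + rng.normal(0, 0.03, n), idx)
        return y, table, groups

    def test_planted_main_effect_detected_without_interaction(self, rng):
        y, table, groups = self.make_cohort(rng, beta_pooled=0.02)
        res = snp_screen(y, table, groups)[0]
        assert res.main_p < 1e-6
        assert res.interaction_p > 0.01

    def test_group_specific_effect_detected_as_interaction(self, rng):
        y, table, groups = self.make_cohort(rng, beta_hc_only=-0.04)
        res = snp_screen(y, table, groups)[0]
        assert res.interaction_p < 1e-4
        assert res.control_p < 1e-6
        assert res.case_p > 0.01

    def test_null_p_uniformity(self):
        """Type-I error of the pooled main effect near nominal 5%."""
        hits, reps = 0, 200
        for r in range(reps):
            rng = np.random.default_rng(5000 + r)
            y, table, groups = self.make_cohort(rng, n=80)
            hits += snp_screen(y, table, groups)[0].main_p < 0.05
        assert abs(hits / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_risk_allele_recode_flips_slope_keeps_p(self, rng):
        y, table, groups = self.make_cohort(rng, beta_pooled=0.01)
        res_g = snp_screen(y, table, groups)[0]
        flipped = GenotypeTable(
            subjects=table.subjects,
            snps=[SNP("rs1", allele_a="A", allele_b="G", risk_allele="A")],
            calls=table.calls,
        )
        res_a = snp_screen(y, flipped, groups)[0]
        assert res_a.main_beta == pytest.approx(-res_g.main_beta)
        assert res_a.main_p == pytest.approx(res_g.main_p, rel=1e-9)

    def test_monomorphic_stratum_flagged(self, rng):
        idx = [f"s{i}" for i in range(40)]
        groups = pd.Series(["HA"] * 20 + ["HC"] * 20, idx)
        geno = ["AA"] * 20 + list(
            np.array(["AA", "AG", "GG"])[rng.binomial(2, 0.4, 20)])
        table = make_table({"rs1": pd.Series(geno, idx)})
        y = pd.Series(rng.normal(0.5, 0.03, 40), idx)
        res = snp_screen(y, table, groups)[0]
        assert np.isnan(res.case_p)
        assert np.isfinite(res.control_p)
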