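import numpy as np
import pandas as pd
import pytest

from rewardnet.atlas import default_atlas
from rewardnet.edgestats import adjusted_t
from rewardnet.popgen import hwe_chisq, ld_pairwise
from rewardnet.simulate import (GeneticEffect, LDBlock, MediationParams,
                                SimulationConfig, SNPSpec, simulate_cohort,
                                simulate_genotypes, simulate_voxel_data)


class TestGenotypeGeneration:
    def test_hwe_holds_at_large_n(self):
        """HW goodness of fit non-significant for a MAF-0.5 SNP at n=10^4."""
        for seed in range(3):
            table = simulate_genotypes(10_000, [SNPSpec("rs1", 0.5)], seed=seed)
            counts = table.genotype_counts("rs1")
            _, p = hwe_chisq(counts)
            assert p > 0.01

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError, match="MAF"):
            SNPSpec("rs1", 0.0)
        with pytest.raises(ValueError, match="MAF"):
            SNPSpec("rs1", 1.0)

    def test_perfect_ld_duplicates_columns(self):
        specs = [SNPSpec("rs1", 0.5), SNPSpec("rs2", 0.5)]
        table = simulate_genotypes(500, specs, [LDBlock(("rs1", "rs2"), 1.0)],
                                   seed=3)
        assert (table.calls["rs1"] == table.calls["rs2"]).all()

    def test_target_haplotype_correlation_recovered_by_em(self):
        """r = 0.9 between two SNPs -> estimated r^2 within 0.05 of 0.81."""
        specs = [SNPSpec("rs1", 0.45), SNPSpec("rs2", 0.40)]
        table = simulate_genotypes(5000, specs, [LDBlock(("rs1", "rs2"), 0.9)],
                                   seed=3)
        res = ld_pairwise(table, "rs1", "rs2")
        assert res.r_squared == pytest.approx(0.81, abs=0.05)

    def test_infeasible_ld_rejected(self):
        specs = [SNPSpec("rs1", 0.05), SNPSpec("rs2", 0.5)]
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genotypes(100, specs, [LDBlock(("rs1", "rs2"), 0.99)],
                               seed=0)

    def test_missingness_rate(self):
        table = simulate_genotypes(2000, [SNPSpec("rs1", 0.3)], seed=5,
                                   missing_rate=0.05)
        rate = table.call_rates()["rs1"]
        assert rate == pytest.approx(0.95, abs=0.02)


class TestVoxelData:
    def test_null_config_has_no_group_difference(self):
        cfg = SimulationConfig(n_per_group=30, affected_edges={},
                               genetic_effect=None, seed=4)
        bundle = simulate_cohort(cfg)
        groups = bundle.subjects["group"]
        # mean FA over each planted region differs only by sampling noise
        diffs = []
        for e, origin in list(bundle.truth.region_origins.items())[:40]:
            data = bundle.voxel_data[e]
            sl = tuple(slice(o, o + r) for o, r in
                       zip(origin, bundle.truth.region_shape))
            vals = data.fa[(slice(None), *sl)].reshape(len(data.subjects), -1).mean(axis=1)
            ha = vals[(groups == "HA").to_numpy()]
            hc = vals[(groups == "HC").to_numpy()]
            diffs.append(ha.mean() - hc.mean())
        # planted effect is zero: average standardized difference near 0
        assert abs(np.mean(diffs)) < 0.5 * cfg.edge_noise_sd

    def test_planted_effect_t_grows_with_n(self):
        """Downstream two-sample t on an affected edge strengthens with n."""
        ts = {}
        edge = None
        for n in (10, 60):
            cfg = SimulationConfig(
                n_per_group=n, seed=8,
                affected_edges=None, genetic_effect=None,
            )
            cfg.affected_edges = {list(cfg.affected_edges)[0]: -0.8}
            bundle = simulate_cohort(cfg)
            edge = next(iter(bundle.truth.affected_edges))
            origin = bundle.truth.region_origins[edge]
            sl = tuple(slice(o, o + r) for o, r in
                       zip(origin, bundle.truth.region_shape))
            data = bundle.voxel_data[edge]
            vals = data.fa[(slice(None), *sl)].reshape(2 * n, -1).mean(axis=1)
            ts[n] = adjusted_t(vals, bundle.subjects["group"])
        assert ts[10] < 0 and ts[60] < 0
        assert abs(ts[60]) > abs(ts[10])

    def test_streamline_support_is_region_only(self, small_bundle):
        truth = small_bundle.truth
        e = next(iter(truth.region_origins))
        data = small_bundle.voxel_data[e]
        sl = tuple(slice(o, o + r) for o, r in
                   zip(truth.region_origins[e], truth.region_shape))
        inside = data.streamline[(slice(None), *sl)]
        outside = data.streamline.copy()
        outside[(slice(None), *sl)] = 0
        assert np.all(inside > 0)
        assert np.all(outside == 0)

    def test_overlapping_regions_rejected(self):
        cfg = SimulationConfig(n_per_group=3, seed=0)
        bundle_rng = np.random.default_rng(0)
        subjects = pd.DataFrame({
            "group": ["HA", "HA", "HA", "HC", "HC", "HC"],
            "age": 35.0, "cigarettes_per_day": 10.0,
        }, index=[f"s{i}" for i in range(6)])
        dosage = pd.Series(0.0, index=subjects.index)
        atlas = default_atlas()
        origins = {e: (0, 0, 0) for e in atlas.edges()[:2]}
        origins.update({e: (4 * (i + 1) % 12, 0, 0)
                        for i, e in enumerate(atlas.edges()[2:])})
        with pytest.raises(ValueError, match="overlaps"):
            simulate_voxel_data(cfg, subjects, dosage, bundle_rng,
                                region_origins=origins)


class TestDeterminismAndPhenotypes:
    def test_same_seed_bit_identical(self):
        cfg1 = SimulationConfig(n_per_group=6, seed=42)
        cfg2 = SimulationConfig(n_per_group=6, seed=42)
        b1, b2 = simulate_cohort(cfg1), simulate_cohort(cfg2)
        pd.testing.assert_frame_equal(b1.subjects, b2.subjects)
        assert b1.genotypes.calls.equals(b2.genotypes.calls)
        e = next(iter(b1.voxel_data))
        assert b1.voxel_data[e].fa.tobytes() == b2.voxel_data[e].fa.tobytes()
        assert (b1.voxel_data[e].streamline.tobytes()
                == b2.voxel_data[e].streamline.tobytes())

    def test_different_seed_differs(self):
        b1 = simulate_cohort(SimulationConfig(n_per_group=6, seed=1))
        b2 = simulate_cohort(SimulationConfig(n_per_group=6, seed=2))
        e = next(iter(b1.voxel_data))
        assert b1.voxel_data[e].fa.tobytes() != b2.voxel_data[e].fa.tobytes()

    def test_noiseless_cognition_is_affine_in_strength(self):
        params = MediationParams(b=100.0, c_prime=0.0, noise_sd=0.0,
                                 intercept=-20.0, group_shift=0.0,
                                 age_beta=0.0, cigs_beta=0.0)
        cfg = SimulationConfig(n_per_group=10, seed=9, mediation=params,
                               genetic_effect=None)
        bundle = simulate_cohort(cfg)
        moca = bundle.subjects["MoCA"].to_numpy()
        m = bundle.truth.true_diff_mean.loc[bundle.subjects.index].to_numpy()
        assert np.allclose(moca, -20.0 + 100.0 * m, atol=1e-9)

    def test_planted_indirect_effect_bookkeeping(self):
        cfg = SimulationConfig(n_per_group=4, seed=0)
        bundle = simulate_cohort(cfg)
        ge = cfg.genetic_effect
        expected = ge.beta * cfg.edge_noise_sd * cfg.mediation.b
        assert bundle.truth.indirect_effect == pytest.approx(expected)
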