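import numpy as np
import pytest
from scipy import stats

from rewardnet.connectome import (ConnectivityRecord, EdgeVoxelData,
                                  EmptyRegionError, StreamlineRegion,
                                  build_connectivity, define_streamline_region,
                                  edge_strength, estimate_regions,
                                  subnetwork_means)

EDGE = ("dlPFC_L", "VTA_L")


def make_edge_data(streamline, fa=None, edge=EDGE):
    n = streamline.shape[0]
    if fa is None:
        fa = np.full_like(streamline, 0.5, dtype=float)
    return EdgeVoxelData(edge=edge, subjects=[f"s{i}" for i in range(n)],
                         streamline=streamline, fa=fa)


class TestStreamlineRegion:
    def test_all_zero_maps_give_empty_mask(self):
        data = make_edge_data(np.zeros((5, 3, 3, 3)))
        region = define_streamline_region(data)
        assert region.empty

    def test_planted_block_recovered_exactly(self, rng):
        """Against the closed-form per-voxel oracle t = mean/(sd/sqrt(n))."""
        n = 20
        maps = np.zeros((n, 3, 3, 3))
        maps[:, 0, 0, :2] = rng.normal(5, 1, size=(n, 2))
        data = make_edge_data(maps)
        region = define_streamline_region(data, alpha=0.05)
        expected = np.zeros((3, 3, 3), dtype=bool)
        expected[0, 0, :2] = True
        assert np.array_equal(region.mask, expected)
        # oracle: the planted voxels' t statistic is far beyond the cutoff
        for idx in zip(*np.where(expected)):
            vals = maps[(slice(None), *idx)]
            t = vals.mean() / (vals.std(ddof=1) / np.sqrt(n))
            assert stats.t.sf(t, n - 1) < 0.05

    def test_zero_variance_rule(self):
        maps = np.zeros((4, 2, 2, 2))
        maps[:, 0, 0, 0] = 3.0  # constant positive: included
        region = define_streamline_region(make_edge_data(maps))
        assert region.mask[0, 0, 0]
        assert region.n_voxels == 1  # constant zero voxels excluded

    def test_requires_two_subjects(self):
        data = make_edge_data(np.ones((1, 2, 2, 2)))
        with pytest.raises(ValueError, match=">= 2 subjects"):
            define_streamline_region(data)

    def test_subject_order_invariance(self, rng):
        maps = rng.gamma(2.0, 1.0, size=(10, 3, 3, 3))
        r1 = define_streamline_region(make_edge_data(maps))
        perm = rng.permutation(10)
        r2 = define_streamline_region(make_edge_data(maps[perm]))
        assert np.array_equal(r1.mask, r2.mask)


class TestEdgeStrength:
    def test_constant_map(self):
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0] = True
        region = StreamlineRegion(EDGE, "HA", mask)
        assert edge_strength(np.full((2, 2, 2), 0.5), region) == pytest.approx(0.5)

    def test_three_point_mean(self):
        fa = np.zeros((3, 1, 1))
        fa[:, 0, 0] = [0.2, 0.4, 0.6]
        mask = np.ones((3, 1, 1), dtype=bool)
        region = StreamlineRegion(EDGE, "HA", mask)
        assert edge_strength(fa, region) == pytest.approx(0.4)

    def test_matches_brute_force_oracle(self, rng):
        fa = rng.uniform(0, 1, size=(4, 4, 4))
        flat = rng.choice(64, size=10, replace=False)
        mask = np.zeros(64, dtype=bool)
        mask[flat] = True
        region = StreamlineRegion(EDGE, "HA", mask.reshape(4, 4, 4))
        total, count = 0.0, 0
        for v in flat:
            total += fa.reshape(-1)[v]
            count += 1
        assert edge_strength(fa, region) == pytest.approx(total / count)

    def test_empty_mask_flagged_not_zero(self):
        region = StreamlineRegion(EDGE, "HA", np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(EmptyRegionError, match="undefined"):
            edge_strength(np.full((2, 2, 2), 0.5), region)

    def test_invariant_to_voxels_outside_mask(self, rng):
        fa = rng.uniform(0, 1, size=(3, 3, 3))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        region = StreamlineRegion(EDGE, "HA", mask)
        before = edge_strength(fa, region)
        fa2 = fa.copy()
        fa2[~mask] = rng.uniform(0, 1, size=(~mask).sum())
        assert edge_strength(fa2, region) == before


class TestBuildConnectivity:
    def test_matrix_properties_on_synthetic_cohort(self, small_bundle, atlas):
        groups = small_bundle.subjects["group"].to_dict()
        records = build_connectivity(small_bundle.voxel_data, atlas, groups)
        assert len(records) == len(small_bundle.subjects)
        rec = records[0]
        assert np.allclose(rec.matrix, rec.matrix.T)
        assert np.all(np.diag(rec.matrix) == 0)
        off = rec.matrix[~np.eye(24, dtype=bool)]
        assert np.all((off >= 0) & (off <= 1))

    def test_identical_voxel_data_identical_records(self, rng):
        from rewardnet.atlas import default_atlas
        atlas = default_atlas()
        maps = rng.gamma(3.0, 1.0, size=(2, 2, 2, 2))
        maps = np.vstack([maps, maps])  # two pairs of clones
        fa = np.full((4, 2, 2, 2), 0.4)
        # single-edge check through the strength path
        data = EdgeVoxelData(edge=EDGE, subjects=list("abcd"),
                             streamline=maps, fa=fa)
        region = define_streamline_region(data)
        s = [edge_strength(fa[i], region) for i in range(4)]
        assert s[0] == s[2] and s[1] == s[3]

    def test_union_mode_uses_pooled_region(self, small_bundle, atlas):
        groups = small_bundle.subjects["group"].to_dict()
        regions = estimate_regions(small_bundle.voxel_data, groups,
                                   region_mode="union")
        assert all(k[1] == "union" for k in regions)
        records = build_connectivity(small_bundle.voxel_data, atlas, groups,
                                     region_mode="union", regions=regions)
        assert len(records) == len(small_bundle.subjects)

    def test_missing_subject_map_is_named(self, small_bundle, atlas):
        groups = small_bundle.subjects["group"].to_dict()
        groups["ghost"] = "HA"
        with pytest.raises(ValueError, match="ghost"):
            build_connectivity(small_bundle.voxel_data, atlas, groups)


class TestSubnetworkMeans:
    def make_record(self, atlas, fill=0.3):
        m = np.full((24, 24), fill)
        np.fill_diagonal(m, 0.0)
        return ConnectivityRecord("s0", m, node_labels=atlas.labels)

    def test_constant_matrix(self, atlas):
        rec = self.make_record(atlas, 0.3)
        diff = [("dlPFC_L", "VTA_L")]
        means = subnetwork_means(rec, atlas, diff)
        assert all(means[k] == pytest.approx(0.3)
                   for k in ("control", "driving", "btn", "diff"))

    def test_singleton_diff_edge(self, atlas):
        rec = self.make_record(atlas, 0.3)
        i, j = atlas.index("dlPFC_L"), atlas.index("VTA_L")
        rec.matrix[i, j] = rec.matrix[j, i] = 0.7
        means = subnetwork_means(rec, atlas, [("dlPFC_L", "VTA_L")])
        assert means["diff"] == pytest.approx(0.7)

    def test_matches_brute_force_on_random_matrix(self, atlas, rng):
        m = rng.uniform(0, 1, (24, 24))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        rec = ConnectivityRecord("s0", m, node_labels=atlas.labels)
        edges = atlas.edges()
        diff = [edges[k] for k in rng.choice(len(edges), 10, replace=False)]
        means = subnetwork_means(rec, atlas, diff)
        acc = sum(m[atlas.index(a), atlas.index(b)] for a, b in diff)
        assert means["diff"] == pytest.approx(acc / 10)

    def test_empty_diff_flagged_nan(self, atlas):
        means = subnetwork_means(self.make_record(atlas), atlas, [])
        assert np.isnan(means["diff"])

    def test_unknown_edge_rejected(self, atlas):
        with pytest.raises(ValueError, match="unknown edge"):
            subnetwork_means(self.make_record(atlas), atlas,
                             [("dlPFC_L", "dlPFC_L2")])
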