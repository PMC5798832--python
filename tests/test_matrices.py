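import numpy as np
import pytest

import noduleomics as no
from noduleomics import matrices as mx
from noduleomics.volumes import DegenerateRoiError
from conftest import make_patch
import oracles


def quantized(voxels, mask=None, levels=8):
    return no.quantize(make_patch(voxels, mask), levels)


class TestGlcm:
    def test_thirteen_unique_nonantipodal_directions(self):
        assert len(mx.DIRECTIONS_13) == 13
        assert len({d for d in mx.DIRECTIONS_13}) == 13
        for d in mx.DIRECTIONS_13:
            assert tuple(-c for c in d) not in mx.DIRECTIONS_13

    def test_constant_cube_has_single_diagonal_entry(self):
        q = quantized(np.full((2, 2, 2), 9.0), levels=256)
        m = mx.glcm(q)
        assert m.probabilities[0, 0] == 1.0
        assert m.probabilities.sum() == pytest.approx(1.0)

    def test_checkerboard_in_plane_mass_is_off_diagonal(self, micro_fixtures):
        vox, mask = micro_fixtures["checker221"]
        q = quantized(vox, mask, levels=2)
        m = mx.glcm(q, directions=[(1, 0, 0), (0, 1, 0)])
        assert m.probabilities[0, 1] == pytest.approx(0.5)
        assert m.probabilities[1, 0] == pytest.approx(0.5)
        assert m.probabilities[0, 0] == 0.0 and m.probabilities[1, 1] == 0.0

    @pytest.mark.parametrize("name", ["constant4", "checker221", "run331",
                                      "twoblob441", "deviant333"])
    def test_matrix_equals_pair_counting_oracle(self, micro_fixtures, name):
        vox, mask = micro_fixtures[name]
        q = quantized(vox, mask, levels=4)
        m = mx.glcm(q)
        counts = oracles.glcm_counts(q.codes, q.levels)
        np.testing.assert_allclose(m.probabilities, counts / counts.sum())

    def test_masked_pairs_are_skipped(self, random_patch):
        q = no.quantize(random_patch, 6)
        m = mx.glcm(q)
        counts = oracles.glcm_counts(q.codes, 6)
        np.testing.assert_allclose(m.probabilities, counts / counts.sum())

    def test_single_voxel_is_degenerate(self):
        q = quantized(np.array([[[5.0]]]), levels=4)
        with pytest.raises(DegenerateRoiError):
            mx.glcm(q)


class TestGlcmFeatures:
    def test_point_mass_matrix_limits(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        m = mx.CooccurrenceMatrix(P, 4, 1, 13)
        f = mx.glcm_features(m)
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["maximum_probability"] == 1.0

    def test_uniform_diagonal_matrix_limits(self):
        L = 8
        P = np.eye(L) / L
        f = mx.glcm_features(mx.CooccurrenceMatrix(P, L, 1, 13))
        assert f["contrast"] == 0.0
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["dissimilarity"] == 0.0

    def test_features_match_direct_summation_oracle(self, random_patch):
        q = no.quantize(random_patch, 6)
        m = mx.glcm(q)
        f = mx.glcm_features(m)
        P = m.probabilities
        L = m.levels
        # explicit double loops, 1-based gray levels
        contrast = dissim = autoc = energy = homo = joint_avg = 0.0
        entropy = 0.0
        for i in range(L):
            for j in range(L):
                p = P[i, j]
                gi, gj = i + 1, j + 1
                contrast += (gi - gj) ** 2 * p
                dissim += abs(gi - gj) * p
                autoc += gi * gj * p
                energy += p * p
                homo += p / (1 + abs(gi - gj))
                joint_avg += gi * p
                if p > 0:
                    entropy -= p * np.log2(p)
        sum_avg = 0.0
        for k in range(2, 2 * L + 1):
            pk = sum(P[i, j] for i in range(L) for j in range(L) if i + j + 2 == k)
            sum_avg += k * pk
        assert f["contrast"] == pytest.approx(contrast)
        assert f["dissimilarity"] == pytest.approx(dissim)
        assert f["autocorrelation"] == pytest.approx(autoc)
        assert f["energy"] == pytest.approx(energy)
        assert f["homogeneity"] == pytest.approx(homo)
        assert f["joint_average"] == pytest.approx(joint_avg)
        assert f["entropy"] == pytest.approx(entropy)
        assert f["sum_average"] == pytest.approx(sum_avg)
        assert len(f) == 26

    def test_difference_average_equals_dissimilarity(self, random_patch):
        f = mx.glcm_features(mx.glcm(no.quantize(random_patch, 5)))
        assert f["difference_average"] == pytest.approx(f["dissimilarity"])


class TestRlm:
    @pytest.mark.parametrize("name", ["constant4", "checker221", "run331",
                                      "twoblob441", "deviant333"])
    def test_matrix_equals_run_scanning_oracle(self, micro_fixtures, name):
        vox, mask = micro_fixtures[name]
        q = quantized(vox, mask, levels=8)
        m = mx.rlm(q)
        np.testing.assert_allclose(m.counts, oracles.rlm_counts(q.codes, 8))

    def test_masked_runs_are_broken(self, random_patch):
        q = no.quantize(random_patch, 4)
        m = mx.rlm(q)
        np.testing.assert_allclose(m.counts, oracles.rlm_counts(q.codes, 4))

    def test_single_line_run_of_three(self):
        q = quantized(np.full((1, 1, 3), 2.0), levels=4)
        m = mx.rlm(q)
        # one run of length 3 along the containing axis, singleton runs elsewhere
        assert m.counts[0, 2] == 1
        assert m.counts[0, 0] == 36  # 12 remaining directions x 3 voxels
        assert m.n_runs == 37

    def test_all_distinct_codes_give_sre_one(self):
        q = quantized(np.array([0.0, 10.0, 20.0, 30.0]).reshape(1, 1, 4), levels=4)
        f = mx.rlm_features(mx.rlm(q))
        assert f["SRE"] == pytest.approx(1.0)
        assert f["LRE"] == pytest.approx(1.0)

    def test_gray_level_reversal_swaps_low_high_emphasis(self, rng):
        # skew the codes low so low/high emphasis differ strongly
        vox = (rng.random((6, 6, 6)) ** 3 * 100).astype(float)
        q = no.quantize(make_patch(vox), 8)
        rev_codes = np.where(q.codes >= 0, q.levels - 1 - q.codes, -1)
        q_rev = no.QuantizedPatch(q.levels, rev_codes, q.level_edges, q.spacing)
        f = mx.rlm_features(mx.rlm(q))
        f_rev = mx.rlm_features(mx.rlm(q_rev))
        # run structure is exactly invariant under gray-level relabeling
        for name in ("SRE", "LRE", "GLN", "RLN", "RP"):
            assert f[name] == pytest.approx(f_rev[name])
        # low/high emphasis swap roles under reversal
        assert f["LGRE"] > f_rev["LGRE"] and f_rev["HGRE"] > f["HGRE"]
        assert f["SRLGE"] > f_rev["SRLGE"] and f_rev["SRHGE"] > f["SRHGE"]


class TestGlszm:
    def test_constant_patch_is_one_zone(self):
        q = quantized(np.full((3, 3, 3), 4.0), levels=16)
        m = mx.glszm(q)
        assert m.n_zones == 1
        assert m.counts[0, 26] == 1  # zone of size 27

    def test_two_disjoint_blobs(self, micro_fixtures):
        vox, mask = micro_fixtures["twoblob441"]
        q = quantized(vox, mask, levels=2)
        m = mx.glszm(q)
        assert m.counts[1, 2] == 2  # two high-code zones of size 3
        assert m.counts[0, 9] == 1  # connected background zone of size 10

    @pytest.mark.parametrize("name", ["constant4", "checker221", "run331",
                                      "twoblob441", "deviant333"])
    def test_matrix_equals_flood_fill_oracle(self, micro_fixtures, name):
        vox, mask = micro_fixtures[name]
        q = quantized(vox, mask, levels=4)
        np.testing.assert_allclose(mx.glszm(q).counts,
                                   oracles.glszm_counts(q.codes, 4))

    def test_zone_sizes_conserve_voxel_count(self, random_patch):
        q = no.quantize(random_patch, 4)
        m = mx.glszm(q)
        sizes = np.arange(1, m.counts.shape[1] + 1)
        assert (m.counts * sizes).sum() == q.n_voxels


class TestNgtdm:
    def test_constant_patch_limits(self):
        q = quantized(np.full((3, 3, 3), 2.0), levels=8)
        t = mx.ngtdm(q)
        assert t.s.sum() == 0.0
        assert t.p.sum() == pytest.approx(1.0)
        f = mx.ngtdm_features(t)
        assert f["busyness"] == 0.0
        assert f["contrast"] == 0.0
        assert f["coarseness"] == pytest.approx(1e6)  # 1/eps cap

    def test_single_deviant_voxel_hand_computed(self, micro_fixtures):
        vox, mask = micro_fixtures["deviant333"]
        q = quantized(vox, mask, levels=2)
        t = mx.ngtdm(q)
        # center voxel (code 1): 26 neighbors all code 0
        assert t.s[1] == pytest.approx(1.0)
        # 8 corners see the center among 7 neighbors, 12 edges among 11,
        # 6 faces among 17
        assert t.s[0] == pytest.approx(8 / 7 + 12 / 11 + 6 / 17)
        assert t.n_valid == 27

    @pytest.mark.parametrize("name", ["constant4", "checker221", "run331",
                                      "twoblob441", "deviant333"])
    def test_table_equals_neighborhood_oracle(self, micro_fixtures, name):
        vox, mask = micro_fixtures[name]
        q = quantized(vox, mask, levels=4)
        t = mx.ngtdm(q)
        p, s, n_valid = oracles.ngtdm_table(q.codes, 4)
        np.testing.assert_allclose(t.p, p)
        np.testing.assert_allclose(t.s, s)
        assert t.n_valid == n_valid

    def test_feature_count(self, random_patch):
        f = mx.ngtdm_features(mx.ngtdm(no.quantize(random_patch, 4)))
        assert len(f) == 5
        assert set(f) == {"coarseness", "contrast", "busyness", "complexity", "strength"}


class TestFractal:
    def test_solid_cube_dimension_near_three(self):
        patch = make_patch(np.full((16, 16, 16), 1.0))
        f = mx.fractal_features(patch)
        for v in f.values():
            assert v == pytest.approx(3.0, abs=0.2)

    def test_box_count_empty_set(self):
        assert mx.box_count(np.zeros((8, 8, 8), bool), 2) == 0

    def test_box_count_matches_manual_grid(self, rng):
        arr = rng.random((8, 8, 8)) < 0.2
        for s in (2, 4):
            manual = 0
            for x in range(0, 8, s):
                for y in range(0, 8, s):
                    for z in range(0, 8, s):
                        if arr[x:x + s, y:y + s, z:z + s].any():
                            manual += 1
            assert mx.box_count(arr, s) == manual

    def test_feature_count_is_eight(self, random_patch):
        f = mx.fractal_features(random_patch)
        assert len(f) == 8
        assert list(f) == [f"FD{p}" for p in range(10, 90, 10)]


class TestFullVector:
    def test_phantom_yields_750_with_table_totals(self):
        vol, mask = no.generate_phantom(no.malignant_default(seed=3, diameter_mm=14.0))
        patch = no.extract_roi(vol, mask)
        feats = no.full_feature_vector(patch)
        assert len(feats) == 750
        from collections import Counter
        from noduleomics.registry import category_of

        totals = Counter(category_of(n) for n in feats)
        assert totals == {"intensity_shape": 33, "log": 96, "wavelet": 128,
                          "laws": 432, "glcm": 26, "rlm": 11, "glszm": 11,
                          "ngtdm": 5, "fractal": 8}

    def test_constant_patch_all_finite(self):
        patch = make_patch(np.full((6, 6, 6), 25.0))
        feats = no.full_feature_vector(patch)
        assert len(feats) == 750
        assert all(np.isfinite(v) for v in feats.values())

    def test_order_follows_registry(self):
        vol, mask = no.generate_phantom(no.benign_default(seed=5, diameter_mm=10.0))
        feats = no.full_feature_vector(no.extract_roi(vol, mask))
        assert list(feats) == no.feature_names()
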