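"""Texture feature bank: hand-derived micro-examples, brute-force oracle
equivalence for GLCM/GLRLM, and the bank's invariance/completeness
contracts."""

import numpy as np
import pandas as pd
import pytest

from lsccpim.synth import TextureParams, TumorPhantom, generate_tumor_phantom
from lsccpim.texture import (DIRECTIONS_2D, DIRECTIONS_3D, FeatureBankConfig,
                             extract_feature_bank, feature_manifest,
                             first_order_features, gabor_features,
                             glcm_features, glcm_matrix, glrlm_features,
                             glrlm_matrix, quantize, TextureFeatureBank)

# ---------------------------------------------------------------------------
# independent oracles: exhaustive pair / run enumeration


def glcm_brute(grid, mask, offset, G):
    counts = np.zeros((G, G))
    for idx in np.ndindex(*grid.shape):
        jdx = tuple(i + o for i, o in zip(idx, offset))
        if all(0 <= j < s for j, s in zip(jdx, grid.shape)):
            if mask[idx] and mask[jdx]:
                counts[grid[idx] - 1, grid[jdx] - 1] += 1
    sym = counts + counts.T
    return sym / sym.sum() if sym.sum() else None


def glrlm_brute(grid, mask, direction, G, max_len):
    R = np.zeros((G, max_len), dtype=int)
    for idx in np.ndindex(*grid.shape):
        if not mask[idx]:
            continue
        prev = tuple(i - d for i, d in zip(idx, direction))
        in_prev = all(0 <= p < s for p, s in zip(prev, grid.shape))
        if in_prev and mask[prev] and grid[prev] == grid[idx]:
            continue  # not a run start
        length = 1
        nxt = tuple(i + d for i, d in zip(idx, direction))
        while (all(0 <= v < s for v, s in zip(nxt, grid.shape))
               and mask[nxt] and grid[nxt] == grid[idx]):
            length += 1
            nxt = tuple(v + d for v, d in zip(nxt, direction))
        R[grid[idx] - 1, length - 1] += 1
    return R


def random_quantized(rng, shape, G, p_mask=0.85):
    from lsccpim.texture import QuantizedVolume
    grid = rng.integers(1, G + 1, size=shape)
    mask = rng.uniform(size=shape) < p_mask
    if not mask.any():
        mask.flat[0] = True
    grid = np.where(mask, grid, 0)
    return QuantizedVolume(grid=grid, G=G, mask=mask)


# ---------------------------------------------------------------------------


class TestQuantize:
    def test_constant_region_maps_to_level_one(self):
        vol = np.full((4, 4, 4), 7.0)
        mask = np.ones_like(vol, bool)
        q = quantize(vol, mask, 8)
        assert (q.grid[mask] == 1).all()

    def test_equal_width_two_levels(self):
        vol = np.arange(256, dtype=float).reshape(4, 8, 8)
        mask = np.ones_like(vol, bool)
        q = quantize(vol, mask, 2)
        assert (q.grid[vol < 128] == 1).all()
        assert (q.grid[vol >= 128] == 2).all()

    def test_support_within_levels(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(6, 6, 6))
        mask = rng.uniform(size=vol.shape) < 0.7
        mask.flat[0] = True
        for G in (2, 8, 64):
            q = quantize(vol, mask, G)
            assert q.grid[mask].min() >= 1 and q.grid[mask].max() <= G
            assert (q.grid[~mask] == 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool), 8)


class TestFirstOrder:
    def test_hand_computed_population_variance(self):
        vol = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        mask = np.ones_like(vol, bool)
        f = first_order_features(vol, mask)
        assert f["variance"] == pytest.approx(1.25)
        assert f["mean"] == pytest.approx(2.5)

    def test_constant_region(self):
        f = first_order_features(np.full((3, 3, 3), 5.0),
                                 np.ones((3, 3, 3), bool))
        assert f["variance"] == 0.0
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])
        assert f["entropy"] == 0.0

    def test_shift_invariance_of_central_moments(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(size=(5, 5, 5))
        mask = rng.uniform(size=vol.shape) < 0.8
        mask.flat[:2] = True
        a = first_order_features(vol, mask)
        b = first_order_features(vol + 100.0, mask)
        for key in ("variance", "sd", "skewness", "kurtosis", "range", "mad"):
            assert a[key] == pytest.approx(b[key], rel=1e-9)


class TestGLCM:
    def test_hand_enumerated_row(self):
        # row [1,1,1,2], offset +1, symmetric: P(1,1)=2/3, P(1,2)=P(2,1)=1/6
        from lsccpim.texture import QuantizedVolume
        grid = np.array([[1, 1, 1, 2]])
        q = QuantizedVolume(grid=grid, G=2, mask=np.ones_like(grid, bool))
        P = glcm_matrix(q, (0, 1))
        assert P[0, 0] == pytest.approx(2 / 3)
        assert P[0, 1] == pytest.approx(1 / 6)
        assert P[1, 0] == pytest.approx(1 / 6)
        f = glcm_features(P)
        assert f["cluster_shade"] == pytest.approx(2 / 27)

    def test_constant_region_has_zero_cluster_shade(self):
        from lsccpim.texture import QuantizedVolume
        grid = np.ones((3, 3), dtype=int)
        q = QuantizedVolume(grid=grid, G=8, mask=np.ones_like(grid, bool))
        P = glcm_matrix(q, (0, 1))
        f = glcm_features(P)
        assert f["cluster_shade"] == pytest.approx(0.0)
        assert f["contrast"] == 0.0
        assert np.isnan(f["correlation"])  # degenerate marginal

    def test_no_valid_pairs_is_missing_not_zero(self):
        from lsccpim.texture import QuantizedVolume
        grid = np.array([[1, 0, 2]])
        mask = np.array([[True, False, True]])
        q = QuantizedVolume(grid=grid, G=2, mask=mask)
        assert glcm_matrix(q, (0, 1)) is None

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        ndim = rng.choice([2, 3])
        shape = tuple(rng.integers(3, 9, size=ndim))
        G = int(rng.choice([2, 4, 8]))
        q = random_quantized(rng, shape, G)
        dirs = DIRECTIONS_2D if ndim == 2 else DIRECTIONS_3D
        off = tuple(int(rng.choice([1, 2])) * c
                    for c in dirs[rng.integers(len(dirs))])
        P = glcm_matrix(q, off)
        expected = glcm_brute(q.grid, q.mask, off, G)
        if expected is None:
            assert P is None
        else:
            np.testing.assert_allclose(P, expected, atol=1e-12)


class TestGLRLM:
    def test_hand_enumerated_row(self):
        # row [2,2,1]: runs {(2, len 2), (1, len 1)}; LGRE = 0.625
        from lsccpim.texture import QuantizedVolume
        grid = np.array([[2, 2, 1]])
        q = QuantizedVolume(grid=grid, G=2, mask=np.ones_like(grid, bool))
        R = glrlm_matrix(q, (0, 1))
        assert R[1, 1] == 1 and R[0, 0] == 1 and R.sum() == 2
        f = glrlm_features(R, n_voxels=3)
        assert f["lgre"] == pytest.approx(0.625)

    def test_constant_region_lgre_is_one(self):
        from lsccpim.texture import QuantizedVolume
        grid = np.ones((4, 4), dtype=int)
        q = QuantizedVolume(grid=grid, G=4, mask=np.ones_like(grid, bool))
        R = glrlm_matrix(q, (0, 1))
        f = glrlm_features(R, n_voxels=16)
        assert f["lgre"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence_random_grids(self, seed):
        rng = np.random.default_rng(100 + seed)
        ndim = rng.choice([2, 3])
        shape = tuple(rng.integers(3, 9, size=ndim))
        G = int(rng.choice([2, 3, 4]))
        q = random_quantized(rng, shape, G)
        dirs = DIRECTIONS_2D if ndim == 2 else DIRECTIONS_3D
        direc = dirs[rng.integers(len(dirs))]
        R = glrlm_matrix(q, direc)
        expected = glrlm_brute(q.grid, q.mask, direc, G, R.shape[1])
        np.testing.assert_array_equal(R, expected)


class TestGabor:
    def test_constant_slice_gives_zero_response(self):
        img = np.full((32, 32), 50.0)
        mask = np.ones_like(img, bool)
        f = gabor_features(img, mask, frequency=0.2, orientation=0.0)
        assert f["variance"] == pytest.approx(0.0, abs=1e-6 * 50.0)
        assert f["entropy"] == pytest.approx(0.0, abs=1e-6)

    def test_matched_orientation_maximizes_response(self):
        # plane sinusoid along x at the kernel frequency
        x = np.arange(48)
        img = np.tile(np.sin(2 * np.pi * 0.2 * x), (48, 1))
        mask = np.ones_like(img, bool)
        aligned = gabor_features(img, mask, 0.2, 0.0)
        orthogonal = gabor_features(img, mask, 0.2, np.pi / 2)
        assert aligned["variance"] > orthogonal["variance"]

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            gabor_features(np.zeros((8, 8)), np.ones((8, 8), bool), 0.7, 0.0)


class TestFeatureBank:
    def test_cardinality_matches_config(self, small_phantom):
        cfg = FeatureBankConfig()
        fv = extract_feature_bank(small_phantom, cfg)
        assert len(fv) == cfg.n_features_3d + cfg.n_features_2d == 592

    def test_identical_phantoms_identical_vectors(self, small_phantom):
        a = extract_feature_bank(small_phantom)
        b = extract_feature_bank(small_phantom)
        pd.testing.assert_series_equal(a, b)

    def test_same_key_set_across_patients(self):
        cfg = FeatureBankConfig()
        bank = TextureFeatureBank(cfg).fit()
        phantoms = [generate_tumor_phantom(TextureParams(), (16, 16, 16), seed=s)
                    for s in (0, 1)]
        df = bank.transform(phantoms)
        assert list(df.columns) == cfg.feature_ids()
        assert df.shape == (2, 592)

    def test_quantized_features_shift_invariant(self, small_phantom):
        shifted = TumorPhantom(volume=small_phantom.volume + 250.0,
                               mask=small_phantom.mask,
                               voxel_spacing=small_phantom.voxel_spacing)
        a = extract_feature_bank(small_phantom)
        b = extract_feature_bank(shifted)
        glcm_ids = [i for i in a.index if "_glcm_" in i or "_glrlm_" in i]
        np.testing.assert_allclose(a[glcm_ids], b[glcm_ids], rtol=1e-9)

    def test_glcm_direction_average_rotation_invariant(self, small_phantom):
        rot = TumorPhantom(volume=np.rot90(small_phantom.volume, axes=(1, 2)),
                           mask=np.rot90(small_phantom.mask, axes=(1, 2)),
                           voxel_spacing=small_phantom.voxel_spacing)
        a = extract_feature_bank(small_phantom)
        b = extract_feature_bank(rot)
        ids = [i for i in a.index if i.startswith("3d_glcm_")
               and i.endswith("_mean")]
        np.testing.assert_allclose(a[ids], b[ids], rtol=1e-8)

    def test_manifest_covers_every_id(self):
        cfg = FeatureBankConfig()
        man = feature_manifest(cfg)
        assert set(man) == set(cfg.feature_ids())
        assert {m["dim"] for m in man.values()} == {"3D", "2D"}

    def test_texture_classes_are_separable(self):
        # two texture classes at contrast ratio 2: at least one GLCM
        # feature separates them with AUC > 0.9 (this grounds the claim
        # that the signature can carry hazard information)
        from sklearn.metrics import roc_auc_score
        cfg = FeatureBankConfig()
        bank = TextureFeatureBank(cfg).fit()
        a = [generate_tumor_phantom(
            TextureParams(correlation_length=3.0, contrast=1.0),
            (16, 16, 16), seed=s) for s in range(8)]
        b = [generate_tumor_phantom(
            TextureParams(correlation_length=1.5, contrast=2.0),
            (16, 16, 16), seed=100 + s) for s in range(8)]
        df = bank.transform(a + b)
        y = np.repeat([0, 1], 8)
        glcm_cols = [c for c in df.columns if c.startswith("3d_glcm_")]
        aucs = [roc_auc_score(y, df[c]) for c in glcm_cols
                if df[c].notna().all()]
        aucs = np.array(aucs)
        assert np.maximum(aucs, 1 - aucs).max() > 0.9
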