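import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stomaseg.tiling import (
    AugmentationSpec,
    BlurSpec,
    TilePair,
    TilingConfig,
    apply_augmentation,
    build_epoch_dataset,
    geometric_variants,
    tile_origins,
    tile_pairs,
)


def _tile(seed=0, n=16):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(n, n), dtype=np.uint8)
    msk = rng.random((n, n)) < 0.3
    return TilePair(image_tile=img, mask_tile=msk, origin=(0, 0))


class TestTileOrigins:
    def test_single_window(self):
        img = np.zeros((128, 128), dtype=np.uint8)
        tiles = tile_pairs(img, np.zeros_like(img, dtype=bool))
        assert len(tiles) == 1 and tiles[0].origin == (0, 0)

    def test_352_gives_three_origins(self):
        assert tile_origins(352, 128, 112) == [0, 112, 224]
        img = np.zeros((352, 128), dtype=np.uint8)
        assert len(tile_pairs(img, np.zeros_like(img, dtype=bool))) == 3

    def test_300_gets_edge_flush_origin(self):
        assert tile_origins(300, 128, 112) == [0, 112, 172]
        img = np.zeros((300, 300), dtype=np.uint8)
        assert len(tile_pairs(img, np.zeros_like(img, dtype=bool))) == 9

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(h=st.integers(128, 500), w=st.integers(128, 500))
    def test_full_coverage(self, h, w):
        cover = np.zeros((h, w), dtype=int)
        win, stride = 128, 112
        for r in tile_origins(h, win, stride):
            for c in tile_origins(w, win, stride):
                cover[r : r + win, c : c + win] += 1
        assert cover.min() >= 1

    def test_overlap_yields_more_tiles_than_none(self):
        img = np.zeros((512, 512), dtype=np.uint8)
        msk = np.zeros_like(img, dtype=bool)
        with_overlap = len(tile_pairs(img, msk, TilingConfig(window=128, overlap=16)))
        without = len(tile_pairs(img, msk, TilingConfig(window=128, overlap=0)))
        assert with_overlap > without

    def test_too_small_image_rejected(self):
        img = np.zeros((100, 100), dtype=np.uint8)
        with pytest.raises(ValueError, match="smaller than"):
            tile_pairs(img, np.zeros_like(img, dtype=bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ in shape"):
            tile_pairs(np.zeros((128, 128)), np.zeros((128, 130), dtype=bool))


class TestGeometricVariants:
    def test_asymmetric_tile_has_eight_distinct_variants(self):
        variants = geometric_variants(_tile(seed=3))
        assert len(variants) == 8
        rasters = {v.image_tile.tobytes() for v in variants}
        assert len(rasters) == 8
        # image and mask transformed identically: foreground travels together
        for v in variants:
            assert v.mask_tile.sum() == variants[0].mask_tile.sum()

    def test_uniform_tile_variants_identical(self):
        t = TilePair(np.full((8, 8), 7, dtype=np.uint8), np.zeros((8, 8), dtype=bool), (0, 0))
        rasters = {v.image_tile.tobytes() for v in geometric_variants(t)}
        assert len(rasters) == 1

    def test_four_turns_no_flip_is_identity(self):
        t = _tile(seed=1)
        out = apply_augmentation(t, AugmentationSpec(quarter_turns=4, vertical_flip=False))
        np.testing.assert_array_equal(out.image_tile, t.image_tile)
        np.testing.assert_array_equal(out.mask_tile, t.mask_tile)

    def test_double_flip_is_identity(self):
        t = _tile(seed=2)
        once = apply_augmentation(t, AugmentationSpec(quarter_turns=4, vertical_flip=True))
        twice = apply_augmentation(once, AugmentationSpec(quarter_turns=4, vertical_flip=True))
        np.testing.assert_array_equal(twice.image_tile, t.image_tile)

    def test_non_square_rejected(self):
        t = TilePair(np.zeros((4, 6), dtype=np.uint8), np.zeros((4, 6), dtype=bool), (0, 0))
        with pytest.raises(ValueError, match="square"):
            geometric_variants(t)


class TestApplyAugmentation:
    def test_zero_sigma_blur_is_identity(self):
        t = _tile(seed=4)
        out = apply_augmentation(
            t, AugmentationSpec(quarter_turns=4, blur=BlurSpec(kernel=3, sigma=0.0))
        )
        np.testing.assert_array_equal(out.image_tile, t.image_tile)

    def test_blur_touches_image_only(self):
        t = _tile(seed=5)
        out = apply_augmentation(
            t, AugmentationSpec(quarter_turns=4, blur=BlurSpec(kernel=7, sigma=2.5))
        )
        assert not np.array_equal(out.image_tile, t.image_tile)
        np.testing.assert_array_equal(out.mask_tile, t.mask_tile)

    @pytest.mark.parametrize("seed", range(20))
    def test_mask_stays_binary_under_any_augmentation(self, seed):
        rng = np.random.default_rng(seed)
        t = _tile(seed=seed)
        aug = AugmentationSpec(
            quarter_turns=int(rng.integers(1, 5)),
            vertical_flip=bool(rng.integers(0, 2)),
            blur=BlurSpec(kernel=int(rng.choice([3, 5, 7])), sigma=float(rng.uniform(0, 3))),
        )
        out = apply_augmentation(t, aug)
        assert out.mask_tile.dtype == bool

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            BlurSpec(kernel=4, sigma=1.0)
        with pytest.raises(ValueError):
            BlurSpec(kernel=3, sigma=3.5)
        with pytest.raises(ValueError):
            AugmentationSpec(quarter_turns=0)


class TestBuildEpochDataset:
    def test_cardinality_preserved(self):
        tiles = [_tile(seed=i) for i in range(7)]
        assert len(build_epoch_dataset(tiles, epoch_seed=1)) == 7

    def test_same_seed_same_dataset(self):
        tiles = [_tile(seed=i) for i in range(5)]
        a = build_epoch_dataset(tiles, epoch_seed=11)
        b = build_epoch_dataset(tiles, epoch_seed=11)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.image_tile, y.image_tile)

    def test_different_seeds_differ(self):
        tiles = [_tile(seed=i) for i in range(5)]
        a = build_epoch_dataset(tiles, epoch_seed=11)
        b = build_epoch_dataset(tiles, epoch_seed=12)
        assert any(not np.array_equal(x.image_tile, y.image_tile) for x, y in zip(a, b))

    def test_blur_and_kernel_frequencies(self):
        # over 3000 draws: blur rate within 3 sigma of 1/3; kernels uniform
        from stomaseg.tiling import sample_augmentation

        rng = np.random.default_rng(123)
        n = 3000
        specs = [sample_augmentation(rng) for _ in range(n)]
        n_blur = sum(s.blur is not None for s in specs)
        p = 1 / 3
        assert abs(n_blur - n * p) < 3 * np.sqrt(n * p * (1 - p))
        kernels = [s.blur.kernel for s in specs if s.blur is not None]
        for k in (3, 5, 7):
            cnt = kernels.count(k)
            assert abs(cnt - len(kernels) / 3) < 3 * np.sqrt(len(kernels) * (1 / 3) * (2 / 3))

    def test_empty_tiles_rejected(self):
        with pytest.raises(ValueError):
            build_epoch_dataset([], epoch_seed=0)
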