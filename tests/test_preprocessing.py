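"""Multi-window edge-fusion pipeline against independent oracles."""

import numpy as np
import pytest

from milcta import (
    PreprocessParams,
    WindowSpec,
    clip_and_normalize,
    fuse_max,
    label_and_rank,
    preprocess_slice,
    sobel_edges,
    threshold_and_clean,
)
from milcta.core import HUSlice
from milcta.synthetic import SliceTruth, generate_slice


def brute_force_sobel(norm: np.ndarray) -> np.ndarray:
    """Direct 3×3 convolution oracle with reflect padding, scaled by 4√2."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = kx.T
    padded = np.pad(norm.astype(float), 1, mode="symmetric")  # edge-repeating reflection
    h, w = norm.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = padded[i : i + 3, j : j + 3]
            gx[i, j] = (win * kx[::-1, ::-1]).sum()  # convolution flips the kernel
            gy[i, j] = (win * ky[::-1, ::-1]).sum()
    return np.sqrt(gx**2 + gy**2) / (4 * np.sqrt(2))


class TestWindowing:
    @pytest.mark.parametrize(
        "value,window,expected",
        [
            (-150.0, (-150, -50), 0.0),
            (-100.0, (-150, -50), 0.5),
            (-50.0, (-150, -50), 1.0),
            (2000.0, (400, 1000), 1.0),
            (700.0, (400, 1000), 0.5),
            (-500.0, (-150, -50), 0.0),
        ],
    )
    def test_linear_clip_map(self, value, window, expected):
        out = clip_and_normalize(np.full((4, 4), value, dtype=np.float32), WindowSpec(*window))
        assert out == pytest.approx(np.full((4, 4), expected), abs=1e-6)

    def test_windowing_is_idempotent(self, rng):
        img = rng.uniform(-300, 1200, size=(16, 16)).astype(np.float32)
        once = clip_and_normalize(img, WindowSpec(-50, 50))
        twice = clip_and_normalize(once, WindowSpec(0, 1))
        np.testing.assert_allclose(twice, once, atol=1e-6)

    def test_nonfinite_pixels_rejected(self):
        bad = HUSlice("p", 0, np.array([[np.nan, 0.0], [0.0, 0.0]], dtype=np.float32))
        with pytest.raises(ValueError, match="p:0000"):
            clip_and_normalize(bad, WindowSpec(0, 100))

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(100, 100)


class TestSobel:
    def test_constant_input_gives_zero_edges(self):
        assert not sobel_edges(np.full((9, 9), 0.7)).any()

    def test_step_edge_matches_brute_force_and_peaks(self, rng):
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        out = sobel_edges(img)
        np.testing.assert_allclose(out, brute_force_sobel(img), atol=1e-6)
        # boundary columns attain the map's maximum
        assert set(np.argwhere(out == out.max())[:, 1]) <= {3, 4}

    def test_random_grids_match_oracle_and_stay_bounded(self, rng):
        for _ in range(5):
            img = rng.random((7, 9))
            out = sobel_edges(img)
            np.testing.assert_allclose(out, brute_force_sobel(img), atol=1e-6)
            assert out.max() <= 1.0 and out.min() >= 0.0


class TestFuseMax:
    def test_identity_and_zero_neutral(self, rng):
        a = rng.random((6, 6)).astype(np.float32)
        np.testing.assert_array_equal(fuse_max([a]), a)
        np.testing.assert_array_equal(fuse_max([a, np.zeros_like(a)]), a)

    def test_pointwise_dominance_commutativity_associativity(self, rng):
        a, b, c = (rng.random((5, 5)).astype(np.float32) for _ in range(3))
        out = fuse_max([a, b])
        assert (out >= a).all() and (out >= b).all()
        np.testing.assert_array_equal(out, fuse_max([b, a]))
        np.testing.assert_array_equal(fuse_max([fuse_max([a, b]), c]), fuse_max([a, fuse_max([b, c])]))
        # pointwise maximum oracle
        np.testing.assert_array_equal(out, np.where(a >= b, a, b))

    def test_shape_mismatch_and_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_max([rng.random((4, 4)), rng.random((5, 5))])
        with pytest.raises(ValueError):
            fuse_max([])


def _blob_map(area: int, size: int = 48, value: float = 0.9) -> np.ndarray:
    """Edge map with one rectangular component of exactly ``area`` pixels,
    placed away from the border margin."""
    out = np.zeros((size, size), dtype=np.float32)
    rows = area // 10
    rem = area % 10
    out[20 : 20 + rows, 20:30] = value
    if rem:
        out[20 + rows, 20 : 20 + rem] = value
    return out


class TestThresholdAndClean:
    def test_small_object_removal_is_strict_below_20(self):
        params = PreprocessParams()
        assert not threshold_and_clean(_blob_map(19), params).any()
        assert threshold_and_clean(_blob_map(20), params).sum() == 20

    def test_border_frame_is_cleared(self):
        params = PreprocessParams()
        fused = np.zeros((48, 48), dtype=np.float32)
        fused[:6, :30] = 0.9  # 180-px structure entirely inside the margin
        assert not threshold_and_clean(fused, params).any()

    def test_zero_map_stays_zero_and_threshold_applies(self):
        params = PreprocessParams()
        assert not threshold_and_clean(np.zeros((32, 32), dtype=np.float32), params).any()
        sub = _blob_map(100, value=params.edge_threshold / 2)
        assert not threshold_and_clean(sub, params).any()


class TestComponentRanking:
    def test_single_component_scores_one(self):
        mask = _blob_map(30) > 0
        table = label_and_rank(mask, PreprocessParams())
        assert len(table) == 1
        assert table.iloc[0]["composite_score"] == pytest.approx(1.0)
        assert table.iloc[0]["rank"] == 1

    def test_larger_square_dominates(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:20, 10:20] = True  # 10×10
        mask[40:44, 40:44] = True  # 4×4
        table = label_and_rank(mask, PreprocessParams()).set_index("rank").sort_index()
        assert table.loc[1, "area"] == 100.0
        assert table.loc[2, "area"] == 16.0
        # oracle: the larger square dominates every metric, so its min-max
        # normalized scores are all 1 and the smaller's all 0
        assert table.loc[1, "composite_score"] == pytest.approx(1.0)
        assert table.loc[2, "composite_score"] == pytest.approx(0.0)

    def test_empty_mask_yields_empty_table(self):
        table = label_and_rank(np.zeros((16, 16), dtype=bool), PreprocessParams())
        assert len(table) == 0

    def test_ranks_are_permutation_and_scores_monotone(self, rng):
        mask = rng.random((64, 64)) > 0.72
        from skimage import morphology

        mask = morphology.remove_small_objects(mask, connectivity=2, max_size=4)
        table = label_and_rank(mask, PreprocessParams())
        if len(table):
            assert sorted(table["rank"]) == list(range(1, len(table) + 1))
            ordered = table.sort_values("rank")["composite_score"].to_numpy()
            assert (np.diff(ordered) <= 1e-12).all()


class TestFullPipeline:
    def test_constant_slice_maps_to_zero(self):
        out = preprocess_slice(np.full((64, 64), -30.0, dtype=np.float32), PreprocessParams(output_size=(48, 48)))
        assert out.shape == (48, 48)
        assert not out.any()

    def test_plaque_region_survives(self, tiny_config):
        params = PreprocessParams(output_size=(64, 64))  # same size: no resize distortion
        hits = 0
        n = 20
        for seed in range(n):
            truth = SliceTruth("p", 0, True, "calcified" if seed % 2 else "soft")
            s = generate_slice(tiny_config, truth, 900 + seed)
            out = preprocess_slice(s, params)
            r0, c0 = truth.plaque_center
            rad = truth.plaque_radius + 2
            rr, cc = np.mgrid[0:64, 0:64]
            hits += bool(out[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2].any())
        assert hits >= 0.95 * n

    def test_small_structures_do_not_change_output(self):
        base = np.full((64, 64), -30.0, dtype=np.float32)
        base[30:36, 30:36] = 450.0  # a real structure (36 px core)
        params = PreprocessParams(output_size=(64, 64))
        with_small = base.copy()
        with_small[50, 50] = 900.0  # isolated speck, far below min_object_px
        np.testing.assert_array_equal(preprocess_slice(base, params), preprocess_slice(with_small, params))

    def test_border_text_leaves_no_component(self):
        img = np.full((64, 64), -30.0, dtype=np.float32)
        img[2:6, 2:20] = 1000.0  # glyph block within the border margin
        out = preprocess_slice(img, PreprocessParams(output_size=(64, 64)))
        assert not out.any()

    def test_output_range_and_size(self, tiny_config):
        s = generate_slice(tiny_config, SliceTruth("p", 0, False), 3)
        out = preprocess_slice(s, PreprocessParams(output_size=(48, 48)))
        assert out.shape == (48, 48)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_transformer_wrapper_matches_function(self, tiny_config):
        from milcta import EdgeFusionPreprocessor

        s = generate_slice(tiny_config, SliceTruth("p", 0, False), 4)
        tf = EdgeFusionPreprocessor(output_size=(48, 48)).fit()
        np.testing.assert_array_equal(
            tf.transform([s])[0], preprocess_slice(s, PreprocessParams(output_size=(48, 48)))
        )
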