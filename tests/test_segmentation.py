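import numpy as np
import pytest

from cornimpurity.errors import DegenerateImageError, ParameterError
from cornimpurity.segmentation import (
    area_filter,
    binarize,
    fill_holes,
    label_components,
    median_filter,
    morph_close,
    morph_dilate,
    morph_open,
    otsu_threshold,
)


def otsu_exhaustive(hist):
    """Independent oracle: try every threshold, score between-class
    variance with plain python loops."""
    total = hist.sum()
    best_t, best_v = None, -1.0
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if total == 0:
            continue
        mu0 = sum(i * hist[i] for i in range(t + 1)) / w0 if w0 else 0.0
        mu1 = sum(i * hist[i] for i in range(t + 1, 256)) / w1 if w1 else 0.0
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_delta_histogram_tie_rule(self):
        hist = np.zeros(256, dtype=int)
        hist[0] = 50
        hist[255] = 50
        assert otsu_threshold(hist) == 0  # every t in 0..254 ties; smallest wins

    def test_matches_exhaustive_search(self, rng):
        for _ in range(300):
            hist = rng.integers(0, 50, size=256)
            hist[rng.integers(0, 256, size=200)] = 0  # sparse cases too
            if np.count_nonzero(hist) < 2:
                continue
            assert otsu_threshold(hist) == otsu_exhaustive(hist.astype(float))

    def test_single_level_degenerate(self):
        hist = np.zeros(256, dtype=int)
        hist[7] = 1000
        with pytest.raises(DegenerateImageError):
            otsu_threshold(hist)

    def test_rejects_malformed_histogram(self):
        with pytest.raises(ParameterError):
            otsu_threshold(np.zeros(100))


class TestBinarize:
    def test_recovers_clean_scene_foreground(self, clean_scene):
        fg = clean_scene.foreground
        mask = binarize(clean_scene.image)
        recall = (mask & fg).sum() / fg.sum()
        assert recall >= 0.99

    def test_all_black_degenerate(self):
        with pytest.raises(DegenerateImageError):
            binarize(np.zeros((8, 8, 3), dtype=np.uint8))

    def test_inversion_gives_complementary_mask(self):
        # two gray levels with equal mass: inverting the image must swap
        # foreground and background exactly
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[:5] = 40
        img[5:] = 200
        mask = binarize(img)
        inv_mask = binarize(255 - img)
        np.testing.assert_array_equal(inv_mask, ~mask)


class TestMorphology:
    def test_open_removes_isolated_pixel(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert not morph_open(m, 1).any()

    def test_open_is_idempotent_and_anti_extensive(self, rng):
        m = rng.uniform(size=(40, 40)) < 0.5
        once = morph_open(m, 2)
        assert (once <= m).all()
        np.testing.assert_array_equal(morph_open(once, 2), once)

    def test_close_bridges_one_pixel_gap_and_is_extensive(self, rng):
        m = np.zeros((7, 11), dtype=bool)
        m[2:5, 1:5] = True
        m[2:5, 6:10] = True  # 1-px gap at column 5
        closed = morph_close(m, 1)
        assert closed[3, 5]
        m2 = rng.uniform(size=(30, 30)) < 0.5
        assert (morph_close(m2, 2) >= m2).all()

    def test_dilate_is_extensive(self, rng):
        m = rng.uniform(size=(30, 30)) < 0.3
        assert (morph_dilate(m, 1) >= m).all()

    def test_radius_validated(self):
        with pytest.raises(ParameterError):
            morph_open(np.zeros((4, 4), dtype=bool), 0)


class TestFillHoles:
    def test_ring_becomes_disk(self):
        yy, xx = np.mgrid[:21, :21]
        r2 = (yy - 10) ** 2 + (xx - 10) ** 2
        ring = (r2 <= 81) & (r2 >= 36)
        disk_full = r2 <= 81
        np.testing.assert_array_equal(fill_holes(ring), disk_full)

    def test_no_holes_identity(self):
        m = np.zeros((15, 15), dtype=bool)
        m[1:5, 1:6] = True
        m[8:14, 3:12] = True  # solid rectangles enclose no background
        np.testing.assert_array_equal(fill_holes(m), m)

    def test_matches_border_flood_fill_oracle(self, rng):
        m = rng.uniform(size=(24, 24)) < 0.55
        filled = fill_holes(m)
        # oracle: 4-connected flood fill of the background from the border
        from collections import deque

        reach = np.zeros_like(m)
        q = deque()
        for i in range(24):
            for j in (0, 23):
                for y, x in ((i, j), (j, i)):
                    if not m[y, x] and not reach[y, x]:
                        reach[y, x] = True
                        q.append((y, x))
        while q:
            y, x = q.popleft()
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if 0 <= ny < 24 and 0 <= nx < 24 and not m[ny, nx] and not reach[ny, nx]:
                    reach[ny, nx] = True
                    q.append((ny, nx))
        np.testing.assert_array_equal(filled, m | ~reach)


class TestMedianFilter:
    def test_removes_isolated_pixel_keeps_solid_interior(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert not median_filter(m, 3).any()
        solid = np.zeros((9, 9), dtype=bool)
        solid[2:7, 2:7] = True
        assert median_filter(solid, 3)[3:6, 3:6].all()

    def test_matches_majority_oracle(self, rng):
        m = rng.uniform(size=(16, 16)) < 0.5
        out = median_filter(m, 3)
        padded = np.pad(m, 1, mode="symmetric")  # scipy's "reflect" convention
        for y in range(16):
            for x in range(16):
                window = padded[y : y + 3, x : x + 3]
                assert out[y, x] == (window.sum() >= 5)

    def test_even_size_rejected(self):
        with pytest.raises(ParameterError):
            median_filter(np.zeros((4, 4), dtype=bool), 4)


class TestComponentsAndAreaFilter:
    def test_component_sizes_sum_to_foreground(self, rng):
        m = rng.uniform(size=(30, 30)) < 0.4
        comps = label_components(m)
        assert comps.sizes.sum() == m.sum()
        assert comps.labels.max() == len(comps.sizes)

    def test_diagonal_touch_is_one_component_at_8_connectivity(self):
        m = np.zeros((4, 4), dtype=bool)
        m[0, 0] = m[1, 1] = True
        assert len(label_components(m, 8).sizes) == 1
        assert len(label_components(m, 4).sizes) == 2

    def test_bract_area_rule_keeps_only_large(self):
        # components of 4600 and 4400 px; threshold 4500 keeps only the large
        m = np.zeros((200, 150), dtype=bool)
        m[2:48, 2:102] = True  # 46 x 100 = 4600
        m[60:104, 2:102] = True  # 44 x 100 = 4400
        out = area_filter(m, 4500, "keep_ge")
        assert out[2:48, 2:102].all() and not out[60:104, 2:102].any()

    def test_stone_area_rule_keeps_only_small(self):
        # components of 350 and 450 px; threshold 400 keeps only the small
        m = np.zeros((60, 60), dtype=bool)
        m[2:16, 2:27] = True  # 14 x 25 = 350
        m[30:48, 2:27] = True  # 18 x 25 = 450
        out = area_filter(m, 400, "keep_lt")
        assert out[2:16, 2:27].all() and not out[30:48, 2:27].any()

    def test_empty_mask_and_retained_sizes_obey_rule(self, rng):
        empty = np.zeros((10, 10), dtype=bool)
        assert not area_filter(empty, 10, "keep_ge").any()
        m = rng.uniform(size=(50, 50)) < 0.45
        out = area_filter(m, 12, "keep_ge")
        assert out.sum() <= m.sum()
        if out.any():
            assert label_components(out).sizes.min() >= 12
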