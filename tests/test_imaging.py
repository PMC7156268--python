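"""Unit and property tests for the shared image operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra.numpy import arrays

from adhesiometry.imaging import (
    BinaryMask,
    DegenerateInputError,
    FormatError,
    IntensityGrid,
    connected_components,
    distance_to_boundary,
    fill_holes_and_largest,
    otsu_threshold,
    read_image,
    watershed_split,
    write_image,
)


# ---------------------------------------------------------------------------
# containers and I/O
# ---------------------------------------------------------------------------


class TestIntensityGrid:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            IntensityGrid(np.full((4, 4), 1.5), 0.01)

    def test_rejects_tiny_and_nonpositive_calibration(self):
        with pytest.raises(ValueError):
            IntensityGrid(np.zeros((1, 5)), 0.01)
        with pytest.raises(ValueError):
            IntensityGrid(np.zeros((4, 4)), 0.0)


@pytest.mark.parametrize("suffix", [".png", ".tif"])
@pytest.mark.parametrize("depth,dtype,scale", [(8, np.uint8, 255), (16, np.uint16, 65535)])
def test_read_image_normalizes_by_bit_depth(tmp_path, suffix, depth, dtype, scale):
    import imageio.v3 as iio

    raw = np.zeros((6, 6), dtype=dtype)
    raw[0, 0] = scale          # full scale -> 1.0
    raw[1, 1] = scale // 5     # 51/255 = 0.2 for 8-bit
    path = tmp_path / f"img{suffix}"
    iio.imwrite(path, raw)
    grid = read_image(path, pixel_size_mm=0.01)
    assert grid.bit_depth_src == depth
    assert grid.pixels[0, 0] == 1.0
    assert grid.pixels[2, 2] == 0.0
    assert grid.pixels[1, 1] == pytest.approx((scale // 5) / scale)


def test_read_image_rejects_multichannel(tmp_path):
    import imageio.v3 as iio

    path = tmp_path / "rgb.png"
    iio.imwrite(path, np.zeros((5, 5, 3), dtype=np.uint8))
    with pytest.raises(FormatError, match="channel"):
        read_image(path, 0.01)


@pytest.mark.parametrize("depth", [8, 16])
def test_write_read_round_trip_within_quantum(tmp_path, depth):
    rng = np.random.default_rng(7)
    grid = IntensityGrid(rng.uniform(0, 1, (16, 16)), 0.02)
    path = tmp_path / "g.tif"
    write_image(grid, path, bit_depth=depth)
    back = read_image(path, 0.02)
    quantum = 1.0 / (2**depth - 1)
    assert np.all(np.abs(back.pixels - grid.pixels) <= quantum)


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------


def otsu_brute_force(values: np.ndarray, n_bins: int) -> float:
    """Independent oracle: score every histogram boundary exhaustively."""
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_score, best_b = -np.inf, None
    for b in range(1, n_bins):
        w0 = counts[:b].sum()
        w1 = counts[b:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float(np.cumsum(counts[:b] * centers[:b])[-1]) / w0
        mu1 = float(np.cumsum(counts[b:] * centers[b:])[-1]) / w1
        score = w0 * w1 * (mu0 - mu1) ** 2
        if score > best_score:
            best_score, best_b = score, b
    return float(edges[best_b])


class TestOtsu:
    def test_two_level_image_threshold_between_levels(self):
        px = np.full((10, 10), 0.1)
        px[:, 5:] = 0.9
        t = otsu_threshold(IntensityGrid(px, 1.0))
        assert 0.1 < t < 0.9

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(IntensityGrid(np.full((8, 8), 0.5), 1.0))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.uniform(0, 1, (16, 16))
        assert otsu_threshold(IntensityGrid(px, 1.0), n_bins=64) == otsu_brute_force(px, 64)


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------


def flood_fill_components(mask: np.ndarray, connectivity: int) -> int:
    """Oracle: count components by explicit stack-based flood fill."""
    offsets4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    offsets = offsets4 + ([(-1, -1), (-1, 1), (1, -1), (1, 1)] if connectivity == 8 else [])
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not seen[r, c]:
                n += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    for dy, dx in offsets:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < rows and 0 <= nx < cols and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return n


class TestConnectedComponents:
    def test_empty_mask(self):
        assert connected_components(BinaryMask(np.zeros((5, 5), bool))).n_labels == 0

    def test_diagonal_pixels_depend_on_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert connected_components(BinaryMask(mask), connectivity=8).n_labels == 1
        assert connected_components(BinaryMask(mask), connectivity=4).n_labels == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        mask=arrays(bool, (12, 12), elements=hst.booleans()),
        connectivity=hst.sampled_from([4, 8]),
    )
    def test_matches_flood_fill_oracle(self, mask, connectivity):
        result = connected_components(BinaryMask(mask), connectivity)
        assert result.n_labels == flood_fill_components(mask, connectivity)
        # labels partition the mask
        assert np.array_equal(result.pixels > 0, mask)


# ---------------------------------------------------------------------------
# watershed
# ---------------------------------------------------------------------------


class TestWatershed:
    def test_empty_mask_gives_zero_labels(self):
        assert watershed_split(BinaryMask(np.zeros((8, 8), bool))).n_labels == 0

    def test_single_disc_one_label(self, disc_mask):
        labels = watershed_split(BinaryMask(disc_mask))
        assert labels.n_labels == 1
        assert np.array_equal(labels.pixels > 0, disc_mask)

    def test_two_overlapping_discs_split_exactly(self, two_disc_mask):
        d1, d2, union = two_disc_mask
        labels = watershed_split(BinaryMask(union))
        assert labels.n_labels == 2
        areas = labels.areas_px()
        assert areas.sum() == union.sum()  # a partition of the union
        disc_area = d1.sum()
        assert np.all(np.abs(areas - disc_area) <= 0.10 * disc_area)

    def test_is_partition_of_mask(self, two_disc_mask):
        _, _, union = two_disc_mask
        labels = watershed_split(BinaryMask(union))
        assert np.array_equal(labels.pixels > 0, union)


# ---------------------------------------------------------------------------
# distance transform and cleanup
# ---------------------------------------------------------------------------


class TestDistanceToBoundary:
    def test_single_true_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        d = distance_to_boundary(BinaryMask(mask))
        assert d[2, 2] == 1.0
        assert d[0, 0] == 0.0

    def test_checkerboard_all_distance_one(self):
        yy, xx = np.indices((8, 8))
        mask = (yy + xx) % 2 == 0
        d = distance_to_boundary(BinaryMask(mask))
        assert np.all(d[mask] == 1.0)

    def test_disc_center_distance_is_radius(self, disc_mask):
        d = distance_to_boundary(BinaryMask(disc_mask))
        assert abs(d.max() - 20) <= 1.0

    def test_lipschitz_between_4_neighbors(self, disc_mask):
        d = distance_to_boundary(BinaryMask(disc_mask))
        assert np.all(np.abs(np.diff(d, axis=0)) <= 1.0 + 1e-9)
        assert np.all(np.abs(np.diff(d, axis=1)) <= 1.0 + 1e-9)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(DegenerateInputError):
            distance_to_boundary(BinaryMask(np.ones((4, 4), bool)))
        with pytest.raises(DegenerateInputError):
            distance_to_boundary(BinaryMask(np.zeros((4, 4), bool)))


class TestFillHolesAndLargest:
    def test_annulus_becomes_filled_disc(self):
        yy, xx = np.indices((40, 40), dtype=float)
        dist = np.hypot(yy - 19.5, xx - 19.5)
        annulus = (dist <= 15) & (dist >= 10)
        filled = fill_holes_and_largest(BinaryMask(annulus))
        assert np.array_equal(filled.pixels, dist <= 15)

    def test_keeps_largest_component_only(self):
        mask = np.zeros((20, 40), bool)
        mask[5:15, 2:12] = True   # 100 px
        mask[5:10, 20:30] = True  # 50 px
        filled = fill_holes_and_largest(BinaryMask(mask))
        assert filled.area_px == 100
        assert not filled.pixels[:, 20:].any()

    def test_single_pixel_unchanged(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert np.array_equal(fill_holes_and_largest(BinaryMask(mask)).pixels, mask)

    def test_empty_mask_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fill_holes_and_largest(BinaryMask(np.zeros((4, 4), bool)))
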