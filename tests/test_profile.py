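"""Tests for scratch geometry, geodesic distances, binning and group stats."""

import heapq

import numpy as np
import pytest

from scratchfret.profile import (
    BinnedProfile,
    DistanceField,
    aggregate_group_profile,
    bin_fret_profile,
    compare_profiles_at_distance,
    quasi_euclidean_distance,
    scratch_edge_masks,
    scratch_mask_from_background,
    side_split_cell_mask,
    welch_ttest,
)
from scratchfret.synthetic import generate_scene

from conftest import small_scene_params

SQRT2 = np.sqrt(2.0)


def dijkstra_oracle(region: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Independent shortest-path oracle with step costs {1, sqrt(2)}."""
    h, w = region.shape
    dist = np.full((h, w), np.inf)
    heap = []
    for r, c in np.argwhere(sources & region):
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, int(r), int(c)))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < h and 0 <= nc < w) or not region[nr, nc]:
                    continue
                nd = d + (SQRT2 if dr and dc else 1.0)
                if nd < dist[nr, nc] - 1e-15:
                    dist[nr, nc] = nd
                    heapq.heappush(heap, (nd, nr, nc))
    dist[~region] = np.nan
    dist[np.isinf(dist)] = np.nan
    return dist


def _profile(ratios, well="w0", group="", n_pixels=None, bin_width=5.0, **kw):
    ratios = np.asarray(ratios, dtype=float)
    n = len(ratios)
    return BinnedProfile(
        bin_edges=np.arange(n + 1) * bin_width,
        mean_donor=np.ones(n),
        mean_acceptor=ratios.copy(),
        mean_ratio=ratios,
        n_pixels=np.full(n, 100) if n_pixels is None else np.asarray(n_pixels),
        well_id=well,
        group_label=group,
        **kw,
    )


class TestScratchMaskFromBackground:
    def test_largest_component_wins(self):
        bg = np.zeros((40, 40), bool)
        bg[2:7, 2:22] = True  # 100 px
        bg[15:35, 10:35] = True  # 500 px
        out = scratch_mask_from_background(bg)
        assert out.sum() == 500 and out[20, 20] and not out[4, 4]

    def test_single_component_identity(self):
        bg = np.zeros((20, 20), bool)
        bg[:, 8:12] = True
        np.testing.assert_array_equal(scratch_mask_from_background(bg), bg)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scratch_mask_from_background(np.zeros((10, 10), bool))

    def test_synthetic_scene_jaccard(self, default_scene):
        from scratchfret.masks import cell_scratch_masks

        don = default_scene.donor_frames[0].astype(float) - 100
        acc = default_scene.acceptor_frames[0].astype(float) - 100
        ms = cell_scratch_masks(don, acc)
        ts = default_scene.truth_scratch_mask[0]
        jac = np.sum(ms.scratch & ts) / np.sum(ms.scratch | ts)
        assert jac >= 0.90


class TestScratchEdgeMasks:
    def test_vertical_band_two_edges(self):
        scratch = np.zeros((60, 80), bool)
        scratch[:, 30:60] = True
        geom = scratch_edge_masks(scratch, dilate_px=2)
        assert geom.left_edge is not None and geom.right_edge is not None
        assert not np.any(geom.left_edge & geom.right_edge)
        # a 1-px edge column dilated by 2 px spans 5 columns
        mid_rows = slice(10, 50)
        left_cols = np.unique(np.argwhere(geom.left_edge[mid_rows])[:, 1])
        assert left_cols.min() == 28 and left_cols.max() == 32
        right_cols = np.unique(np.argwhere(geom.right_edge[mid_rows])[:, 1])
        assert right_cols.min() == 57 and right_cols.max() == 61

    def test_edges_exclude_top_bottom_rows(self):
        scratch = np.zeros((40, 40), bool)
        scratch[:, 15:25] = True
        geom = scratch_edge_masks(scratch, dilate_px=0)
        assert not geom.left_edge[0].any() and not geom.left_edge[-1].any()

    def test_scratch_touching_border_single_edge(self):
        scratch = np.zeros((40, 40), bool)
        scratch[:, 0:12] = True
        with pytest.warns(UserWarning, match="single"):
            geom = scratch_edge_masks(scratch, dilate_px=1)
        assert geom.left_edge is None and geom.right_edge is not None

    def test_wavy_edges_close_to_truth(self):
        p = small_scene_params(edge_wave_amplitude=4.0, edge_wave_period=40.0, noise_sd=0.0)
        scene = generate_scene(p)
        scratch = scene.truth_scratch_mask[0]
        geom = scratch_edge_masks(scratch, dilate_px=2)
        edges = geom.left_edge | geom.right_edge
        # every truth boundary pixel within 2 px of a detected edge pixel
        from scipy.ndimage import binary_erosion, distance_transform_edt

        boundary = scratch & ~binary_erosion(scratch, border_value=1)
        boundary[0] = boundary[-1] = False
        d_to_edge = distance_transform_edt(~edges)
        assert d_to_edge[boundary].max() <= 2.0 + 1e-9

    def test_empty_scratch_rejected(self):
        with pytest.raises(ValueError):
            scratch_edge_masks(np.zeros((10, 10), bool))


class TestSideSplitCellMask:
    def test_symmetric_split(self):
        scratch = np.zeros((40, 41), bool)
        scratch[:, 18:23] = True
        cells = ~scratch
        left, right = side_split_cell_mask(cells, scratch)
        assert left.sum() == right.sum() == 18 * 40
        assert not np.any(left & right)

    def test_one_side_empty_ok(self):
        scratch = np.zeros((30, 30), bool)
        scratch[:, 20:26] = True
        cells = np.zeros((30, 30), bool)
        cells[:, 26:] = True
        left, right = side_split_cell_mask(cells, scratch)
        assert not left.any() and right.sum() == cells.sum()

    def test_synthetic_scene_side_accuracy(self, default_scene):
        scratch = default_scene.truth_scratch_mask[0]
        cells = default_scene.truth_cell_mask[0]
        left, right = side_split_cell_mask(cells, scratch)
        w = scratch.shape[1]
        truth_left = cells & (np.arange(w)[None, :] < w / 2)
        agree = (left & truth_left) | (right & cells & ~truth_left)
        assert agree.sum() / cells.sum() >= 0.99

    def test_pixels_inside_span_assigned_nearer_side(self):
        scratch = np.zeros((10, 21), bool)
        scratch[:, 8:13] = True
        cells = np.zeros((10, 21), bool)
        cells[:, 9] = True  # inside span, nearer left
        cells[:, 12] = True  # inside span, nearer right
        left, right = side_split_cell_mask(cells, scratch)
        assert left[:, 9].all() and right[:, 12].all()


class TestQuasiEuclideanDistance:
    def test_source_zero_and_neighbours(self):
        region = np.ones((5, 5), bool)
        src = np.zeros((5, 5), bool)
        src[2, 2] = True
        d = quasi_euclidean_distance(region, src, pixel_scale=0.5).distance
        assert d[2, 2] == 0.0
        assert d[2, 3] == pytest.approx(0.5)
        assert d[3, 3] == pytest.approx(0.5 * SQRT2)

    def test_matches_dijkstra_on_random_obstacles(self, rng):
        for _ in range(10):
            region = rng.random((32, 32)) > 0.25
            src = np.zeros((32, 32), bool)
            src[rng.integers(0, 32), rng.integers(0, 32)] = True
            if not (src & region).any():
                continue
            mine = quasi_euclidean_distance(region, src, 1.0).distance
            oracle = dijkstra_oracle(region, src)
            np.testing.assert_allclose(mine, oracle, atol=1e-9, equal_nan=True)

    def test_unreachable_is_nan(self):
        region = np.ones((5, 5), bool)
        region[:, 2] = False  # wall
        src = np.zeros((5, 5), bool)
        src[2, 0] = True
        d = quasi_euclidean_distance(region, src, 1.0).distance
        assert np.isnan(d[2, 4]) and np.isnan(d[2, 2])

    def test_no_source_in_region_rejected(self):
        region = np.ones((4, 4), bool)
        region[0, 0] = False
        src = np.zeros((4, 4), bool)
        src[0, 0] = True
        with pytest.raises(ValueError, match="source"):
            quasi_euclidean_distance(region, src, 1.0)


class TestBinFretProfile:
    def _dist(self, d):
        return DistanceField(distance=np.asarray(d, float), side="left", pixel_scale=1.0)

    def test_uniform_ratio_every_bin(self):
        h, w = 20, 50
        dist = np.tile(np.arange(w, dtype=float), (h, 1))
        don = np.full((h, w), 200.0)
        acc = 1.0 * don
        prof = bin_fret_profile(self._dist(dist), don, acc, bin_width=5.0)
        assert np.all(prof.n_pixels == 100)
        np.testing.assert_allclose(prof.mean_ratio, 1.0, atol=1e-12)

    def test_fully_masked_bin_missing(self):
        dist = np.tile(np.arange(20, dtype=float), (4, 1))
        don = np.full((4, 20), 100.0)
        acc = don.copy()
        don[:, 5:10] = np.nan  # second bin fully missing
        acc[:, 5:10] = np.nan
        prof = bin_fret_profile(self._dist(dist), don, acc, bin_width=5.0)
        assert prof.n_pixels[1] == 0
        assert np.isnan(prof.mean_ratio[1]) and np.isnan(prof.mean_donor[1])

    def test_pixel_conservation(self):
        rng = np.random.default_rng(0)
        dist = rng.uniform(0, 40, (30, 30))
        dist[rng.random((30, 30)) < 0.2] = np.nan
        don = np.full((30, 30), 100.0)
        prof = bin_fret_profile(self._dist(dist), don, don, bin_width=5.0)
        assert prof.n_pixels.sum() == np.isfinite(dist).sum()

    def test_half_open_bins(self):
        dist = np.array([[0.0, 4.999, 5.0, 9.999]])
        don = np.full((1, 4), 10.0)
        prof = bin_fret_profile(self._dist(dist), don, don, bin_width=5.0)
        assert prof.n_pixels[0] == 2 and prof.n_pixels[1] == 2

    def test_ratio_of_means_vs_mean_of_ratios(self):
        dist = np.zeros((1, 4))
        don = np.array([[100.0, 200.0, 100.0, 200.0]])
        acc = np.array([[200.0, 200.0, 200.0, 200.0]])
        p1 = bin_fret_profile(self._dist(dist), don, acc, bin_width=5.0)
        p2 = bin_fret_profile(self._dist(dist), don, acc, bin_width=5.0, ratio_of_means=False)
        assert p1.mean_ratio[0] == pytest.approx(200.0 / 150.0)
        assert p2.mean_ratio[0] == pytest.approx((2.0 + 1.0 + 2.0 + 1.0) / 4.0)

    def test_correction_folded_once(self):
        from scratchfret.corrections import RatioCorrectionImage

        dist = np.zeros((2, 2))
        don = np.full((2, 2), 100.0)
        acc = np.full((2, 2), 150.0)
        corr = RatioCorrectionImage(np.full((2, 2), 1.5))
        prof = bin_fret_profile(self._dist(dist), don, acc, correction=corr, bin_width=5.0)
        assert prof.mean_ratio[0] == pytest.approx(1.0)


class TestAggregateGroupProfile:
    def test_single_well(self):
        gp = aggregate_group_profile([_profile([1.1, 1.0])])
        np.testing.assert_allclose(gp.mean_ratio, [1.1, 1.0])
        assert np.isnan(gp.sem_ratio).all()
        assert np.all(gp.n_wells == 1)

    def test_two_wells_closed_form(self):
        gp = aggregate_group_profile([_profile([1.0], well="a"), _profile([1.2], well="b")])
        assert gp.mean_ratio[0] == pytest.approx(1.1)
        assert gp.sem_ratio[0] == pytest.approx(0.1)

    def test_frames_averaged_within_well_first(self):
        profiles = [
            _profile([1.0], well="a", frame_time=0.0),
            _profile([2.0], well="a", frame_time=15.0),
            _profile([3.0], well="b"),
        ]
        gp = aggregate_group_profile(profiles)
        assert gp.mean_ratio[0] == pytest.approx((1.5 + 3.0) / 2.0)

    def test_simulated_wells_consistency(self):
        rng = np.random.default_rng(7)
        truth = np.array([1.3, 1.2, 1.1, 1.05])
        wells = [
            _profile(truth + rng.normal(0, 0.02, 4), well=f"w{k}") for k in range(27)
        ]
        gp = aggregate_group_profile(wells)
        assert np.all(np.abs(gp.mean_ratio - truth) <= 3 * gp.sem_ratio)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="bin grids"):
            aggregate_group_profile(
                [_profile([1.0]), _profile([1.0], bin_width=10.0, well="b")]
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_group_profile([])


class TestWelchTest:
    def test_identical_groups(self):
        t, p = welch_ttest(np.array([1.0, 1.1, 0.9]), np.array([1.0, 1.1, 0.9]))
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        from scipy import stats

        a = rng.normal(1.0, 0.1, 12)
        b = rng.normal(1.1, 0.2, 9)
        t, p = welch_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_guard(self):
        with pytest.warns(UserWarning, match="epsilon"):
            t, p = welch_ttest(np.array([1.0, 1.0, 1.0]), np.array([2.0, 2.0, 2.0]))
        assert np.isfinite(t) and p < 1e-6

    def test_degenerate_equal_constant_groups(self):
        t, p = welch_ttest(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert (t, p) == (0.0, 1.0)

    def test_too_few_wells_rejected(self):
        with pytest.raises(ValueError):
            welch_ttest(np.array([1.0]), np.array([1.0, 2.0]))


class TestCompareProfilesAtDistance:
    def test_bin_selection(self):
        # bins are [0,5) and [5,10); distance 5.0 selects the second
        ga = [_profile([1.3, 1.25], well=f"a{k}") for k in range(3)]
        gb = [_profile([1.1, 1.08], well=f"b{k}") for k in range(3)]
        for k, p in enumerate(ga + gb):
            p.mean_ratio += 0.01 * (k % 3)
        t5, p5 = compare_profiles_at_distance(ga, gb, distance=5.0)
        assert t5 > 0 and p5 < 0.05
        t2, _ = compare_profiles_at_distance(ga, gb, distance=2.5)
        assert t2 > 0 and t2 != pytest.approx(t5)

    def test_power_simulation(self):
        # true difference 0.1, well sd 0.05, n = 24/group: ~100% power
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(1.3, 0.05, 24)
            b = rng.normal(1.2, 0.05, 24)
            _, p = welch_ttest(a, b)
            rejections += p < 0.05
        assert rejections / n_rep >= 0.99

    def test_too_few_wells_rejected(self):
        ga = [_profile([1.0], well="a0")]
        gb = [_profile([1.0], well=f"b{k}") for k in range(3)]
        with pytest.raises(ValueError):
            compare_profiles_at_distance(ga, gb, distance=2.0)
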