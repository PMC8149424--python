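import numpy as np
import pytest

from enamel_oct import connectivity as conn
from enamel_oct import depth_profile as dp
from enamel_oct import phantom as ph

import oracles


class TestLogFilter:
    def test_kernel_sums_to_zero(self):
        for size, sigma in ((5, 0.5), (7, 1.0), (9, 2.0)):
            assert conn.log_kernel(size, sigma).sum() == pytest.approx(0.0, abs=1e-12)

    def test_constant_image_maps_to_zero(self):
        out = conn.log_filter(np.full((20, 20), 7.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_impulse_response_is_kernel(self):
        img = np.zeros((11, 11))
        img[5, 5] = 1.0
        out = conn.log_filter(img, 5, 0.5)
        np.testing.assert_allclose(out[3:8, 3:8], conn.log_kernel(5, 0.5), atol=1e-12)

    def test_matches_naive_convolution(self, rng):
        img = rng.random((16, 18))
        out = conn.log_filter(img, 5, 0.5)
        expected = oracles.convolve_naive(img, conn.log_kernel(5, 0.5))
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_step_edge_zero_crossing_on_edge(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        out = conn.log_filter(img)
        # response is antisymmetric across the step: sign change within +-1 col
        assert np.all(out[:, 9] * out[:, 10] <= 0)
        assert np.allclose(out[:, :7], 0, atol=1e-10)

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            conn.log_filter(np.zeros((4, 4)), 5, 0.5)


class TestBinarize:
    def test_two_valued_image_against_exhaustive_otsu(self, rng):
        img = np.where(rng.random((50, 50)) < 0.4, 10.0, 200.0)
        mask, t = conn.binarize(img)
        # threshold strictly between the two values; foreground = bright mode
        scaled_low, scaled_high = 0.0, 1.0
        assert scaled_low < t < scaled_high
        assert mask.mean() == pytest.approx((img == 200.0).mean())
        np.testing.assert_array_equal(mask, img == 200.0)

    def test_constant_image_empty_foreground(self):
        with pytest.warns(UserWarning, match="constant"):
            mask, _ = conn.binarize(np.full((10, 10), 3.0))
        assert not mask.any()

    def test_noise_free_phantom_raw_intensity_covers_enamel(self):
        spec = ph.PhantomSpec(
            shape=(300, 128),
            surface=ph.SurfaceModel(base_row=50),
            enamel_thickness_px=150,
            speckle_k=None,
            noise_floor_sigma=0.0,
        )
        bscan, truth = ph.generate_bscan(spec)
        mask, _ = conn.binarize(bscan.pixels)
        assert mask[truth.enamel_mask].mean() > 0.99

    def test_otsu_matches_exhaustive_search_on_random_histograms(self, rng):
        """Otsu equals exhaustive-threshold search on 20 random value sets."""
        for _ in range(20):
            levels = rng.choice(np.arange(256), size=rng.integers(2, 6), replace=False)
            img = rng.choice(levels, size=(40, 40)).astype(float)
            t_impl = conn.otsu_threshold(img, nbins=4096)
            t_oracle = oracles.exhaustive_otsu(img)
            np.testing.assert_array_equal(img > t_impl, img > t_oracle)


class TestTraceComponents:
    def test_diagonal_touch_connectivity_semantics(self):
        mask = np.zeros((8, 8), bool)
        mask[0:3, 0:3] = True
        mask[3:6, 3:6] = True
        labels8, t8 = conn.trace_components(mask, 8, 1)
        labels4, t4 = conn.trace_components(mask, 4, 1)
        assert len(t8) == 1
        assert len(t4) == 2

    def test_checkerboard_matches_flood_fill(self):
        mask = np.indices((4, 4)).sum(axis=0) % 2 == 0
        labels, table = conn.trace_components(mask, 4, 1)
        assert len(table) == 8
        oracle = oracles.flood_fill_components(mask, 4)
        assert oracle.max() == 8

    def test_empty_mask(self):
        labels, table = conn.trace_components(np.zeros((5, 5), bool), 8, 1)
        assert len(table) == 0 and not labels.any()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_masks_match_flood_fill(self, connectivity, rng):
        """Component partition equals brute-force flood fill on 50 random masks."""
        for _ in range(50):
            mask = rng.random((64, 64)) < rng.uniform(0.2, 0.7)
            labels, _ = conn.trace_components(mask, connectivity, min_component_px=1)
            oracle = oracles.flood_fill_components(mask, connectivity)
            assert labels.max() == oracle.max()
            # same partition: label images agree up to renaming
            pairs = {(a, b) for a, b in zip(labels.ravel(), oracle.ravel()) if a or b}
            assert len({a for a, _ in pairs}) == len(pairs)
            assert len({b for _, b in pairs}) == len(pairs)

    def test_labels_ordered_by_size_and_min_size_filter(self, rng):
        mask = np.zeros((30, 30), bool)
        mask[0:2, 0:2] = True      # 4 px -> dropped at min 5
        mask[10:15, 10:20] = True  # 50 px -> label 1
        mask[20:23, 2:5] = True    # 9 px -> label 2
        labels, table = conn.trace_components(mask, 8, min_component_px=5)
        assert table["px"].tolist() == [50, 9]
        assert labels[12, 12] == 1 and labels[21, 3] == 2 and labels[0, 0] == 0

    def test_8_connectivity_never_more_components_than_4(self, rng):
        for _ in range(10):
            mask = rng.random((32, 32)) < 0.5
            _, t8 = conn.trace_components(mask, 8, 1)
            _, t4 = conn.trace_components(mask, 4, 1)
            assert len(t8) <= len(t4)


class TestOpening:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert not conn.open_then_visualize(mask).any()

    def test_solid_block_unchanged(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        np.testing.assert_array_equal(conn.open_then_visualize(mask), mask)

    def test_anti_extensive(self, rng):
        for _ in range(10):
            mask = rng.random((40, 40)) < 0.6
            opened = conn.open_then_visualize(mask)
            assert np.all(mask[opened])  # opened subset of input

    def test_salt_noise_does_not_change_component_count(self, rng):
        spec = ph.PhantomSpec(
            shape=(200, 128), surface=ph.SurfaceModel(base_row=40),
            enamel_thickness_px=100, speckle_k=None, noise_floor_sigma=0.0,
        )
        _, truth = ph.generate_bscan(spec)
        clean = truth.enamel_mask.copy()
        noisy = clean.copy()
        salt = tuple(rng.integers(0, s, 50) for s in clean.shape)
        # only isolated salt (keep pixels away from the band)
        for r, c in zip(*salt):
            if not clean[max(r - 2, 0): r + 3, max(c - 2, 0): c + 3].any():
                noisy[r, c] = True
        n_clean = conn.trace_components(conn.open_then_visualize(clean), 8, 1)[1]
        n_noisy = conn.trace_components(conn.open_then_visualize(noisy), 8, 1)[1]
        assert len(n_clean) == len(n_noisy)


class TestSobelOverlay:
    def test_vertical_step_edge_band(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        edge, *_ = conn.sobel_overlay(img, np.zeros_like(img, bool), 0.5)
        cols = np.unique(np.nonzero(edge)[1])
        assert set(cols) <= {9, 10}
        assert len(cols) >= 1

    def test_constant_image_no_edges(self):
        edge, *_ = conn.sobel_overlay(np.full((10, 10), 2.0), np.zeros((10, 10), bool))
        assert not edge.any()

    def test_empty_edges_overlay_is_grayscale_rgb(self, rng):
        img = rng.random((10, 10))
        edge, overlay_gray, _, _ = conn.sobel_overlay(
            np.full((10, 10), 2.0), np.zeros((10, 10), bool)
        )
        assert overlay_gray.shape == (10, 10, 3)
        assert (overlay_gray[..., 0] == overlay_gray[..., 1]).all()


class TestCloseAndAccount:
    def test_interior_gap_filled(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        mask[9, 9] = False
        closed, _, px = conn.close_and_account(np.ones((20, 20)), mask, 1)
        assert closed[9, 9]
        assert px == mask.sum() + 1

    def test_empty_mask_zero_totals(self):
        closed, total, px = conn.close_and_account(np.ones((10, 10)), np.zeros((10, 10), bool))
        assert total == 0.0 and px == 0

    def test_extensive(self, rng):
        for _ in range(10):
            mask = rng.random((40, 40)) < 0.3
            closed, _, _ = conn.close_and_account(np.ones((40, 40)), mask, 3)
            assert np.all(closed[mask])  # input subset of closed

    def test_intensity_monotone_in_mask(self, rng):
        img = rng.random((30, 30))
        small = rng.random((30, 30)) < 0.2
        big = small | (rng.random((30, 30)) < 0.2)
        assert img[big].sum() >= img[small].sum()

    def test_speckled_phantom_accounting_near_truth(self):
        """Median closed-mask pixel count across seeds within +-5% of truth."""
        ratios = []
        for seed in (3, 11, 42, 7, 19):
            spec = ph.PhantomSpec(
                shape=(400, 256),
                surface=ph.SurfaceModel(base_row=60),
                enamel_thickness_px=200,
                seed=seed,
            )
            bscan, truth = ph.generate_bscan(spec)
            res = conn.run_pipeline(bscan)
            ratios.append(res.total_enamel_px / truth.enamel_mask.sum())
        assert abs(np.median(ratios) - 1.0) <= 0.05


class TestDetectAbrasion:
    def test_identical_masks_no_sites(self):
        mask = np.zeros((30, 30), bool)
        mask[10:20, :] = True
        sites = conn.detect_abrasion(mask, mask, np.full(30, 10))
        assert sites == []

    def test_single_notch_found_with_overlap(self):
        """One 20-px-wide, 5-px-deep notch -> exactly 1 site, >=50% x-overlap."""
        spec = ph.PhantomSpec(
            shape=(300, 256),
            surface=ph.SurfaceModel(base_row=60),
            enamel_thickness_px=150,
            speckle_k=16.0,
            seed=3,
            notches=(ph.AbrasionNotch(x_center=128, width=20, depth_px=5),),
        )
        bscan, truth = ph.generate_bscan(spec)
        surface = dp.detect_surface(bscan)
        res = conn.run_pipeline(bscan, surface_row_per_column=surface)
        assert len(res.abrasion_sites) == 1
        site = res.abrasion_sites[0]
        overlap = max(0, min(site.x_end, 138) - max(site.x_start, 118))
        assert overlap >= 10

    def test_two_disjoint_notches_two_sites(self):
        spec = ph.PhantomSpec(
            shape=(300, 256),
            surface=ph.SurfaceModel(base_row=60),
            enamel_thickness_px=150,
            speckle_k=None,
            noise_floor_sigma=0.0,
            notches=(
                ph.AbrasionNotch(x_center=64, width=20, depth_px=5),
                ph.AbrasionNotch(x_center=192, width=20, depth_px=5),
            ),
        )
        bscan, truth = ph.generate_bscan(spec)
        res = conn.run_pipeline(bscan, surface_row_per_column=dp.detect_surface(bscan))
        assert len(res.abrasion_sites) == 2
        spans = sorted((s.x_start, s.x_end) for s in res.abrasion_sites)
        assert spans[0][0] <= 64 <= spans[0][1]
        assert spans[1][0] <= 192 <= spans[1][1]


class TestPipelineInvariants:
    def test_component_labels_partition_foreground(self, rng):
        mask = rng.random((40, 40)) < 0.4
        labels, _ = conn.trace_components(mask, 8, 1)
        np.testing.assert_array_equal(labels > 0, mask)

    def test_open_subset_input_subset_closed(self, rng):
        mask = rng.random((50, 50)) < 0.4
        opened = conn.open_then_visualize(mask)
        closed, _, _ = conn.close_and_account(np.ones((50, 50)), mask, 1)
        assert np.all(mask[opened])
        assert np.all(closed[mask])

    def test_speckled_series_median_total_decreases(self):
        """Across seeds, median total enamel drops with each treatment stage."""
        deltas = [ph.StageDelta(d) for d in (0, 10, 20, 30)]
        totals = np.zeros((12, 4))
        for i in range(12):
            base = ph.PhantomSpec(
                shape=(300, 256),
                surface=ph.SurfaceModel(base_row=60),
                enamel_thickness_px=200,
                attenuation=0.001,
                seed=i,
            )
            series = ph.generate_treatment_series(base, deltas, seed=i * 10)
            totals[i] = [conn.run_pipeline(b).total_enamel_px for b, _ in series]
        med = np.median(totals, axis=0)
        assert np.all(np.diff(med) < 0)
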