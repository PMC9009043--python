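"""Segmentation stage: hot pixels, scaling, pixel classifier, watershed,
measurement, neighbor graph."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from imcscope import segment, simulate
from imcscope.segment import (
    PixelProbabilities,
    SegmentationParams,
    build_neighbor_graph,
    downscale_mask,
    match_cells,
    measure_cells,
    remove_hot_pixels,
    segment_cells,
    train_pixel_classifier,
    upscale2x,
)


class TestHotPixels:
    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 7.0)
        assert np.array_equal(remove_hot_pixels(img, 5.0), img)

    def test_spike_replaced_by_neighborhood_median(self):
        img = np.full((9, 9), 10.0)
        img[4, 4] = 1000.0
        out = remove_hot_pixels(img, 5.0)
        assert out[4, 4] == 10.0
        assert np.array_equal(out != img, img == 1000.0)

    def test_spike_in_zeros_removed(self):
        img = np.zeros((9, 9))
        img[2, 3] = 50.0
        assert remove_hot_pixels(img, 5.0).sum() == 0

    def test_idempotent_on_isolated_outliers(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(10, (30, 30)).astype(float)
        img[10, 10] = 500
        once = remove_hot_pixels(img, 5.0)
        assert np.array_equal(remove_hot_pixels(once, 5.0), once)

    def test_factor_must_exceed_one(self):
        with pytest.raises(ValueError):
            remove_hot_pixels(np.zeros((4, 4)), 1.0)


class TestScaling:
    def test_upscale_shape(self):
        assert upscale2x(np.zeros((3, 4, 4))).shape == (3, 8, 8)

    def test_mask_downscale_preserves_label_and_area(self):
        mask2x = np.zeros((20, 20), dtype=int)
        mask2x[4:10, 6:12] = 5  # one 6x6 cell
        out = downscale_mask(mask2x)
        assert set(np.unique(out)) == {0, 5}
        assert (out == 5).sum() == 9

    def test_upscale_downscale_mask_identity_on_labels(self):
        rng = np.random.default_rng(1)
        mask = rng.integers(0, 6, (16, 16))
        mask2x = np.kron(mask, np.ones((2, 2), dtype=int))
        assert np.array_equal(downscale_mask(mask2x), mask)

    def test_odd_dimensions_floor(self):
        assert downscale_mask(np.zeros((9, 7), dtype=int)).shape == (4, 3)


class TestPixelClassifier:
    def test_missing_class_named_in_error(self, cr_roi):
        roi, truth = cr_roi
        stack2x = upscale2x(roi.stack[:, :64, :64])
        labels = np.zeros(stack2x.shape[1:], dtype=np.uint8)
        labels[0, 0] = 1
        labels[0, 1] = 2  # background (3) absent
        with pytest.raises(segment.TrainingError, match="background"):
            train_pixel_classifier([stack2x], [labels])

    def test_training_deterministic(self, segmented_cr):
        roi, truth, clf, _, _ = segmented_cr
        stack2x = upscale2x(remove_hot_pixels(roi.stack, 5.0))
        labels2x = simulate.training_labels_from_truth(truth, 1500, seed=0)
        clf2 = train_pixel_classifier([stack2x], [labels2x], seed=0)
        tile = stack2x[:, :100, :100]
        p1 = clf.predict_probabilities(tile)
        p2 = clf2.predict_probabilities(tile)
        assert np.array_equal(p1.nuclear, p2.nuclear)

    def test_heldout_pixel_accuracy(self, segmented_cr):
        """>= 0.9 accuracy against the simulator's true 3-class map on
        pixels not used for training."""
        roi, truth, clf, _, _ = segmented_cr
        stack2x = upscale2x(remove_hot_pixels(roi.stack, 5.0))
        probs = clf.predict_probabilities(stack2x)
        cell2x = np.kron(truth.true_mask, np.ones((2, 2), dtype=int))
        nuc2x = np.kron(truth.nucleus_mask, np.ones((2, 2), dtype=int))
        true_class = np.where(nuc2x > 0, 0, np.where(cell2x > 0, 1, 2))
        pred = np.argmax(
            np.stack([probs.nuclear, probs.cytoplasm, probs.background]), axis=0
        )
        rng = np.random.default_rng(1)
        sel = rng.choice(true_class.size, 20_000, replace=False)
        acc = (pred.ravel()[sel] == true_class.ravel()[sel]).mean()
        assert acc >= 0.9

    def test_probabilities_sum_to_one(self, segmented_cr):
        roi, _, clf, _, _ = segmented_cr
        tile = upscale2x(remove_hot_pixels(roi.stack[:, :80, :80], 5.0))
        probs = clf.predict_probabilities(tile)
        total = probs.nuclear + probs.cytoplasm + probs.background
        rng = np.random.default_rng(0)
        pts = rng.integers(0, total.shape[0], (1000, 2))
        assert np.allclose(total[pts[:, 0], pts[:, 1]], 1.0, atol=1e-9)

    def test_background_tile_classified_background(self, segmented_cr):
        roi, truth, clf, _, _ = segmented_cr
        # carve out a pure-background window from the truth mask
        free = truth.true_mask == 0
        probs = clf.predict_probabilities(
            upscale2x(remove_hot_pixels(roi.stack, 5.0))
        )
        bg2x = np.kron(free, np.ones((2, 2), dtype=bool))
        # away from cell borders: erode the free region
        from scipy.ndimage import binary_erosion

        core = binary_erosion(bg2x, iterations=4)
        assert probs.background[core].mean() > 0.9


class TestSegmentCells:
    def test_all_background_gives_empty_mask(self):
        shape = (64, 64)
        probs = PixelProbabilities(
            nuclear=np.zeros(shape),
            cytoplasm=np.zeros(shape),
            background=np.ones(shape),
        )
        assert segment_cells(probs).max() == 0

    def test_two_disks_separate_cells(self):
        """Probabilities built analytically from two disks 20 px apart."""
        shape = (80, 80)
        yy, xx = np.mgrid[0:80, 0:80]
        nuc = np.zeros(shape)
        cyt = np.zeros(shape)
        for cy, cx in [(30, 30), (30, 58)]:
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            nuc[d2 <= 16] = 1.0
            cyt[(d2 > 16) & (d2 <= 49)] = 1.0
        bg = 1.0 - nuc - cyt
        probs = PixelProbabilities(nuclear=nuc, cytoplasm=cyt, background=bg)
        mask = segment_cells(probs)
        labels = np.unique(mask)
        assert len(labels[labels > 0]) == 2

    def test_synthetic_roi_recall(self, segmented_cr, cr_roi):
        """>= 95% of planted cells recovered 1:1 at IoU >= 0.5 with mean
        centroid error <= 2 px."""
        _, truth, _, mask, _ = segmented_cr
        matches = match_cells(truth.true_mask, mask)
        assert matches["matched"].mean() >= 0.95
        assert matches.loc[matches["matched"], "centroid_error_px"].mean() <= 2.0

    def test_oracle_probabilities_recover_exact_count(self, cr_roi):
        """Analytic probabilities from ground truth give exactly the
        planted cell count."""
        _, truth = cr_roi
        nuc2x = np.kron(truth.nucleus_mask > 0, np.ones((2, 2))).astype(float)
        cell2x = np.kron(truth.true_mask > 0, np.ones((2, 2))).astype(float)
        cyt = cell2x * (1 - nuc2x)
        bg = 1 - cell2x
        probs = PixelProbabilities(nuclear=nuc2x, cytoplasm=cyt, background=bg)
        mask2x = segment_cells(probs)
        n_found = len(np.unique(mask2x)) - 1
        assert n_found == truth.n_cells


class TestMeasureCells:
    def test_single_cell_arithmetic(self, panel):
        mask = np.zeros((5, 5), dtype=int)
        mask[2, :5] = 1
        stack = np.zeros((10, 5, 5))
        stack[panel.index_of("CD3"), 2, :5] = [1, 2, 3, 4, 5]
        table = measure_cells(mask, stack, panel)
        assert table["area_px"].iloc[0] == 5
        assert table["CD3"].iloc[0] == 3.0
        assert table["centroid_row"].iloc[0] == 2.0

    def test_empty_mask_empty_table(self, panel):
        table = measure_cells(np.zeros((8, 8), dtype=int), np.zeros((10, 8, 8)), panel)
        assert table.empty

    def test_shape_mismatch_rejected(self, panel):
        with pytest.raises(ValueError):
            measure_cells(np.zeros((8, 8), dtype=int), np.zeros((10, 9, 9)), panel)

    def test_measured_cd3_tracks_planted_expression(self, cr_roi, panel):
        """Per-cell measured CD3 correlates (Spearman >= 0.8) with the true
        per-cell expression draws, measured on the true mask."""
        from scipy.stats import spearmanr

        roi, truth = cr_roi
        filt = remove_hot_pixels(roi.stack, 5.0)
        table = measure_cells(truth.true_mask, filt, panel, roi_id=roi.roi_id)
        planted = truth.cells.set_index("cell_id").loc[table["cell_id"], "CD3"]
        rho = spearmanr(table["CD3"], planted).statistic
        assert rho >= 0.8


class TestNeighborGraph:
    @staticmethod
    def _two_cells(gap):
        mask = np.zeros((30, 60), dtype=int)
        mask[10:20, 10:20] = 1
        mask[10:20, 20 + gap : 30 + gap] = 2
        return mask

    def test_small_gap_is_neighbor(self):
        graph = build_neighbor_graph(self._two_cells(3), radius_px=4)
        assert graph.n_edges == 1

    def test_large_gap_not_neighbor(self):
        graph = build_neighbor_graph(self._two_cells(10), radius_px=4)
        assert graph.n_edges == 0

    def test_single_cell_empty_graph(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[5:10, 5:10] = 1
        assert build_neighbor_graph(mask, 4).n_edges == 0

    def test_matches_bruteforce_min_pixel_distance(self):
        """Dilation adjacency equals minimum pairwise pixel distance <=
        radius, checked exhaustively on a small random instance."""
        rng = np.random.default_rng(3)
        cfg = simulate.TissueSimConfig(
            cohort="NR", roi_shape_px=(120, 120), n_nonimmune=20, n_immune=15,
            seed=9,
        )
        _, truth = simulate.simulate_roi(cfg, render=False)
        mask = truth.true_mask
        graph = build_neighbor_graph(mask, radius_px=4)
        got = {tuple(e) for e in graph.edges}
        labels = np.unique(mask)
        labels = labels[labels > 0]
        pix = {l: np.argwhere(mask == l) for l in labels}
        expected = set()
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                if cdist(pix[a], pix[b]).min() <= 4:
                    expected.add((int(a), int(b)))
        assert got == expected

    def test_radius_must_be_positive(self):
        with pytest.raises(ValueError):
            build_neighbor_graph(np.zeros((4, 4), dtype=int), 0.5)
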