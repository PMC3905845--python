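import numpy as np
import pytest
from skimage.draw import disk

from halodyn import segquant
from halodyn.simdata import SimConfig, make_cell_geometry, simulate_timelapse

PX = 0.207


def two_disc_image(rng, centers=((40, 40), (88, 88)), radius=16,
                   amplitude=20.0, background=2.0, shape=(128, 128)):
    img = np.full(shape, background)
    areas = []
    for cen in centers:
        rr, cc = disk(cen, radius, shape=shape)
        img[rr, cc] += amplitude
        areas.append(len(rr))
    noisy = rng.poisson(img * 5) / 5.0
    return noisy, areas


class TestMaxProject:
    def test_single_slice_identity(self, rng):
        stack = rng.uniform(size=(1, 8, 8))
        assert np.array_equal(segquant.max_project(stack), stack[0])

    def test_dominant_slice(self, rng):
        stack = rng.uniform(size=(6, 8, 8))
        stack[3] = 10.0
        out = segquant.max_project(stack, range(6))
        assert np.array_equal(out, stack[3])

    def test_matches_bruteforce(self, rng):
        stack = rng.uniform(size=(5, 6, 7))
        out = segquant.max_project(stack, [1, 2, 4])
        for y in range(6):
            for x in range(7):
                assert out[y, x] == max(stack[i, y, x] for i in (1, 2, 4))

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            segquant.max_project(rng.uniform(size=(5, 4, 4)), [])

    def test_out_of_depth_rejected(self, rng):
        with pytest.raises(ValueError):
            segquant.max_project(rng.uniform(size=(5, 4, 4)), [0, 9])


class TestSegmentCells:
    def test_blank_image(self):
        labels = segquant.segment_cells(np.zeros((64, 64)), pixel_size_um=PX)
        assert labels.max() == 0

    def test_uncalibrated_rejected(self):
        with pytest.raises(ValueError):
            segquant.segment_cells(np.ones((32, 32)))

    def test_two_separated_cells_area_accuracy(self, rng):
        img, true_areas = two_disc_image(rng)
        labels = segquant.segment_cells(img, pixel_size_um=PX)
        assert labels.max() == 2
        for cen, true_px in zip([(40, 40), (88, 88)], true_areas):
            lab = labels[cen]
            assert lab > 0
            seg_px = (labels == lab).sum()
            assert abs(seg_px - true_px) / true_px < 0.10

    def test_touching_cells_split_by_seeds(self, rng):
        img, _ = two_disc_image(rng, centers=((48, 33), (48, 63)), radius=16,
                                shape=(96, 96))
        split = segquant.segment_cells(img, pixel_size_um=PX, split_by_seeds=True)
        merged = segquant.segment_cells(img, pixel_size_um=PX, split_by_seeds=False)
        assert split.max() == 2
        assert merged.max() == 1

    def test_label_count_invariant_under_scaling(self, rng):
        img, _ = two_disc_image(rng)
        a = segquant.segment_cells(img, pixel_size_um=PX)
        b = segquant.segment_cells(img * 137.5, pixel_size_um=PX)
        assert a.max() == b.max()

    def test_simulated_field_recovery(self):
        cfg = SimConfig(image_shape=(256, 256), rng_seed=2, n_frames=8)
        true_labels, truth = make_cell_geometry(cfg, 12)
        stack, truth = simulate_timelapse(true_labels, truth)
        seg = segquant.segment_cells(stack.mean_image(), pixel_size_um=cfg.pixel_size_um)
        assert seg.max() == truth.n_placed
        matched = 0
        for cell in truth.cells:
            m = true_labels == cell.cell_id
            ids, counts = np.unique(seg[m], return_counts=True)
            nz = ids > 0
            if nz.any() and counts[nz].max() / m.sum() > 0.5:
                matched += 1
        assert matched == truth.n_placed

    def test_invalid_parameters_rejected(self, rng):
        img, _ = two_disc_image(rng)
        with pytest.raises(ValueError):
            segquant.segment_cells(img, pixel_size_um=PX, smooth_width_um=0.0)


class TestDetectFoci:
    def _image_with_foci(self, rng, positions, amplitude=100.0):
        img = np.full((96, 96), 2.0)
        rr, cc = disk((48, 48), 30)
        img[rr, cc] += 6.0
        for r, c in positions:
            img[r, c] += amplitude
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, 1.3)
        return rng.poisson(img * 200) / 200.0

    def test_three_planted_foci_found(self, rng):
        positions = [(40, 40), (52, 58), (60, 42)]
        img = self._image_with_foci(rng, positions)
        labels = (np.hypot(*np.mgrid[0:96, 0:96] - np.array([[[48]], [[48]]])) <= 30
                  ).astype(np.int32)
        foci = segquant.detect_foci(img, labels, quality_threshold=1.0,
                                    pixel_size_um=PX)
        assert len(foci) == 3
        assert all(f.cell_id == 1 for f in foci)
        found = {(round(f.centroid_um[1] / PX), round(f.centroid_um[0] / PX))
                 for f in foci}
        for pos in positions:
            assert any(abs(pos[0] - r) <= 2 and abs(pos[1] - c) <= 2
                       for r, c in found)

    def test_threshold_above_all_responses(self, rng):
        img = self._image_with_foci(rng, [(40, 40)])
        labels = np.ones((96, 96), np.int32)
        foci = segquant.detect_foci(img, labels, quality_threshold=1e9,
                                    pixel_size_um=PX)
        assert foci == []

    def test_missing_threshold_rejected(self, rng):
        img = self._image_with_foci(rng, [(40, 40)])
        with pytest.raises(ValueError, match="quality threshold"):
            segquant.detect_foci(img, np.ones((96, 96), np.int32),
                                 pixel_size_um=PX)

    def test_threshold_monotonicity(self, rng):
        img = self._image_with_foci(rng, [(40, 40), (52, 58), (60, 42)])
        labels = np.ones((96, 96), np.int32)
        counts = [
            len(segquant.detect_foci(img, labels, quality_threshold=q,
                                     pixel_size_um=PX))
            for q in (0.05, 0.5, 1.5, 3.0, 50.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_focus_outside_cells_gets_id_zero(self, rng):
        img = np.full((64, 64), 1.0)
        img[10, 10] += 40.0
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, 1.3)
        labels = np.zeros((64, 64), np.int32)
        labels[40:60, 40:60] = 1
        foci = segquant.detect_foci(img, labels, quality_threshold=0.2,
                                    pixel_size_um=PX)
        assert len(foci) == 1
        assert foci[0].cell_id == 0

    def test_poisson_foci_recovery(self):
        # simulated cells with Poisson(2) foci: detected mean within 10%
        detected, truth_mean, n_cells = 0, 0.0, 0
        for seed in (1, 2, 3):
            cfg = SimConfig(image_shape=(256, 256), rng_seed=seed, n_frames=8)
            labels, truth = make_cell_geometry(cfg, 12)
            stack, truth = simulate_timelapse(labels, truth)
            img = stack.mean_image()
            seg = segquant.segment_cells(img, pixel_size_um=cfg.pixel_size_um)
            foci = segquant.detect_foci(img, seg, quality_threshold=1.0,
                                        pixel_size_um=cfg.pixel_size_um)
            detected += sum(1 for f in foci if f.cell_id > 0)
            truth_mean += sum(c.n_foci for c in truth.cells)
            n_cells += truth.n_placed
        assert abs(detected - truth_mean) / truth_mean < 0.10


class TestPerCellMetrics:
    def test_uniform_cell_exact_total(self):
        img = np.zeros((32, 32))
        labels = np.zeros((32, 32), np.int32)
        labels[8:16, 8:20] = 1
        img[labels == 1] = 3.5
        records = segquant.per_cell_metrics(img, labels, [], pixel_size_um=PX)
        assert len(records) == 1
        rec = records[0]
        assert rec.total_intensity == pytest.approx(3.5 * 8 * 12, rel=1e-12)
        assert rec.surface_um2 == pytest.approx(8 * 12 * PX * PX, rel=1e-12)
        assert rec.n_foci == 0
        assert rec.foci_total_intensity == 0.0

    def test_focus_fraction_matches_construction(self):
        img = np.zeros((64, 64))
        labels = np.zeros((64, 64), np.int32)
        rr, cc = disk((32, 32), 20)
        labels[rr, cc] = 1
        img[labels == 1] = 1.0
        # bright spot holding a known fraction of the total
        rr2, cc2 = disk((32, 32), 1.5)
        img[rr2, cc2] += 100.0
        focus = segquant.FocusRecord(
            cell_id=1, centroid_um=(32 * PX, 32 * PX),
            diameter_um=0.75, intensity=0.0, quality=10.0,
        )
        records = segquant.per_cell_metrics(img, labels, [focus], pixel_size_um=PX)
        rec = records[0]
        expected_fraction = img[rr2, cc2].sum() / img[labels == 1].sum()
        got = rec.foci_total_intensity / rec.total_intensity
        assert got == pytest.approx(expected_fraction, rel=0.05)
        assert rec.foci_total_intensity <= rec.total_intensity

    def test_empty_labels_empty_list(self):
        out = segquant.per_cell_metrics(
            np.ones((16, 16)), np.zeros((16, 16), np.int32), [], pixel_size_um=PX
        )
        assert out == []

    def test_overlapping_disc_union_not_double_counted(self):
        img = np.ones((32, 32))
        labels = np.ones((32, 32), np.int32)
        f = lambda x, y: segquant.FocusRecord(
            cell_id=1, centroid_um=(x * PX, y * PX),
            diameter_um=2.0, intensity=0.0, quality=1.0,
        )
        rec1 = segquant.per_cell_metrics(img, labels, [f(16, 16)], pixel_size_um=PX)[0]
        rec2 = segquant.per_cell_metrics(
            img, labels, [f(16, 16), f(16, 16)], pixel_size_um=PX
        )[0]
        assert rec2.foci_total_intensity == pytest.approx(
            rec1.foci_total_intensity, rel=1e-12
        )


class TestPopulationSummary:
    def _cell(self, cid, foci=0, area=28.0, total=100.0, foci_int=0.0):
        return segquant.CellRecord(
            cell_id=cid, surface_um2=area, total_intensity=total,
            n_foci=foci, foci_total_intensity=foci_int,
        )

    def test_mean_foci_per_cell(self):
        summary = segquant.population_summary(
            [self._cell(1, foci=1), self._cell(2, foci=3)]
        )
        assert summary.mean_foci_per_cell == 2.0

    def test_totals_ratio_identity(self):
        cells = [self._cell(1, area=20.0, total=50.0),
                 self._cell(2, area=40.0, total=250.0)]
        s = segquant.population_summary(cells)
        assert s.mean_intensity_per_surface * s.average_cell_surface_um2 == \
            pytest.approx(s.mean_intensity_per_cell, rel=1e-12)

    def test_all_intensity_in_foci(self):
        cells = [self._cell(1, foci=2, total=80.0, foci_int=80.0)]
        assert segquant.population_summary(cells).fraction_intensity_in_foci == 1.0

    def test_histogram_sums_and_clamps(self):
        cells = [self._cell(i, foci=f) for i, f in enumerate([0, 1, 1, 25])]
        s = segquant.population_summary(cells)
        assert s.foci_count_histogram.sum() == 4
        assert s.foci_count_histogram[20] == 1  # clamped
        assert s.foci_count_histogram[1] == 2

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            segquant.population_summary([])

    def test_control_like_distribution(self):
        # Poisson(2) foci/cell: modal class at 1-2 as in control populations
        cfg = SimConfig(image_shape=(400, 400), rng_seed=21)
        _, truth = make_cell_geometry(cfg, 60)
        cells = [
            self._cell(c.cell_id, foci=c.n_foci) for c in truth.cells
        ]
        s = segquant.population_summary(cells)
        hist = s.foci_count_histogram
        assert hist.argmax() in (1, 2)
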