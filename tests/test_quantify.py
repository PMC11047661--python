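"""Image quantification: auto-threshold, ROI grid search, segmentation,
intensity measurement, trace extraction."""

import numpy as np
import pytest

from ocuscreen import (
    ROI,
    CalciumTrace,
    SimChipConfig,
    SimTraceConfig,
    ValidationError,
    autothreshold_binarize,
    extract_traces,
    measure_cell_intensity,
    measure_cells,
    optimize_roi_grid,
    segment_nuclei,
    simulate_chip_image,
    simulate_timelapse,
)


def exhaustive_offset_search(dapi, layout, max_shift):
    """Independent oracle: score every integer offset by directly counting
    foreground pixels inside each shifted ROI disc."""
    fg = autothreshold_binarize(dapi)
    h, w = fg.shape
    yy, xx = np.mgrid[0:h, 0:w]
    scores = {}
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            s = 0
            for roi in layout.rois(offset=(dx, dy)):
                inside = (xx - roi.cx) ** 2 + (yy - roi.cy) ** 2 <= roi.radius**2
                s += int(fg[inside].sum())
            scores[(dx, dy)] = s
    best = max(scores.values())
    return best, {d for d, s in scores.items() if s == best}


class TestAutothreshold:
    def test_bimodal_image_separates_exactly(self):
        rng = np.random.default_rng(0)
        img = np.full((50, 50), 10.0)
        bright = rng.random((50, 50)) < 0.1
        img[bright] = 200.0
        mask = autothreshold_binarize(img)
        assert np.array_equal(mask, bright)

    def test_constant_image_gives_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = autothreshold_binarize(np.full((20, 20), 7.0))
        assert not mask.any()

    def test_noiseless_chip_foreground_equals_rendered_nuclei(self, noiseless_chip):
        sim = noiseless_chip
        fg = autothreshold_binarize(sim.dapi)
        r = sim.config.nucleus_radius_px
        h, w = sim.dapi.shape
        yy, xx = np.mgrid[0:h, 0:w]
        expected = np.zeros((h, w), dtype=bool)
        for row in sim.truth.itertuples():
            expected |= (xx - row.x_px) ** 2 + (yy - row.y_px) ** 2 <= r**2
        assert np.array_equal(fg, expected)

    def test_non_finite_image_rejected(self):
        img = np.ones((5, 5))
        img[0, 0] = np.nan
        with pytest.raises(ValidationError):
            autothreshold_binarize(img)


class TestRoiGridSearch:
    def test_aligned_chip_returns_zero_offset(self, noiseless_chip):
        fit = optimize_roi_grid(noiseless_chip.dapi, noiseless_chip.layout, seed=1)
        assert fit.offset == (0, 0)
        assert not fit.blank

    def test_known_offset_recovered_as_exhaustive_optimum(self, noisy_offset_chip):
        sim = noisy_offset_chip
        fit = optimize_roi_grid(
            sim.dapi, sim.layout, iterations=500, max_shift_px=10, seed=3
        )
        best, argmax = exhaustive_offset_search(sim.dapi, sim.layout, 10)
        assert fit.score == best
        assert fit.offset in argmax
        # the true misalignment attains the optimum too
        assert (5, -3) in argmax

    def test_search_matches_exhaustive_oracle_across_seeds(self):
        agree = 0
        n = 6
        for seed in range(n):
            cfg = SimChipConfig(
                grid_rows=2, grid_cols=2, noise_sd=2.0,
                grid_offset_px=(-4, 6), seed=seed,
            )
            sim = simulate_chip_image(cfg, 0.0)
            fit = optimize_roi_grid(
                sim.dapi, sim.layout, iterations=500, max_shift_px=10, seed=seed
            )
            best, argmax = exhaustive_offset_search(sim.dapi, sim.layout, 10)
            agree += fit.score == best and fit.offset in argmax
        assert agree / n >= 0.95

    def test_blank_image_returns_origin_with_flag(self):
        layout = SimChipConfig(grid_rows=1, grid_cols=1).layout()
        with pytest.warns(UserWarning, match="blank"):
            fit = optimize_roi_grid(np.zeros((200, 200)), layout, seed=0)
        assert fit.offset == (0, 0)
        assert fit.blank

    def test_deterministic_under_seed(self, noisy_offset_chip):
        sim = noisy_offset_chip
        a = optimize_roi_grid(sim.dapi, sim.layout, iterations=50, seed=9)
        b = optimize_roi_grid(sim.dapi, sim.layout, iterations=50, seed=9)
        assert a.offset == b.offset and a.score == b.score


class TestSegmentation:
    def test_blank_roi_yields_no_nuclei(self):
        img = np.zeros((100, 100))
        img[5, 5] = 100.0  # somewhere outside the ROI, to avoid constant image
        records, _ = segment_nuclei(img, ROI(0, 60.0, 60.0, 20.0), min_area_px=1)
        assert records == []

    def test_three_disjoint_discs_give_three_nuclei(self):
        img = np.zeros((80, 80))
        yy, xx = np.mgrid[0:80, 0:80]
        for cx, cy in [(25, 25), (45, 30), (30, 50)]:
            img[(xx - cx) ** 2 + (yy - cy) ** 2 <= 16] = 200.0
        records, _ = segment_nuclei(img, ROI(0, 35.0, 35.0, 30.0), min_area_px=5)
        assert len(records) == 3

    def test_noiseless_chip_counts_equal_ground_truth(self, noiseless_chip):
        sim = noiseless_chip
        records, _ = segment_nuclei(sim.dapi, sim.layout.rois())
        got = {}
        for r in records:
            got[r.pattern_id] = got.get(r.pattern_id, 0) + 1
        expected = sim.truth.groupby("pattern_id").size().to_dict()
        assert got == expected

    def test_min_area_filters_specks(self):
        img = np.zeros((60, 60))
        yy, xx = np.mgrid[0:60, 0:60]
        img[(xx - 30) ** 2 + (yy - 30) ** 2 <= 25] = 200.0  # real nucleus
        img[10, 10] = 200.0  # 1-px speck
        records, _ = segment_nuclei(img, ROI(0, 30.0, 30.0, 29.0), min_area_px=20)
        assert len(records) == 1

    def test_every_centroid_lies_in_exactly_one_roi(self, noiseless_chip):
        sim = noiseless_chip
        rois = sim.layout.rois()
        records, _ = segment_nuclei(sim.dapi, rois)
        for rec in records:
            x, y = rec.centroid_px
            owners = [r.pattern_id for r in rois if r.contains(x, y)]
            assert owners == [rec.pattern_id]


def brute_force_dilated_mean(image, mask, dilation_px):
    """Direct pixel enumeration of the dilated-mask mean."""
    h, w = mask.shape
    seeds = np.argwhere(mask)
    total, count = 0.0, 0
    for y in range(h):
        for x in range(w):
            if np.any((seeds[:, 0] - y) ** 2 + (seeds[:, 1] - x) ** 2 <= dilation_px**2):
                total += image[y, x]
                count += 1
    return total / count


class TestIntensityMeasurement:
    def test_uniform_image_returns_its_value(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[8:12, 8:12] = True
        assert measure_cell_intensity(np.full((20, 20), 37.5), mask) == 37.5

    def test_zero_dilation_measures_exact_mask(self):
        img = np.zeros((20, 20))
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:7, 5:7] = True
        img[5, 5] = 4.0
        assert measure_cell_intensity(img, mask, dilation_px=0) == 1.0

    def test_disc_mask_mean_matches_pixel_enumeration_oracle(self):
        img = np.zeros((30, 30))
        yy, xx = np.mgrid[0:30, 0:30]
        disc = (xx - 15) ** 2 + (yy - 15) ** 2 <= 9
        img[disc] = 10.0
        expected = brute_force_dilated_mean(img, disc, 2)
        assert measure_cell_intensity(img, disc, dilation_px=2) == pytest.approx(
            expected, rel=1e-12
        )

    def test_constant_shift_invariance(self, noiseless_chip):
        sim = noiseless_chip
        records, labels = segment_nuclei(sim.dapi, sim.layout.rois())
        mask = labels == records[0].component_label
        base = measure_cell_intensity(sim.caspase, mask)
        shifted = measure_cell_intensity(sim.caspase + 11.25, mask)
        assert shifted == pytest.approx(base + 11.25, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            measure_cell_intensity(np.ones((5, 5)), np.zeros((5, 5), dtype=bool))


class TestTraceExtraction:
    def test_constant_stack_gives_constant_traces(self):
        cfg = SimTraceConfig(
            n_frames=40, induction_frame=10, peak_shape="none",
            noise_sd=0.0, baseline_cv=0.0, seed=0,
        )
        sim = simulate_timelapse(cfg, n_cells=3)
        records, labels = segment_nuclei(sim.dapi, sim.roi)
        traces = extract_traces(sim.stack, labels, records, induction_frame=10)
        for t in traces:
            assert np.allclose(t.values, t.values[0])

    def test_single_cell_noiseless_stack_matches_generator_truth(self):
        cfg = SimTraceConfig(
            n_frames=60, induction_frame=20, peak_shape="broad",
            noise_sd=0.0, seed=6,
        )
        sim = simulate_timelapse(cfg, n_cells=1)
        records, labels = segment_nuclei(sim.dapi, sim.roi)
        assert len(records) == 1
        (trace,) = extract_traces(sim.stack, labels, records, induction_frame=20)
        np.testing.assert_allclose(trace.values, sim.traces[0], atol=1e-3)

    def test_window_boundary_cases(self):
        sim = simulate_timelapse(
            SimTraceConfig(n_frames=40, induction_frame=5, peak_shape="none",
                           noise_sd=0.0, seed=0),
            n_cells=1,
        )
        records, labels = segment_nuclei(sim.dapi, sim.roi)
        # 21 frames with induction at 0 is the smallest admissible window
        traces = extract_traces(sim.stack[:21], labels, records, induction_frame=0)
        assert len(traces[0].values) == 21
        with pytest.raises(ValidationError, match="21"):
            extract_traces(sim.stack[:20], labels, records, induction_frame=0)

    def test_trace_invariants_enforced(self):
        with pytest.raises(ValidationError, match="frames"):
            CalciumTrace(0, 0, np.zeros(20), 5.0, induction_frame=0)
        with pytest.raises(ValidationError, match="finite"):
            CalciumTrace(0, 0, np.full(30, np.nan), 5.0, induction_frame=0)


def test_measured_caspase_levels_are_exact_on_noiseless_chip(noiseless_chip):
    sim = noiseless_chip
    records, labels = segment_nuclei(sim.dapi, sim.layout.rois())
    measure_cells(sim.caspase, labels, records, "caspase")
    cfg = sim.config
    levels = {round(r.intensity["caspase"], 9) for r in records}
    assert levels == {cfg.control_level, cfg.control_level * cfg.apoptotic_factor}
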