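"""Threshold, morphology, blob labeling and density-score computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from plaquescope.scoring import (
    MorphologyParams,
    RegionMask,
    ScoreResult,
    clean_binary,
    compute_score,
    label_blobs,
    percent_change,
    threshold_heatmap,
)
from plaquescope.synthetic import SyntheticSlideSpec, density_for_exact_count, generate_heatmap

from conftest import flood_fill_count


def manual_morphology(raster, element, op):
    """Independent erosion/dilation by explicit neighborhood scan."""
    h, w = raster.shape
    eh, ew = element.shape
    cy, cx = eh // 2, ew // 2
    out = np.zeros_like(raster)
    for r in range(h):
        for c in range(w):
            vals = []
            for dy in range(eh):
                for dx in range(ew):
                    if not element[dy, dx]:
                        continue
                    rr, cc = r + dy - cy, c + dx - cx
                    vals.append(
                        raster[rr, cc] if 0 <= rr < h and 0 <= cc < w else False
                    )
            out[r, c] = all(vals) if op == "erode" else any(vals)
    return out


class TestThreshold:
    def test_zero_threshold_full_raster(self):
        hm = np.random.default_rng(0).random((5, 5))
        assert threshold_heatmap(hm, 0.0).all()

    def test_threshold_above_max_empty(self):
        hm = np.full((4, 4), 0.9)
        assert not threshold_heatmap(hm, 1.0).any()

    def test_elementwise_membership(self):
        hm = np.array([[0.1, 0.5, 0.9], [0.49, 0.51, 0.2], [0.7, 0.0, 1.0]])
        out = threshold_heatmap(hm, 0.5)
        assert np.array_equal(out, hm >= 0.5)

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_heatmap(np.zeros((2, 2)), 1.5)

    def test_raising_threshold_never_grows_coverage(self):
        hm = np.random.default_rng(3).random((32, 32))
        prev = threshold_heatmap(hm, 0.2)
        for t in (0.4, 0.6, 0.8):
            cur = threshold_heatmap(hm, t)
            assert not (cur & ~prev).any()
            prev = cur


class TestCleanBinary:
    def test_isolated_pixel_removed_by_opening(self):
        raster = np.zeros((7, 7), dtype=bool)
        raster[3, 3] = True
        params = MorphologyParams(opening_iterations=1, closing_iterations=0)
        assert not clean_binary(raster, params).any()

    def test_solid_square_unchanged_by_square_opening(self):
        raster = np.zeros((9, 9), dtype=bool)
        raster[2:7, 2:7] = True
        params = MorphologyParams(element="square", opening_iterations=1, closing_iterations=1)
        assert np.array_equal(clean_binary(raster, params), raster)

    def test_cross_opening_matches_manual_morphology(self):
        rng = np.random.default_rng(5)
        raster = rng.random((12, 12)) > 0.6
        params = MorphologyParams(opening_iterations=1, closing_iterations=0)
        el = params.structuring_element()
        expected = manual_morphology(manual_morphology(raster, el, "erode"), el, "dilate")
        assert np.array_equal(clean_binary(raster, params), expected)

    def test_zero_iterations_identity(self):
        rng = np.random.default_rng(2)
        raster = rng.random((10, 10)) > 0.5
        params = MorphologyParams(opening_iterations=0, closing_iterations=0)
        assert np.array_equal(clean_binary(raster, params), raster)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MorphologyParams(connectivity=6)
        with pytest.raises(ValueError):
            MorphologyParams(thresholds={"cored": 1.4})
        with pytest.raises(ValueError):
            MorphologyParams(element_size=4)


class TestLabelBlobs:
    def test_empty_raster(self):
        _, count, cents = label_blobs(np.zeros((5, 5), dtype=bool))
        assert count == 0 and cents == []

    def test_diagonal_pixels_connectivity(self):
        raster = np.zeros((4, 4), dtype=bool)
        raster[1, 1] = raster[2, 2] = True
        assert label_blobs(raster, 8)[1] == 1
        assert label_blobs(raster, 4)[1] == 2

    def test_five_disjoint_squares(self):
        raster = np.zeros((20, 20), dtype=bool)
        for i in range(5):
            r, c = 4 * (i % 4), 5 * (i // 2)
            raster[r : r + 2, c + 10 : c + 12] = True
        want = flood_fill_count(raster, 8)
        assert label_blobs(raster, 8)[1] == want

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        raster=arrays(bool, st.tuples(st.integers(1, 64), st.integers(1, 64))),
        connectivity=st.sampled_from([4, 8]),
    )
    def test_matches_flood_fill_oracle(self, raster, connectivity):
        assert label_blobs(raster, connectivity)[1] == flood_fill_count(raster, connectivity)


class TestComputeScore:
    def _params(self):
        return MorphologyParams()

    def test_zero_heatmap_zero_score(self):
        hm = np.zeros((40, 40), dtype=np.float32)
        region = RegionMask(mask=np.ones((40, 40), dtype=bool))
        res = compute_score(hm, "cored", self._params(), region, "s")
        assert res.blob_count == 0 and res.cnn_score == 0.0

    def test_planted_deposits_give_exact_density(self):
        base = SyntheticSlideSpec(width_px=2048, height_px=2048, seed=21)
        spec = SyntheticSlideSpec(
            width_px=2048,
            height_px=2048,
            seed=21,
            class_densities={"cored": density_for_exact_count(base, 5)},
        )
        hm, gt = generate_heatmap(spec, "cored")
        region = RegionMask(mask=gt.tissue_mask)
        res = compute_score(hm, "cored", self._params(), region, "s")
        assert res.blob_count == 5
        assert res.cnn_score == pytest.approx(5 / region.area_px)

    def test_gray_matter_subset_scoring(self):
        spec = SyntheticSlideSpec(seed=13, white_matter_leak=0.3)
        hm, gt = generate_heatmap(spec, "cored")
        wt = compute_score(hm, "cored", self._params(), RegionMask(mask=gt.tissue_mask), "s")
        gm = compute_score(
            hm, "cored", self._params(), RegionMask(mask=gt.gm_mask, label="gray_matter"), "s"
        )
        assert gm.blob_count == gt.counts_gm["cored"]
        assert wt.blob_count == gt.counts_tissue["cored"]
        assert gm.region_area_px <= wt.region_area_px

    def test_partition_additivity(self):
        spec = SyntheticSlideSpec(seed=17, white_matter_leak=0.25)
        hm, gt = generate_heatmap(spec, "diffuse")
        params = self._params()
        wt = compute_score(hm, "diffuse", params, RegionMask(mask=gt.tissue_mask), "s")
        gm = compute_score(hm, "diffuse", params, RegionMask(mask=gt.gm_mask), "s")
        comp_mask = gt.tissue_mask & ~gt.gm_mask
        comp = compute_score(hm, "diffuse", params, RegionMask(mask=comp_mask), "s")
        assert wt.blob_count == gm.blob_count + comp.blob_count

    def test_doubling_area_halves_score(self):
        hm = np.zeros((40, 80), dtype=np.float32)
        hm[10:13, 10:13] = 0.95
        half = np.zeros((40, 80), dtype=bool)
        half[:, :40] = True
        full = np.ones((40, 80), dtype=bool)
        params = self._params()
        s_half = compute_score(hm, "cored", params, RegionMask(mask=half), "s")
        s_full = compute_score(hm, "cored", params, RegionMask(mask=full), "s")
        assert s_half.blob_count == s_full.blob_count == 1
        assert s_full.cnn_score == pytest.approx(s_half.cnn_score / 2)

    def test_empty_region_rejected(self):
        hm = np.zeros((10, 10), dtype=np.float32)
        with pytest.raises(ValueError):
            compute_score(hm, "cored", self._params(), RegionMask(mask=np.zeros((10, 10), bool)), "s")

    def test_score_zero_iff_no_blobs(self):
        spec = SyntheticSlideSpec(seed=19)
        hm, gt = generate_heatmap(spec, "caa")
        res = compute_score(hm, "caa", self._params(), RegionMask(mask=gt.tissue_mask), "s")
        assert (res.cnn_score == 0) == (res.blob_count == 0)


class TestPercentChange:
    def _score(self, value, region="whole_tissue"):
        return ScoreResult("s", "cored", region, int(value * 1e4), int(1e4), value)

    def test_equal_scores_zero_percent(self):
        assert percent_change(self._score(1e-3, "gray_matter"), self._score(1e-3)) == 0.0

    def test_increase_23_percent(self):
        gm = ScoreResult("s", "cored", "gray_matter", 123, 100000, 1.23e-3)
        wt = ScoreResult("s", "cored", "whole_tissue", 100, 100000, 1.00e-3)
        assert percent_change(gm, wt) == pytest.approx(23.0)

    def test_decrease_22_9_percent(self):
        gm = ScoreResult("s", "cored", "gray_matter", 771, 1000000, 0.771e-3)
        wt = ScoreResult("s", "cored", "whole_tissue", 1000, 1000000, 1.000e-3)
        assert percent_change(gm, wt) == pytest.approx(-22.9)

    def test_zero_whole_tissue_reported_missing(self):
        gm = ScoreResult("s", "cored", "gray_matter", 1, 100, 0.01)
        wt = ScoreResult("s", "cored", "whole_tissue", 0, 100, 0.0)
        assert np.isnan(percent_change(gm, wt))

    def test_mismatched_slides_rejected(self):
        gm = ScoreResult("a", "cored", "gray_matter", 1, 100, 0.01)
        wt = ScoreResult("b", "cored", "whole_tissue", 1, 100, 0.01)
        with pytest.raises(ValueError):
            percent_change(gm, wt)
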