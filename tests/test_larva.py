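import numpy as np
import pandas as pd
import pytest

from lc3screen.config import LarvaConfig
from lc3screen.errors import NoLarvaDetectedError, UsageError
from lc3screen.io import ImageStack
from lc3screen.larva import (
    PunctaMeasurement,
    SegmentationResult,
    compute_body_mask,
    locate_larvae,
    max_project,
    measure_puncta,
    process_well,
    segment_larva,
    segment_puncta,
)
from lc3screen.synthetic import make_larva_stack, make_well_image


class TestMaxProject:
    def test_single_plane_is_identity(self):
        plane = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(max_project(ImageStack(plane[None])), plane)

    def test_disjoint_spots_both_survive(self):
        z = np.zeros((2, 5, 5))
        z[0, 1, 1] = 50.0
        z[1, 3, 3] = 70.0
        proj = max_project(z)
        assert proj[1, 1] == 50.0 and proj[3, 3] == 70.0

    def test_multichannel_without_selection_is_usage_error(self):
        stack = ImageStack(np.zeros((2, 4, 4)), channels=["G", "R"])
        with pytest.raises(UsageError):
            max_project(stack)
        np.testing.assert_array_equal(max_project(stack, channel="R"), np.zeros((4, 4)))

    def test_planted_peak_appears_at_planted_intensity(self, clean_stack):
        stack, truth = clean_stack
        proj = max_project(stack)
        bg = truth.params["background"] + truth.params["body_level"]
        for p in truth.objects[truth.objects["type"] == "punctum"].itertuples():
            y, x = int(round(p.y)), int(round(p.x))
            assert proj[y, x] == pytest.approx(bg + p.amplitude)


class TestBodyMask:
    def test_planted_body_area_recovered_with_erosion_rim(self, tiny_well_image):
        img, body = tiny_well_image
        shrink = 5
        smoothed, mask = compute_body_mask(img, min_body_area=2000, shrink_radius=shrink)
        # analytic erosion-rim correction of the planted ellipse
        expected = np.pi * (140 - shrink) * (50 - shrink)
        assert mask.sum() == pytest.approx(expected, rel=0.10)
        assert smoothed.shape == img.shape

    def test_blank_image_raises_no_larva(self):
        noise = np.random.default_rng(0).normal(10, 2, (128, 128)).clip(0)
        with pytest.raises(NoLarvaDetectedError):
            compute_body_mask(noise, min_body_area=5000)

    def test_dust_speck_filtered_leaves_single_component(self, tiny_well_image):
        from scipy import ndimage

        img, _ = tiny_well_image
        img = img.copy()
        img[5:9, 5:9] += 200.0  # 16 px speck, far below min_body_area
        _, mask = compute_body_mask(img, min_body_area=2000)
        _, n = ndimage.label(mask)
        assert n == 1
        assert not mask[0:20, 0:20].any()


def _clean_segmentation(stack, truth):
    proj = max_project(stack)
    smoothed, body = compute_body_mask(proj)
    return proj, smoothed, body


class TestSegmentPuncta:
    def test_all_planted_puncta_recovered_with_exact_areas(self, clean_stack):
        stack, truth = clean_stack
        proj, smoothed, body = _clean_segmentation(stack, truth)
        seg = segment_puncta(proj, smoothed, body)
        planted = truth.objects[truth.objects["type"] == "punctum"]
        assert len(seg.objects) == len(planted) == 12
        # noise-free step-profile puncta: detected areas equal planted areas
        assert sorted(seg.objects["area"]) == sorted(planted["area_px2"].astype(float))

    def test_bright_spot_outside_body_is_excluded(self, tiny_well_image):
        img, body = tiny_well_image
        img = img.copy()
        img[100:103, 210:213] += 500.0  # inside the body
        img[20:23, 20:23] += 500.0  # outside
        smoothed, mask = compute_body_mask(img, min_body_area=2000)
        seg = segment_puncta(img, smoothed, mask)
        assert len(seg.objects) == 1
        assert not seg.puncta_mask[20:23, 20:23].any()

    def test_uniform_body_yields_zero_puncta(self, tiny_well_image):
        img, _ = tiny_well_image
        smoothed, mask = compute_body_mask(img, min_body_area=2000)
        seg = segment_puncta(img, smoothed, mask)
        assert len(seg.objects) == 0
        assert not seg.puncta_mask.any()

    def test_empty_body_mask_is_usage_error(self, tiny_well_image):
        img, _ = tiny_well_image
        with pytest.raises(UsageError):
            segment_puncta(img, img, np.zeros_like(img, dtype=bool))

    @pytest.mark.parametrize("scale", [0.5, 3.0, 17.0])
    def test_count_invariant_under_intensity_rescaling(self, clean_stack, scale):
        """T is proportional to the smoothed body mean, so gain cancels."""
        stack, truth = clean_stack
        proj, smoothed, body = _clean_segmentation(stack, truth)
        base = segment_puncta(proj, smoothed, body)
        scaled = segment_puncta(proj * scale, smoothed * scale, body)
        assert len(scaled.objects) == len(base.objects)

    def test_adding_a_punctum_increments_count_and_area(self, clean_stack):
        stack, truth = clean_stack
        proj, smoothed, body = _clean_segmentation(stack, truth)
        base = segment_puncta(proj, smoothed, body)
        added = proj.copy()
        ys, xs = np.nonzero(body)
        cy, cx = int(np.mean(ys)), int(np.mean(xs))
        # find an interior spot clear of existing puncta
        spot = None
        for dy in range(-40, 41, 7):
            for dx in range(-40, 41, 7):
                y, x = cy + dy, cx + dx
                region = base.puncta_labels[y - 6 : y + 7, x - 6 : x + 7]
                if body[y - 6 : y + 7, x - 6 : x + 7].all() and not region.any():
                    spot = (y, x)
                    break
            if spot:
                break
        assert spot is not None
        y, x = spot
        added[y : y + 2, x : x + 2] += truth.params["amplitude"]
        seg2 = segment_puncta(added, smoothed, body)
        assert len(seg2.objects) == len(base.objects) + 1
        assert seg2.objects["area"].sum() == pytest.approx(base.objects["area"].sum() + 4)

    def test_centroid_inside_keeps_edge_straddling_object(self, tiny_well_image):
        img, body_truth = tiny_well_image
        img = img.copy()
        # place a spot straddling the mask edge: centroid inside, tail outside
        edge_x = 200 + 140 - 6
        img[98:102, edge_x - 4 : edge_x + 4] += 500.0
        smoothed, mask = compute_body_mask(img, min_body_area=2000)
        strict = segment_puncta(img, smoothed, mask, containment="fully_inside")
        loose = segment_puncta(img, smoothed, mask, containment="centroid_inside")
        assert len(loose.objects) >= len(strict.objects)

    def test_containment_invariant_holds(self, default_stack):
        stack, _ = default_stack
        proj = max_project(stack)
        smoothed, body = compute_body_mask(proj)
        seg = segment_puncta(proj, smoothed, body)
        assert not np.any(seg.puncta_mask & ~body)


class TestMeasurePuncta:
    def _seg(self, n_obj, obj_area, body_area):
        body = np.zeros((100, 100), dtype=bool)
        body[:body_area // 100, :100] = True
        objects = pd.DataFrame(
            {"label": range(1, n_obj + 1), "area": [obj_area] * n_obj,
             "centroid_y": 0.0, "centroid_x": 0.0, "mean_intensity": 1.0}
        )
        labels = np.zeros((100, 100), dtype=int)
        return SegmentationResult(
            projection=np.zeros((100, 100)), smoothed=np.zeros((100, 100)),
            subtracted=np.zeros((100, 100)), body_mask=body,
            puncta_labels=labels, objects=objects, threshold=1.0,
        )

    def test_relative_area_arithmetic(self):
        m = measure_puncta(self._seg(10, 5.0, 1000))
        assert m.puncta_total_area_px2 == 50.0
        assert m.relative_puncta_area == pytest.approx(0.05)
        assert m.puncta_count == 10

    def test_zero_puncta(self):
        m = measure_puncta(self._seg(0, 0.0, 1000))
        assert m.puncta_count == 0
        assert m.relative_puncta_area == 0.0

    def test_micron_conversion(self):
        m = measure_puncta(self._seg(2, 8.0, 1000), pixel_size_um=0.5)
        assert m.puncta_total_area_um2 == pytest.approx(16.0 * 0.25)
        assert m.body_area_um2 == pytest.approx(1000 * 0.25)

    def test_displaced_measurement_has_absent_metrics(self):
        m = PunctaMeasurement.displaced_larva()
        assert m.displaced
        assert np.isnan(m.relative_puncta_area)


class TestLocateLarvae:
    def test_single_larva_center_near_truth(self):
        img, truth = make_well_image(n_larvae=1, seed=3)
        rois = locate_larvae(img, max_larvae=3, head_tail_offset=20, min_area=300)
        assert len(rois) == 1
        t = truth.objects.iloc[0]
        assert np.hypot(rois[0].centroid[0] - t.y, rois[0].centroid[1] - t.x) < 10

    def test_blank_well_gives_empty_list(self):
        noise = np.random.default_rng(0).poisson(10.0, (256, 256)).astype(float)
        assert locate_larvae(noise, min_area=300) == []

    def test_three_larvae_all_found_with_stable_order(self):
        img, truth = make_well_image(n_larvae=3, seed=11)
        rois = locate_larvae(img, max_larvae=3, head_tail_offset=20, min_area=300)
        assert len(rois) == 3
        assert [r.larva_index for r in rois] == [0, 1, 2]
        centroids = [r.centroid for r in rois]
        assert centroids == sorted(centroids)

    def test_too_short_silhouette_dropped_not_returned(self):
        img = np.full((128, 128), 5.0)
        img[60:68, 50:70] += 100.0  # 20 px long: shorter than 2 * offset
        rois = locate_larvae(img, head_tail_offset=20, min_area=50)
        assert rois == []


def _composite_well(seed, n_larvae=3):
    subs = [
        make_larva_stack(n_puncta=5, body_area=15000, shape=(160, 352), seed=seed * 10 + i)[0]
        for i in range(n_larvae)
    ]
    z = subs[0].pixels.shape[0]
    canvas = np.random.default_rng(seed).poisson(20.0, (z, 160 * 3, 352)).astype(float)
    for i in range(3):
        canvas[:, i * 160 : (i + 1) * 160, :] = 20.0 if i >= n_larvae else subs[i].pixels
    return ImageStack(canvas, pixel_size_um=0.65, meta={"well": "A01"})


class TestProcessWell:
    row = pd.Series(dict(plate="P1", well="A01", compound="DMSO", dose_um=0.0,
                         phase="pre_nh4cl", role="vehicle", toxic=False))
    cfg = LarvaConfig(min_body_area=3000)

    def test_three_larvae_both_phases_gives_three_matched_pairs(self):
        table = process_well(_composite_well(1), _composite_well(2), self.row, self.cfg)
        df = table.frame
        assert set(df["larva"]) == {0, 1, 2}
        assert set(df["phase"]) == {"pre_nh4cl", "post_nh4cl"}
        assert not df["excluded"].any()
        counts = df[df["metric"] == "puncta_count"]
        assert len(counts) == 6

    def test_larva_missing_post_phase_is_displaced_pair(self):
        table = process_well(_composite_well(3), _composite_well(4, n_larvae=2), self.row, self.cfg)
        df = table.frame
        displaced = df[df["excluded"]]
        assert len(displaced) == 2  # one pair, both phases flagged
        assert (displaced["exclusion_reason"].str.contains("displaced")).all()
        assert displaced["value"].isna().all()
        kept = df[~df["excluded"]]
        assert set(kept["larva"]) == {0, 1}

    def test_absent_post_stack_yields_pre_only_records(self):
        table = process_well(_composite_well(5), None, self.row, self.cfg)
        assert set(table.frame["phase"]) == {"pre_nh4cl"}
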