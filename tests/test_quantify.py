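"""Image import, segmentation, detection and frontier measurement."""

import numpy as np
import pytest
import tifffile
from conftest import single_cell_scene

from migchip import chipmodel as cm
from migchip import quantify as q


class TestLoadImage:
    def test_three_page_round_trip(self, mixed_image, tmp_path):
        path = tmp_path / "dev.tif"
        cm.write_tiff(mixed_image, path)
        loaded = q.load_image(path)
        for name in loaded.planes:
            assert np.array_equal(loaded.planes[name], mixed_image.planes[name])

    def test_16bit_rejected(self, tmp_path):
        path = tmp_path / "deep.tif"
        tifffile.imwrite(path, np.zeros((4, 4), dtype=np.uint16))
        with pytest.raises(ValueError, match="8-bit"):
            q.load_image(path)

    def test_single_page_warns_and_fills_live(self, tmp_path):
        plane = np.full((6, 8), 99, dtype=np.uint8)
        path = tmp_path / "one.tif"
        tifffile.imwrite(path, plane)
        with pytest.warns(UserWarning, match="single-page"):
            image = q.load_image(path)
        assert np.array_equal(image.live_fluor, plane)
        assert not image.bright_field.any() and not image.dead_fluor.any()

    def test_wrong_page_count_rejected(self, tmp_path):
        path = tmp_path / "two.tif"
        tifffile.imwrite(path, np.zeros((2, 4, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="pages"):
            q.load_image(path)


class TestSegmentChannels:
    def test_roi_count_and_disjointness(self, mixed_image, small_geometry):
        rois = q.segment_channels(mixed_image, small_geometry)
        assert len(rois) == small_geometry.total_channels == 20
        boxes = [r.bbox_px for r in rois]
        for i, a in enumerate(boxes):
            for b in boxes[i + 1 :]:
                overlap = (
                    max(a[0], b[0]) < min(a[2], b[2])
                    and max(a[1], b[1]) < min(a[3], b[3])
                )
                assert not overlap

    def test_translation_registration_recovers_offset(
        self, mixed_image, small_geometry
    ):
        shift = (3, -5)
        shifted = cm.RenderedImage(
            *[
                np.roll(p, shift, axis=(0, 1))
                for p in (
                    mixed_image.bright_field,
                    mixed_image.live_fluor,
                    mixed_image.dead_fluor,
                )
            ]
        )
        base = q.segment_channels(mixed_image, small_geometry)
        moved = q.segment_channels(shifted, small_geometry, registration="translation")
        for r0, r1 in zip(base, moved):
            assert r1.bbox_px[0] - r0.bbox_px[0] == shift[0]
            assert r1.bbox_px[1] - r0.bbox_px[1] == shift[1]

    def test_registration_out_of_bounds_raises(self, small_geometry):
        # shift larger than the image margin pushes the template off-image
        tight = cm.DeviceGeometry(n_channels_per_side=10, margin_px=10)
        scene = cm.sample_scene(tight, 20, "uniform", {"low": 50, "high": 950}, seed=1)
        image = cm.render(scene)
        shifted = cm.RenderedImage(
            *[
                np.roll(p, (0, -15), axis=(0, 1))
                for p in (image.bright_field, image.live_fluor, image.dead_fluor)
            ]
        )
        with pytest.raises(ValueError, match="bounds"):
            q.segment_channels(shifted, tight, registration="translation")

    def test_geometry_image_mismatch_rejected(self, mixed_image):
        other = cm.DeviceGeometry(n_channels_per_side=5)
        with pytest.raises(ValueError, match="does not match"):
            q.segment_channels(mixed_image, other)


class TestBrightPixels:
    def test_threshold_is_strict(self):
        plane = np.array([[49, 50, 51]], dtype=np.uint8)
        assert q.find_bright_pixels(plane, 50).tolist() == [[False, False, True]]

    def test_uniform_extremes(self):
        assert not q.find_bright_pixels(np.zeros((4, 4), np.uint8), 50).any()
        assert q.find_bright_pixels(np.full((4, 4), 255, np.uint8), 254).all()


class TestDetectObjects:
    def test_empty_mask(self, mixed_image, small_geometry, small_config):
        rois = q.segment_channels(mixed_image, small_geometry)
        mask = np.zeros_like(mixed_image.live_fluor, dtype=bool)
        assert q.detect_objects(mask, small_config, rois) == []

    def test_single_block_counted_once(self, mixed_image, small_geometry):
        rois = q.segment_channels(mixed_image, small_geometry)
        mask = np.zeros_like(mixed_image.live_fluor, dtype=bool)
        r0, c0, _, _ = rois[0].bbox_px
        mask[r0 + 5 : r0 + 10, c0 + 30 : c0 + 36] = True  # 30 px
        config = q.QuantConfig(min_bright_pixels=10, central_window=10)
        objects = q.detect_objects(mask, config, rois)
        assert len(objects) == 1
        assert objects[0].bright_pixel_count == 30
        assert objects[0].cls == "live"

    def test_debris_rejected_cells_kept(
        self, mixed_scene, mixed_image, small_geometry, small_config
    ):
        rois = q.segment_channels(mixed_image, small_geometry)
        mask = q.find_bright_pixels(mixed_image.live_fluor, 50)
        objects = q.detect_objects(mask, small_config, rois)
        valid = [o for o in objects if o.cls != "rejected"]
        rejected = [o for o in objects if o.cls == "rejected"]
        assert len(valid) == len(mixed_scene.cells)
        assert len(rejected) == mixed_scene.debris_count

    def test_min_bright_pixels_monotone(self, mixed_image, small_geometry):
        mask = q.find_bright_pixels(mixed_image.live_fluor, 50)
        rois = q.segment_channels(mixed_image, small_geometry)
        counts = []
        for mbp in (5, 20, 60, 200):
            cfg = q.QuantConfig(min_bright_pixels=mbp, central_window=10)
            objs = q.detect_objects(mask, cfg, rois)
            counts.append(sum(1 for o in objs if o.cls != "rejected"))
        assert counts == sorted(counts, reverse=True)

    def test_live_threshold_monotone(self, mixed_image, small_geometry, small_config):
        rois = q.segment_channels(mixed_image, small_geometry)
        counts = []
        for thr in (30, 50, 120, 200):
            mask = q.find_bright_pixels(mixed_image.live_fluor, thr)
            objs = q.detect_objects(mask, small_config, rois)
            counts.append(sum(1 for o in objs if o.cls != "rejected"))
        assert counts == sorted(counts, reverse=True)


class TestViability:
    def test_dead_count_matches_ground_truth(
        self, mixed_scene, mixed_image, small_geometry, small_config
    ):
        rois = q.segment_channels(mixed_image, small_geometry)
        live_mask = q.find_bright_pixels(mixed_image.live_fluor, 50)
        dead_mask = q.find_bright_pixels(mixed_image.dead_fluor, 50)
        objects = q.classify_viability(
            q.detect_objects(live_mask, small_config, rois), live_mask, dead_mask
        )
        truth_dead = sum(1 for c in mixed_scene.cells if c.viability == "dead")
        assert sum(1 for o in objects if o.cls == "dead") == truth_dead

    def test_no_dead_signal_keeps_objects_live(
        self, mixed_image, small_geometry, small_config
    ):
        rois = q.segment_channels(mixed_image, small_geometry)
        live_mask = q.find_bright_pixels(mixed_image.live_fluor, 50)
        objects = q.classify_viability(
            q.detect_objects(live_mask, small_config, rois),
            live_mask,
            np.zeros_like(live_mask),
        )
        assert all(o.cls in ("live", "rejected") for o in objects)

    def test_all_dead_scene_empties_every_channel(self, small_geometry, small_config):
        scene = cm.sample_scene(
            small_geometry,
            n_cells=20,
            distance_dist="uniform",
            dist_params={"low": 50, "high": 950},
            dead_fraction=1.0,
            seed=4,
        )
        results = q.quantify_device(cm.render(scene), small_geometry, small_config)
        assert all(r.n_live == 0 for r in results)
        assert all(r.frontier_distance_um == 0.0 for r in results)


class TestFrontier:
    def test_single_cell_at_300_um(self, small_geometry, small_config):
        scene = single_cell_scene(small_geometry, 300.0)
        results = q.quantify_device(cm.render(scene), small_geometry, small_config)
        target = [r for r in results if r.side == "left" and r.channel_index == 0][0]
        assert target.frontier_distance_um == pytest.approx(300.0, abs=1e-9)
        assert not target.reached_central

    def test_cell_at_exit_scores_full_length(self, small_geometry, small_config):
        scene = single_cell_scene(small_geometry, 1000.0, side="right", channel_index=3)
        results = q.quantify_device(cm.render(scene), small_geometry, small_config)
        target = [r for r in results if r.side == "right" and r.channel_index == 3][0]
        assert target.frontier_distance_um == 1000.0
        assert target.reached_central

    def test_empty_channel_scores_zero(self, small_geometry, small_config):
        rois = q.segment_channels(
            cm.render(cm.sample_scene(small_geometry, 0, seed=0)), small_geometry
        )
        res = q.channel_frontier(rois[0], [], small_config)
        assert res.frontier_distance_um == 0.0
        assert res.n_live == 0 and not res.reached_central

    def test_frontier_ignores_cells_behind_it(self, small_geometry, small_config):
        rois = q.segment_channels(
            cm.render(cm.sample_scene(small_geometry, 0, seed=0)), small_geometry
        )
        roi = rois[0]
        row = roi.entrance_px[0]
        col = roi.entrance_px[1]

        def obj(dist):
            return q.DetectedObject(
                channel_index=roi.channel_index,
                side=roi.side,
                centroid_px=(row, col + dist),
                bright_pixel_count=50,
                cls="live",
                footprint=(np.array([int(row)]), np.array([int(col + dist)])),
            )

        front = q.channel_frontier(roi, [obj(700.0)], small_config)
        with_extra = q.channel_frontier(roi, [obj(700.0), obj(200.0)], small_config)
        assert with_extra.frontier_distance_um == front.frontier_distance_um


class TestQuantifyDevice:
    def test_full_device_channel_counts(self):
        geom = cm.DeviceGeometry()  # published layout: 450 per side
        image = cm.render(cm.sample_scene(geom, n_cells=0, seed=0))
        results = q.quantify_device(image, geom)
        assert len(results) == 900
        assert sum(r.used_in_analysis for r in results) == 600

    def test_central_window_full_width(self, mixed_image, small_geometry):
        results = q.quantify_device(
            mixed_image, small_geometry, q.QuantConfig(central_window=10)
        )
        assert all(r.used_in_analysis for r in results)

    def test_noise_free_distances_match_ground_truth(
        self, mixed_scene, mixed_image, small_geometry, small_config
    ):
        results = q.results_to_frame(
            q.quantify_device(mixed_image, small_geometry, small_config)
        )
        truth = cm.ground_truth_frontiers(mixed_scene)
        merged = results.merge(
            truth, on=["channel_index", "side"], suffixes=("", "_truth")
        )
        assert (merged["n_live"] == merged["n_live_truth"]).all()
        assert (
            merged["frontier_distance_um"] == merged["frontier_distance_um_truth"]
        ).all()


class TestPopulations:
    def test_all_at_entrance_no_migratory(self, small_geometry, small_config):
        scene = cm.sample_scene(
            small_geometry, 10, "point_mass_at_entrance", seed=0
        )
        results = q.quantify_device(cm.render(scene), small_geometry, small_config)
        pops = q.classify_populations(results)
        assert pops["migratory"] == []
        assert len(pops["non_migratory"]) == 20

    def test_partition_is_disjoint_and_complete(
        self, mixed_image, small_geometry, small_config
    ):
        results = q.quantify_device(mixed_image, small_geometry, small_config)
        pops = q.classify_populations(results)
        mig, non = set(pops["migratory"]), set(pops["non_migratory"])
        used = {
            (r.side, r.channel_index) for r in results if r.used_in_analysis
        }
        assert mig.isdisjoint(non)
        assert mig | non == used

    def test_two_component_migratory_fraction_matches_truth(self, small_config):
        geom = cm.DeviceGeometry(n_channels_per_side=30)
        scene = cm.sample_scene(
            geom,
            n_cells=90,
            distance_dist="two_component",
            dist_params={"migratory_fraction": 0.15, "low": 50, "high": 950},
            seed=21,
        )
        results = q.quantify_device(
            cm.render(scene), geom, q.QuantConfig(central_window=30)
        )
        pops = q.classify_populations(results)
        truth = cm.ground_truth_frontiers(scene)
        truth_migratory = (truth["frontier_distance_um"] >= 1000.0).sum()
        assert len(pops["migratory"]) == truth_migratory


class TestSpheres:
    @staticmethod
    def _disk_plane(diameters_um, pixel_size_um=1.0, spacing=80):
        size = spacing * (len(diameters_um) + 1)
        plane = np.zeros((160, size), dtype=np.uint8)
        yy, xx = np.mgrid[: plane.shape[0], : plane.shape[1]]
        for i, d in enumerate(diameters_um):
            r = d / 2.0 / pixel_size_um
            cx = spacing * (i + 1)
            plane[(yy - 80) ** 2 + (xx - cx) ** 2 <= r * r] = 200
        return plane

    def test_disk_above_cutoff_counted(self):
        sc = q.count_spheres(self._disk_plane([45.0]), 50, 1.0, n_seeded_wells=10)
        assert sc.n_spheres == 1
        assert sc.sphere_rate == pytest.approx(0.1)

    def test_disk_below_cutoff_not_counted(self):
        sc = q.count_spheres(self._disk_plane([35.0]), 50, 1.0, n_seeded_wells=10)
        assert sc.n_spheres == 0

    def test_mixed_diameters_match_brute_force(self):
        rng = np.random.default_rng(8)
        diameters = rng.uniform(20.0, 70.0, size=20)
        sc = q.count_spheres(
            self._disk_plane(diameters), 50, 1.0, n_seeded_wells=100
        )
        # rasterized disks reproduce target diameters within one pixel
        assert np.allclose(np.sort(sc.diameters_um), np.sort(diameters), atol=2.0)
        expected = sum(1 for d in sc.diameters_um if d > 40.0)
        assert sc.n_spheres == expected

    def test_zero_wells_rejected(self):
        with pytest.raises(ValueError):
            q.count_spheres(np.zeros((8, 8), np.uint8), 50, 1.0, n_seeded_wells=0)
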