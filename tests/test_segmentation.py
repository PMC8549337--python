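"""Threshold segmentation, volumetry and unseeded detection."""

import numpy as np
import pytest
from oracles import bfs_flood_fill

from fidct.phantom import (
    CTVolume,
    SceneConfig,
    acquire_ct,
    build_scene,
    default_marker,
    default_protocol,
)
from fidct.segmentation import (
    SegmentationParams,
    detect_markers,
    segment_marker,
    suggest_lower_level,
)


def _cube_volume(value=200.0, background=0.0, size=5, block=3, spacing=(1.0, 1.0, 1.0)):
    hu = np.full((size, size, size), background)
    lo = (size - block) // 2
    hu[lo : lo + block, lo : lo + block, lo : lo + block] = value
    return CTVolume(hu, spacing)


class TestSuggestLowerLevel:
    def test_constant_soft_tissue_gives_next_integer(self):
        vol = CTVolume(np.full((10, 10, 10), 50.0), (1, 1, 1))
        assert suggest_lower_level(vol) == 51

    def test_pure_air_gives_minus_999(self):
        vol = CTVolume(np.full((10, 10, 10), -1000.0), (1, 1, 1))
        assert suggest_lower_level(vol) == -999

    def test_noisy_phantom_background_stays_below_140(self):
        # worst default noise (sd 8 HU at 120 kV) on a 50 HU background
        rng = np.random.default_rng(0)
        vol = CTVolume(rng.normal(50.0, 8.0, size=(60, 60, 60)), (1, 1, 1))
        assert suggest_lower_level(vol) <= 140

    def test_empty_mask_rejected(self):
        vol = CTVolume(np.full((4, 4, 4), 50.0), (1, 1, 1))
        with pytest.raises(ValueError):
            suggest_lower_level(vol, background_mask=np.zeros((4, 4, 4), bool))


class TestSegmentMarker:
    def test_cube_volume_counted_exactly(self):
        vol = _cube_volume()
        m = segment_marker(vol, (2.5, 2.5, 2.5), SegmentationParams(roi_radius_mm=4.0))
        assert m.visible
        assert m.volume_ul == 27.0
        assert m.peak_hu == 200.0

    def test_threshold_above_everything_is_not_visible(self):
        vol = _cube_volume()
        m = segment_marker(
            vol, (2.5, 2.5, 2.5), SegmentationParams(lower_threshold=250.0, roi_radius_mm=4.0)
        )
        assert not m.visible
        assert m.volume_ul == 0.0

    def test_voxel_at_threshold_is_included(self):
        vol = _cube_volume(value=140.0)
        m = segment_marker(vol, (2.5, 2.5, 2.5), SegmentationParams(roi_radius_mm=4.0))
        assert m.visible and m.volume_ul == 27.0

    def test_seed_outside_grid_is_an_error(self):
        vol = _cube_volume()
        with pytest.raises(ValueError, match="outside"):
            segment_marker(vol, (9.0, 2.5, 2.5))

    def test_roi_sphere_limits_component(self):
        hu = np.zeros((30, 5, 5))
        hu[:, 2, 2] = 200.0  # a 30 mm rod
        vol = CTVolume(hu, (1.0, 1.0, 1.0))
        m = segment_marker(vol, (15.5, 2.5, 2.5), SegmentationParams(roi_radius_mm=3.0))
        assert m.volume_ul <= 7.0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_grids(self, connectivity, rng):
        params = SegmentationParams(
            lower_threshold=0.5, connectivity=connectivity, roi_radius_mm=100.0
        )
        for _ in range(15):
            hu = (rng.random((12, 12, 12)) > 0.5).astype(float)
            seed_idx = tuple(rng.integers(0, 12, size=3))
            expected = bfs_flood_fill(hu > 0.5, seed_idx, connectivity)
            point = tuple(i + 0.5 for i in seed_idx)
            m = segment_marker(CTVolume(hu, (1, 1, 1)), point, params)
            got = set(map(tuple, m.voxel_indices))
            assert got == expected

    def test_raising_threshold_never_grows_the_marker(self):
        # threshold monotonicity on a real phantom volume
        scene = build_scene(SceneConfig(markers=[default_marker(30.0)], seed=3))
        vol = acquire_ct(scene, default_protocol(70), seed=9)
        seed_point = scene.markers[0].center_mm
        vols = [
            segment_marker(vol, seed_point, SegmentationParams(lower_threshold=t)).volume_ul
            for t in (140.0, 200.0, 400.0, 800.0)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        hu = np.zeros((20, 20, 20))
        hu[4:9, 4:9, 4:9] = rng.uniform(150, 300, (5, 5, 5))
        shift = (3, 2, 1)
        vol = CTVolume(hu, (1, 1, 1))
        vol_shifted = CTVolume(np.roll(hu, shift, axis=(0, 1, 2)), (1, 1, 1))
        m = segment_marker(vol, (6.5, 6.5, 6.5))
        m2 = segment_marker(vol_shifted, (9.5, 8.5, 7.5))
        assert m2.volume_ul == m.volume_ul
        assert set(map(tuple, m2.voxel_indices)) == {
            tuple((np.array(v) + shift) % 20) for v in map(tuple, m.voxel_indices)
        }


class TestDetectMarkers:
    def test_phantom_markers_all_detected(self):
        scene = build_scene(
            SceneConfig(
                markers=[default_marker(v) for v in (10, 20, 30) * 3],
                bone_top_mm=0.0,
                surface_mm=14.0,
                flap_top_mm=20.0,
                shape=(100, 100, 40),
                include_teeth=False,
                seed=2,
            )
        )
        vol = acquire_ct(scene, default_protocol(100), seed=4)
        found = detect_markers(vol, min_volume_ul=2.0)
        assert len(found) == 9
        vols = [m.volume_ul for m in found]
        assert vols == sorted(vols, reverse=True)

    def test_all_below_threshold_gives_empty_list(self):
        vol = CTVolume(np.full((10, 10, 10), 50.0), (1, 1, 1))
        assert detect_markers(vol) == []

    def test_blocks_split_by_subthreshold_plane_are_two_detections(self):
        hu = np.zeros((11, 5, 5))
        hu[0:5] = 200.0
        hu[6:11] = 200.0  # plane at index 5 stays at 0 HU
        found = detect_markers(CTVolume(hu, (1, 1, 1)), SegmentationParams(connectivity=26))
        assert len(found) == 2

    def test_max_volume_filter_drops_large_anatomy(self):
        hu = np.zeros((20, 20, 20))
        hu[:, :, :5] = 900.0  # slab
        hu[10:12, 10:12, 10:12] = 200.0  # small object
        found = detect_markers(CTVolume(hu, (1, 1, 1)), min_volume_ul=2.0, max_volume_ul=100.0)
        assert len(found) == 1 and found[0].volume_ul == 8.0
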