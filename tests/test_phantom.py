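"""Scene construction and the CT forward model."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from fidct.phantom import (
    DEFAULT_HU_TABLE,
    IODINE_HU_PER_MG_ML,
    AcquisitionProtocol,
    ConfounderSpec,
    MarkerSpec,
    SceneConfig,
    SceneError,
    acquire_ct,
    acquire_dect,
    build_scene,
    default_dect_protocols,
    default_marker,
    default_protocol,
)


def _flat_scene(markers=(), spacing=(0.4, 0.4, 0.6), shape=(100, 100, 48), **kw):
    return build_scene(
        SceneConfig(shape=shape, spacing=spacing, markers=list(markers), seed=7, **kw)
    )


def _noise_free(kv=120, fwhm=0.0):
    return AcquisitionProtocol(kv, 0.0, IODINE_HU_PER_MG_ML[kv], psf_fwhm_mm=fwhm, noise_sd_hu=0.0)


class TestBuildScene:
    def test_nine_markers_form_nine_disjoint_iodine_components(self):
        scene = _flat_scene([default_marker(v) for v in (10, 20, 30) * 3])
        _, n = ndimage.label(
            scene.iodine_grid > 0, structure=ndimage.generate_binary_structure(3, 3)
        )
        assert n == 9

    def test_empty_marker_list_gives_zero_iodine(self):
        scene = _flat_scene([])
        assert not scene.iodine_grid.any()

    def test_rasterized_sphere_volume_matches_voxel_count_oracle(self):
        # 0.4*0.4*0.6 mm voxels are 0.096 µl each
        scene = _flat_scene([MarkerSpec(10.0)])
        n_vox = int(np.count_nonzero(scene.iodine_grid))
        assert 9.5 <= n_vox * 0.096 <= 10.5

    @pytest.mark.parametrize("volume", [10.0, 20.0, 30.0])
    def test_rasterized_volume_within_5pct_of_nominal(self, volume):
        scene = _flat_scene([default_marker(volume)])
        vox_ul = float(np.prod(scene.spacing))
        got = np.count_nonzero(scene.iodine_grid) * vox_ul
        assert abs(got - volume) / volume < 0.05

    def test_unit_identity_any_spacing(self):
        # voxel count x dx dy dz is the volume in µl for any spacing
        scene = _flat_scene([MarkerSpec(10.0)], spacing=(0.5, 0.3, 0.8))
        vox_ul = 0.5 * 0.3 * 0.8
        got = np.count_nonzero(scene.iodine_grid) * vox_ul
        assert abs(got - 10.0) < vox_ul  # exact to within the half-voxel rounding

    def test_overlapping_markers_rejected(self):
        m = MarkerSpec(10.0, center_mm=(20.0, 20.0, 15.0))
        with pytest.raises(SceneError, match="overlap"):
            _flat_scene([m, replace(m)])

    def test_marker_outside_grid_rejected(self):
        with pytest.raises(SceneError, match="outside"):
            _flat_scene([MarkerSpec(10.0, center_mm=(0.5, 20.0, 15.0))])

    def test_markers_sit_below_surface_under_the_flap(self):
        scene = _flat_scene([default_marker(10.0)])
        zs = np.argwhere(scene.iodine_grid > 0)[:, 2]
        z_mm = (zs + 0.5) * scene.spacing[2]
        assert z_mm.max() < scene.config.surface_mm
        flap = scene.material_mask("muscle_flap")
        assert flap.any()

    def test_multilobular_markers_are_connected(self):
        scene = _flat_scene([MarkerSpec(30.0, shape="multilobular", n_lobes=4)])
        _, n = ndimage.label(
            scene.iodine_grid > 0, structure=ndimage.generate_binary_structure(3, 3)
        )
        assert n == 1

    def test_rounded_marker_requires_single_lobe(self):
        with pytest.raises(ValueError):
            MarkerSpec(10.0, shape="rounded", n_lobes=2)


class TestAcquire:
    def test_pure_soft_tissue_identity_forward_model(self):
        scene = _flat_scene([], bone_top_mm=0.0, surface_mm=28.8, flap_top_mm=28.8)
        vol = acquire_ct(scene, _noise_free(120), seed=0)
        assert np.all(vol.hu_grid == DEFAULT_HU_TABLE["soft_tissue"][120])

    def test_same_seed_bit_identical(self):
        scene = _flat_scene([default_marker(10.0)])
        a = acquire_ct(scene, default_protocol(100), seed=42)
        b = acquire_ct(scene, default_protocol(100), seed=42)
        assert np.array_equal(a.hu_grid, b.hu_grid)

    def test_marker_voxel_closed_form(self):
        # noise- and blur-free: HU = soft tissue + c * iodine contrast(70 kV)
        scene = _flat_scene([default_marker(10.0)], concentration_jitter_sd=0.0)
        c = scene.markers[0].iodine_mg_ml
        vol = acquire_ct(scene, _noise_free(70), seed=0)
        inside = scene.iodine_grid > 0
        expected = DEFAULT_HU_TABLE["soft_tissue"][70] + c * IODINE_HU_PER_MG_ML[70]
        assert np.allclose(vol.hu_grid[inside], expected)

    def test_unknown_kv_rejected(self):
        scene = _flat_scene([])
        bad = AcquisitionProtocol(95, 0.0, 30.0, noise_sd_hu=0.0)
        with pytest.raises(ValueError, match="95"):
            acquire_ct(scene, bad, seed=0)

    def test_iodine_contrast_strictly_decreases_with_kv(self):
        kvs = sorted(IODINE_HU_PER_MG_ML)
        contrasts = [IODINE_HU_PER_MG_ML[kv] for kv in kvs]
        assert all(a > b for a, b in zip(contrasts, contrasts[1:]))

    def test_mean_marker_hu_decreases_with_kv(self):
        scene = _flat_scene([default_marker(20.0)])
        inside = scene.iodine_grid > 0
        means = [
            acquire_ct(scene, _noise_free(kv, fwhm=2.0), seed=0).hu_grid[inside].mean()
            for kv in (70, 100, 120)
        ]
        assert means[0] > means[1] > means[2]


class TestDect:
    def test_no_marker_scene_differs_only_by_material_tables(self):
        scene = _flat_scene([])
        pa, pb = default_dect_protocols()
        pa = replace(pa, psf_fwhm_mm=0.0, noise_sd_hu=0.0)
        pb = replace(pb, psf_fwhm_mm=0.0, noise_sd_hu=0.0)
        va, vb = acquire_dect(scene, pa, pb, seed=0)
        diff = va.hu_grid - vb.hu_grid
        soft = scene.material_mask("soft_tissue")
        bone = scene.material_mask("bone")
        assert np.allclose(diff[soft], 0.0)
        assert np.allclose(
            diff[bone], DEFAULT_HU_TABLE["bone"][80] - DEFAULT_HU_TABLE["bone"][150]
        )

    def test_marker_voxel_dual_energy_closed_form(self):
        scene = _flat_scene([default_marker(10.0)], concentration_jitter_sd=0.0)
        c = scene.markers[0].iodine_mg_ml
        pa, pb = default_dect_protocols()
        pa = replace(pa, psf_fwhm_mm=0.0, noise_sd_hu=0.0)
        pb = replace(pb, psf_fwhm_mm=0.0, noise_sd_hu=0.0)
        va, vb = acquire_dect(scene, pa, pb, seed=0)
        inside = scene.iodine_grid > 0
        expected = c * (IODINE_HU_PER_MG_ML[80] - IODINE_HU_PER_MG_ML[150])
        assert np.allclose((va.hu_grid - vb.hu_grid)[inside], expected)

    def test_titanium_clip_hyperdense_in_both_tubes(self):
        scene = build_scene(
            SceneConfig(
                markers=[],
                confounders=[ConfounderSpec("titanium_clip", (20.0, 20.0, 10.0), 20.0)],
                seed=1,
            )
        )
        pa, pb = default_dect_protocols()
        pa = replace(pa, psf_fwhm_mm=0.0, noise_sd_hu=0.0)
        pb = replace(pb, psf_fwhm_mm=0.0, noise_sd_hu=0.0)
        va, vb = acquire_dect(scene, pa, pb, seed=0)
        clip = scene.material_mask("titanium_clip")
        assert va.hu_grid[clip].min() >= 1000
        assert vb.hu_grid[clip].min() >= 1000

    def test_tube_ordering_enforced(self):
        scene = _flat_scene([])
        pa, pb = default_dect_protocols()
        with pytest.raises(ValueError):
            acquire_dect(scene, pb, pa, seed=0)
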