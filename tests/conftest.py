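from dataclasses import replace

import numpy as np
import pytest

from fidct.dual_energy import make_dect_images
from fidct.phantom import (
    ConfounderSpec,
    SceneConfig,
    acquire_dect,
    build_scene,
    default_dect_protocols,
    default_marker,
)
from fidct.pipeline import ExperimentConfig, run_preclinical


@pytest.fixture(scope="session")
def preclinical_report():
    """One full default preclinical replication (75 markers x 3 kV), shared."""
    return run_preclinical(ExperimentConfig(seed=1234))


def make_dect_scene(n_markers_10=16, n_markers_30=4, confounders=True, seed=11):
    """Flap-type scene with markers plus a clear row of clips/calcifications."""
    markers = [default_marker(10.0) for _ in range(n_markers_10)] + [
        default_marker(30.0) for _ in range(n_markers_30)
    ]
    confs = []
    if confounders:
        confs = [
            ConfounderSpec(mat, (x, 5.0, 10.0), 15.0)
            for mat, x in zip(
                ["titanium_clip", "calcification"] * 3, [15.0, 30.0, 45.0, 60.0, 75.0]
            )
        ]
    cfg = SceneConfig(
        shape=(240, 160, 40),
        bone_top_mm=0.0,
        surface_mm=14.0,
        flap_top_mm=20.0,
        include_teeth=False,
        marker_pitch_mm=12.0,
        markers=markers,
        confounders=confs,
        seed=seed,
    )
    return build_scene(cfg)


@pytest.fixture(scope="session")
def noisy_dect_images():
    """Default noisy dual-energy study: 20 markers + 5 confounders."""
    scene = make_dect_scene()
    pa, pb = default_dect_protocols()
    vol_a, vol_b = acquire_dect(scene, pa, pb, seed=5)
    return scene, make_dect_images(vol_a, vol_b)


@pytest.fixture(scope="session")
def ideal_dect_images():
    """Noise-free, blur-free dual-energy study of the same scene."""
    scene = make_dect_scene(seed=3)
    pa, pb = default_dect_protocols()
    pa = replace(pa, psf_fwhm_mm=0.0, noise_sd_hu=0.0)
    pb = replace(pb, psf_fwhm_mm=0.0, noise_sd_hu=0.0)
    vol_a, vol_b = acquire_dect(scene, pa, pb, seed=0)
    return scene, make_dect_images(vol_a, vol_b)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
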