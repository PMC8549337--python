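"""Dual-energy CT: mixed image, two-material decomposition, classification.

The A-tube (80 kV) sees iodine with much higher contrast than the
tin-filtered B-tube (150Sn kV).  A mixed-energy image (default weight 0.6
for the A-tube) serves as the reading image.  A two-material (soft tissue
plus iodine) linear decomposition yields a voxelwise iodine concentration
estimate and a virtual non-contrast (VNC) image with the iodine
contribution removed.  Iodine markers vanish (or are markedly reduced) in
the VNC while titanium clips and calcifications stay hyperdense, which is
the basis for classifying hyperdense objects; the iodine map alone does
not discriminate, since materials with any spectral slope (calcium, bone)
leak into it.

The inversion vectors are configurable independently of the simulation
vectors so that model mismatch can be studied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import CTVolume
from .segmentation import SegmentedMarker

__all__ = [
    "DectImages",
    "ObjectClassification",
    "mix_images",
    "decompose",
    "make_dect_images",
    "classify_hyperdense",
    "downsample_slices",
]

#: Default soft-tissue reference (HU) against which object contrast and VNC
#: retention are measured.
SOFT_TISSUE_REFERENCE_HU = 50.0


@dataclass
class DectImages:
    """The five co-registered grids of one dual-energy study."""

    a_volume: CTVolume
    b_volume: CTVolume
    mix_weight: float
    mixed: np.ndarray
    vnc: np.ndarray
    iodine_map: np.ndarray  # mg/ml, clamped at 0

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.a_volume.spacing

    def mixed_volume(self) -> CTVolume:
        """The mixed grid wrapped as a CTVolume (for segmentation)."""
        return CTVolume(self.mixed, self.spacing, self.a_volume.protocol, None)


def _grids(a, b) -> tuple[np.ndarray, np.ndarray]:
    ga = a.hu_grid if isinstance(a, CTVolume) else np.asarray(a)
    gb = b.hu_grid if isinstance(b, CTVolume) else np.asarray(b)
    if ga.shape != gb.shape:
        raise ValueError("A and B grids must be co-registered (same shape)")
    return ga, gb


def mix_images(a_volume, b_volume, mix_weight: float = 0.6) -> np.ndarray:
    """Voxelwise mixed-energy image: w·A + (1 − w)·B."""
    ga, gb = _grids(a_volume, b_volume)
    return mix_weight * ga + (1.0 - mix_weight) * gb


def decompose(
    a_volume,
    b_volume,
    iodine_vector: tuple[float, float],
    spectral_offset: float = 0.0,
    mix_weight: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-material decomposition into (VNC grid, iodine map).

    Per voxel the linear model HU_A = base_A + c·i_A, HU_B = base_B + c·i_B
    is solved under the constraint base_A − base_B = ``spectral_offset``
    (0 for a soft-tissue background), giving

        c   = (HU_A − HU_B − offset) / (i_A − i_B),   clamped at 0,
        VNC = mixed − c·(w·i_A + (1 − w)·i_B).

    ``iodine_vector`` is (HU per mg/ml at A, at B); the A component must
    exceed the B component, otherwise the system is singular.
    """
    i_a, i_b = iodine_vector
    if not (i_a > 0 and i_b > 0):
        raise ValueError("iodine vector components must be positive")
    if i_a <= i_b:
        raise ValueError("singular decomposition: A-tube iodine contrast must exceed B's")
    ga, gb = _grids(a_volume, b_volume)
    conc = (ga - gb - spectral_offset) / (i_a - i_b)
    np.clip(conc, 0.0, None, out=conc)
    mixed = mix_images(ga, gb, mix_weight)
    vnc = mixed - conc * (mix_weight * i_a + (1.0 - mix_weight) * i_b)
    return vnc, conc


def make_dect_images(
    a_volume: CTVolume,
    b_volume: CTVolume,
    mix_weight: float = 0.6,
    iodine_vector: tuple[float, float] | None = None,
    spectral_offset: float = 0.0,
) -> DectImages:
    """Build the full DECT bundle from an A/B volume pair.

    When ``iodine_vector`` is omitted it is taken from the two volumes'
    acquisition protocols (matched inversion).
    """
    if iodine_vector is None:
        if a_volume.protocol is None or b_volume.protocol is None:
            raise ValueError("iodine_vector required when volumes carry no protocol")
        iodine_vector = (
            a_volume.protocol.iodine_hu_per_unit,
            b_volume.protocol.iodine_hu_per_unit,
        )
    mixed = mix_images(a_volume, b_volume, mix_weight)
    vnc, iodine = decompose(a_volume, b_volume, iodine_vector, spectral_offset, mix_weight)
    return DectImages(a_volume, b_volume, mix_weight, mixed, vnc, iodine)


@dataclass
class ObjectClassification:
    """A hyperdense object labeled as iodine marker vs clip/calcification."""

    object: SegmentedMarker
    vnc_retention: float
    mean_iodine_mg_ml: float
    label: str  # "iodine_marker" or "clip_or_calcification"


def classify_hyperdense(
    dect: DectImages,
    objects: list[SegmentedMarker],
    retention_threshold: float = 0.3,
    reference_hu: float = SOFT_TISSUE_REFERENCE_HU,
) -> list[ObjectClassification]:
    """Label hyperdense objects by their VNC retention.

    For each object (segmented on the mixed image) the retention is the
    mean VNC contrast over its voxels divided by the mean mixed-image
    contrast, both referenced to soft tissue.  Iodine markers vanish in the
    VNC (retention near 0, "absent or markedly reduced"), clips and
    calcifications retain their contrast; the default cutoff is 0.3.
    A small tolerance admits objects at exact equality with the threshold
    (relevant only for the degenerate threshold 1.0 on noise-free data).
    """
    out: list[ObjectClassification] = []
    for obj in objects:
        sel = tuple(obj.voxel_indices.T)
        mixed_contrast = float(np.mean(dect.mixed[sel])) - reference_hu
        if mixed_contrast <= 0:
            raise ValueError("object has no mixed-image contrast over soft tissue")
        vnc_contrast = float(np.mean(dect.vnc[sel])) - reference_hu
        retention = vnc_contrast / mixed_contrast
        mean_iodine = float(np.mean(dect.iodine_map[sel]))
        is_iodine = retention < retention_threshold + 1e-9
        out.append(
            ObjectClassification(
                object=obj,
                vnc_retention=retention,
                mean_iodine_mg_ml=mean_iodine,
                label="iodine_marker" if is_iodine else "clip_or_calcification",
            )
        )
    return out


def downsample_slices(grid: np.ndarray, dz_mm: float, target_mm: float = 3.0) -> np.ndarray:
    """Boxcar-average thin slices into thicker ones along the slice axis.

    Models the thicker reconstructions used for VNC images and iodine maps
    (e.g. 3 mm from 0.6 mm acquisitions).  Trailing slices that do not fill
    a whole block are dropped.
    """
    k = max(1, int(round(target_mm / dz_mm)))
    nz = (grid.shape[2] // k) * k
    if nz == 0:
        raise ValueError("volume thinner than one output slice")
    return grid[:, :, :nz].reshape(grid.shape[0], grid.shape[1], -1, k).mean(axis=3)
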