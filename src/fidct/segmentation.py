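"""Two-step threshold-based marker segmentation and volumetry.

Step one chooses a lower HU window level that excludes the soft tissue
surrounding the markers (here automated as a background quantile rule; in
interactive practice this is set visually and lands at 140 HU).  Step two
grows, inside a spherical region of interest around a seed point, the
connected component of voxels at or above the threshold, and counts voxels:
with spacing in mm, voxel count x dx*dy*dz is the marker volume in µl
(1 mm^3 = 1 µl).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import CTVolume

__all__ = [
    "SegmentationParams",
    "SegmentedMarker",
    "suggest_lower_level",
    "segment_marker",
    "detect_markers",
]

#: scipy connectivity rank (for generate_binary_structure) per voxel adjacency
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold, adjacency and ROI size for marker segmentation.

    The 140 HU default is the window level that excludes soft tissue while
    keeping iodine markers; a voxel exactly at the threshold is included.
    26-connectivity reads "coherent voxels" as full 3D adjacency.
    """

    lower_threshold: float = 140.0
    connectivity: int = 26
    roi_radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lower_threshold):
            raise ValueError("lower_threshold must be finite")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.roi_radius_mm <= 0:
            raise ValueError("roi_radius_mm must be positive")


@dataclass
class SegmentedMarker:
    """A coherent above-threshold voxel set with its derived volume."""

    voxel_indices: np.ndarray  # (n, 3) int voxel indices
    volume_ul: float
    centroid_mm: tuple[float, float, float] | None
    seed_point_mm: tuple[float, float, float] | None
    peak_hu: float
    visible: bool = True
    label: str | None = None

    @classmethod
    def not_visible(cls, seed_point_mm) -> "SegmentedMarker":
        """Result for a seed voxel below threshold: marker not visible."""
        return cls(
            voxel_indices=np.empty((0, 3), dtype=int),
            volume_ul=0.0,
            centroid_mm=None,
            seed_point_mm=tuple(seed_point_mm) if seed_point_mm is not None else None,
            peak_hu=float("-inf"),
            visible=False,
        )

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])


def suggest_lower_level(volume: CTVolume, background_mask: np.ndarray | None = None) -> int:
    """Smallest integer HU level excluding >= 99.9% of background voxels.

    Automated surrogate for visually raising the lower window level until
    the soft tissue around the markers disappears.  With the default
    phantom noise (sd <= 8 HU on a 50 HU background) this stays below the
    140 HU working threshold.
    """
    hu = volume.hu_grid
    values = hu[background_mask] if background_mask is not None else hu.ravel()
    if values.size == 0:
        raise ValueError("empty volume or empty background mask")
    q = np.quantile(values, 0.999)
    return int(np.floor(q)) + 1


def _world_to_voxel(point_mm, spacing, shape) -> tuple[int, int, int]:
    idx = tuple(int(np.floor(p / d)) for p, d in zip(point_mm, spacing))
    if any(i < 0 or i >= n for i, n in zip(idx, shape)):
        raise ValueError(f"seed point {tuple(point_mm)} mm lies outside the grid")
    return idx


def segment_marker(
    volume: CTVolume,
    seed_point_mm,
    params: SegmentationParams = SegmentationParams(),
) -> SegmentedMarker:
    """Segment the marker containing ``seed_point_mm``.

    Returns the connected component (at the configured connectivity) of
    voxels with HU >= lower_threshold that contains the seed, restricted to
    the sphere of ``roi_radius_mm`` around the seed point.  If the seed
    voxel itself is below threshold the marker counts as not visible at
    this threshold (a regular outcome, not an error).
    """
    hu = volume.hu_grid
    spacing = volume.spacing
    seed_idx = _world_to_voxel(seed_point_mm, spacing, hu.shape)
    if hu[seed_idx] < params.lower_threshold:
        return SegmentedMarker.not_visible(seed_point_mm)

    # crop to the ROI bounding box for speed
    half = [int(np.ceil(params.roi_radius_mm / d)) + 1 for d in spacing]
    lo = [max(0, i - h) for i, h in zip(seed_idx, half)]
    hi = [min(n, i + h + 1) for i, h, n in zip(seed_idx, half, hu.shape)]
    sub = hu[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]

    centers = [
        (np.arange(l, h) + 0.5) * d for l, h, d in zip(lo, hi, spacing)
    ]
    dist2 = (
        (centers[0][:, None, None] - seed_point_mm[0]) ** 2
        + (centers[1][None, :, None] - seed_point_mm[1]) ** 2
        + (centers[2][None, None, :] - seed_point_mm[2]) ** 2
    )
    mask = (sub >= params.lower_threshold) & (dist2 <= params.roi_radius_mm**2)

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[params.connectivity])
    labeled, _ = ndimage.label(mask, structure=structure)
    local_seed = tuple(i - l for i, l in zip(seed_idx, lo))
    comp_id = labeled[local_seed]
    comp = labeled == comp_id
    idx = np.argwhere(comp) + np.asarray(lo)

    vox_ul = volume.voxel_volume_ul
    centroid = tuple(((idx.mean(axis=0) + 0.5) * np.asarray(spacing)).tolist())
    return SegmentedMarker(
        voxel_indices=idx,
        volume_ul=idx.shape[0] * vox_ul,
        centroid_mm=centroid,
        seed_point_mm=tuple(seed_point_mm),
        peak_hu=float(sub[comp].max()),
    )


def detect_markers(
    volume: CTVolume,
    params: SegmentationParams = SegmentationParams(),
    min_volume_ul: float = 0.0,
    max_volume_ul: float | None = None,
) -> list[SegmentedMarker]:
    """Unseeded detection of all above-threshold components.

    Used by the clinical-simulation mode, where markers are found rather
    than seeded.  Components are filtered by volume (``max_volume_ul``
    discards large anatomical structures such as the bone slab) and
    returned sorted by decreasing volume; each voxel belongs to at most one
    detection.
    """
    hu = volume.hu_grid
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[params.connectivity])
    labeled, n = ndimage.label(hu >= params.lower_threshold, structure=structure)
    if n == 0:
        return []
    vox_ul = volume.voxel_volume_ul
    counts = np.bincount(labeled.ravel())
    out: list[SegmentedMarker] = []
    slices = ndimage.find_objects(labeled)
    for comp_id in range(1, n + 1):
        vol_ul = counts[comp_id] * vox_ul
        if vol_ul < min_volume_ul:
            continue
        if max_volume_ul is not None and vol_ul > max_volume_ul:
            continue
        sl = slices[comp_id - 1]
        comp = labeled[sl] == comp_id
        idx = np.argwhere(comp) + np.array([s.start for s in sl])
        centroid = tuple(((idx.mean(axis=0) + 0.5) * np.asarray(volume.spacing)).tolist())
        out.append(
            SegmentedMarker(
                voxel_indices=idx,
                volume_ul=vol_ul,
                centroid_mm=centroid,
                seed_point_mm=None,
                peak_hu=float(hu[sl][comp].max()),
            )
        )
    out.sort(key=lambda m: -m.volume_ul)
    return out
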