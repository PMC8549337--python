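"""Synthetic CT phantoms of injectable liquid fiducial markers.

The scenes emulate an ex-vivo mandible preparation used to characterise
iodinated liquid markers (SAIB/x-SAIB type): a slab of cortical bone with
embedded teeth, a flat soft-tissue surface into which markers of nominal
volume 10/20/30 µl are injected 1--2 mm deep on a regular grid, and a
muscle flap covering the surface, as after reconstructive surgery.
Hyperdense non-iodine confounders (titanium clips, calcifications) can be
added for the clinical-simulation and dual-energy workflows.

The forward model is deliberately simple: per-material HU lookup at the
tube voltage, plus a linear iodine term (HU per mg/ml, decreasing with kV
to model the loss of iodine contrast away from the k-edge), followed by an
isotropic Gaussian point-spread function and additive Gaussian noise.
Partial-volume blooming from the PSF is the mechanism that makes segmented
marker volumes several-fold larger than the injected volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "MaterialSpec",
    "MarkerSpec",
    "ConfounderSpec",
    "SceneConfig",
    "PhantomScene",
    "AcquisitionProtocol",
    "CTVolume",
    "SceneError",
    "MATERIALS",
    "DEFAULT_HU_TABLE",
    "IODINE_HU_PER_MG_ML",
    "DEFAULT_IODINE_MG_ML",
    "build_scene",
    "acquire_ct",
    "acquire_dect",
    "default_protocol",
    "default_single_energy_protocols",
    "default_dect_protocols",
]

# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

#: Material label codes, index = integer stored in ``PhantomScene.label_grid``.
MATERIALS = (
    "air",
    "soft_tissue",
    "muscle_flap",
    "bone",
    "tooth",
    "titanium_clip",
    "calcification",
)

_KVS = (70, 80, 100, 120, 150)

#: Baseline attenuation (HU) per material and tube voltage.  150 stands for
#: the tin-filtered 150Sn spectrum of the dual-energy B-tube.  Values are
#: physics-plausible rather than scanner-calibrated: air at -1000, water-like
#: soft tissue near 50 HU with negligible spectral dependence, dense bone and
#: enamel strongly kV-dependent, titanium effectively saturated at all
#: energies, calcification hyperdense with a spectral slope much shallower
#: than iodine's (which is what lets a two-material decomposition keep it in
#: the virtual non-contrast image).
DEFAULT_HU_TABLE: dict[str, dict[int, float]] = {
    "air": {kv: -1000.0 for kv in _KVS},
    "soft_tissue": {kv: 50.0 for kv in _KVS},
    "muscle_flap": {kv: 55.0 for kv in _KVS},
    "bone": {70: 1200.0, 80: 1100.0, 100: 900.0, 120: 800.0, 150: 700.0},
    "tooth": {70: 1900.0, 80: 1800.0, 100: 1600.0, 120: 1500.0, 150: 1400.0},
    "titanium_clip": {kv: 3000.0 for kv in _KVS},
    "calcification": {70: 700.0, 80: 650.0, 100: 600.0, 120: 575.0, 150: 550.0},
}

#: Iodine contrast (HU per mg/ml) by tube voltage; strictly decreasing with
#: kV, modelling the k-edge proximity of low-kV spectra.
IODINE_HU_PER_MG_ML: dict[int, float] = {70: 38.0, 80: 34.0, 100: 26.0, 120: 22.0, 150: 12.0}

#: Default marker iodine concentration (mg/ml equivalent).  The iodinated
#: marker is extremely radiodense; its interior must carry contrast in the
#: thousands of HU for the above-threshold volume (bounded by iodine mass
#: divided by threshold contrast) to reach the observed several-fold
#: blooming ratios.  100 mg/ml gives a noise-free plateau of 50 + 2200 HU
#: at 120 kV, far above the 140 HU threshold at every clinical kV.
DEFAULT_IODINE_MG_ML = 100.0


class SceneError(ValueError):
    """Raised for invalid scene configurations (overlap, out-of-grid, ...)."""


@dataclass(frozen=True)
class MaterialSpec:
    """A named material with its per-kV baseline attenuation."""

    name: str
    hu_by_kv: dict[int, float]

    def __post_init__(self) -> None:
        if self.name not in MATERIALS:
            raise ValueError(f"unknown material {self.name!r}")
        for kv, hu in self.hu_by_kv.items():
            if not np.isfinite(hu):
                raise ValueError(f"{self.name}: non-finite HU at {kv} kV")
        if self.name == "air" and any(hu > -900 for hu in self.hu_by_kv.values()):
            raise ValueError("air must be <= -900 HU at all kV")


def default_materials() -> list[MaterialSpec]:
    return [MaterialSpec(name, dict(DEFAULT_HU_TABLE[name])) for name in MATERIALS]


def _hu_lookup_vector(kv: int) -> np.ndarray:
    """HU per material label code at a given tube voltage."""
    try:
        return np.array([DEFAULT_HU_TABLE[m][kv] for m in MATERIALS])
    except KeyError as exc:
        raise ValueError(f"no material HU entry for tube voltage {kv} kV") from exc


# ---------------------------------------------------------------------------
# Markers and scenes
# ---------------------------------------------------------------------------


@dataclass
class MarkerSpec:
    """One injected marker.

    ``center_mm`` may be left ``None``, in which case :func:`build_scene`
    places the marker on the regular injection grid.  ``depth_mm`` is the
    depth of the marker's upper pole below the soft-tissue surface (the
    injection technique advances the needle 1--2 mm deep).
    """

    nominal_volume_ul: float
    center_mm: tuple[float, float, float] | None = None
    shape: str = "rounded"
    n_lobes: int = 1
    iodine_mg_ml: float = DEFAULT_IODINE_MG_ML
    depth_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.nominal_volume_ul <= 0:
            raise ValueError("nominal_volume_ul must be positive")
        if self.shape not in ("rounded", "multilobular"):
            raise ValueError(f"unknown marker shape {self.shape!r}")
        if self.shape == "rounded" and self.n_lobes != 1:
            raise ValueError("rounded markers have exactly one lobe")
        if self.shape == "multilobular" and not 2 <= self.n_lobes <= 4:
            raise ValueError("multilobular markers have 2-4 lobes")
        if self.iodine_mg_ml < 0:
            raise ValueError("iodine concentration must be >= 0")

    @property
    def radius_mm(self) -> float:
        """Radius of the volume-equivalent sphere."""
        return float((3.0 * self.nominal_volume_ul / (4.0 * np.pi)) ** (1.0 / 3.0))


def default_marker(volume_ul: float, **kwargs) -> MarkerSpec:
    """Marker with the shape observed for its injection volume.

    10 µl injections form rounded, homogeneous deposits; larger volumes form
    increasingly heterogeneous multilobular ones.
    """
    if volume_ul <= 10:
        shape, lobes = "rounded", 1
    elif volume_ul <= 20:
        shape, lobes = "multilobular", 2
    else:
        shape, lobes = "multilobular", 3
    return MarkerSpec(volume_ul, shape=shape, n_lobes=lobes, **kwargs)


@dataclass
class ConfounderSpec:
    """A non-iodine hyperdense object (titanium clip or calcification)."""

    material: str
    center_mm: tuple[float, float, float]
    volume_ul: float

    def __post_init__(self) -> None:
        if self.material not in ("titanium_clip", "calcification"):
            raise ValueError("confounder material must be titanium_clip or calcification")
        if self.volume_ul <= 0:
            raise ValueError("confounder volume must be positive")


@dataclass
class SceneConfig:
    """Geometry and content of a phantom scene.

    The grid is layered along the third axis: bone (with optional teeth)
    from 0 to ``bone_top_mm``, soft tissue up to ``surface_mm``, muscle flap
    up to ``flap_top_mm``, air above.  Setting ``bone_top_mm`` to 0 yields a
    pure soft-tissue bed (used for the clinical flap scenes).
    """

    shape: tuple[int, int, int] = (100, 100, 48)
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.6)
    bone_top_mm: float = 6.0
    surface_mm: float = 20.0
    flap_top_mm: float = 26.0
    include_teeth: bool = True
    marker_pitch_mm: float = 12.0
    markers: list[MarkerSpec] = field(default_factory=list)
    confounders: list[ConfounderSpec] = field(default_factory=list)
    #: lognormal sigma of the per-marker effective iodine concentration,
    #: emulating variable spread/dilution of the low-viscosity liquid on
    #: injection (the dominant source of volumetric variance); the deposit
    #: geometry itself stays at the nominal volume
    concentration_jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise SceneError("spacing components must be positive")
        if not 0 <= self.bone_top_mm <= self.surface_mm <= self.flap_top_mm:
            raise SceneError("layer boundaries must satisfy bone <= surface <= flap")


@dataclass
class PhantomScene:
    """Material labels plus iodine concentration field of one scene."""

    label_grid: np.ndarray  # int8, codes into MATERIALS
    iodine_grid: np.ndarray  # mg/ml, > 0 only inside marker voxels
    spacing: tuple[float, float, float]
    markers: list[MarkerSpec]
    confounders: list[ConfounderSpec]
    config: SceneConfig

    @property
    def voxel_volume_ul(self) -> float:
        # 1 mm^3 of voxel space is exactly 1 µl
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def material_mask(self, name: str) -> np.ndarray:
        return self.label_grid == MATERIALS.index(name)


def _voxel_centers(shape: tuple[int, int, int], spacing: Sequence[float]):
    """World-coordinate voxel centers per axis (mm from the origin corner)."""
    return [
        (np.arange(n) + 0.5) * d for n, d in zip(shape, spacing)
    ]


def _rasterize_blob(
    centers: np.ndarray,
    radii: np.ndarray,
    n_target: int,
    shape: tuple[int, int, int],
    spacing: Sequence[float],
) -> np.ndarray:
    """Rasterize a union-of-balls blob as exactly ``n_target`` voxels.

    Voxels are ranked by the normalized distance min_l |x - c_l| / r_l and
    the ``n_target`` nearest are taken, so the voxel-count volume matches
    the nominal volume to within half a voxel regardless of resolution.
    Returns an (n, 3) array of voxel indices.

    Raises :class:`SceneError` if the blob would extend outside the grid.
    """
    spacing = np.asarray(spacing, float)
    pad = 2.0 * float(radii.max())
    lo_mm = centers.min(axis=0) - pad
    hi_mm = centers.max(axis=0) + pad
    lo = np.floor(lo_mm / spacing).astype(int)
    hi = np.ceil(hi_mm / spacing).astype(int)
    if np.any(lo < 0) or np.any(hi > np.asarray(shape)):
        raise SceneError("marker or confounder extends outside the grid")
    axes = [
        (np.arange(l, h) + 0.5) * d for l, h, d in zip(lo, hi, spacing)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d = np.full(xx.shape, np.inf)
    for c, r in zip(centers, radii):
        dist = np.sqrt((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2) / r
        np.minimum(d, dist, out=d)
    flat = d.ravel()
    if n_target > flat.size:
        raise SceneError("marker or confounder extends outside the grid")
    order = np.argpartition(flat, n_target - 1)[:n_target]
    # deterministic tie-break at the boundary shell
    order = order[np.lexsort((order, flat[order]))]
    idx = np.stack(np.unravel_index(order, d.shape), axis=1) + lo
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        raise SceneError("marker or confounder extends outside the grid")
    return idx


def _marker_voxels(
    marker: MarkerSpec,
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    vox_ul = float(np.prod(spacing))
    n_target = max(1, int(round(marker.nominal_volume_ul / vox_ul)))
    r = marker.radius_mm
    c = np.asarray(marker.center_mm, float)
    if marker.shape == "rounded":
        centers = c[None, :]
        radii = np.array([r])
    else:
        k = marker.n_lobes
        offsets = rng.uniform(-1.0, 1.0, size=(k, 3))
        norms = np.linalg.norm(offsets, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        offsets = offsets / norms * rng.uniform(0.2, 0.5, size=(k, 1)) * r
        centers = c[None, :] + offsets
        radii = r * 0.75 * rng.uniform(0.85, 1.15, size=k)
    return _rasterize_blob(centers, radii, n_target, shape, spacing)


def _grid_positions(n: int, config: SceneConfig) -> list[tuple[float, float]]:
    """In-plane injection-grid positions (consistent pattern, uniform pitch)."""
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    ext_x = config.shape[0] * config.spacing[0]
    ext_y = config.shape[1] * config.spacing[1]
    pitch = config.marker_pitch_mm
    x0 = (ext_x - (cols - 1) * pitch) / 2.0
    y0 = (ext_y - (rows - 1) * pitch) / 2.0
    pos = []
    for i in range(n):
        rr, cc = divmod(i, cols)
        pos.append((x0 + cc * pitch, y0 + rr * pitch))
    return pos


def build_scene(config: SceneConfig) -> PhantomScene:
    """Build a layered phantom scene with injected markers and confounders.

    Markers without explicit centers are placed on a regular grid at their
    configured depth below the soft-tissue surface; the surface is covered
    by a muscle-flap layer.  Rasterized marker volumes match the nominal
    injection volume to within half a voxel (well inside 5%).
    """
    shape = tuple(config.shape)
    spacing = tuple(config.spacing)
    dz = spacing[2]
    labels = np.full(shape, MATERIALS.index("air"), dtype=np.int8)
    zc = (np.arange(shape[2]) + 0.5) * dz
    labels[:, :, zc < config.flap_top_mm] = MATERIALS.index("muscle_flap")
    labels[:, :, zc < config.surface_mm] = MATERIALS.index("soft_tissue")
    labels[:, :, zc < config.bone_top_mm] = MATERIALS.index("bone")

    if config.include_teeth and config.bone_top_mm > 0:
        # two enamel blocks embedded in the bone slab
        xc = (np.arange(shape[0]) + 0.5) * spacing[0]
        yc = (np.arange(shape[1]) + 0.5) * spacing[1]
        for x_lo, y_lo in ((2.0, 2.0), (shape[0] * spacing[0] - 8.0, 2.0)):
            xm = (xc >= x_lo) & (xc < x_lo + 6.0)
            ym = (yc >= y_lo) & (yc < y_lo + 6.0)
            zm = zc < config.bone_top_mm
            labels[np.ix_(xm, ym, zm)] = MATERIALS.index("tooth")

    # resolve marker centers
    markers: list[MarkerSpec] = []
    auto = [m for m in config.markers if m.center_mm is None]
    positions = _grid_positions(len(auto), config) if auto else []
    it = iter(positions)
    for m in config.markers:
        if m.center_mm is None:
            x, y = next(it)
            z = config.surface_mm - m.depth_mm - m.radius_mm
            m = replace(m, center_mm=(x, y, z))
        markers.append(m)

    iodine = np.zeros(shape, dtype=np.float64)
    occupied = np.zeros(shape, dtype=bool)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(max(1, len(markers)))
    resolved: list[MarkerSpec] = []
    for m, child in zip(markers, children):
        rng = np.random.default_rng(child)
        if config.concentration_jitter_sd > 0:
            m = replace(
                m,
                iodine_mg_ml=m.iodine_mg_ml
                * float(np.exp(rng.normal(0.0, config.concentration_jitter_sd))),
            )
        idx = _marker_voxels(m, shape, spacing, rng)
        sel = tuple(idx.T)
        if occupied[sel].any():
            raise SceneError("overlapping markers in scene configuration")
        occupied[sel] = True
        iodine[sel] = m.iodine_mg_ml
        resolved.append(m)
    markers = resolved

    for conf in config.confounders:
        vox_ul = float(np.prod(spacing))
        n_target = max(1, int(round(conf.volume_ul / vox_ul)))
        r = (3.0 * conf.volume_ul / (4.0 * np.pi)) ** (1.0 / 3.0)
        idx = _rasterize_blob(
            np.asarray(conf.center_mm, float)[None, :],
            np.array([r]),
            n_target,
            shape,
            spacing,
        )
        sel = tuple(idx.T)
        if occupied[sel].any():
            raise SceneError("confounder overlaps a marker or another confounder")
        occupied[sel] = True
        labels[sel] = MATERIALS.index(conf.material)

    return PhantomScene(labels, iodine, spacing, markers, list(config.confounders), config)


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Single acquisition: tube voltage, iodine contrast, PSF and noise.

    ``iodine_hu_per_unit`` is HU per mg/ml iodine at this spectrum; across
    the default protocol set it decreases strictly with kV.  ``mas`` is
    metadata only: its effect is folded into ``noise_sd_hu`` (higher dose,
    lower noise).  The PSF full-width-at-half-maximum subsumes the scanner's
    reconstruction kernel.
    """

    kv: int
    mas: float
    iodine_hu_per_unit: float
    psf_fwhm_mm: float = 2.0
    noise_sd_hu: float = 5.0
    slice_thickness_mm: float = 0.6
    tin_filter: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd_hu < 0 or self.psf_fwhm_mm < 0:
            raise ValueError("noise_sd_hu and psf_fwhm_mm must be >= 0")


#: (mAs, noise sd) presets coupled to kV as on the clinical scanner:
#: lower kV is run at higher dose, keeping noise in check.
_SINGLE_ENERGY_PRESETS = {70: (500.0, 4.0), 100: (200.0, 6.0), 120: (120.0, 8.0)}


def default_protocol(kv: int) -> AcquisitionProtocol:
    """Default single-energy protocol at 70, 100 or 120 kV."""
    if kv not in _SINGLE_ENERGY_PRESETS:
        raise ValueError(f"no default single-energy protocol at {kv} kV")
    mas, sd = _SINGLE_ENERGY_PRESETS[kv]
    return AcquisitionProtocol(kv, mas, IODINE_HU_PER_MG_ML[kv], noise_sd_hu=sd)


def default_single_energy_protocols() -> dict[int, AcquisitionProtocol]:
    return {kv: default_protocol(kv) for kv in (70, 100, 120)}


def default_dect_protocols() -> tuple[AcquisitionProtocol, AcquisitionProtocol]:
    """Dual-energy pair: 80 kV A-tube and tin-filtered 150 kV B-tube."""
    a = AcquisitionProtocol(80, 250.0, IODINE_HU_PER_MG_ML[80], noise_sd_hu=5.0)
    b = AcquisitionProtocol(
        150, 120.0, IODINE_HU_PER_MG_ML[150], noise_sd_hu=5.0, tin_filter=True
    )
    return a, b


@dataclass
class CTVolume:
    """A reconstructed 3D HU grid with voxel spacing and acquisition metadata."""

    hu_grid: np.ndarray
    spacing: tuple[float, float, float]
    protocol: AcquisitionProtocol | None = None
    seed: int | None = None

    @property
    def voxel_volume_ul(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


def _psf_sigma_vox(fwhm_mm: float, spacing: Sequence[float]) -> list[float]:
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return [sigma_mm / d for d in spacing]


def acquire_ct(scene: PhantomScene, protocol: AcquisitionProtocol, seed: int) -> CTVolume:
    """Simulate one CT acquisition of a scene.

    HU = blur(material HU at kV + iodine * contrast, PSF) + N(0, noise sd).
    Bit-identical for identical (scene, protocol, seed).
    """
    table = _hu_lookup_vector(protocol.kv)
    hu = table[scene.label_grid] + scene.iodine_grid * protocol.iodine_hu_per_unit
    if protocol.psf_fwhm_mm > 0:
        hu = gaussian_filter(hu, _psf_sigma_vox(protocol.psf_fwhm_mm, scene.spacing))
    if protocol.noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, protocol.noise_sd_hu, size=hu.shape)
    return CTVolume(hu, scene.spacing, protocol, seed)


def acquire_dect(
    scene: PhantomScene,
    protocol_a: AcquisitionProtocol,
    protocol_b: AcquisitionProtocol,
    seed: int,
) -> tuple[CTVolume, CTVolume]:
    """Simulate a dual-energy acquisition (two co-registered volumes).

    The A-tube runs at the lower voltage and must have strictly higher
    iodine contrast than the B-tube.  Noise streams of the two tubes are
    independent but both derived deterministically from ``seed``.
    """
    if protocol_a.kv >= protocol_b.kv:
        raise ValueError("A-tube voltage must be below the B-tube voltage")
    if protocol_a.iodine_hu_per_unit <= protocol_b.iodine_hu_per_unit:
        raise ValueError("A-tube iodine contrast must exceed the B-tube's")
    child_a, child_b = np.random.SeedSequence(seed).spawn(2)
    seed_a = int(child_a.generate_state(1)[0] % (2**31))
    seed_b = int(child_b.generate_state(1)[0] % (2**31))
    vol_a = acquire_ct(scene, protocol_a, seed_a)
    vol_b = acquire_ct(scene, protocol_b, seed_b)
    return vol_a, vol_b
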