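"""End-to-end replication pipelines.

Two workflows:

* ``run_preclinical`` — the ex-vivo design: 25 injections each of 10, 20
  and 30 µl distributed over 9 mandible-segment scenes (8 or 9 markers per
  segment), each scene acquired at 70, 100 and 120 kV, every marker
  segmented from its known injection site, per-group summaries, pairwise
  kV comparisons and the 10-vs-30 µl discriminability decision per kV.
* ``run_clinical_sim`` — the clinical setting: many small markers injected
  at a flap reconstruction surface, a Bernoulli per-marker loss process
  (flap manipulation or injection failure), unseeded detection, and in
  dual-energy mode VNC-based classification against clip/calcification
  confounders.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discriminability import DiscriminabilityResult, assess
from .dual_energy import (
    DectImages,
    ObjectClassification,
    classify_hyperdense,
    make_dect_images,
)
from .phantom import (
    ConfounderSpec,
    SceneConfig,
    acquire_ct,
    acquire_dect,
    build_scene,
    default_dect_protocols,
    default_marker,
    default_protocol,
)
from .segmentation import SegmentationParams, detect_markers, segment_marker
from .stats import (
    PairwiseResult,
    VolumeSample,
    VolumeSummary,
    all_pairwise,
    summarize,
    summary_table,
)

__all__ = [
    "ExperimentConfig",
    "ClinicalConfig",
    "RunReport",
    "ClinicalReport",
    "run_preclinical",
    "run_clinical_sim",
    "visibility_replicates",
    "visibility_percent",
]


def visibility_percent(n_detected: int, n_injected: int) -> int:
    """Visibility as a whole-number percentage of injected markers."""
    if n_injected <= 0:
        raise ValueError("n_injected must be positive")
    return int(round(100.0 * n_detected / n_injected))


# ---------------------------------------------------------------------------
# Preclinical replication
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Design of the preclinical experiment."""

    n_segments: int = 9
    injections_per_volume: int = 25
    volumes_ul: tuple[float, ...] = (10.0, 20.0, 30.0)
    kv_list: tuple[int, ...] = (70, 100, 120)
    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    marker_pitch_mm: float = 12.0

    @property
    def n_markers(self) -> int:
        return self.injections_per_volume * len(self.volumes_ul)

    @property
    def n_measurements(self) -> int:
        return self.n_markers * len(self.kv_list)

    def validate(self) -> None:
        if self.n_segments <= 0 or self.injections_per_volume <= 0:
            raise ValueError("n_segments and injections_per_volume must be positive")
        if not self.volumes_ul or not self.kv_list:
            raise ValueError("volumes_ul and kv_list must be nonempty")
        if len(set(self.volumes_ul)) != len(self.volumes_ul):
            raise ValueError("volumes_ul must be distinct")
        if self.n_markers < self.n_segments:
            raise ValueError("fewer markers than segments")


@dataclass
class RunReport:
    """Everything the preclinical replication produces."""

    config: ExperimentConfig
    samples: dict[tuple[float, int], VolumeSample]
    summaries: dict[tuple[float, int], VolumeSummary]
    summary_table: pd.DataFrame
    pairwise: list[PairwiseResult]
    discriminability: dict[int, DiscriminabilityResult]
    visibility: tuple[int, int, int]  # (n_injected, n_detected, percent)
    markers_table: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write the report as CSV/JSON files (byte-stable for a fixed seed)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary_table.to_csv(outdir / "summary.csv", index=False, float_format="%.4f")
        self.markers_table.to_csv(outdir / "markers.csv", index=False, float_format="%.6f")
        pairwise = [
            {
                "injected_ul": r.injected_volume_ul,
                "kv_a": r.kv_a,
                "kv_b": r.kv_b,
                "statistic": round(r.statistic, 6),
                "pvalue": float(f"{r.pvalue:.6g}"),
                "method": r.method,
            }
            for r in self.pairwise
        ]
        (outdir / "pairwise.json").write_text(json.dumps(pairwise, indent=2) + "\n")
        disc = {
            str(kv): {
                "delta_ul": round(d.delta_ul, 4),
                "border_ul": round(d.border_ul, 4),
                "separation_probability": round(d.separation_probability, 6),
                "prob_above_border": round(d.prob_above_border, 6),
                "reliable": d.reliable,
            }
            for kv, d in sorted(self.discriminability.items())
        }
        (outdir / "discriminability.json").write_text(json.dumps(disc, indent=2) + "\n")
        n_inj, n_det, pct = self.visibility
        (outdir / "visibility.json").write_text(
            json.dumps({"n_injected": n_inj, "n_detected": n_det, "percent": pct}, indent=2)
            + "\n"
        )


def _segment_assignments(config: ExperimentConfig) -> list[list[tuple[str, float]]]:
    """Distribute (marker id, volume) over segments, 8-9 per segment.

    Volumes are interleaved so every segment receives a balanced mix, and
    markers are dealt round-robin, giving floor/ceil(total/segments) per
    segment.
    """
    deck: list[tuple[str, float]] = []
    for i in range(config.injections_per_volume):
        for v in config.volumes_ul:
            deck.append((f"v{v:g}_i{i:02d}", v))
    segments: list[list[tuple[str, float]]] = [[] for _ in range(config.n_segments)]
    for j, item in enumerate(deck):
        segments[j % config.n_segments].append(item)
    return segments


def run_preclinical(config: ExperimentConfig | None = None) -> RunReport:
    """Run the full preclinical replication.

    Builds one scene per segment, acquires it at every configured kV with
    the default kV-coupled protocols, segments each marker from its known
    injection site, and aggregates summaries, pairwise kV tests and the
    small-vs-large discriminability decision.
    """
    if config is None:
        config = ExperimentConfig()
    config.validate()

    ss = np.random.SeedSequence(config.seed)
    seg_assign = _segment_assignments(config)
    scene_seeds = ss.spawn(config.n_segments)
    noise_root = ss.spawn(1)[0]
    noise_seeds = noise_root.spawn(config.n_segments * len(config.kv_list))

    records: list[dict] = []
    n_visible = 0
    for seg_i, assignment in enumerate(seg_assign):
        markers = [default_marker(v) for (_mid, v) in assignment]
        scene_cfg = SceneConfig(
            markers=markers,
            marker_pitch_mm=config.marker_pitch_mm,
            seed=int(scene_seeds[seg_i].generate_state(1)[0] % (2**31)),
        )
        scene = build_scene(scene_cfg)
        for kv_i, kv in enumerate(config.kv_list):
            protocol = default_protocol(kv)
            nseed = int(
                noise_seeds[seg_i * len(config.kv_list) + kv_i].generate_state(1)[0]
                % (2**31)
            )
            volume = acquire_ct(scene, protocol, nseed)
            for (mid, vol_ul), marker in zip(assignment, scene.markers):
                seg = segment_marker(volume, marker.center_mm, config.segmentation)
                n_visible += int(seg.visible)
                records.append(
                    {
                        "marker_id": mid,
                        "segment": seg_i,
                        "injected_ul": vol_ul,
                        "kv": kv,
                        "volume_ul": seg.volume_ul,
                        "peak_hu": seg.peak_hu,
                        "visible": seg.visible,
                    }
                )

    markers_table = pd.DataFrame(records).sort_values(
        ["injected_ul", "kv", "marker_id"], kind="stable"
    )
    samples: dict[tuple[float, int], VolumeSample] = {}
    for (vol, kv), grp in markers_table.groupby(["injected_ul", "kv"], sort=True):
        grp = grp.sort_values("marker_id", kind="stable")
        samples[(float(vol), int(kv))] = VolumeSample(
            float(vol), int(kv), grp["volume_ul"].to_numpy(), grp["marker_id"].tolist()
        )
    summaries = {key: summarize(s) for key, s in samples.items()}
    pairwise = all_pairwise(samples.values(), paired=True) if len(config.kv_list) > 1 else []

    discriminability: dict[int, DiscriminabilityResult] = {}
    if len(config.volumes_ul) >= 2:
        v_small, v_large = min(config.volumes_ul), max(config.volumes_ul)
        for kv in config.kv_list:
            discriminability[kv] = assess(
                samples[(v_small, kv)],
                samples[(v_large, kv)],
                summaries[(v_small, kv)],
                summaries[(v_large, kv)],
            )

    n_injected = config.n_measurements
    return RunReport(
        config=config,
        samples=samples,
        summaries=summaries,
        summary_table=summary_table(summaries.values()),
        pairwise=pairwise,
        discriminability=discriminability,
        visibility=(n_injected, n_visible, visibility_percent(n_visible, n_injected)),
        markers_table=markers_table,
    )


# ---------------------------------------------------------------------------
# Clinical simulation
# ---------------------------------------------------------------------------


@dataclass
class ClinicalConfig:
    """Design of the clinical-simulation run.

    ``n_by_volume`` gives marker counts per injected volume (default: the
    single-energy patient's 64 x 10 µl + 2 x 30 µl).  Each marker fails
    independently with ``failure_probability`` (manipulation at the
    resection surface, injection failure); failed injections deposit no
    marker.  The scene has no mandible bone: markers sit in the soft
    tissue under the reconstructed flap.
    """

    n_by_volume: dict[float, int] = field(default_factory=lambda: {10.0: 64, 30.0: 2})
    failure_probability: float = 0.15
    kv: int = 100
    dual_energy: bool = False
    n_confounders: int = 0
    seed: int = 0
    marker_pitch_mm: float = 10.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    min_detect_volume_ul: float = 2.0

    @property
    def n_markers(self) -> int:
        return sum(self.n_by_volume.values())

    def validate(self) -> None:
        if not 0.0 <= self.failure_probability <= 1.0:
            raise ValueError("failure probability must be in [0, 1]")
        if self.n_markers <= 0:
            raise ValueError("at least one marker must be injected")
        if self.n_confounders < 0:
            raise ValueError("n_confounders must be >= 0")


@dataclass
class ClinicalReport:
    """Per-marker accounting of one clinical simulation."""

    config: ClinicalConfig
    marker_status: pd.DataFrame  # marker_id, injected_ul, survived, detected
    n_injected: int
    n_detected: int
    percent: int
    classifications: list[ObjectClassification]
    dect: DectImages | None


def _clinical_scene_config(config: ClinicalConfig, survived: np.ndarray):
    """Scene config with surviving markers and confounders laid out."""
    volumes: list[float] = []
    ids: list[str] = []
    for v, n in sorted(config.n_by_volume.items()):
        for i in range(n):
            volumes.append(v)
            ids.append(f"v{v:g}_i{i:02d}")
    n = len(volumes)
    pitch = config.marker_pitch_mm
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    conf_rows = int(np.ceil(config.n_confounders / cols)) if config.n_confounders else 0
    margin = 8.0
    ext_x = (cols - 1) * pitch + 2 * margin
    ext_y = (rows + conf_rows - 1) * pitch + 2 * margin
    spacing = (0.4, 0.4, 0.6)
    shape = (int(np.ceil(ext_x / spacing[0])), int(np.ceil(ext_y / spacing[1])), 40)
    surface = 14.0

    markers = []
    positions = []
    for i, v in enumerate(volumes):
        rr, cc = divmod(i, cols)
        x = margin + cc * pitch
        y = margin + rr * pitch
        m = default_marker(v)
        z = surface - m.depth_mm - m.radius_mm
        positions.append((x, y, z))
        if survived[i]:
            markers.append(default_marker(v, center_mm=(x, y, z)))

    confounders = []
    for j in range(config.n_confounders):
        rr, cc = divmod(j, cols)
        x = margin + cc * pitch
        y = margin + (rows + rr) * pitch
        material = "titanium_clip" if j % 2 == 0 else "calcification"
        confounders.append(ConfounderSpec(material, (x, y, surface - 4.0), 15.0))

    scene_cfg = SceneConfig(
        shape=shape,
        spacing=spacing,
        bone_top_mm=0.0,
        surface_mm=surface,
        flap_top_mm=surface + 6.0,
        include_teeth=False,
        marker_pitch_mm=pitch,
        markers=markers,
        confounders=confounders,
        seed=config.seed,
    )
    return scene_cfg, ids, volumes, positions


def run_clinical_sim(config: ClinicalConfig | None = None) -> ClinicalReport:
    """Simulate one clinical marking + postoperative CT reading.

    Injects the configured markers, ablates each independently with the
    failure probability, images the scene (single-energy at ``config.kv``
    or dual-energy 80/150Sn), detects hyperdense objects without seeds,
    and matches detections to the known injection sites.  Every injected
    marker is accounted for exactly once as detected or not detected.  In
    dual-energy mode each detection is also classified via VNC retention.
    """
    if config is None:
        config = ClinicalConfig()
    config.validate()

    ss = np.random.SeedSequence(config.seed)
    ablate_child, image_child = ss.spawn(2)
    rng = np.random.default_rng(ablate_child)
    n = config.n_markers
    survived = rng.random(n) >= config.failure_probability

    scene_cfg, ids, volumes, positions = _clinical_scene_config(config, survived)
    scene = build_scene(scene_cfg)
    image_seed = int(image_child.generate_state(1)[0] % (2**31))

    dect: DectImages | None = None
    if config.dual_energy:
        pa, pb = default_dect_protocols()
        vol_a, vol_b = acquire_dect(scene, pa, pb, image_seed)
        dect = make_dect_images(vol_a, vol_b)
        read_volume = dect.mixed_volume()
    else:
        read_volume = acquire_ct(scene, default_protocol(config.kv), image_seed)

    detections = detect_markers(
        read_volume, config.segmentation, min_volume_ul=config.min_detect_volume_ul
    )

    # match detections to injection sites (nearest site within half a pitch)
    match_radius = config.marker_pitch_mm / 2.0
    sites = np.asarray(positions)
    detected = np.zeros(n, dtype=bool)
    marker_detections = []
    for det in detections:
        c = np.asarray(det.centroid_mm)
        d = np.linalg.norm(sites - c[None, :], axis=1)
        i = int(np.argmin(d))
        if d[i] <= match_radius and not detected[i]:
            detected[i] = True
            det.label = ids[i]
            marker_detections.append(det)

    classifications: list[ObjectClassification] = []
    if config.dual_energy and dect is not None and detections:
        classifications = classify_hyperdense(dect, detections)

    status = pd.DataFrame(
        {
            "marker_id": ids,
            "injected_ul": volumes,
            "survived": survived,
            "detected": detected,
        }
    )
    n_detected = int(detected.sum())
    return ClinicalReport(
        config=config,
        marker_status=status,
        n_injected=n,
        n_detected=n_detected,
        percent=visibility_percent(n_detected, n),
        classifications=classifications,
        dect=dect,
    )


def visibility_replicates(
    n_markers: int, failure_probability: float, n_replicates: int, seed: int
) -> np.ndarray:
    """Monte-Carlo replicates of the visibility percentage.

    Marker loss is the only random mechanism of the clinical detection
    model (a surviving marker is always detected, which the imaging path
    verifies at zero failure probability), so replicates are drawn at the
    Bernoulli level: per replicate, each of ``n_markers`` markers survives
    with probability 1 − failure_probability and the visibility percentage
    is recorded.
    """
    if not 0.0 <= failure_probability <= 1.0:
        raise ValueError("failure probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    detected = rng.binomial(n_markers, 1.0 - failure_probability, size=n_replicates)
    return np.round(100.0 * detected / n_markers)
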