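"""Readers and writers: NIfTI volumes, YAML/JSON configs, CSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import (
    AcquisitionProtocol,
    ConfounderSpec,
    CTVolume,
    MarkerSpec,
    SceneConfig,
    default_marker,
)
from .segmentation import SegmentedMarker

__all__ = [
    "save_volume",
    "load_volume",
    "load_scene_config",
    "load_seed_points",
    "write_markers_csv",
    "read_markers_csv",
]


def save_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a CT volume as NIfTI-1 with spacing in the header."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.hu_grid, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_volume(path: str | Path, protocol: AcquisitionProtocol | None = None) -> CTVolume:
    """Read a NIfTI-1 volume; spacing comes from the header zooms."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(np.asarray(img.get_fdata(), dtype=np.float64), spacing, protocol)


def _marker_from_dict(d: dict) -> MarkerSpec:
    d = dict(d)
    volume = float(d.pop("volume_ul"))
    center = d.pop("center_mm", None)
    if center is not None:
        center = tuple(float(c) for c in center)
    if "shape" in d or "n_lobes" in d:
        return MarkerSpec(
            volume,
            center_mm=center,
            shape=d.get("shape", "rounded"),
            n_lobes=int(d.get("n_lobes", 1)),
            iodine_mg_ml=float(d.get("iodine_mg_ml", MarkerSpec(volume).iodine_mg_ml)),
            depth_mm=float(d.get("depth_mm", 1.5)),
        )
    kwargs = {}
    if "iodine_mg_ml" in d:
        kwargs["iodine_mg_ml"] = float(d["iodine_mg_ml"])
    if "depth_mm" in d:
        kwargs["depth_mm"] = float(d["depth_mm"])
    return default_marker(volume, center_mm=center, **kwargs)


def load_scene_config(path: str | Path) -> SceneConfig:
    """Load a scene configuration from YAML (or JSON, a YAML subset).

    ``seed`` is a required key; markers are given as a list of mappings
    with at least ``volume_ul``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("scene configuration must set an RNG 'seed'")
    markers = [_marker_from_dict(m) for m in raw.get("markers", [])]
    confounders = [
        ConfounderSpec(c["material"], tuple(float(x) for x in c["center_mm"]), float(c["volume_ul"]))
        for c in raw.get("confounders", [])
    ]
    kwargs = {
        k: raw[k]
        for k in (
            "bone_top_mm",
            "surface_mm",
            "flap_top_mm",
            "include_teeth",
            "marker_pitch_mm",
        )
        if k in raw
    }
    if "shape" in raw:
        kwargs["shape"] = tuple(int(n) for n in raw["shape"])
    if "spacing" in raw:
        kwargs["spacing"] = tuple(float(s) for s in raw["spacing"])
    return SceneConfig(markers=markers, confounders=confounders, seed=int(raw["seed"]), **kwargs)


def load_seed_points(path: str | Path) -> list[tuple[str, tuple[float, float, float]]]:
    """Read seed points from CSV with columns x_mm, y_mm, z_mm[, label]."""
    df = pd.read_csv(path)
    labels = df["label"] if "label" in df else [f"m{i:03d}" for i in range(len(df))]
    return [
        (str(lab), (float(r.x_mm), float(r.y_mm), float(r.z_mm)))
        for lab, (_, r) in zip(labels, df.iterrows())
    ]


def write_markers_csv(markers: list[SegmentedMarker], path: str | Path) -> None:
    """Write a per-marker volumetry table."""
    rows = []
    for i, m in enumerate(markers):
        cx, cy, cz = m.centroid_mm if m.centroid_mm is not None else (np.nan,) * 3
        rows.append(
            {
                "label": m.label or f"m{i:03d}",
                "visible": m.visible,
                "volume_ul": m.volume_ul,
                "centroid_x_mm": cx,
                "centroid_y_mm": cy,
                "centroid_z_mm": cz,
                "peak_hu": m.peak_hu if np.isfinite(m.peak_hu) else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_markers_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-marker volumes table (marker_id, injected_ul, kv, volume_ul)."""
    df = pd.read_csv(path)
    required = {"marker_id", "injected_ul", "kv", "volume_ul"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"markers CSV missing columns: {sorted(missing)}")
    return df
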