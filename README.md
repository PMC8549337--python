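# fidct

Simulation and volumetry of low-dose injectable liquid fiducial markers in
head-and-neck CT.

Intraoperatively injected iodinated liquid markers (SAIB/x-SAIB type,
10–30 µl per deposit) mark soft-tissue tumor resection surfaces so the
tumor bed can be delineated in postoperative CT for radiotherapy planning.
Their apparent size in CT depends strongly on the tube voltage: iodine
contrast falls as kV rises away from the iodine k-edge, and partial-volume
blooming makes the segmented volume several-fold larger than the injected
volume. This package is for imaging scientists and medical physicists who
want to study, quantitatively and reproducibly, (i) how visible and how
large such markers appear at clinical kV settings, (ii) whether two
injection volumes can be told apart from the segmented volumes, and (iii)
how dual-energy CT separates iodine markers from other hyperdense objects
(titanium clips, calcifications).

## What it computes

* **Phantom simulation** — layered soft-tissue/bone/tooth scenes with
  injected markers (rounded 10 µl deposits, multilobular 20–30 µl ones)
  and a muscle-flap cover; the forward model is a per-material HU lookup
  at the tube voltage plus a linear iodine term `HU = HU_mat(kV) + c·k(kV)`,
  an isotropic Gaussian PSF, and additive Gaussian noise coupled to the
  kV-specific mAs preset.
* **Threshold segmentation** — the two-step procedure: a lower window
  level excluding soft tissue (140 HU by default), then the 26-connected
  component of voxels ≥ threshold inside a spherical ROI around a seed.
  Volume in µl is the voxel count × voxel volume (1 mm³ ≡ 1 µl).
* **Group statistics** — per (injected volume, kV): mean, sample SD, the
  norm interval `mean ± 1.96·SD`, the segmented/injected ratio, and paired
  t-tests across kV settings.
* **Discriminability** — for small (10 µl) vs large (30 µl) groups:
  the gap `Δ = min(large) − max(small)`, the border line
  `lower norm limit(large) − Δ/2`, and the normal-model separation
  probability `Φ((border − mean_small)/sd_small)`; differentiation is
  reliable when this exceeds 95%.
* **Dual energy** — 80 kV / tin-filtered 150 kV acquisition, mixed image
  (0.6 A-tube weight), two-material decomposition into a virtual
  non-contrast (VNC) image and an iodine map, and classification of
  hyperdense objects by VNC retention.

## Worked example

```python
from fidct.pipeline import ExperimentConfig, run_preclinical

report = run_preclinical(ExperimentConfig(seed=7))
print(report.summary_table.to_string(index=False))
for kv, d in sorted(report.discriminability.items()):
    print(f"{kv} kV: delta={d.delta_ul:.1f} ul  border={d.border_ul:.1f} ul  "
          f"P(separation)={d.separation_probability:.4f}  reliable={d.reliable}")
```

prints

```
 injected_ul  kv  n  mean_segmented_ul  sd_segmented_ul  norm_lower_ul  norm_upper_ul  ratio_segmented_to_injected
        10.0  70 25              74.20             9.44          55.70          92.69                          7.4
        10.0 100 25              61.72             9.18          43.73          79.72                          6.2
        10.0 120 25              56.44             9.01          38.78          74.10                          5.6
        20.0  70 25             117.66            12.08          93.98         141.35                          5.9
        20.0 100 25             101.20            11.99          77.71         124.69                          5.1
        20.0 120 25              94.09            11.92          70.73         117.45                          4.7
        30.0  70 25             147.54            17.09         114.04         181.04                          4.9
        30.0 100 25             128.17            16.90          95.04         161.30                          4.3
        30.0 120 25             119.81            16.85          86.78         152.84                          4.0
70 kV: delta=15.9 ul  border=106.1 ul  P(separation)=0.9996  reliable=True
100 kV: delta=10.8 ul  border=89.7 ul  P(separation)=0.9988  reliable=True
120 kV: delta=8.7 ul  border=82.4 ul  P(separation)=0.9980  reliable=True
```

That is the full preclinical design: 25 injections each of 10/20/30 µl
spread over 9 mandible-segment scenes, each scanned at 70/100/120 kV
(225 volume measurements). Segmented volumes are several-fold larger than
injected ones (blooming), shrink as kV rises, and the ratio falls with the
injected volume; 10 vs 30 µl separation is reliable (> 95%) at every kV.

A CLI exposes the same workflows (`fidct simulate | segment | analyze |
dect | replicate-preclinical | replicate-clinical`); volumes are
exchanged as NIfTI-1, configs as YAML, results as CSV/JSON, all
deterministic under a fixed `--seed`.

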