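# Methods

## Forward model

A phantom scene is a pair of co-registered 3D grids: integer material
labels (air, soft tissue, muscle flap, bone, tooth, titanium clip,
calcification) and an iodine concentration field that is nonzero only
inside marker deposits. Acquisition at tube voltage `kV` computes

    HU(x) = G_psf * [ HU_mat(label(x), kV) + c(x) · k(kV) ] + ε,
    ε ~ N(0, σ_noise²),

where `k(kV)` is the iodine contrast in HU per mg/ml and `G_psf` an
isotropic Gaussian kernel. The model is linear and mass-conserving in the
iodine term, which has a useful consequence: the volume of voxels that can
exceed a threshold `t` over a background `b` is bounded by
`∫c·k / (t − b)`. This bound is what forces the marker calibration below.

**Material HU table** (70/80/100/120/150Sn kV): air −1000; soft tissue 50;
muscle flap 55; bone 1200/1100/900/800/700; tooth 1900/1800/1600/1500/1400;
titanium 3000 at all energies; calcification 700/650/600/575/550. Only the
orderings carry meaning (bone > soft tissue, marker plateau > 140 HU, and
the spectral slopes discussed under dual energy); the absolute numbers are
physics-plausible, not scanner-calibrated.

**Iodine contrast** `k(kV)` = 38/34/26/22/12 HU per mg/ml at
70/80/100/120/150Sn kV — strictly decreasing, modelling the loss of
contrast away from the iodine k-edge. This monotonicity is the single
mechanism behind the negative correlation of segmented volumes with kV.

**Marker concentration, default 100 mg/ml.** The iodinated marker is
extremely radiodense. The mass bound above means a blooming ratio near 9
at 70 kV (observed for 10 µl injections) requires interior contrast of at
least ~800 HU; at 100 mg/ml the noise-free plateau is 3850 HU at 70 kV and
2250 HU at 120 kV. Together with the PSF width this was calibrated once,
on noise-free single-marker scenes, to put the blooming ratios in the
observed several-fold range with the observed orderings; it was not tuned
to any test outcome afterwards.

**PSF, default FWHM 2.0 mm (isotropic Gaussian).** Stands in for the
scanner's reconstruction kernel and is the sole mechanism of partial-volume
blooming. Beam hardening and metal/streak artifacts are not modelled; the
volume distortion the model reproduces is therefore purely PSF-driven.

**Noise**, additive Gaussian in HU, coupled to the kV-specific clinical
mAs presets: 4 HU at 70 kV (500 mAs), 6 HU at 100 kV (200 mAs), 8 HU at
120 kV (120 mAs), 5 HU per tube for the dual-energy pair. No dose model —
the coupling only preserves the preset pairing of kV and mAs.

**Geometry.** Voxels default to 0.4 × 0.4 mm in-plane with 0.6 mm slices
(only the slice thickness is constrained by the acquisition protocol; the
in-plane pitch is an assumption and configurable). Layers are stacked
along the slice axis: bone slab with embedded enamel blocks, soft tissue,
muscle-flap cover, air. Markers are placed on a regular grid (12 mm pitch)
with their upper pole 1–2 mm below the soft-tissue surface. 10 µl deposits
are rasterized as spheres; 20/30 µl deposits as unions of 2–3 jittered
ellipsoidal lobes, reproducing the rounded-vs-multilobular morphology and
the higher variance of larger injections. Rasterization ranks voxels by
normalized distance to the lobe set and takes exactly
`round(volume / voxel volume)` of them, so the geometric deposit volume
equals the nominal injection volume to within half a voxel (1 mm³ ≡ 1 µl).

**Injection-spread variability.** The liquid marker's low initial
viscosity makes its distribution in tissue variable. Since the deposit
geometry is pinned to the nominal volume, this is modelled as a per-marker
lognormal factor (σ = 0.3) on the effective iodine concentration, drawn
once per marker at scene build so it is constant across the kV scans of
the same segment (repeated-measures structure). It is the dominant source
of group variance; imaging noise alone would give unrealistically tight
groups.

## Segmentation

Two steps. `suggest_lower_level` is an automated surrogate for the visual
window-level choice: the smallest integer HU excluding ≥ 99.9% of
background voxels. `segment_marker` takes the connected component of
voxels ≥ threshold (140 HU default; voxels exactly at the threshold are
included) containing a seed, restricted to a spherical ROI (8 mm default —
large enough for the biggest blurred 30 µl marker, smaller than the
injection pitch). Connectivity defaults to 26 (full 3D adjacency; 6 and 18
are available and oracle-tested). Partial-volume voxels count fully; no
sub-voxel weighting. `detect_markers` is the unseeded variant for the
clinical workflow, with min/max volume filters (the max filter discards
large anatomy such as the bone slab).

## Statistics

Per (injected volume, kV) group: mean, sample SD (n−1), the norm interval
mean ± 1.96·SD, and ratio = mean segmented / injected volume. Reporting
rounds to 2 decimals (volumes, bounds) and 1 decimal (ratio); computation
is unrounded. The published table's interval row is numerically the norm
interval (mean ± 1.96·SD), not a standard-error CI, and is implemented as
such. The kV comparison is a paired two-sided t-test by default (the same
physical markers are scanned at every kV); Welch's test is the unpaired
option. No multiple-testing correction by default; Bonferroni is a flag.

## Discriminability

Δ = min(large-group values) − max(small-group values); border = lower norm
limit of the large group − Δ/2; separation probability =
Φ((border − mean_small)/sd_small). The decision "reliable" requires
probability > 0.95. Two conventions deserve note: (i) Δ is signed so that
a positive value is an observed gap and an overlap raises the border;
(ii) the probability reported as the decision criterion is that of a small
marker falling on the *small* side of the border — the only reading under
which "> 95%" can mean separability — and the complementary tail is
reported alongside. With sd = 0 the normal model degenerates to a point
mass (probability 1 if mean < border, else 0).

## Dual energy

A-tube 80 kV, B-tube tin-filtered 150 kV; mixed image = 0.6·A + 0.4·B.
Vendor VNC algorithms are proprietary; here a two-material (soft tissue +
iodine) linear decomposition is used: per voxel,
`c = (HU_A − HU_B − offset)/(k_A − k_B)` clamped at 0 (offset = the
non-iodine spectral difference, 0 for soft tissue), and
`VNC = mixed − c·(0.6·k_A + 0.4·k_B)`. With matched forward/inverse
vectors and no blur or noise this inverts the forward model exactly. The
inversion vectors are configurable separately from the simulation vectors
so model mismatch can be studied.

Classification uses VNC retention: mean object contrast in VNC divided by
mean object contrast in the mixed image, both referenced to soft tissue
(50 HU). Iodine markers retain ≈ 0 ("absent in VNC"), titanium ≈ 1,
calcification ≈ 0.8. The cutoff defaults to 0.3 ("markedly reduced") — an
engineering choice, with a 1e-9 tolerance at exact threshold equality so
the degenerate cutoff 1.0 labels everything iodine. The calcification
spectral slope (650 → 550 HU from 80 to 150Sn kV) was chosen shallow
relative to iodine's so that the two-material decomposition retains
calcium in the VNC, matching the clinical observation that calcified
structures stay visible there; a steeper calcium slope would be stripped
into the iodine map instead. The iodine map consequently shows clips or
calcifications with any spectral slope as pseudo-iodine, which is why the
map supports detection but not discrimination. Thick-slice (3 mm) VNC and
iodine-map reconstructions are available as an optional boxcar
downsampling, off by default. Co-registration is assumed perfect (shared
grid); no registration is implemented.

## Pipelines and problem sizes

The preclinical replication builds 9 segment scenes (100 × 100 × 48 voxels
each), distributes 75 markers over them round-robin (8–9 per segment,
volumes interleaved so each segment holds a balanced mix), scans each
scene at 70/100/120 kV and segments all 225 marker instances from their
known injection sites — about a second on one core, which is why the test
suite runs it in full. The clinical simulation lays out the injected
markers on a 10 mm grid in a boneless flap scene, ablates each
independently with the configured failure probability (0.15 default,
bracketing the observed 83–86% visibility), detects without seeds, and
matches detections to injection sites within half a pitch. Monte-Carlo
visibility replicates are drawn at the Bernoulli level: marker loss is the
only stochastic mechanism of the detection model, and the imaging path
verifies that every surviving marker is detected.

Seeds: every workflow takes one integer seed; scene jitter, per-tube noise
streams and ablation draws are derived from it via seed sequences, so all
outputs (including written CSV/JSON) are byte-stable.

## What the synthetic data does and does not show

The generator reproduces the *mechanisms* — kV-dependent iodine contrast,
PSF blooming, threshold volumetry, spectral separation — and its defaults
are calibrated so the derived quantities (ratios of 4–7, group CVs near
10–15%, reliable 10-vs-30 µl separation) resemble the published ex-vivo
values in character. It does not attempt to match the published group
means themselves: those depend on the real marker's HU, the scanner
kernel, and injection technique, none of which are published. Passing
tests therefore demonstrate correctness of the procedures and the
qualitative/ordering claims, not agreement of absolute segmented volumes
with any particular scanner. Known limitations: no beam hardening or metal
artifacts, no projection-domain simulation, no scanner kernels beyond the
Gaussian PSF, perfect co-registration, and a single global failure
probability for clinical marker loss regardless of injected volume.
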