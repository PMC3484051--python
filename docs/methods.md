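# Methods

## The measurement model

A thoracic micro-CT volume is a scalar field of attenuation values on an
isotropic grid (46 µm default). On the Hounsfield scale, air is −1000 HU,
water 0 HU. Aerated mouse lung averages roughly −450 to −650 HU because
parenchyma is a fine mixture of air and tissue; bronchial walls are much
denser (−300 to −100 HU). Airway remodeling deposits extra tissue in and
around the bronchial wall; inflammation adds cellular infiltrate both
peribronchially and in the distal parenchyma.

The pipeline reduces a volume to three numbers:

* **TLA** — mean HU over the lung field, segmented by seeded volume
  growing over the closed band [−900, −100] HU;
* **PBA** — mean HU over a *peribronchial shell*: the bronchial lumen
  (seeded volume growing over [−1024, −900] HU) dilated by a Euclidean
  radius of 8 voxels, minus every lumen-band voxel inside the dilated
  region (the "second segmentation", which also removes disconnected air
  pockets swept up by dilation), minus a trachea/mediastinum exclusion
  mask;
* **normalized PBA = 1 − PBA/TLA**.

Why the normalization works: with PBA and TLA both negative, attenuation
added only near the airways raises PBA toward zero while leaving TLA
almost unchanged, so 1 − PBA/TLA rises. Attenuation added across the
whole lung shifts PBA and TLA together and the ratio is nearly invariant.
The cancellation is a *spatial-distribution* argument, not an algebraic
identity — it requires the inflammatory signal to extend well beyond the
8-voxel shell. The ratio is only exactly invariant under multiplicative
changes; a lung-wide additive change of realistic size (≤ 100 HU) moves
normalized PBA by a few thousandths, versus ~0.05 per voxel of wall
thickening (see the phantom series in `scripts/acceptance.py`).

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| lumen band | [−1024, −900] | HU | air-filled lumen down to the scale minimum; bounds inclusive |
| lung band | [−900, −100] | HU | aerated parenchyma + wall, excludes luminal air and soft tissue |
| dilation radius | 8 | voxels | at 46 µm (≈ 0.37 mm) reaches across the wall into the immediate peribronchial space |
| connectivity | face-6 | — | conservative against diagonal leakage through thin walls; 26-connectivity available |
| dilation mode | euclidean | — | distance-transform ball, rotation-fair and reproducible; `iterated_face` mode brackets tools that iterate a unit structuring element |

A voxel at exactly −900 HU belongs to both closed bands; the shell
subtraction resolves the overlap in favour of the lumen (any lumen-band
voxel is removed from the shell).

HU calibration is a two-point affine map (air → −1000, water → 0). A bone
standard, when given, is mapped through the fitted line and logged as a
linearity diagnostic only: two points are the minimal model the
calibration data support, and adding a third would silently trade air/water
accuracy against beam-hardening effects the pipeline does not model.

## The synthetic thorax

The phantom paints, in order: a soft-tissue block (0 HU), an ellipsoidal
parenchyma region (−550 HU, mid lung-band so that 20 HU noise keeps
essentially all of it in band), a dichotomous airway tree (trachea plus 4
branching generations, radius decaying by 0.75 per generation) as −1000 HU
cylinders sheathed in walls of configurable thickness (−200 HU default),
optional air/water calibration cylinders, and an optional inflammation
halo; Gaussian noise (SD 20 HU default) is added last and the volume is
clamped at −1024 HU, the scanner minimum — without the clamp, noise would
carry air voxels below the lumen band's lower bound, which no real
reconstruction does.

Two contrast series emulate the biology of interest:

* **remodeling**: wall thickness 1 → 3 voxels at fixed geometry, seed and
  noise — attenuation accumulates at the airway;
* **inflammation**: a halo raising parenchymal attenuation (+100 HU
  default) within a default extent of 48 voxels (2.2 mm) of the airway
  wall — pan-parenchymal at the default geometry. The extent is
  deliberately much larger than the shell: inflammatory infiltrates in
  allergic-asthma models reach the distal parenchyma, and that spread is
  the mechanism that lets TLA-normalization cancel them. A halo confined
  to the shell's neighbourhood would be indistinguishable from remodeling
  by *any* attenuation statistic computed on the shell, normalized or not.

Ground-truth expectations are computed from the truth masks with
brute-force shifted-mask dilation and plain label-mean attenuations —
independent of the distance-transform dilation and component labeling the
pipeline under test uses.

What the phantom does **not** emulate: partial-volume blur (optional
smoothing aside), beam hardening, scatter, cardiac/respiratory motion,
anatomical airway curvature and lobar structure, and attenuation
heterogeneity within a tissue class. A green phantom test therefore
establishes correctness of the *computation* (segmentation, morphology,
statistics) under realistic contrast and noise, not robustness to scanner
physics or anatomical variability.

## Statistics

Bland–Altman: differences a − b; bias = mean, limits = bias ± 2 sample SD
(n − 1 denominator) — ±2 SD exactly, not 1.96. "Measurement error" is
reported as the SD of the differences and labelled as such in the JSON,
since the term has no unique definition. The ICC is ICC(2,1) — two-way
random effects, absolute agreement, single measurement — computed from the
two-way mean squares; it penalizes systematic bias, unlike Pearson r, and
equals it only in the no-bias, equal-variance, large-n limit. Degenerate
input (all values identical) returns 1 by convention and is logged.
Spearman uses midranks for ties with the t-approximation p-value.
Mann–Whitney is two-sided, exact by enumeration when n_a·n_b ≤ 400 with no
ties, otherwise normally approximated with tie and continuity corrections.

## Numerical and design choices

* Volumes are (z, y, x) with z cranio-caudal; one fixed convention
  prevents silent transpositions. NIfTI is written x-fastest with zooms in
  mm; MetaImage is written uncompressed (`.mha`).
* Distance-dependent operations (dilation) refuse anisotropic grids
  (tolerance 1% relative) rather than resampling silently, because
  resampling changes attenuation statistics.
* Non-finite voxels at read time become −1024 HU and are logged.
* The shell is *not* intersected with the lung mask by default (the
  procedure defines them independently); `restrict_shell_to_lung` is an
  escape hatch for mediastinal leakage.
* Exact-arithmetic contracts (`normalized_pba`, mask subtraction,
  determinism of region growing) are tested to 1e-12; mean-attenuation
  identities to 1e-9 relative.
* Seeds are explicit voxel coordinates for reproducibility; `auto_seed`
  proposes the centroid of the most cranial lumen-band component (the
  trachea), mimicking the natural manual choice.

## Limitations

Trachea/mediastinum exclusion is an input mask, not an automatic
segmentation; on real data it must be drawn once per scan (the phantom
emits its own). The pipeline assumes HU-calibrated input or usable
air/water standards. No wall-thickness or per-generation measurements are
attempted — the read-out is aggregate attenuation only.
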