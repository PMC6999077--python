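# Methods

This note documents the models and procedures implemented in `retoct`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic phantoms do and do not emulate, and the numerical choices made
where the design was genuinely open.

## Data model

A volume is a pair of complex backscatter arrays — co- and cross-polarized
detection channels — indexed `[repeat, y, x, z]` (repeat, slow axis, fast
axis, depth; depth increases posteriorly).  Physical units come from the
acquisition metadata: a 1 mm × 1 mm field sampled with 512 A-scans × 400
B-scan locations (1.95 × 2.5 μm en-face pitch at full scale) and an axial
pitch that defaults to 2.0 μm in the phantoms.  On disk, each channel is a
multi-page 32-bit-float TIFF with real/imaginary planes interleaved per
B-scan, plus a JSON sidecar; the layout is deterministic and round-trips
bit-exactly, and validation rejects any shape/metadata inconsistency.

## Scan-protocol derivations

Pure closed forms: B-scan period = A-scans/rate + flyback (512/83 kHz +
1.5 ms ≈ 7.7 ms — the inter-scan delay that produces angiographic
contrast); telescope beam reduction d·f2/f1 (0.8 mm × 50/80 = 0.5 mm);
lateral resolution as the Gaussian 1/e² focal-spot diameter 4λf/(πd)
(840 nm, f = 2.6 mm, d = 0.5 mm → 5.6 μm).  The spot-diameter formula is the
standard Gaussian-optics result; it is the convention under which the
printed system resolution is reproduced exactly.

## Synthetic phantom

The generator's aim is statistical, not optical, fidelity: it realizes
exactly the statistics each pipeline stage consumes.

* **Speckle** — independent circular complex Gaussian per voxel, scaled by a
  per-voxel reflectivity; amplitude in a homogeneous slab is therefore
  exactly Rayleigh.  No lateral PSF correlation is simulated (an optional
  amplitude blur exists but is off by default).  Consequence: speckle in
  *static* tissue is frozen across repeats, which is why detectors that work
  on repeat-averaged intensity still need spatial smoothing (see HRF below).
* **Layer architecture** — vitreous (noise only), inner retina (reflectivity
  0.5), a bright OPL band (0.9, 12 μm) ending at the posterior OPL, ONL
  (0.3), a thin melanin RPE band (1.2, 4 μm) ending at the posterior RPE,
  and choroid (0.5) whose signal decays exponentially below the RPE with a
  40 μm attenuation length — without attenuation a semi-infinite choroid
  would outshine the thin RPE band in the smoothed cross-polarized profile,
  which real attenuated data do not do.  Total retina 224 μm, inner retina
  130 μm, consistent with the adult mouse; smooth en-face undulation
  (6 μm amplitude, 500 μm period) exercises the flattening.  The RPE band is
  kept at 4 μm so the melanin slab lies entirely within the
  expected-depolarization mask (posterior RPE − 5 μm).
* **Polarization split** — polarization-preserving voxels put ≥ 99% of their
  amplitude in the co channel (half-normal retardation, σ = 2°, clipped at
  5.7° so the cross-channel *energy* fraction stays below 1%).  Melanin
  voxels (RPE band, choroid, ONH remnant column, ectopic deposits) draw a
  per-voxel retardation uniform on [0°, 90°]: amplitude·cos δ goes to the co
  channel, amplitude·sin δ to the cross channel.  This emulates polarization
  scrambling without simulating Jones-matrix propagation or birefringence.
* **Flow** — vessels are straight tubes clipped to their plexus slab (SVP:
  20 μm below the ILM; DCP: 15 μm above the posterior OPL), carrying their
  own blood reflectivity (0.5) independent of the host layer.  Inside a
  vessel the speckle field evolves as an AR(1) chain,
  g_{r+1} = √(1−p)·g_r + √p·fresh, where p is the decorrelation fraction:
  the chain is stationary, every consecutive pair decorrelates equally, and
  the complex-difference amplitude grows monotonically with p.  (A
  per-voxel Bernoulli redraw was considered and rejected: it is
  all-or-nothing per voxel, so after maximum-intensity projection the
  angiogram amplitude is insensitive to p.)
* **Motion** — an integer random-walk axial shift per B-scan location
  (σ = 0.8 px under study conditions), shared by all repeats, plus a random
  global phase per repeat; these are the artifacts the preprocessing and
  bulk-phase stages must remove.
* **ONH** — a layerless disc (radius 100 μm) at the field center with a
  depolarizing remnant column, so annulus geometry and exclusion logic are
  exercised.
* **Scale** — the desk-scale grid (100 × 128 en-face samples over 1 mm) is
  4–5× coarser than the full acquisition, so structures are sized to span
  the same number of *pixels* as their real counterparts: vessel radii of
  2 (SVP) and 1.5 (DCP) fast-axis pixels, HRF radii 18–25 μm, deposit radii
  ≥ 15 μm.  The full-scale grid is supported but not used by the tests.
* **Ground truth** — realized boundary maps, per-plexus vessel masks (en
  face and voxel), HRF and deposit voxel masks with volumes, applied shifts
  and phases.  The truth for the RPE *detector* is the argmax of the
  generator's own noise-free expected cross-amplitude profile after the same
  5-px boxcar the detector applies — a deterministic forward model, so
  ±1 px recovery is well defined under speckle.

What passing tests on these phantoms do **not** show: robustness to PSF-
correlated speckle, to curved/branching vasculature, to projection artifacts
of superficial flow onto deep layers, to birefringent tissue (the fibrous
RNFL), or to eye-specific aberrations and cataract-induced signal loss.

### Cohort and histology generators

The cohort model draws, per eye and per annulus region, total thickness =
baseline − slope·age + N(0, σ), with inner = 0.58 × total (so inner + outer
= total exactly).  Defaults are the study conditions: 44 transgenic eyes
(baseline 250 μm, thinning 0.37 μm/week) vs 28 wild-type eyes (245 μm,
0.26 μm/week), ages uniform on 45–104 weeks, σ = 5 μm.  The histology
generator places non-overlapping brown (DAB-toned) disks of 8–25 μm radius
on an eosin-pink textured background at 2 μm/px.

## Preprocessing

Axial motion is estimated per B-scan by cross-correlating depth profiles of
adjacent B-scans (integer lags, accumulated).  The RPE/choroid depth is the
argmax of the 5-px boxcar-smoothed cross-polarized amplitude (averaged over
repeats) per A-scan; A-scans whose peak stays below 3× the amplitude noise
floor (default 0.05) are invalid and filled by nearest-neighbour
interpolation, and > 20% invalid raises a typed exclusion (mirroring the
failed-flattening exclusion policy of the study design).  The depth map is
median-filtered 3 × 9 (slow × fast axis): the fast axis lies within one
B-scan and is motion-free, so a wide median is safe there, while real
motion steps between B-scans must not be smeared.  Flattening rolls each
A-scan by an integer shift (zero padding) so the detected RPE rests at 75%
of the z extent; complex values are never interpolated, so repeat-to-repeat
complex differences are untouched outside the padding — sub-pixel shifts
would alter the speckle statistics the angiography stage depends on.

## Layer segmentation

On the repeat-averaged log intensity of the co channel (amplitudes floored
at the anterior-region noise level so flattening pads cannot inject edges),
smoothed by a 3-D Gaussian (σ = 1 px per axis), boundaries are axial
gradient edges:

* threshold = 4 × (1.4826 × MAD of the gradient over the whole volume),
  floored at 0.5 dB/px.  The MAD over the volume is a robust noise estimate
  because boundary voxels are a small minority; the anterior noise region
  alone underestimates tissue speckle noise.
* **ILM** = first supra-threshold rising run; **posterior RPE** = first
  falling run at the RPE anchor (the cross-polarized detected depth, the
  same landmark used for flattening), searching from 3 px anterior of the
  anchor; **posterior OPL** = the most posterior *significant* falling run
  between the ILM and a 10-px margin anterior to the anchor, where
  significant means integrated gradient excess ≥ half the strongest run's —
  this keeps the posterior-most-edge rule while rejecting isolated speckle
  flickers.
* each boundary is the excess-weighted centroid of its gradient run,
  restricted to ±2 px around the steepest voxel (symmetric window, so
  one-sided shoulders such as choroidal attenuation do not bias the edge);
  the estimate is exact on a noise-free step.
* boundary maps are median-filtered 5 × 5 as residuals relative to the RPE
  anchor (anatomy is smooth across B-scans; residual motion steps are shared
  by boundary and anchor and cancel), monotonicity violations are flagged
  invalid and interpolated, and > 30% invalid raises an exclusion error.

On speckled phantoms with motion, all three boundaries recover within ±2 px
for ≥ 95% of valid A-scans.

## Annulus and thickness statistics

The annulus (inner/outer diameters 500/900 μm) is computed in physical
coordinates with pixel centers at (index + 0.5)·pitch, so anisotropic
sampling is exact; the transverse split line through the ONH center
(orientation configurable, default along the fast axis) partitions it into
superior and inferior halves.  Thickness metrics are means of
(boundary difference × axial pitch) over valid annulus pixels; inner + outer
= total holds identically.

Group comparison per metric: OLS pretest thickness ~ age in each group; the
ANCOVA branch is taken only when *both* groups are age-dependent (the
procedure switches to ANOVA when any pretest fails).  "Difference in trend"
is the age×group interaction F-test; the adjusted-means group effect from
the additive model is also reported as a secondary quantity, since either
reading of an ANCOVA comparison is defensible.  No multiple-testing
correction is applied across the nine metrics by default (a Bonferroni flag
exists).  Under a matched-slope null the full procedure's type-I error is
~5% (calibrated over 500 replicates); slope recovery at the default cohort
sizes is unbiased.

## Angiography

Bulk phase between adjacent repeats is arg Σ C_{i+1}·C̄_i, removed
sequentially; a repeat whose mean normalized complex difference against the
pixel-wise median repeat exceeds 0.6 is dropped, and a B-scan with fewer
than two survivors is excluded and logged (a quantitative surrogate for
visual screening of motion-corrupted angiograms).  The OCTA image is the
mean |C_{i+1} − C_i| over consecutive retained pairs.  En-face maps are
max projections over the plexus slabs; binarization is CLAHE (tile ≈ image/8,
clip limit 0.01) → global Otsu → opening and closing with a disk of radius
1 → skeletonization → 5×5 square averaging with any positive response marked
vessel (equivalently, skeleton dilation by a 5×5 square; the positivity test
uses a half-pixel-weight threshold to be robust to floating-point fuzz).
Otsu after gentle CLAHE was chosen as the single-parameter standard; local
adaptive thresholds can be configured.  The Weber contrast uses the *raw*
(pre-equalization) projection, since equalization would distort the
intensity ratio the metric audits.

## Polarization

δ = arctan(A_cross/A_co) in degrees on repeat-averaged amplitudes (arctan2,
so the zero-amplitude limits are 0° and 90°), masked where the combined
amplitude is below 3× the noise floor.  The ratio convention keeps
polarization-preserving tissue near 0°, which is the physically meaningful
reading; a config switch provides the transposed ratio for comparison.  The
expected-depolarization mask is the union of the RPE/choroid slab
(z ≥ posterior RPE − 5 μm, rounded to the nearest voxel) and a cylinder
around the ONH (radius + 50 μm).  Deposit screening takes SNR-valid voxels
with δ > 30° outside the mask, labels 26-connected components, drops
components below 27 voxels and components *adjacent to* the expected mask —
those are attached to the RPE/choroid complex or the ONH remnant, not
ectopic; the trade-off is that a deposit touching the RPE would be missed.
Thresholds were chosen so preserving phantom tissue (δ 95th percentile
< 10°) never triggers; both are configurable and reported with each run.

## Hyper-reflective foci

Detection operates on the repeat-averaged log intensity smoothed with a 3-D
Gaussian (σ = 1 px) — necessary because static-tissue speckle is identical
across repeats, so repeat averaging alone does not suppress it (~6% of raw
voxels exceed +6 dB over the median; after smoothing, supra-threshold
clusters of ≥ 8 voxels do not occur in background).  Candidates exceed the
per-depth background median of the outer-retina slab by 6 dB; 26-connected
components within 8–4000 voxels are kept, excluding components touching the
RPE band (4 μm margin) and any en-face exclusion region (the layerless ONH
disc).  The reported extent grows each detection by bounded hysteresis
(≤ 4 dilation steps) into the 0.75 × threshold contour: the smoothing erodes
the detection contour of a compact bright inclusion, and the looser contour
restores the pre-blur extent (volumes recover within ±15% on 18–25 μm
phantom spheres) while the step bound prevents percolation through
background speckle.

## Histomorphometry

Brown segmentation is an HSV window (hue 10°–40°, saturation > 0.2,
value < 0.9 — the DAB tone), restricted to the user-supplied cortex mask;
8-connected components with equivalent area ≥ 20 μm² are counted.  Touching
deposits merge into one component and are counted once.  Plaque load =
count/area (mm²); the age trend is OLS with slope, R², and slope p-value
(a constant response is reported as slope 0, R² 0, p 1).  Color
deconvolution was not used because the tool being emulated is a color-window
segmenter; the window is configurable.

## Problem sizes

Tests and the acceptance script use the desk-scale phantom
(5 × 100 × 128 × 256, ≈ 7 s to generate), 10 preserving-only phantoms at
5 × 64 × 96 × 224 for the false-positive screen, 500/300-replicate cohort
simulations for the type-I and slope-recovery calibrations, and 14 synthetic
histology sections of 0.25 mm² at 2 μm/px.  These sizes keep the full suite
around two minutes while leaving every statistical check adequately powered.

## Known limitations

Integer-only flattening leaves ±0.5 px quantization in layer positions; the
segmentation surrogate assumes the standard band ordering (bright OPL band,
dimmer ONL, bright RPE) and is validated only on phantoms; vessel
binarization is tuned for vessels a few pixels wide; the deposit screen
cannot see deposits attached to the RPE; the phantom's polarization model
has no birefringence, so retardation in preserving tissue is structureless
noise rather than the slow RNFL-induced drift real data may show.
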