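# retoct — multicontrast OCT retinal analysis

`retoct` re-implements a multicontrast optical coherence tomography (OCT)
analysis pipeline for the mouse retina, of the kind used to characterize
retinal structure in transgenic disease models (e.g. APP/PS1 mice) against
wild-type littermates.  One raster scan of a polarization-sensitive OCT
system yields three contrasts at once, and the package quantifies all of
them:

* **Reflectivity** — axial-motion correction and flattening to the
  RPE/choroid complex (detected from the cross-polarized channel), layer
  segmentation (ILM, posterior OPL, posterior RPE), and mean total / inner /
  outer retinal thickness inside a peripapillary annulus (500/900 μm
  diameters) and its superior/inferior halves — nine metrics per eye.
  Cohort statistics follow a regression pretest: thickness ~ age per group
  by ordinary least squares; if both groups are age-dependent (p < 0.05) the
  groups are compared by ANCOVA on the age×group interaction (difference in
  the thinning trend), otherwise by one-way ANOVA on the group means.
* **Angiography (OCTA)** — five repeated B-scans per location; after bulk
  phase correction the angiogram is the averaged magnitude of complex
  differences between consecutive repeats, `mean_i |C_{i+1} − C_i|`.
  Maximum-intensity en-face projections over the superficial vascular plexus
  (SVP) and deep capillary plexus (DCP) are binarized (CLAHE → Otsu →
  open/close with a disk of radius 1 → skeletonize → 5×5 square averaging)
  and quantified as vessel density (% vessel pixels in the annulus) and the
  modified Weber contrast `C_W = (Īv − Īb)/Īb` on the raw projection.
* **Polarization** — per-voxel phase retardation `δ = arctan(A_cross/A_co)`
  on repeat-averaged amplitudes.  Melanin (RPE, choroid, hyaloid remnant at
  the ONH) scrambles the polarization state, so δ is random on [0°, 90°]
  there and near 0° in polarization-preserving tissue; connected
  high-retardation components *outside* the expected melanin regions are
  screened as abnormal depolarizing deposits.
* **Hyper-reflective foci (HRF)** — bright inclusions in the outer retina
  (posterior OPL to posterior RPE), detected as connected components
  exceeding the per-depth background median by 6 dB, with volume, centroid,
  and normalized outer-retina depth.
* **Histomorphometry** — brown (DAB) plaque segmentation in brightfield
  cortex images by an HSV color window, plaque load in plaques/mm², and the
  load-vs-age linear regression.

No public raw data exist for this kind of acquisition, so the package ships
a **synthetic PS-OCT phantom generator** with complete ground truth (layer
boundaries, vessel masks, HRF and melanin-deposit voxel masks, applied
motion), plus cohort-level and histology-image generators.  Every stage is
validated by parameter recovery against that ground truth.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on the
reference phantom (5 repeats × 100 × 128 × 256 voxels over a 1 mm × 1 mm
field, 2 μm axial pitch) and write tables under `results/`:

```
python analysis/01_protocol_report.py
python analysis/02_simulate_phantom.py
python analysis/03_thickness_morphometry.py
python analysis/04_angiography.py
python analysis/05_polarization_hrf.py
python analysis/06_histomorphometry.py
```

Selected output (what it means in brackets):

```
B-scan period 7.7 ms, beam 0.5 mm on the pupil, 5.6 um focal spot.
  [512 A-scans at 83 kHz + 1.5 ms flyback; 0.8 mm beam through the 80/50 mm
   telescope; Gaussian spot 4λf/(πd) at 840 nm for a 2.6 mm mouse eye]

single eye: total thickness 225.2 um in the annulus (ground truth 224.0 um);
inner 130.0, outer 95.2
  [flatten → segment → nine annulus metrics; recovery within ~1 μm]

SVP: vessel density 14.5% (superior 15.5, inferior 13.6), Weber contrast 5.72
DCP: vessel density 19.5% (superior 19.5, inferior 19.5), Weber contrast 3.87
  [the DCP here decorrelates fully, so its density is genuine; the Weber
   contrast audits angiogram signal strength against background]

1 depolarizing deposit(s) outside the expected melanin regions (truth: 1);
preserving-tissue retardation 95th percentile 9.6 deg
3 HRF detected (truth: 3); volumes [30938, 63281, 22656] um^3

plaque load increases by 0.203 plaques/mm^2/week (configured 0.354);
R^2 = 0.532, p = 0.0031
  [14 sections, ages 54–104 weeks: with this sample size the slope estimate
   scatters with SE ≈ 0.1 around the configured value]
```

The cohort comparison table (`results/thickness_comparison.csv`) mirrors the
pretest → ANCOVA/ANOVA procedure for all nine thickness metrics.  Note that
the default cohort assigns genuinely different thinning rates to the two
groups (0.37 vs 0.26 μm/week), so occasional significant interactions are
correct detections, not false positives; power at these sample sizes
(44 vs 28 eyes, σ = 5 μm) is modest.

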