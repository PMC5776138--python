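# Methods

## Data model and conventions

A reconstructed OPT scan is stored as one multi-page grayscale TIFF per
channel; page order is anterior→posterior, and within a page rows run
dorsal→ventral, columns left→right.  This orientation is a package
convention (reconstruction software does not record anatomy) and is the
orientation the phantom generator emits; real stacks prepared differently
must be reordered on import.  Intensities are 16-bit.  The intensity
domain is [0, 65535]: the scanner's nominal "0–65,536" range cannot be
represented in 16 bits, so 65,535 is white.  8-bit inputs are upscaled by
257 (not 256) so that 255 maps exactly to 65,535.  Voxels are isotropic;
all coordinates are 0-based with half-open `[start, stop)` intervals.

## Quantizer

Sixteen fixed bins of width 4,096 tile the intensity domain; the top bin
also absorbs 65,535 (16 × 4,096 exceeds the maximum by one).  Two
distinct "non-black" notions are kept deliberately separate:

* for **Histogram Analysis**, a non-black *pixel* is any pixel with
  I > 0 (the threshold mask on the projection);
* for **Structure/Slice Analysis**, the non-black *bins* are bins 1–15,
  i.e. I ≥ 4,096 — pixels with 0 < I < 4,096 sit in the black bin and do
  not count toward volume.

Bins are labeled by their lower edge (4,096, 8,192, …).  Binning is over
the full fixed 16-bit range, not each image's display range, so bin
membership is comparable across specimens scanned with standardized
exposure.

## Histogram Analysis

The horizontal maximum projection is masked to I > 0 and cut into A-P
segments of `segment_um` (default 20 µm): the pixel whose anterior edge
is at `i·p` µm belongs to segment `floor(i·p / segment_um)`.  The
trailing partial segment is kept and flagged.  Segment means are taken
over masked pixels only (mask-then-mean); averaging over all pixels of a
segment would dilute the signal with brain-width variation.  A documented
`include_zero_pixels` toggle provides the all-pixel mean for comparison.
Segments with no non-black pixel report mean 0 (not NaN) so profiles stay
plottable; percent change from control still guards division by zero and
flags such segments undefined.  Group profiles align profiles at the
anterior end and truncate to the shortest — age-matched animals give
near-equal segment counts, so no registration or warping is attempted.

## Structure and Slice Analysis

Structure Analysis counts every voxel of a box ROI across its full A-P
depth; default bin subset is all 15 non-black bins.  Slice Analysis
samples the niche's A-P interval starting at its first section (the
anchor is unspecified in the field's workflows; starting at 0 is
deterministic and covers the anterior boundary), every `stride` sections
(default 5), counts only pixels inside the per-section mask, and defaults
to bins {1, 2, 3}.  Reported slice volumes are of the *sampled* voxels
only — within-method comparisons cancel the constant 1-in-5 factor — and
an `extrapolate` flag multiplies by the stride for whole-niche estimates.
At stride 1 with full-frame masks and equal bin subsets, Slice Analysis
equals Structure Analysis exactly (tested).

## Morphometry

Brain volume from the autofluorescence channel uses a transparent
threshold segmentation: explicit threshold (mask is I ≥ t) or Otsu (mask
is I > t, the Otsu convention), optionally keeping only the largest
26-connected component, then voxel count × voxel volume.  Commercial
volumetric renderers do the same job with undisclosed parameters; this
implementation trades their surface meshing for reproducibility.  A
constant volume yields an empty mask rather than an error.  Digitized
ellipsoids of semi-axes ≥ 20 voxels are recovered within 2% of
(4/3)πabc (tested).

## Group statistics

One-way ANOVA (scipy's F test) across treatment groups, then
Tukey–Kramer pairwise comparisons: for groups *a*, *b* with pooled
within-group mean square `MSE` on `N − k` degrees of freedom,
`q = |ȳ_a − ȳ_b| / sqrt(MSE/2 · (1/n_a + 1/n_b))`, with adjusted p from
the studentized-range distribution.  Tukey records are emitted even when
the omnibus test fails, flagged with the omnibus outcome, so per-pair
results are never silently dropped.  SEM uses the n−1 standard deviation
(0 when n = 1).  All-constant data yields a defined "no test" outcome
(F = NaN, nothing significant); zero within-group variance with distinct
means reports perfect separation.  Calibration: the null type-I error at
α = 0.05 over 2,000 simulated 4-group cohorts lies in [0.03, 0.07], and
adjusted p-values match statsmodels' independent Tukey implementation to
4 decimals (both exercised by the acceptance script).  ANOVA is run per
ROI independently; no correction across ROIs is applied, since one is not
part of the standard workflow being reproduced.

## Phantom generator

The phantom emulates *reconstructed* scans, not raw projections.  Default
grid: 120 × 48 × 48 voxels at 5 µm (a 600 × 240 × 240 µm caricature
brain; desk-scale so that replicate studies run in seconds per cohort).
Components:

* **brain** — ellipsoid (semi-axes 290/105/105 µm) at autofluorescence
  level 18,000, plus noise, in its own channel;
* **niches** — midline pallial bands (one per hemisphere), a dorsal
  tectal shell, and a cerebellar band, each with a Poisson focus count
  (λ per µm³ × niche volume), foci as hard-edged spheres (radius 6 µm,
  peak 30,000) at uniform positions in the niche;
* **parenchymal infiltrate** — a smoothed uniform random field scaled by
  a per-group amplitude, confined to the lesioned (left) forebrain
  hemisphere and excluded from a 3-voxel dilation of every niche;
* **optics** — global Gaussian blur (σ = 5 µm) standing in for the OPT
  point-spread and reconstruction smoothing, then additive Gaussian noise
  (sd 800), clipping and 16-bit quantization.  Reconstructed data are
  emulated, so no Poisson shot-noise model is used.

Default injury schedule: parenchymal amplitude 0 / 12,000 / 6,000 / 1,500
(control / 1 / 3 / 7-dpl); ipsilateral pallial rate multiplier
1 / 1.6 / 2.5 / 1.2 (peaking at 3-dpl); contralateral 1 / 1.8 / 1.2 / 1
(peaking at 1-dpl); tectal and cerebellar niches unchanged.  Baseline
focus rate 2×10⁻⁴ µm⁻³ (1.5×10⁻⁴ for the tectal shell) gives tens of
foci per niche, i.e. Poisson coefficients of variation around 10% —
comparable to the between-animal variability the real cohorts show.
These defaults produce the qualitative dichotomy the pipeline is designed
to resolve: hemisphere-level Structure Analysis peaks at 1-dpl (niche
plus infiltrate), niche-restricted Slice Analysis peaks at 3-dpl
ipsilaterally and stays flat in tectal/cerebellar niches.

Determinism: a cohort seed draws per-sample seeds once (recorded in the
manifest); each sample consumes its random stream in a fixed order, and
the parenchymal field is drawn even at amplitude 0, so same-seed samples
from different groups differ only in signal.  Ground truth (focus counts,
focus voxels, parenchymal voxels ≥ 4,096, brain-mask size) is recorded
before blur and noise.

What the phantom does *not* emulate: anatomically faithful niche
geometry, tomographic reconstruction artifacts, scatter, depth-dependent
attenuation, pigment remnants, or between-animal size variation.  Passing
tests therefore demonstrate that the arithmetic and statistics of the
pipeline are correct and that its contrasts are recoverable under
OPT-like noise — not that any particular biological effect size will be
detectable in real scans.

## Replicate studies and problem sizes

The validation studies run the package end-to-end at sizes chosen to keep
each study at desk scale: oracle equivalence on 50 randomized 32³ ROIs;
the injury power study over 50 seeded replicates of an 18-brain cohort
(n = 5/4/4/5, the published group sizes); the null-calibration study over
2,000 simulated 4-group cohorts of n = 5.  The power study asserts ≥ 90%
recovery of the two true contrasts and ≤ 25% familywise false-positive
rate in the unchanged niches (the observed rates sit near the Tukey
familywise 5%).

## Bench calculators

The staining-solution recipe is fixed to the 3 mL reference composition
(PBS 2,241 µL; 0.5 M ascorbic acid 600 µL; 2 M Tris 150 µL; azide 6 µL;
1 M CuSO₄ 3 µL) and scaled proportionally, reported to 0.1 µL
(pipettable precision; components sum to the total within 0.5 µL after
rounding).  Stock molarity is mM = mg / (g·mol⁻¹ × mL) × 1000; 50 mg EdU
(252.23 g/mol) in 20 mL gives 9.91 mM, the nominal 10 mM stock.

## Known limitations

* The A-P page-orientation convention is asserted, not detected.
* Anisotropic voxels are unsupported throughout.
* Niche masks are inputs; no automatic niche segmentation is provided.
* Slice Analysis volumes are sample-fraction volumes unless
  `extrapolate=True`; mixing the two conventions across cohorts is the
  caller's responsibility.
* Morphometry's threshold segmentation is not equivalent to any
  particular commercial renderer's algorithm; absolute volumes should be
  compared only within a fixed parameter set.
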