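# optquant

Quantification of EdU-labeled whole-brain optical projection tomography
(OPT) volumes of adult zebrafish.

After a short EdU pulse, click-chemistry staining, BABB clearing and OPT
scanning, a reconstructed brain is an isotropic 3-D 16-bit stack: 1-pixel
virtual cross-sections ordered along the anterior–posterior (A-P) axis,
with intensities in [0, 65535] and voxels of ~91–125 µm³ (4.5–5 µm
pixels).  `optquant` implements three complementary quantification methods
for such stacks, plus the statistics, morphometry, bench calculators and a
synthetic phantom generator that makes the whole pipeline verifiable
without scanner data.

**Who it is for**: labs quantifying proliferation (or any punctate or
diffuse fluorescent signal) in cleared whole-mount brains, and anyone who
needs a transparent, scriptable replacement for ad-hoc FIJI workflows.

## The three analyses

* **Histogram Analysis** — maximum-project the volume through the
  horizontal plane, mask to non-black pixels (I > 0), cut the A-P axis
  into 20 µm segments, and report each segment's mean masked intensity
  `Ī_s`.  Group profiles are the across-animal mean ± SEM per like
  segment, optionally expressed as percent change from control,
  `100·(Ī_s^trt − Ī_s^ctl)/Ī_s^ctl`.
* **Structure Analysis** — inside a box ROI spanning its full A-P depth,
  quantize intensities into 16 bins of width 4,096 (bin 0, I < 4,096, is
  the "black" bin), sum pixel counts over the 15 non-black bins, and
  convert to volume: `V = N_px · p³` µm³ for pixel size `p`.
* **Slice Analysis** — sample every 5th A-P section of a neurogenic-niche
  ROI, count only pixels inside that section's mask, restrict by default
  to the first three non-black bins (lower edges 4,096 / 8,192 / 12,288),
  and convert to volume the same way.  The bin restriction and niche
  masks suppress bright immune-cell infiltrate so that the niche
  stem-cell response is read out selectively.

Group comparisons use one-way ANOVA followed by Tukey's HSD
(Tukey–Kramer for unequal n), significance at p < 0.05; data are
summarised as mean + SEM.  Morphometry segments the autofluorescence
channel by threshold (or Otsu) and counts voxels.  The phantom module
generates OPT-like brains — ellipsoidal autofluorescent shell, midline /
tectal / cerebellar niches with Poisson-distributed EdU foci, a
lesion-schedule-dependent diffuse parenchymal component, blur, noise and
16-bit quantization — with ground truth recorded before blur/noise.

## Worked example

Generate a phantom cohort with the published group sizes (control n=5,
1-dpl n=4, 3-dpl n=4, 7-dpl n=5), run Structure Analysis over the
lesioned telencephalic hemisphere, and compare groups:

```python
from optquant import (compare_groups, default_spec, generate_cohort,
                      hemisphere_box, structure_volume)

spec = default_spec()
samples, manifest, truth = generate_cohort(
    spec, {"control": 5, "1dpl": 4, "3dpl": 4, "7dpl": 5}, seed=1)
box = hemisphere_box(spec, "left")
volumes = {g: [] for g in ("control", "1dpl", "3dpl", "7dpl")}
for s in samples:
    volumes[s.group].append(structure_volume(s, "edu", box).volume_um3)

result = compare_groups(volumes, alpha=0.05)
for g in result.groups:
    print(f"{g.name:>8}: n={g.n}  mean={g.mean:>10.0f} um^3  sem={g.sem:>8.0f}")
print(f"ANOVA: F={result.anova_f:.1f}, p={result.anova_p:.2e}")
for rec in result.pairwise:
    flag = "*" if rec.significant else " "
    print(f"{rec.group_a:>8} vs {rec.group_b:<8} diff={rec.mean_diff:>+11.0f}"
          f"  p_adj={rec.p_adj:.4f} {flag}")
```

Output:

```
 control: n=5  mean=    113875 um^3  sem=    9140
    1dpl: n=4  mean=   1122625 um^3  sem=   17778
    3dpl: n=4  mean=    304969 um^3  sem=   26334
    7dpl: n=5  mean=    131550 um^3  sem=   13126
ANOVA: F=782.9, p=8.04e-16
 control vs 1dpl     diff=   +1008750  p_adj=0.0000 *
 control vs 3dpl     diff=    +191094  p_adj=0.0000 *
 control vs 7dpl     diff=     +17675  p_adj=0.8548
    1dpl vs 3dpl     diff=    -817656  p_adj=0.0000 *
    1dpl vs 7dpl     diff=    -991075  p_adj=0.0000 *
    3dpl vs 7dpl     diff=    -173419  p_adj=0.0000 *
```

The hemisphere-level EdU volume bursts at 1-dpl (immune infiltrate plus
niche activation), partially recedes by 3-dpl, and returns to baseline by
7-dpl — exactly the injury schedule the phantom encodes.  Running Slice
Analysis on the ipsilateral pallial niche instead peaks at 3-dpl, because
the niche masks and low-bin restriction exclude the diffuse infiltrate.

The same pipeline is available from the shell:

```sh
optquant generate --out cohort --seed 1
optquant structure --manifest cohort/manifest.csv \
    --roi cohort/rois/lesioned_hemisphere.json --out structure.csv
optquant compare --measurements structure.csv --out comparison.csv
optquant recipe --total-ml 6          # scaled staining-solution recipe
optquant stock                        # EdU stock molarity (9.91 mM)
```

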