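# adipovol

Semi-automatic segmentation and volumetry of adipose tissue depots on
abdominal fat–water MRI, with agreement statistics for method comparison and
a synthetic phantom generator for offline testing.

## Who this is for

Studies of obesity and metabolic risk need separate volumes of visceral
(VAT) and subcutaneous (SAT) adipose tissue: VAT carries the higher
metabolic risk, so total fat mass alone is not informative. MRI with fat
suppression (CHESS water images subtracted from T1 RARE base images, or
2-point Dixon in-phase/out-of-phase pairs) yields fat-only images in which
adipose voxels are bright, but MRI has no fixed intensity units — a fixed
global threshold cannot separate fat from tissue and noise across subjects
and scanners. This package implements a standardised, mostly automatic
thresholding scheme that works across intensity regimes as different as
small-animal scans (signals around 30,000, heavy background noise) and
clinical scans (signals below 500), with a small scripted-edit step
replacing interactive voxel clicking.

## Method

Per axial slice of the fat image:

1. **Background noise.** The image margin band is split into 8 fields
   (4 corners + 4 edge strips); voxels are sampled at random from the
   non-excluded fields and the noise level is `BG = mean + sd` of the
   sample. Fields contaminated by high-signal objects (e.g. arms) can be
   excluded explicitly or by a median + k·MAD outlier rule.
2. **Body mask and contour.** The anatomy reference (base image for mice,
   in-phase image for humans) is Otsu-thresholded; the largest connected
   object is kept, interior holes are filled, and the contour is the line
   of mask voxels facing the background. Everything outside the mask is
   zeroed in the fat image.
3. **Adaptive threshold.** Much of the body contour runs through
   subcutaneous fat, so the fat-image intensities along the contour give a
   fat-signal floor: `TC = mean − sd` of the contour intensities. If that
   falls below BG, the fallback `TC = BG + 0.1 · sd` is used instead.
4. **Local thresholding.** A voxel is fat iff its intensity exceeds the
   mean of the moving window centred on it (15×15 voxels for mice, 50×50
   for humans) plus the offset TC. The local window makes the decision
   robust to intensity gradients and spatially varying noise.
5. **Labelling, edits, depots.** Connected objects are labelled
   (4-connectivity by default, so one-voxel-wide cuts split objects). A
   declarative edit script removes artefacts, cuts apart touching depots
   and adds voxels lost to incomplete fat suppression; seed points assign
   each object to SAT (label 1) or VAT (label 2); cut voxels are reinserted
   into the majority depot of their neighbours so no volume is lost.
6. **Volumetry.** Depot volumes are voxel counts times the voxel volume
   (0.156 × 0.156 × 1 mm for the mouse protocol, 1.234 × 1.234 × 2.5 mm for
   the human protocol).

For method comparison the package computes the Jaccard difference
`100·(1 − |A∩B|/|A∪B|)` (0 % = perfect overlap), the signed relative volume
difference `100·(A − B)/B`, Spearman rank correlations of paired volumes,
and Bland–Altman analysis (bias, 1.96·SD limits of agreement with 95 %
confidence intervals, proportional-bias test via Spearman correlation of
differences against pair means, absolute or proportional y-axis).

## Worked example

```python
from adipovol import (PipelineConfig, generate_phantom, mouse_spec,
                      segment_subject, jaccard_difference)

spec = mouse_spec(seed=42)             # noisy mouse regime, 10 slices
scan, truth = generate_phantom(spec)
config = PipelineConfig.for_species("mouse", seed=42)
result = segment_subject(scan, config, truth.edits)

print(result.report.to_frame("mouse-42").to_string(index=False))
row = result.provenance.iloc[0]
print(f"slice 0: BG={row.bg:.0f}  TC={row.tc:.0f}  fallback={row.fallback_used}")
for depot, name in ((1, "SAT"), (2, "VAT")):
    j = jaccard_difference(result.depot_map == depot, truth.depot_map == depot)
    print(f"{name} Jaccard difference vs truth: {j:.2f}%")
```

prints

```
 subject depot  voxels  volume_cm3
mouse-42   SAT   26501    0.644928
mouse-42   VAT    2570    0.062544
mouse-42   TAT   29071    0.707472
slice 0: BG=1308  TC=7534  fallback=False
SAT Jaccard difference vs truth: 1.12%
VAT Jaccard difference vs truth: 0.00%
```

The volume report counts SAT/VAT/TAT voxels across the 10 analysed slices
and converts them to cm³; the provenance line shows the estimated background
noise and the contour-derived threshold offset used on the first slice (the
fallback did not fire); the Jaccard differences show that even with heavy
background noise the pipeline recovers the known phantom truth to about 1 %
overlap error.

The same workflow is available from the shell:

```sh
adipovol phantom --preset mouse --seed 42 --out bundle/
adipovol segment --bundle bundle/ --species mouse --seed 42 --out seg/
adipovol evaluate --maps-a seg/labels.nii.gz --maps-b bundle/truth_labels.nii.gz --out eval/
```

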