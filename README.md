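# hemiasym

Hemispheric-asymmetry analysis of 2D brain-slice images for staging early
dementia.

Structural asymmetry between the left and right cerebral hemispheres changes
with neurodegeneration: it *decreases* in early amnestic mild cognitive
impairment (EMCI) relative to normal cognition (NC) and *increases* markedly
in Alzheimer's disease (AD). `hemiasym` turns that observation into a
classification pipeline for T1-weighted MRI slices (and for synthetic
phantoms with exact ground truth, since clinical MRI repositories are
access-controlled):

1. **Preprocess** — load PNG/JPEG/TIFF (or one NIfTI slice), min-max
   normalize, resize to 256×256, and skull-strip by an intensity threshold
   band, keeping the largest 8-connected component.
2. **Align** — binarize, translate the brain's centroid to the image center,
   then grid-search the in-plane rotation (±15° at 0.5° steps by default)
   that minimizes the mean squared difference between the slice and its
   vertical mirror, placing the midsagittal axis on the image midline.
3. **Asymmetry map** — two-way saturating hemispheric subtraction
   `D = (L − R)₊ + (R − L)₊ = |I − mirror(I)|`; bilaterally symmetric pixels
   are exactly 0.
4. **Features** — an ordered 10-statistic vector per map (mirror-MSE
   computed on the aligned slice itself; Mean, Std, Entropy, RMS, Variance,
   Smoothness, Kurtosis, Skewness and GLCM inverse difference moment on the
   Haar DWT approximation subband of the map), plus a bag-of-features
   histogram (blob-detector keypoints, 64-dim gradient descriptors, K-Means
   vocabulary).
5. **Classify** — eight fixed-hyperparameter models (Gaussian NB, linear
   discriminant, linear/quadratic/cubic/medium-Gaussian SVMs, 1-NN
   Euclidean, 10-NN cosine) evaluated with 10 runs of stratified 10-fold
   cross-validation on the binary datasets EMCI vs. NC, AD vs. NC and
   AD vs. EMCI, reporting accuracy, sensitivity, specificity and ROC/AUC.

The synthetic module generates brain-like phantoms — symmetric skull ring,
tissue ellipse with smooth bilateral texture, ventricle pair — carrying
purely unilateral lesions whose amplitude encodes the class
(EMCI < NC < AD), plus random pose and noise, so every stage is testable
against construction-time ground truth.

## Worked example

Recover the pose of a phantom with a known rotation of +4°, shift of
(+8, −5) px, strong unilateral lesions and noise σ = 2:

```python
from hemiasym import (PhantomSpec, ThresholdBand, generate_phantom,
                      skull_strip, align_and_extract, stat_features)

spec = PhantomSpec(label="AD", seed=21, rotation_deg=4.0,
                   shift=(8.0, -5.0), noise_sigma=2.0)
bundle = generate_phantom(spec)
stripped = skull_strip(bundle.image, ThresholdBand(60, 200))
aligned, amap, pose = align_and_extract(stripped)
print(f"recovered rotation: {pose.angle_deg:+.1f} deg")
print(f"recovered shift:    ({pose.shift_row:+.2f}, {pose.shift_col:+.2f}) px")
s = stat_features(amap, aligned)
print(f"mirror MSE: {s.mse:.3f}   entropy: {s.entropy:.3f} bits   IDM: {s.idm:.3f}")
```

prints

```
recovered rotation: -4.0 deg
recovered shift:    (-7.94, +5.02) px
mirror MSE: 8.178   entropy: 2.749 bits   IDM: 0.697
```

— the alignment undoes the true pose to within a fraction of a pixel and of
the 0.5° angular grid, and the asymmetry statistics quantify the lesions
that survive into the map.

The same flow from the shell:

```bash
hemiasym simulate --n-per-class 30 --out cohort/ --seed 7
hemiasym run --simulate 30 --seed 7 --out results/
```

`results/metrics.csv` holds the accuracy/sensitivity/specificity grid
(3 class pairs × 8 models), `results/auc.csv` the AUC summary, and
`results/alignment.csv` the per-image pose provenance.

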