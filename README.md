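# octplaq

Pixel-wise characterization of atherosclerotic plaque tissue — fibrous,
calcified, lipid — in intravascular optical coherence tomography (OCT),
for researchers building or validating quantitative plaque analysis
pipelines.  The package implements the full workflow used in ex-vivo
histology-validated plaque studies, plus a forward-model phantom simulator
that supplies ground truth, so every stage can be validated end to end
without access to clinical pullbacks.

## What it does

Working on polar-coordinate B-scans (rows = A-lines over 360°, columns =
depth), the pipeline runs:

1. **Lumen segmentation** — guide-wire shadow masking and a
   dynamic-programming minimum-cost closed contour over the axial edge
   cost, with a per-A-line smoothness constraint.
2. **Optical-parameter inversion** — the depth-resolved signal is modelled
   as `I(r) = I0 · T(r) · s(r) · exp(−μt r)` with confocal PSF
   `T(r) = [((r−z0)/zR)² + 1]^(−1/2)` and Gaussian roll-off
   `s(r) = exp[−((r−zC)/zW)²]`; after dividing out `T` and `s`,
   `log I(r) = log I0 − μt r`, and sliding-window least squares yields
   per-pixel attenuation `μt` (mm⁻¹) and intercept `log I0` over a 1-mm
   analysis band anchored at the lumen.
3. **Texture features** — first-order statistics, gray-level co-occurrence
   (distance 1, four directions, averaged), Amadasun neighbourhood
   gray-tone difference, four-scale differential box-counting fractal
   signature, and boundary-relative position: 25 features per pixel.
4. **Random-forest classification** — pixel-wise tissue maps
   (green = fibrous, white = calcified, pink = lipid) with per-class
   probability rasters.
5. **Evaluation** — per-class sensitivity/specificity/accuracy,
   image-grouped k-fold cross-validation with feature-set ablations
   (OP+RP, FOS+RP, GLCM+RP, NGTDM+RP, FD+RP, ALL), and annotation
   agreement statistics (ICC(2,1), Bland–Altman, regression).

The phantom module renders annular three-tissue geometries through the
same signal model with speckle, per-tissue texture fields, calcified
border rings and a guide-wire shadow; see `docs/methods.md` for the model
details and for what the phantom does and does not emulate.

## Worked example

```python
import numpy as np
from octplaq import (PhantomSpec, SystemParams, generate_phantom,
                     detect_guidewire_shadow, segment_lumen,
                     attenuation_map, estimate_noise_floor)
from octplaq.pipeline import make_study_stacks
from octplaq.evaluate import cross_validate

# render one three-tissue phantom frame and run the pipeline on it
sys_p = SystemParams()          # 96 A-lines, 10 um axial spacing
spec = PhantomSpec(
    tissue_sectors=((0.0, 130.0, 1, 1.2),    # fibrous sector
                    (130.0, 230.0, 2, 1.2),  # calcified sector
                    (230.0, 360.0, 3, 1.2)), # lipid sector
    guidewire_sector=(300.0, 320.0), seed=11)
img, truth, _ = generate_phantom(spec, sys=sys_p)

shadow = detect_guidewire_shadow(img)
boundary = segment_lumen(img, shadow)
print(f"guide-wire shadow: {shadow.sum()} of {img.n_alines} A-lines")
print(f"mean lumen radius: {np.mean(boundary) * sys_p.axial_spacing:.3f} mm")

maps = attenuation_map(img, boundary, sys_p,
                       noise_floor=estimate_noise_floor(img, boundary))
for lab, name in ((1, "fibrous"), (2, "calcified"), (3, "lipid")):
    sel = (truth.labels == lab) & maps.roi
    print(f"median mu_t {name:9s}: {np.nanmedian(maps.mu_t[sel]):.2f} mm^-1")

# a small multi-patient suite with image-grouped 5-fold cross-validation
stacks, _ = make_study_stacks(n_images=10, n_patients=5, seed=0)
report = cross_validate(stacks, k=5, feature_sets=("ALL",), seed=0)
print(report.summary.round(1).to_string())
```

prints

```
guide-wire shadow: 6 of 96 A-lines
mean lumen radius: 0.791 mm
median mu_t fibrous  : 1.94 mm^-1
median mu_t calcified: 3.54 mm^-1
median mu_t lipid    : 5.88 mm^-1
                       mean   sd  median
feature_set class
ALL         calcified  86.8  7.7    89.4
            fibrous    96.6  2.1    97.3
            lipid      87.6  6.9    88.2
```

The detector flags the simulated guide-wire sector, the DP contour
recovers the 0.8-mm lumen, and the median attenuation per sector tracks
the simulated tissue values (2.0, 3.2, 6.5 mm⁻¹ — the calcified median is
pulled up by its bright border rings, the lipid median down by deep
pixels near the noise floor).  The cross-validation table reports
per-class accuracy (mean per-image recall, %) over folds of whole images;
larger suites (see below) push all three classes above 90%.

## Command line

```sh
octplaq simulate --out data/frame0 --seed 0          # phantom dataset
octplaq segment  --in data/frame0 --out boundary.csv # DP lumen contour
octplaq features --in data/frame0 --out features.csv # 25-feature stack
octplaq train    --features features.csv --model model.bin --seed 7
octplaq predict  --model model.bin --in data/frame0 \
                 --features features.csv --out pred.png
octplaq evaluate --pred data/pred --truth data/frame0 --out report.csv
octplaq cv       --features-dir data/features --folds 10
```

All commands are deterministic given `--seed`: re-running produces
bit-identical TIFF/PNG/CSV outputs.

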