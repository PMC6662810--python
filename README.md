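# trabtex

Texture and shape analysis of low-magnification trabecular bone images for
two-class (control vs. estrogen-deficient) osteoporosis recognition.

At low optical magnification a whole bone-slice fits in one field of view,
but the trabecular network is too blurry for standard texture parameters
taken at a single direction and distance.  `trabtex` implements the full
recognition pipeline for this regime:

1. **Texture** — gray-level co-occurrence (GLCM) and run-length (GLRLM)
   matrices in the four raster directions (0°, 45°, 90°, 135°), yielding
   11 + 4 named parameters per direction;
2. **Direction weighting** — each matrix family's most direction-sensitive
   parameter (correlation for the GLCM at pixel distance 3, long run
   emphasis for the GLRLM) acts as a sentinel: its per-direction variation
   coefficients v(i,j) = |x(i,j) − x̄ᵢ| / x̄ᵢ are normalized into weights
   w(i,j) that collapse every parameter of the family to a weighted
   average p̄ᵢ = Σⱼ w(i,j) p(i,j);
3. **Shape** — six dimensionless ratios (solidity, regional density,
   correction rate, convexity, roundness, length–width ratio) and the
   seven Hu invariant moments of each trabecular ROI component,
   area-weighted into 13 image-level values;
4. **Feature selection** — the fused 28-feature table enters a sparse
   convex model that augments the Lasso loss with the intra-class
   dispersion of the selected-and-mapped features:

       min_b ‖Ab − Y‖₂² + ‖C₁∘b‖_F²/n₁ + ‖C₂∘b‖_F²/n₂ + λ₁‖b‖₁

   where Cₖ is class block k with its column means removed and ∘ scales
   column j by bⱼ.  The smooth part has gradient
   (2AᵀA + (2/n₁)D₁ + (2/n₂)D₂)b − 2AᵀY with Dₖ the diagonal of squared
   column norms of Cₖ, and the problem is solved by ISTA (proximal
   gradient with soft thresholding at step 1/L, L the top eigenvalue of
   that matrix).  Setting the dispersion terms to zero recovers the
   ordinary Lasso baseline;
5. **Evaluation** — a linear SVM under leave-one-out cross-validation,
   reporting ACC/SEN/SPE and Youden's index for six pipeline variants
   (TNS, TSNS, TYS, TSYS, TSYLS, TSYLC: plain vs. weighted texture, with
   or without shape, Lasso- vs. dispersion-selected).

Because the original rat tibial micrographs are not redistributable, the
package ships a synthetic generator producing two-class trabecular-like
images (thresholded Gaussian random fields) and labeled feature matrices
with known informative columns, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from trabtex import (DispersionLasso, extract_tables, gen_dataset,
                     run_all_variants)

images, masks, labels = gen_dataset(n_sham=10, n_ovx=8, seed=7)
tex_simple, tex_weighted, shape = extract_tables(images, masks)

model = DispersionLasso.from_dataframe(
    tex_weighted.join(shape).assign(label=labels), label_col="label")
print(model.fit().summary())
```

prints

```
Intra-class dispersion feature selection
========================================================
model:        dispersion-penalized lasso
samples:      n1=8, n2=10
features:     28
lambda1:      2.0522
Lipschitz L:  748.791
iterations:   1 (converged)
dispersion S: 135.815
support size: 2
--------------------------------------------------------
feature                             coef
mean_sum                        -0.89679
grey_level_nonuniformity         0.04001
========================================================
```

i.e. on this small synthetic set the selector keeps two texture
parameters and shrinks the other 26 coefficients to exactly zero under
the λ₁‖b‖₁ penalty.  The dominant one, the GLCM sum average (`mean_sum`),
is negative: OVX-coded images (the positive class) have a lower mean gray
sum, reflecting their sparser bone area.  λ₁ is picked by extended BIC
over a warm-started penalty path, so the final solve continues from the
path iterate (hence the single reported iteration).  The six
classification variants run with

```python
report = run_all_variants(tex_simple, tex_weighted, shape,
                          np.array(labels))
print({tag: round(entry["ACC"], 3) for tag, entry in report.items()})
# {'TNS': 1.0, 'TSNS': 1.0, 'TYS': 1.0, 'TSYS': 1.0, 'TSYLS': 1.0,
#  'TSYLC': 1.0}
```

(the default synthetic class contrast is strong, so LOOCV accuracy sits at
the ceiling; lower the generator's effect sizes to probe the ordering of
the variants).

The same pipeline is scriptable from the shell:

```bash
trabtex simulate --out ds/ --n-sham 34 --n-ovx 18 --seed 1
trabtex run-all --data ds/ --out report.json
```

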