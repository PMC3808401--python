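# finstripe

Automated species and sex identification of rock-dwelling Lake Malawi
cichlids (mbuna) from lateral photographs. The haplochromine species flocks
of the African great lakes are notoriously difficult to tell apart by eye —
closely related species differ mainly in coloration, stripe pattern and
body proportions, and much of the color variation is intra-specific.
`finstripe` implements a computer-vision + geometric-morphometrics pipeline
for this problem: it converts each background-masked photograph into a
compact numeric summary, appends landmark-based body-shape variables, and
evaluates how well statistical classifiers recover the class
(species × sex) labels. It is aimed at evolutionary biologists and
ichthyologists exploring automated identification, and at anyone who needs
the individual stages (palette features, F-score selection, GPA, repeated
holdout CV, Mantel tests) as a library.

## The method

Each image, with its background replaced by a magenta sentinel that all
stages ignore, is summarized by **48 features**:

* **42 color features** — the foreground is quantized into its k = 7 most
  frequent representative colors (k-means in RGB space); each is recorded
  as RGB and HSV, 7 × (3+3) = 42 values.
* **color ratio** — pixel count of the most frequent color over the second
  most frequent (600 brown vs 500 blue pixels → 1.2).
* **entropy** — Shannon entropy of the 8-bit grayscale histogram,
  H = −Σᵢ pᵢ log₂ pᵢ, a proxy for pattern complexity.
* **edge count** — Canny edge pixels divided by foreground pixels, which
  compensates for larger fish carrying longer edges.
* **line counts** — straight segments from a probabilistic Hough transform
  at 45° angular granularity, binned into horizontal / diagonal / vertical.

Features are screened by the **F-score**

F(i) = Σ_c (x̄ᵢ,c − x̄ᵢ)² / Σ_c Var_c(xᵢ),

keeping features with F ≥ 0.7. Body shape enters through **Generalized
Procrustes Analysis** of 17 landmarks per specimen (translation, unit
centroid size, rotation-only least-squares superimposition), whose 34
aligned coordinates are appended to give an 82-variable table. Classifiers
(RBF-kernel SVM; random forest with mtry = 14, 500 trees) are evaluated by
**repeated random subsampling**: 100 independent 80/20 splits, min/max
scaling fitted per split on the training rows only, all test predictions
pooled into a confusion matrix. Finally, pairwise **misclassification
rates** between classes can be tested against **Kimura two-parameter**
distances of mitochondrial ND2 sequences with a one-tailed **Mantel
permutation test** for negative association.

The original field photographs are not publicly available, so the package
ships a first-class synthetic generator (`finstripe.synth`) that emulates
their structure — elliptical bodies, class-specific 3-color palettes,
stripe bars, class-specific body heights, additive noise — and every stage
is specified and tested against it.

## Worked example

`examples/04_classification.py` builds six synthetic classes that share
three palettes pairwise and differ only in body depth, then classifies them
with and without the shape variables:

```
color+stripe only (48 vars): 74.2% (s.d. 10.7)
with shape variables (82 vars): 100.0% (s.d. 0.0)
pooled predictions: 120, overall accuracy 100.0%
```

Color features alone cannot separate a deep-bodied class from its
slender-bodied palette twin, so the 48-variable accuracy sits near the 75%
ceiling set by the palette groups; adding the 34 Procrustes coordinates
resolves the remaining pairs. The other scripts in `examples/` demonstrate
feature extraction, F-score selection, GPA and the Mantel test, each
printing the quantities it computes.

The same pipeline is available from the shell:

```bash
finstripe simulate --classes 12 --n-per-class 10 --seed 1 --out-dir data/
finstripe extract --images data/images --out features.csv
finstripe gpa --tps data/landmarks.tps --out shapes.csv
finstripe cv --features features.csv --labels data/labels.csv --classifier svm --out report/
```

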