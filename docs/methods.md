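# Methods

This note documents the models, conventions and numerical choices behind
`finstripe`, and what the synthetic tests do and do not demonstrate.

## Background masking

All stages share one convention: background pixels carry the sentinel
color magenta (255, 0, 255) and a boolean foreground mask is derived from
sentinel (in)equality. Statistics are computed over the mask only; the
edge detector additionally flattens the background to the sentinel's gray
level before filtering so that smoothing cannot bleed background content
into foreground edge counts. For lossless images the sentinel test is
exact; for JPEG input an L∞ tolerance of 8 intensity units absorbs
compression noise (chroma-subsampled JPEGs smear magenta further and
should be saved with subsampling disabled or re-masked).

`remove_background` is a contract, not an algorithm commitment: the
bundled reference segmenter estimates the background color from the image
border and thresholds Euclidean RGB distance (default 30) within a
user-supplied rectangle. Anything that preserves the majority of the true
subject — e.g. a GrabCut-class method — can be registered in
`SEGMENTERS`. An input that is already sentinel-masked passes through
unchanged, which also makes the operation idempotent. No automatic
mask-quality score is attempted; imperfect masks are the caller's
responsibility.

`normalize_colors` (per-channel linear stretch of foreground intensities
to [0, 255]) is deliberately off by default everywhere: image-wise
normalization makes colors inconsistent across photographs and degrades
classification, so it exists only as an explicit opt-in.

## Feature extraction

* **Palette (k = 7).** K-means in RGB space over foreground pixels,
  k-means++ initialization, fixed seed. Pixels are sorted
  lexicographically before clustering, making the palette a function of
  the pixel multiset — position-invariant and independent of raster
  layout. When the image holds ≤ 7 distinct colors they are returned
  exactly (descending by count, color value as tie-break) and the
  remaining slots are padded with the last color at count 0 so the
  feature vector length never varies. HSV entries are exact conversions
  of the stored RGB entries; all six channels are reported on [0, 1] so
  the 42 color features share a scale.
* **Color ratio.** count₀/count₁ of the two most frequent palette
  entries; undefined (NaN in the assembled vector, an error when called
  directly) for single-color foregrounds.
* **Entropy.** Base-2 Shannon entropy with 0·log 0 = 0, over the 256-bin
  histogram of the ITU-R BT.601 grayscale foreground; bounded by [0, 8]
  bits.
* **Edge count.** Canny (sigma 1.0, thresholds 50/150 on 8-bit
  intensities, all configurable) restricted to the foreground, divided by
  the foreground pixel count. The normalization makes the feature
  scale-decreasing: edge length grows linearly with body size, area
  quadratically.
* **Line counts.** Probabilistic Hough transform on the foreground edge
  map with normals sampled at 45° granularity (accumulator threshold 10,
  minimum length 15 px, maximum gap 3 px at the default 256×96 canvas
  scale — all configurable, since useful values depend on image scale).
  Segments are binned by endpoint angle: within 22.5° of 0° horizontal,
  within 22.5° of 90° vertical, the rest diagonal. The Hough stage is the
  only stochastic feature; it takes an explicit seed.

## Feature selection and scaling

The F-score generalizes the two-class form to |C| classes: the numerator
sums squared deviations of class means from the grand mean, the
denominator sums per-class sample variances (n_c − 1 denominator), which
requires every class to have at least two members. Selection keeps
features with F ≥ threshold (default 0.7; ≥ rather than > — no score in
practice sits exactly on the threshold). Selection applies to the 48
image features only; Procrustes coordinates are always retained. Scaling
is a per-feature linear map of the training min/max onto [0, 1] (or
[−1, 1]); test values are not clipped, constant features map to the lower
bound, and the map is always fitted on training rows only.

## Geometric morphometrics

TPS records (`LM=17`, 17 coordinate lines, optional `ID=`/`IMAGE=`/
`SCALE=`) are read verbatim; `flip_y` converts raster-digitised files to
Cartesian y-up. GPA centers each configuration, scales it to unit
centroid size, and iteratively rotates all configurations onto the
consensus (least-squares orthogonal rotation with the determinant
corrected to +1 — rotation only, no reflection, the standard GM
convention). The consensus is initialized from the first configuration,
re-centered and re-normalized each round, and iteration stops when it
moves less than 1e-10 in Frobenius norm (maximum 100 iterations; the
returned consensus is the plain mean of the aligned configurations). No
tangent-space projection is applied: the raw aligned coordinates, ordered
x₁,y₁,…,x₁₇,y₁₇ and named `ProcCoord_<k>x/y`, are the shape variables
appended to the image features (48 + 34 = 82).

## Classification protocol

Repetitions draw uniform unstratified partitions with
floor(test_fraction·n) test rows (floor(0.2·594) = 118, hence 11,800
pooled predictions at 100 repetitions). A repetition whose training rows
miss a class is redrawn and logged rather than silently scored. Scaling
— and per-repetition F-score selection, if enabled; it is off by default
because selection is normally done once globally — is fitted inside each
repetition. The SVM default is an RBF kernel with C = 10 and
gamma = "scale"; a small log-spaced (C, gamma) grid search on the
training rows is available behind `grid_search=True` but is not the
default, since a per-repetition grid multiplies cost ~75× for no benefit
on the synthetic conditions. The RF default is 500 trees with
mtry = min(14, p). Confusion matrices are laid out predicted × actual;
per-class accuracy is the diagonal over the column (actual-class) sum.

## Genetics link

The pairwise misclassification rate between classes i and j is the
symmetric pooled rate (count(i→j) + count(j→i)) / (total_i + total_j)
with a zero diagonal — one of several defensible constructions; it is the
package's fixed convention. K2P distances use pairwise deletion of
gap/ambiguity sites and raise a saturation error when 1−2P−Q ≤ 0 or
1−2Q ≤ 0. The Mantel statistic is the Pearson correlation of
upper-triangle entries, with rows/columns of the second matrix permuted
jointly; the default alternative is one-tailed negative (the
biologically motivated direction: confusions concentrate between close
relatives) with 9,999 permutations and p = (exceedances + 1)/(n + 1).

## Synthetic study conditions

The generator emulates the structure of the original field photographs —
roughly 1100×400 px lateral views on a uniform background — at 256×96 px
for test speed. Twelve default classes named after the study composition
(gm_f … toc_m) each carry a 3-color palette (55/30/15% proportions), 0–4
stripe bars of width body_width/(2·stripes+1), body heights 40–72 px at
width 200 px, landmark noise 1.5 px and color noise s.d. 6 — values
chosen once as plausible stand-ins for within-class photographic
variation. Stripes are drawn in the RGB complement of the dominant color,
replaced by a dark/light bar when the complement's luminance contrast
(< 80) would be invisible to the edge detector. Landmarks scale a generic
17-point lateral-fish template (mouth tip 1; dorsal and ventral midpoints
5 and 10 tracking body height) to the body box. Two purpose-built spec
sets exist alongside: `disjoint_palette_specs` (12 hue-spaced palettes,
for near-ceiling color-only classification) and
`shape_differentiated_specs` (3 shared palettes × 2 body depths, where
only the shape variables can resolve the pairs).

What the generator does **not** emulate: pose and illumination variation,
fin damage, gradual color morphs, photographic blur, or imperfect
segmentation masks. Passing tests therefore demonstrate that the pipeline
recovers the signal it is designed to measure when that signal is
present and the mask is correct — not that field accuracy on live fishes
would match.

Test and acceptance runs use deliberately modest problem sizes (6–10
specimens per class, 10 CV repetitions, 50–200 RF trees) so the whole
suite runs in minutes on one CPU; all sizes are parameters.

## Known limitations

* The Hough stage is scale-sensitive; its defaults suit the synthetic
  canvas and must be retuned for full-resolution photographs.
* K-means palettes on heavily noisy images depend mildly on the seed;
  the seed is therefore part of the extractor configuration.
* The misclassification-rate construction and the K2P inputs fix one
  convention each; alternative symmetrizations will shift Mantel r.
* `remove_background`'s reference segmenter assumes a roughly uniform
  background; textured backgrounds need a plugged-in segmenter.
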