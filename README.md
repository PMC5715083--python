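# glandbam

Glandular morphometrics for colorectal tissue images: shape analysis of
segmented glands with the **Best Alignment Metric (BAM)** and SVM-based
grading into normal / low-grade / high-grade tumour.

Colorectal adenocarcinoma is graded largely by the degree of gland
formation.  Healthy colonic crypts are tubular, so a tissue section shows
them as near-elliptical blobs; tumour progression deforms the gland
boundaries.  Given an integer label mask of segmented glands (e.g. the
output of any gland-segmentation model), `glandbam` measures each gland's
deviation from ellipticity, summarizes an image by three features, and
grades it — all downstream of segmentation, which is out of scope here.

## The metric and the pipeline

A *shape* is a closed curve up to translation, rotation and cyclic
re-parametrization.  For curves represented by N equally spaced, zero-mean
complex points the BAM distance is

```
d([u],[v]) = sqrt( (1/N) · min_{r,θ} Σ_j |v_j − e^{iθ} u_{j+r}|² ),
```

minimized over all cyclic shifts r and rotations θ — computed in
O(N log N) via a closed-form rotation per shift and one FFT
cross-correlation, and verified against a brute-force grid search.

The per-gland **aberrance** (BAM value) is computed in three steps:

1. fit the minimum-area enclosing ellipse of the boundary and apply the
   whitening map that turns that ellipse into a circle (this removes the
   effect of the angle at which the section cuts the tubular gland);
2. normalize both curves to unit perimeter, zero mean, N = 128 points;
3. aberrance = BAM distance between them.

Ellipses of any pose score ≈ 0; deformed glands score up to ~0.1.  Per
image, three features summarize the gland population: **mean BAM**, **BAM
entropy** (Shannon entropy of the aberrance histogram, bin step 0.015)
and the **Regularity Index** (fraction of glands in the first two bins).
A postprocessing step removes tangential crypt sections and border-clipped
glands from normal-looking images before grading.  Grading is a
standardized RBF-kernel SVM evaluated by repeated stratified 3-fold
cross-validation.

## Worked example

No public per-gland mask dataset with grade labels exists, so the package
ships a synthetic generator (ellipse base × radial harmonics, with
grade-controlled deformation amplitude and injectable tangential/border
artifacts).  `examples/synthetic_grading.py` generates 6 images per grade
and runs the full pipeline:

```
$ python examples/synthetic_grading.py
            mean_bam  bam_entropy  regularity_index
label
high_grade    0.0363       1.2109            0.3751
low_grade     0.0122       0.5383            1.0000
normal        0.0011       0.0000            1.0000

3-class accuracy: 100.0% ± 0.0% (mean ± sd over fold x repeat runs)
```

Mean BAM rises with grade while the Regularity Index falls, and on this
cleanly separated synthetic data the cross-validated classifier is
perfect.  The other examples show the metric itself
(`bam_basics.py`), single-gland scoring (`gland_aberrance.py`) and
artifact removal (`artifact_postprocessing.py`), each printing a line on
what its numbers mean.

A thin CLI covers the same ground from a shell:

```bash
glandbam synth --out masks/ --n-per-grade 20 20 20 --seed 0
glandbam run --masks masks/ --labels masks/labels.csv --out results/
```

writing `glands.csv` (per-gland aberrance), `features_pre.csv` /
`features_post.csv` (per-image features) and `report.json`
(cross-validated metrics, confusion matrix, AUCs).  `glandbam
postprocess-mask` converts a gland-probability map into a clean label
mask first, if that is what your segmenter produces.

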