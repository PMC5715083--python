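# Methods

## The problem

Colorectal adenocarcinoma is graded in large part by how well the tumour
forms glands.  Healthy colonic crypts are tubular, so a tissue section
shows them as near-elliptical blobs; as grade increases, gland boundaries
deform and eventually disintegrate.  `glandbam` quantifies this with a
single per-gland number — the *aberrance* — and aggregates it into
per-image features that a conventional classifier can grade.

The package operates downstream of segmentation: its input is an integer
label mask (one positive label per gland section), or a gland-probability
map that it first converts into such a mask (threshold, small-object
removal, hole filling, and one binary opening to separate slightly merged
objects — note an opening cannot split heavily merged glands, because the
dilation half re-joins what the erosion cut; the `watershed_split` flag
substitutes a distance-transform watershed that cuts merged objects at
their necks).

## The Best Alignment Metric (BAM)

A *shape* is an equivalence class of simple closed planar curves under
translation, rotation and cyclic re-parametrization.  Reflection is
deliberately **not** in the class; curves are canonicalized to
counter-clockwise orientation (positive shoelace area in the x = column,
y = row pixel frame) before comparison.

Discretely, a curve is N points equally spaced by arc length, treated as
complex numbers `u_0..u_{N-1}` with zero mean and unit perimeter.  The
distance between shapes [u] and [v] is

```
d([u],[v]) = sqrt( (1/N) * min_{r, θ}  Σ_j |v_j − e^{iθ} u_{j+r}|² )
```

with j + r mod N, r over all N cyclic shifts and θ over [0, 2π).

**Fast evaluation.**  For fixed r the optimal rotation is closed-form:
with `c(r) = Σ_j v_j conj(u_{j+r})`, the best angle is `θ*(r) = arg c(r)`
and the objective becomes `Σ|u|² + Σ|v|² − 2|c(r)|`; the whole vector
`c(·)` is one circular cross-correlation, computed with the FFT in
O(N log N).  The final distance is then re-evaluated directly as the root
mean squared residual at the chosen (r, θ*) — a sum of non-negative terms —
so identical shapes score exactly 0 instead of the ~1e-9 cancellation floor
of the subtractive form.  An exhaustive evaluator over all shifts and a
uniform θ grid (`bam_distance_bruteforce`) is kept as an independent
oracle; the fast path agrees with a 4096-point grid to < 1e-6 on random
shape pairs.

Tie-breaks: among shifts with equal |c(r)| the smallest r wins; if
c(r) = 0 at the optimum (disjoint Fourier support), every rotation is
optimal, θ is reported as 0 and the alignment is flagged.

## Glandular aberrance

For a gland boundary u:

1. **Whitening.**  Fit the minimum-area enclosing ellipse (MVEE) v of u,
   then apply to u the affine map that turns v into a circle: translate
   the center to the origin, rotate the major axis onto +x, scale x by
   √(b/a) and y by √(a/b).  The geometric-mean target radius √(ab) is
   area-preserving; the choice is immaterial because the next step
   rescales to unit perimeter (verified: target radius a, b or √(ab)
   changes the result by < 1e-9).  Whitening removes the anisotropy of
   the angle at which the section plane cuts the tubular gland, which is
   why an anisotropic stretch of the input (ratio ≤ 2) changes the
   aberrance by well under 20 % — in practice by ~0, up to resampling
   noise.
2. **Normalization.**  Resample both the whitened boundary and the circle
   to N points (default 128, a power of two for the FFT), rescale to unit
   perimeter, subtract the mean.  The circle's representative is the
   regular N-gon of unit perimeter (radius `1/(2N sin(π/N))` → 1/(2π));
   discretizing it exactly like the boundary keeps a perfect ellipse at
   the resampling noise floor.  Its starting phase is irrelevant — the
   metric minimizes over shift and rotation (verified to 1e-9).
3. **Distance.**  The aberrance is `d([u],[v])`.

Ellipses of any pose and axis ratio ≤ 5 score < 1e-3 even after
rasterization; realistic deformed glands score up to ~0.1.  The value is
invariant under similarity transforms of the input contour (< 1e-6).

## Contour extraction

Each label's outer boundary is traced at sub-pixel precision by marching
squares on the 0.5 level of its indicator (binary masks are first
relabeled by 8-connected components); interior holes (lumina) are ignored
since the analysis concerns only the boundary curve.  Marching squares on
a binary image leaves a half-pixel staircase worth up to ~2.5e-3 of
spurious aberrance on thin glands, so the polygon is smoothed with a short
periodic moving average (default 15 vertices ≈ 10 px of arc, capped at a
sixth of the contour).  At realistic gland sizes this attenuates genuine
harmonic deformation of order ≤ 8 by under ~15 % while cutting the
rasterization floor to < 1e-3.  Boundaries with fewer than `min_vertices`
(default 8) points are geometric noise and skipped with a warning.  A
gland `touches_border` when any of its pixels lies within 2 px of the
image edge (tolerant of 1-px mask erosion).

## Minimum-area enclosing ellipse

Khachiyan-style iterative reweighting on the lifted points, run on the
convex-hull vertices only (the MVEE depends on nothing else) after
centering and scaling for conditioning.  Plain add/away steps zig-zag
indefinitely between clustered hull vertices of rasterized contours, so
each iteration performs a *pairwise* step — weight moves from the
least-sensitive support point to the worst violator with an exact line
search on the rank-two log-det update.  Convergence is certified by the
duality gap (default tolerance 1e-5, iteration cap 1e5), which bounds the
area suboptimality by ~1.5e-5 — three orders below every downstream
tolerance; near-optimal iterates on jagged near-elliptical point sets
show gaps of ~3e-6 that never certify much tighter than this even when
the log-det is optimal to < 1e-6, which is why the tolerance is not set
lower.  After convergence the ellipse is inflated by the worst residual
quadratic form, so containment of every input point holds exactly (to
float precision) regardless of the gap.  The inner loop is compiled with
numba; a pure-Python twin of the same function is the importable fallback
and the readable reference.

## Image-level features

* **mean BAM** — arithmetic mean of per-gland aberrance.
* **BAM entropy** — Shannon entropy (natural log; the base only rescales
  a feature that is standardized before classification) of the histogram
  of aberrance values.  Bins are fixed at start 0, step 0.015, 7 bins
  (covering [0, 0.105), matching the observed [0, 0.1] range), the last
  bin absorbing overflow; empty bins contribute nothing.  Fixed edges
  keep the feature comparable across images and runs; a value sitting on
  a boundary within 1e-9 of a step is assigned to the upper bin to absorb
  decimal-float noise.
* **Regularity Index (RI)** — fraction of glands in the first two bins
  (aberrance < 0.03).  Near 1 for healthy images.

Feature Set 1 = {mean BAM, BAM entropy}; Feature Set 2 adds RI.

Fixed edges are the default; `data_driven_bins` derives the bin count from
an observed value range at the same step, for experiments that want edges
tied to the dataset at hand.

**Postprocessing.**  Two artifacts inflate normal images' features:
small tangential crypt sections (the section plane clips a crypt near its
tip) and glands cut by the image border.  Images whose *pre-processing*
RI exceeds a threshold (default 0.5) are treated as normal; in those
images glands with area below a threshold (default 3000 px², an absolute
value appropriate for ~0.275 µm/px at 20×) are excluded as tangential
sections and border-touching glands are excluded, then the features are
recomputed.  The area rule is checked before the border rule, so a small
border gland is recorded as a tangential exclusion.  Both thresholds are
empirical and configurable; a scale-free mode (`relative_area`) replaces
the absolute threshold with a fraction of the median gland area.

## Grading

Two tasks: normal vs cancer (low and high grade merged) and normal vs low
vs high grade, on Feature Set 1 or 2.  Features are standardized with
training-fold statistics; the classifier is a support-vector machine with
an RBF kernel (C = 1, γ = 1/(n_features · pooled variance), i.e. ~1/d
after standardization — the defaults are deliberate, not tuned).
Evaluation is stratified 3-fold cross-validation repeated 10 times with
per-repeat reshuffling, at the image level; metrics (accuracy, per-class
precision, recall, specificity, F1) are reported as mean ± sd over
fold × repeat runs, with one-vs-rest decision scores pooled across folds
for ROC/AUC.  Three-class predictions can be collapsed into two binary
views — "cancer" (low + high positive) and "high grade" (normal + low
negative).  A Kruskal-Wallis rank test (tie-corrected, χ² approximation)
checks that each feature separates the grade groups.  A small grid search
over (C, γ) is available (`grid_search_hyperparameters`) but off by
default: the fixed defaults keep runs deterministic and comparable.

## Synthetic data generator

No suitable public dataset of per-gland label masks with grade labels
exists, so the generator emulates the relevant structure of graded tissue
images.  Each gland boundary is a polar model around an ellipse:

```
r(φ) = r_ellipse(φ) · (1 + Σ_k a_k cos(kφ + ψ_k))
```

with 2–4 harmonics of orders 2–8 and a total amplitude drawn from the
grade's range — normal [0, 0.03], low grade [0.08, 0.18], high grade
[0.2, 0.45].  The ranges are disjoint and increasing, chosen so the
resulting aberrance lands inside the observed [0, 0.1] band; the positive
radial factor keeps every curve star-shaped, hence simple.  Defaults:
1024 × 1024 px images, 40–60 glands each, base semi-major radius
38–55 px, eccentricity up to 0.55 — sized so every regular gland clears
the 3000 px² tangential threshold with margin even after rasterization.
Placement is rejection sampling with ≥ 5 px boundary separation; failures
after the retry cap just reduce the gland count (logged).  Normal images
receive a configurable fraction (default 5 % each) of injected artifacts:
tangential sections (shrunk to 800–1800 px², strongly deformed) and
border glands (centered within 0.2–0.6 of their radius from an edge so
they clip).  A manifest records every gland's role, which is what lets
the tests assert that postprocessing removes *exactly* the injected
artifacts.

What the generator does **not** emulate: segmentation errors (merged or
fragmented glands), lumen holes, stromal texture, staining variation, or
the gradual boundary disintegration of real high-grade tumours (it always
produces closed star-shaped curves).  Passing tests therefore demonstrate
the correctness and internal consistency of the morphometric machinery
under the stated shape model — not clinical performance.  In particular,
grading accuracy on this synthetic data is near-perfect because the
deformation regimes are disjoint by construction; on real data the grade
classes overlap and accuracy is necessarily lower.

## Problem sizes and numerical choices

The bundled study uses 60 images per grade (180 total, ~9000 glands),
generated and analysed in a few minutes on one CPU; group-separation
statistics use the first 30 images per grade.  Oracle comparisons use a
4096-point rotation grid, whose worst-case discretization error near the
optimum (O(Δθ²) on the squared distance) sits well below the 1e-6
comparison band for genuinely distinct shapes.  Determinism: every
stochastic step (generator, fold shuffling, SVM) is driven by an explicit
seed, and identical inputs and configuration reproduce outputs
byte-for-byte.

## Known limitations

* Reflection is outside the equivalence class; a mirrored gland can score
  a large distance against its original.  This follows the printed
  definition of the metric; segmentation masks do not produce mirrored
  duplicates, so the practical impact is nil.
* Aberrance of a *convex but non-elliptical* shape (e.g. a rectangle) is
  moderate, not zero — the metric measures deviation from ellipticity,
  not convexity.
* The per-gland failure policy (flag and continue) means an image's
  features can rest on fewer glands than were segmented; the `n_glands`
  column records how many actually contributed.
* The fixed histogram edges assume aberrance values of at most ~0.105;
  grossly larger values all land in the overflow bin, flattening the
  entropy's resolution there.
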