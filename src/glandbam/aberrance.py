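"""Per-gland aberrance: from a boundary curve to its BAM value.

The aberrance of a gland quantifies how far its boundary deviates from the
ideal elliptical cross-section of a healthy tubular crypt:

1. fit the minimum-area enclosing ellipse (MVEE) of the boundary and apply
   the whitening transform that turns that ellipse into a circle to the
   boundary itself — this removes the anisotropy introduced by the angle at
   which the section cuts through the tube;
2. normalize both the whitened boundary and the circle to unit perimeter,
   zero mean and N sampling points;
3. the aberrance is the BAM distance between the two shapes.

A perfectly elliptical gland therefore scores ~0 regardless of its
eccentricity, position or orientation; deformation of the boundary raises
the score.  Typical values for real glands fall in roughly [0, 0.1].

The module also converts continuous gland-probability maps into clean label
masks (thresholding plus morphological cleanup).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .bam import bam_distance
from .exceptions import (
    ConvergenceError,
    DegenerateCurveError,
    DegenerateInputError,
    InvalidInputError,
)
from .geometry import (
    Curve,
    GlandRecord,
    NormalizedShape,
    apply_transform,
    baseline_shape_features,
    ellipse_whitening,
    extract_gland_contours,
    min_area_enclosing_ellipse,
    normalize_shape,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AberranceConfig",
    "circle_shape",
    "gland_aberrance",
    "image_aberrance_table",
    "postprocess_probability_map",
]


@dataclass(frozen=True)
class AberranceConfig:
    """Tunables of the per-gland pipeline and mask cleanup.

    N           number of sampling points per shape (power of two recommended
                for fast correlation).
    mvee_tol    relative tolerance of the enclosing-ellipse solver.
    prob_threshold, min_object_area, fill_holes, opening_radius
                probability-map cleanup: binarization threshold, smallest
                object kept (px^2), hole filling, and the disk radius of the
                single opening pass that separates slightly merged objects.
    min_vertices, border_margin, smooth_window
                contour extraction: smallest usable boundary, border-gland
                margin (px) and boundary smoothing window.
    """

    N: int = 128
    mvee_tol: float = 1e-5
    prob_threshold: float = 0.5
    min_object_area: int = 300
    fill_holes: bool = True
    opening_radius: int = 3
    watershed_split: bool = False
    min_vertices: int = 8
    border_margin: int = 2
    smooth_window: int = 15

    def __post_init__(self):
        if self.N < 8:
            raise InvalidInputError(f"N must be >= 8, got {self.N}")
        if not (0.0 < self.prob_threshold < 1.0):
            raise InvalidInputError("prob_threshold must be in (0, 1)")
        if self.mvee_tol <= 0:
            raise InvalidInputError("mvee_tol must be positive")


def circle_shape(n: int) -> NormalizedShape:
    """The normalized circle: a regular CCW n-gon with unit perimeter, zero mean.

    This is what any ellipse becomes after whitening and normalization.  Its
    radius 1/(2*n*sin(pi/n)) tends to 1/(2*pi) as n grows; discretizing the
    circle exactly like the gland boundary keeps the aberrance of a perfect
    ellipse at the resampling-noise floor.  The starting phase is irrelevant:
    the metric minimizes over cyclic shift and rotation.
    """
    t = 2 * np.pi * np.arange(n) / n
    r = 1.0 / (2.0 * n * np.sin(np.pi / n))
    return NormalizedShape(np.column_stack([r * np.cos(t), r * np.sin(t)]))


def gland_aberrance(contour: Curve, config: AberranceConfig = AberranceConfig()) -> float:
    """BAM value of one gland boundary (see module docstring for the steps).

    Raises :class:`DegenerateCurveError` / :class:`DegenerateInputError` /
    :class:`ConvergenceError` for contours the pipeline cannot handle; image
    level callers catch these and flag the gland instead of aborting.
    """
    ellipse = min_area_enclosing_ellipse(contour.points, tol=config.mvee_tol)
    whitening = ellipse_whitening(ellipse)
    whitened = apply_transform(contour, whitening)
    u = normalize_shape(whitened, config.N)
    v = circle_shape(config.N)
    return bam_distance(u, v)


def image_aberrance_table(
    mask: np.ndarray,
    image_id: str = "",
    config: AberranceConfig = AberranceConfig(),
    include_baseline: bool = False,
) -> list[GlandRecord]:
    """Extract all gland contours of a label mask and score each one.

    Per-gland failures (degenerate contours, non-convergent ellipse fits)
    leave ``aberrance = None`` and are logged; the image is never aborted.
    """
    records = extract_gland_contours(
        mask,
        image_id=image_id,
        min_vertices=config.min_vertices,
        border_margin=config.border_margin,
        smooth_window=config.smooth_window,
    )
    for rec in records:
        try:
            rec.aberrance = gland_aberrance(rec.contour, config)
        except (DegenerateCurveError, DegenerateInputError, ConvergenceError) as exc:
            logger.warning(
                "gland %s in image %s: aberrance undefined (%s)",
                rec.gland_id, image_id, exc,
            )
            rec.aberrance = None
        if include_baseline:
            try:
                rec.baseline = baseline_shape_features(rec.contour, rec.area)
            except (DegenerateCurveError, DegenerateInputError) as exc:
                logger.warning(
                    "gland %s in image %s: baseline features undefined (%s)",
                    rec.gland_id, image_id, exc,
                )
    return records


def postprocess_probability_map(
    prob: np.ndarray, config: AberranceConfig = AberranceConfig()
) -> np.ndarray:
    """Convert a gland-probability map into a clean integer label mask.

    Threshold at ``prob_threshold``, drop objects smaller than
    ``min_object_area``, optionally fill holes, separate slightly merged
    objects with one binary opening (disk of ``opening_radius``), and label
    the result by 8-connected components.  With ``watershed_split`` a
    distance-transform watershed is used instead of the opening to cut
    merged objects at their necks.
    """
    prob = np.asarray(prob, dtype=float)
    if prob.ndim != 2:
        raise InvalidInputError("probability map must be 2-D")
    if prob.min() < 0.0 or prob.max() > 1.0:
        raise InvalidInputError("probability values must lie in [0, 1]")
    binary = prob >= config.prob_threshold
    if config.min_object_area > 0:
        labeled = measure.label(binary, connectivity=2)
        areas = np.bincount(labeled.ravel())
        keep = areas >= config.min_object_area
        keep[0] = False
        binary = keep[labeled]
    if config.fill_holes:
        binary = ndimage.binary_fill_holes(binary)
    if config.watershed_split:
        from skimage.feature import peak_local_max
        from skimage.segmentation import watershed

        distance = ndimage.distance_transform_edt(binary)
        coords = peak_local_max(
            distance, labels=measure.label(binary, connectivity=2),
            min_distance=max(config.opening_radius * 2, 5),
        )
        peaks = np.zeros(binary.shape, dtype=bool)
        peaks[tuple(coords.T)] = True
        markers, _ = ndimage.label(peaks)
        return watershed(-distance, markers, mask=binary).astype(np.int32)
    if config.opening_radius > 0:
        binary = morphology.opening(binary, morphology.disk(config.opening_radius))
    return measure.label(binary, connectivity=2)
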