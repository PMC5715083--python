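"""Geometric primitives for gland-shape analysis.

Coordinate convention (used throughout the package): 0-based pixel indices
with ``x`` = column and ``y`` = row, so ``y`` increases downward.
Counter-clockwise (CCW) is *defined* as positive signed area under the
shoelace formula in this frame.  All boundary curves are canonicalized to
CCW before any shape comparison, because the alignment metric does not
minimize over traversal reversal.

The module provides:

* :class:`Curve`, :class:`NormalizedShape`, :class:`Ellipse`,
  :class:`WhiteningTransform`, :class:`GlandRecord` containers;
* contour extraction from integer label masks (sub-pixel marching squares);
* arc-length resampling and shape normalization (unit perimeter, zero mean);
* the minimum-area enclosing ellipse (MVEE) via Khachiyan-style iterative
  reweighting with pairwise Frank-Wolfe steps;
* the whitening transform that maps an ellipse onto a circle;
* classical baseline shape descriptors (roundness, aspect ratio, elongation,
  solidity, convexity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .exceptions import (
    ConvergenceError,
    DegenerateCurveError,
    DegenerateInputError,
    InvalidInputError,
    InvalidTransformError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Curve",
    "NormalizedShape",
    "Ellipse",
    "WhiteningTransform",
    "GlandRecord",
    "signed_area",
    "perimeter",
    "canonical_orientation",
    "resample_closed_curve",
    "normalize_shape",
    "min_area_enclosing_ellipse",
    "ellipse_whitening",
    "apply_transform",
    "extract_gland_contours",
    "baseline_shape_features",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError(f"points must be an (n, 2) array, got shape {pts.shape}")
    return pts


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (positive = CCW here)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(points: np.ndarray) -> float:
    """Perimeter of the closed polygon through ``points`` (last→first included)."""
    d = np.roll(points, -1, axis=0) - points
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


@dataclass(frozen=True)
class Curve:
    """A simple closed planar curve given by a cyclic vertex sequence.

    Consecutive duplicate vertices are rejected; the closing edge
    (last → first vertex) is implicit.
    """

    points: np.ndarray

    def __post_init__(self):
        pts = _as_points(self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise InvalidInputError("a curve needs at least 3 points")
        seg = np.roll(pts, -1, axis=0) - pts
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seglen == 0.0):
            raise InvalidInputError("consecutive duplicate points in curve")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("non-finite coordinates in curve")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        return perimeter(self.points)

    @property
    def signed_area(self) -> float:
        return signed_area(self.points)

    @property
    def is_ccw(self) -> bool:
        return self.signed_area > 0


@dataclass(frozen=True)
class NormalizedShape:
    """A shape representative: N equally spaced points, zero mean, unit perimeter.

    This is the discrete representation fed to the alignment metric: points
    are equally spaced by arc length along the source curve, the polygon
    perimeter is exactly 1 and the vertex mean sits at the origin.  The
    orientation is canonically counter-clockwise.
    """

    points: np.ndarray

    def __post_init__(self):
        pts = _as_points(self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise InvalidInputError("a normalized shape needs at least 3 points")
        per = perimeter(pts)
        if abs(per - 1.0) > 1e-6:
            raise InvalidInputError(f"normalized shape perimeter {per} != 1")
        mean = pts.mean(axis=0)
        if np.hypot(*mean) > 1e-9:
            raise InvalidInputError(f"normalized shape mean {mean} != origin")
        if signed_area(pts) <= 0:
            raise InvalidInputError("normalized shape must be counter-clockwise")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def as_complex(self) -> np.ndarray:
        return self.points[:, 0] + 1j * self.points[:, 1]


@dataclass(frozen=True)
class Ellipse:
    """An ellipse: center, semi-axes (a >= b), major-axis angle in [0, pi)."""

    center: np.ndarray
    a: float
    b: float
    angle: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float).reshape(2)
        object.__setattr__(self, "center", c)
        if not (self.a >= self.b > 0):
            raise InvalidInputError(f"ellipse axes must satisfy a >= b > 0, got {self.a}, {self.b}")
        object.__setattr__(self, "angle", float(self.angle) % np.pi)

    @property
    def area(self) -> float:
        return np.pi * self.a * self.b

    def boundary(self, n: int = 256) -> np.ndarray:
        """``n`` points on the ellipse boundary (uniform in parametric angle)."""
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        return np.column_stack([self.center[0] + ca * x - sa * y,
                                self.center[1] + sa * x + ca * y])

    def quadratic_form(self, points) -> np.ndarray:
        """Evaluate (p-c)^T A (p-c); boundary points give 1, interior < 1."""
        pts = _as_points(points) - self.center
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        # rotate into the ellipse frame
        u = ca * pts[:, 0] + sa * pts[:, 1]
        v = -sa * pts[:, 0] + ca * pts[:, 1]
        return (u / self.a) ** 2 + (v / self.b) ** 2

    def contains(self, points, tol: float = 1e-7) -> bool:
        return bool(np.all(self.quadratic_form(points) <= 1.0 + tol))


@dataclass(frozen=True)
class WhiteningTransform:
    """Affine map p -> linear @ (p + offset) that turns an ellipse into a circle."""

    linear: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        lin = np.asarray(self.linear, dtype=float).reshape(2, 2)
        off = np.asarray(self.offset, dtype=float).reshape(2)
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "offset", off)

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        return (pts + self.offset) @ self.linear.T

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.linear))


@dataclass
class GlandRecord:
    """Per-gland bookkeeping: contour, size, location, aberrance, exclusions."""

    gland_id: int
    image_id: str
    contour: Curve
    area: float
    centroid: np.ndarray
    touches_border: bool
    aberrance: float | None = None
    excluded: bool = False
    exclusion_reason: str = "none"
    baseline: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.area <= 0:
            raise InvalidInputError("gland area must be positive")
        if self.excluded and self.exclusion_reason == "none":
            raise InvalidInputError("excluded gland needs an exclusion_reason")


# ---------------------------------------------------------------------------
# curve operations
# ---------------------------------------------------------------------------


def canonical_orientation(curve: Curve) -> Curve:
    """Return the curve traversed counter-clockwise (positive shoelace area).

    The point set is unchanged; only the traversal order may be reversed.
    Raises :class:`DegenerateCurveError` for zero signed area.
    """
    area = curve.signed_area
    if area == 0.0:
        raise DegenerateCurveError("curve has zero signed area (collinear/degenerate)")
    if area > 0:
        return curve
    return Curve(curve.points[::-1].copy())


def resample_closed_curve(curve: Curve, n: int) -> Curve:
    """Resample a closed polyline at ``n`` equal arc-length positions.

    Positions are k*L/n (k = 0..n-1) measured from the curve's first vertex,
    so the first output point equals the first input vertex.
    """
    if n < 3:
        raise InvalidInputError(f"need n >= 3 sample points, got {n}")
    pts = curve.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])  # arc length at each vertex
    total = s[-1]
    targets = np.arange(n) * (total / n)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    out = np.column_stack([x, y])
    # guard against numerically coincident neighbours on very dense inputs
    d = np.roll(out, -1, axis=0) - out
    if np.any(np.hypot(d[:, 0], d[:, 1]) == 0.0):
        raise DegenerateCurveError("resampling produced duplicate points")
    return Curve(out)


def normalize_shape(curve: Curve, n: int = 128) -> NormalizedShape:
    """Map a curve to its shape representative: CCW, n points, unit perimeter, zero mean.

    The scaling divides by the perimeter of the *resampled* polygon, so the
    representative's polygon perimeter is exactly 1 (an n-gon inscribed in the
    source curve).  Equal arc-length spacing holds along the source curve by
    construction.
    """
    ccw = canonical_orientation(curve)
    res = resample_closed_curve(ccw, n)
    pts = res.points / perimeter(res.points)
    pts = pts - pts.mean(axis=0)
    return NormalizedShape(pts)


# ---------------------------------------------------------------------------
# minimum-area enclosing ellipse (MVEE)
# ---------------------------------------------------------------------------


def _mvee_core_py(Q: np.ndarray, tol: float, max_iter: int):
    """Pairwise Frank-Wolfe core on lifted points Q (n, 3).

    Moves weight from the least-sensitive support point to the worst
    violator with an exact line search on the rank-two log-det update;
    this avoids the zig-zag stalls of pure add/away steps on clustered
    hull vertices.  Returns (weights, achieved gap, status) with status
    0 = converged, 1 = iteration cap or float-precision stall,
    2 = degenerate input."""
    n = Q.shape[0]
    dp1 = 3.0
    u = np.full(n, 1.0 / n)
    achieved = np.inf
    for _ in range(max_iter):
        X = np.zeros((3, 3))
        for i in range(n):
            w = u[i]
            if w > 0.0:
                for a in range(3):
                    qa = w * Q[i, a]
                    for b in range(3):
                        X[a, b] += qa * Q[i, b]
        # closed-form 3x3 inverse via the adjugate
        det = (
            X[0, 0] * (X[1, 1] * X[2, 2] - X[1, 2] * X[2, 1])
            - X[0, 1] * (X[1, 0] * X[2, 2] - X[1, 2] * X[2, 0])
            + X[0, 2] * (X[1, 0] * X[2, 1] - X[1, 1] * X[2, 0])
        )
        if det == 0.0 or not np.isfinite(det):
            return u, achieved, 2  # degenerate
        Xi = np.empty((3, 3))
        Xi[0, 0] = (X[1, 1] * X[2, 2] - X[1, 2] * X[2, 1]) / det
        Xi[0, 1] = (X[0, 2] * X[2, 1] - X[0, 1] * X[2, 2]) / det
        Xi[0, 2] = (X[0, 1] * X[1, 2] - X[0, 2] * X[1, 1]) / det
        Xi[1, 0] = (X[1, 2] * X[2, 0] - X[1, 0] * X[2, 2]) / det
        Xi[1, 1] = (X[0, 0] * X[2, 2] - X[0, 2] * X[2, 0]) / det
        Xi[1, 2] = (X[0, 2] * X[1, 0] - X[0, 0] * X[1, 2]) / det
        Xi[2, 0] = (X[1, 0] * X[2, 1] - X[1, 1] * X[2, 0]) / det
        Xi[2, 1] = (X[0, 1] * X[2, 0] - X[0, 0] * X[2, 1]) / det
        Xi[2, 2] = (X[0, 0] * X[1, 1] - X[0, 1] * X[1, 0]) / det
        jp = 0
        mp = -np.inf
        jm = 0
        mm = np.inf
        for i in range(n):
            mi = 0.0
            for a in range(3):
                ra = 0.0
                for b in range(3):
                    ra += Xi[a, b] * Q[i, b]
                mi += Q[i, a] * ra
            if mi > mp:
                mp = mi
                jp = i
            if u[i] > 1e-12 and mi < mm:
                mm = mi
                jm = i
        achieved = max(mp / dp1 - 1.0, 1.0 - mm / dp1)
        if achieved <= tol:
            return u, achieved, 0
        mpm = 0.0
        for a in range(3):
            ra = 0.0
            for b in range(3):
                ra += Xi[a, b] * Q[jm, b]
            mpm += Q[jp, a] * ra
        denom = mp * mm - mpm * mpm
        lam = (mp - mm) / (2.0 * denom) if denom > 1e-15 else u[jm]
        lam = min(max(lam, 0.0), u[jm])
        if lam <= 0.0:
            break
        u[jp] += lam
        u[jm] -= lam
    return u, achieved, 1  # not converged


try:  # compiled fast path; the pure-python core is the documented reference
    from numba import njit as _njit

    _mvee_core = _njit(cache=True, fastmath=False)(_mvee_core_py)
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _mvee_core = _mvee_core_py


def min_area_enclosing_ellipse(
    points, tol: float = 1e-5, max_iter: int = 100_000
) -> Ellipse:
    """Minimum-area ellipse enclosing a planar point set.

    Khachiyan's iterative reweighting (with away steps for linear
    convergence), run on the convex-hull vertices only.  After convergence
    the ellipse is inflated by the worst residual quadratic form so that
    containment holds exactly (to floating point), at an area cost bounded
    by the tolerance.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise DegenerateInputError("MVEE needs at least 3 points")
    # the MVEE depends only on hull vertices; Qhull also detects degeneracy
    try:
        hull = ConvexHull(pts)
        work = pts[hull.vertices]
    except QhullError as exc:
        raise DegenerateInputError("points are collinear or degenerate") from exc

    # the optimal weights are affine-invariant: solve on centered/scaled
    # points for numerical conditioning, apply the weights to the originals
    shift = work.mean(axis=0)
    scale = float(work.std()) or 1.0
    scaled = (work - shift) / scale
    Q = np.column_stack([scaled, np.ones(len(scaled))])
    u, achieved, status = _mvee_core(Q, tol, max_iter)
    if status == 2:
        raise DegenerateInputError("degenerate point configuration for MVEE")
    if status == 1 and achieved > tol:
        raise ConvergenceError(
            f"MVEE did not reach tolerance {tol} in {max_iter} iterations "
            f"(achieved slack {achieved:.3g})",
            achieved_slack=float(achieved),
        )
    center = u @ work
    cov = (work * u[:, None]).T @ work - np.outer(center, center)
    A = np.linalg.inv(cov) / 2.0  # (p-c)^T A (p-c) <= 1
    # guarantee containment: inflate by the worst-case quadratic form
    diff = pts - center
    q = np.einsum("ij,jk,ik->i", diff, A, diff)
    qmax = float(q.max())
    if qmax > 1.0:
        A = A / qmax
    evals, evecs = np.linalg.eigh(A)
    if np.any(evals <= 0):
        raise DegenerateInputError("points are collinear or degenerate")
    # eigh sorts ascending: smallest eigenvalue -> major axis
    a = 1.0 / np.sqrt(evals[0])
    b = 1.0 / np.sqrt(evals[1])
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0])) % np.pi
    return Ellipse(center=center, a=float(a), b=float(b), angle=angle)


def ellipse_whitening(ellipse: Ellipse) -> WhiteningTransform:
    """Affine map sending the ellipse to a circle of radius sqrt(a*b).

    Composition: translate the center to the origin, rotate the major axis
    onto +x, then scale x by sqrt(b/a) and y by sqrt(a/b).  The
    geometric-mean target radius preserves area; the choice of target radius
    is immaterial downstream because shapes are rescaled to unit perimeter
    before comparison.
    """
    ca, sa = np.cos(ellipse.angle), np.sin(ellipse.angle)
    rot = np.array([[ca, sa], [-sa, ca]])  # rotate by -angle
    s = np.sqrt(ellipse.b / ellipse.a)
    scale = np.array([[s, 0.0], [0.0, 1.0 / s]])
    return WhiteningTransform(linear=scale @ rot, offset=-ellipse.center)


def apply_transform(curve: Curve, transform: WhiteningTransform) -> Curve:
    """Apply an affine (whitening) transform to a curve.

    Raises :class:`InvalidTransformError` if the linear part is singular.
    A negative-determinant map would flip orientation; whitening transforms
    built here always have positive determinant.
    """
    if abs(transform.determinant) < 1e-12:
        raise InvalidTransformError("transform linear part is singular")
    return Curve(transform.apply(curve.points))


# ---------------------------------------------------------------------------
# contour extraction from label masks
# ---------------------------------------------------------------------------


def _smooth_closed(points: np.ndarray, window: int) -> np.ndarray:
    """Periodic moving average along a closed polygon (window made odd, capped)."""
    # cap so short contours are not flattened; marching-squares vertices sit
    # ~0.5-0.8 px apart, so `window` vertices span roughly `0.7*window` px
    window = min(window, max(len(points) // 6, 1))
    if window % 2 == 0:
        window -= 1
    if window <= 1:
        return points
    k = window // 2
    ext = np.vstack([points[-k:], points, points[:k]])
    kernel = np.ones(window) / window
    out = np.column_stack([
        np.convolve(ext[:, 0], kernel, mode="valid"),
        np.convolve(ext[:, 1], kernel, mode="valid"),
    ])
    return out


def extract_gland_contours(
    mask: np.ndarray,
    image_id: str = "",
    min_vertices: int = 8,
    border_margin: int = 2,
    smooth_window: int = 15,
) -> list[GlandRecord]:
    """Extract per-gland boundary records from an integer label mask.

    Each positive label is one gland; a binary mask (exactly two distinct
    values) is first relabeled by 8-connected components.  The outer boundary
    is traced at sub-pixel precision (marching squares at level 0.5 of the
    label's indicator) and lightly smoothed with a short periodic moving
    average to suppress the half-pixel staircase of rasterized boundaries;
    interior holes (lumina) are ignored.

    ``touches_border`` is set when any labeled pixel lies within
    ``border_margin`` pixels of the image edge.  Area is the labeled pixel
    count; the centroid is the mean labeled pixel coordinate as (x, y).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InvalidInputError(f"mask must be 2-D, got {mask.ndim}-D")
    if not np.issubdtype(mask.dtype, np.integer) and not np.issubdtype(mask.dtype, np.bool_):
        if np.any(mask != np.floor(mask)):
            raise InvalidInputError("mask must contain integers")
        mask = mask.astype(np.int64)
    if mask.min() < 0:
        raise InvalidInputError("mask labels must be nonnegative")

    distinct = np.unique(mask)
    if len(distinct) == 2 and distinct[0] == 0:
        # binary mask: relabel with 8-connectivity
        mask = measure.label(mask > 0, connectivity=2)

    h, w = mask.shape
    records: list[GlandRecord] = []
    for prop in measure.regionprops(mask.astype(np.int64)):
        label = prop.label
        r0, c0, r1, c1 = prop.bbox
        touches = (
            r0 <= border_margin
            or c0 <= border_margin
            or r1 >= h - border_margin
            or c1 >= w - border_margin
        )
        # pad the crop so marching squares always yields closed contours
        crop = np.pad(prop.image.astype(float), 1)
        contours = measure.find_contours(crop, level=0.5)
        if not contours:
            logger.warning("label %s in %s produced no contour; skipped", label, image_id)
            continue
        # outer boundary = contour with the largest absolute enclosed area
        best = max(contours, key=lambda c: abs(signed_area(c[:, ::-1])))
        if np.allclose(best[0], best[-1]):
            best = best[:-1]
        if len(best) < min_vertices:
            logger.warning(
                "label %s in %s has %d boundary vertices (< %d); skipped",
                label, image_id, len(best), min_vertices,
            )
            continue
        # (row, col) -> (x, y), undo pad and bbox offsets
        xy = np.column_stack([best[:, 1] + c0 - 1, best[:, 0] + r0 - 1])
        xy = _smooth_closed(xy, smooth_window)
        # drop numerically duplicate consecutive vertices
        d = np.roll(xy, -1, axis=0) - xy
        keep = np.hypot(d[:, 0], d[:, 1]) > 1e-12
        xy = xy[keep]
        if len(xy) < min_vertices:
            logger.warning("label %s in %s degenerate after cleanup; skipped", label, image_id)
            continue
        rows, cols = np.nonzero(mask == label)
        centroid = np.array([cols.mean(), rows.mean()])
        records.append(
            GlandRecord(
                gland_id=int(label),
                image_id=image_id,
                contour=Curve(xy),
                area=float(prop.area),
                centroid=centroid,
                touches_border=bool(touches),
            )
        )
    return records


# ---------------------------------------------------------------------------
# baseline shape descriptors
# ---------------------------------------------------------------------------


def baseline_shape_features(contour: Curve, area: float | None = None) -> dict:
    """Classical shape descriptors of a closed contour.

    roundness = 4*pi*A / P^2; aspect_ratio = a/b of the MVEE;
    elongation = 1 - b/a; solidity = A / hull area;
    convexity = hull perimeter / P.  ``area`` defaults to the polygon area
    of the contour itself.
    """
    pts = contour.points
    P = contour.perimeter
    A = abs(contour.signed_area) if area is None else float(area)
    if A <= 0 or P <= 0:
        raise DegenerateCurveError("contour has nonpositive area or perimeter")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateCurveError("contour is degenerate (collinear)") from exc
    hull_area = float(hull.volume)  # 2-D: volume = area, area = perimeter
    hull_perim = float(hull.area)
    ell = min_area_enclosing_ellipse(pts)
    return {
        "roundness": 4.0 * np.pi * A / P**2,
        "aspect_ratio": ell.a / ell.b,
        "elongation": 1.0 - ell.b / ell.a,
        "solidity": A / hull_area,
        "convexity": hull_perim / P,
    }
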