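"""Best Alignment Metric (BAM) between discretely represented planar shapes.

A shape is an equivalence class of closed curves under translation, rotation
and cyclic re-parametrization (reflection is *not* in the class).  For two
representatives u, v with the same number N of equally spaced, zero-mean
points (treated as complex numbers), the distance is

    d(u, v) = sqrt( (1/N) * min_{r, theta} sum_j |v_j - e^{i theta} u_{j+r}|^2 )

with the index j + r taken mod N, r ranging over {0, .., N-1} and theta over
[0, 2*pi).  The rotation minimization is closed-form for each shift: writing
c(r) = sum_j v_j * conj(u_{j+r}), the optimal angle is theta*(r) = arg c(r)
and the objective becomes S_u + S_v - 2|c(r)| where S_u = sum |u_j|^2.  The
cross-correlation c(r) for all shifts is computed at once with the FFT, so
the metric costs O(N log N).  A brute-force evaluator over an explicit
(shift x angle) grid serves as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .geometry import NormalizedShape

__all__ = ["Alignment", "bam_distance", "bam_distance_bruteforce", "optimal_alignment"]


@dataclass(frozen=True)
class Alignment:
    """Optimal alignment between two shapes: cyclic shift, rotation, distance.

    ``degenerate_rotation`` flags the (measure-zero) case c(r) = 0 where
    every rotation is optimal; theta is then reported as 0.
    """

    shift: int
    theta: float
    distance: float
    degenerate_rotation: bool = False


def _check_pair(u: NormalizedShape, v: NormalizedShape) -> tuple[np.ndarray, np.ndarray]:
    if u.n_points != v.n_points:
        raise InvalidInputError(
            f"shapes must share N: got {u.n_points} and {v.n_points}"
        )
    return u.as_complex, v.as_complex


def _cross_correlation(uz: np.ndarray, vz: np.ndarray) -> np.ndarray:
    """c(r) = sum_j v_j * conj(u_{j+r}) for all shifts r, via the FFT."""
    # with a_j = v_j and b_j = conj(u_j): c(r) = sum_j a_j b_{j+r}
    # = ifft( fft(b) * conj(fft(conj(a))) )
    return np.fft.ifft(np.fft.fft(np.conj(uz)) * np.conj(np.fft.fft(np.conj(vz))))


def optimal_alignment(u: NormalizedShape, v: NormalizedShape) -> Alignment:
    """Best cyclic shift and rotation aligning u onto v, with the distance.

    For each shift the optimal rotation is closed-form; the best shift
    maximizes |c(r)| (ties broken by the smallest r).
    """
    uz, vz = _check_pair(u, v)
    n = len(uz)
    c = _cross_correlation(uz, vz)
    mag = np.abs(c)
    r = int(np.argmax(mag))  # argmax returns the first (smallest) maximizer
    degenerate = bool(mag[r] < 1e-15)
    theta = 0.0 if degenerate else float(np.angle(c[r])) % (2 * np.pi)
    # evaluate the objective at the optimum directly: the sum of squared
    # residuals has no cancellation, so d(u, u) is exactly 0
    residual = vz - np.exp(1j * theta) * np.roll(uz, -r)
    dist = float(np.sqrt(np.sum(np.abs(residual) ** 2) / n))
    return Alignment(shift=r, theta=theta, distance=dist, degenerate_rotation=degenerate)


def bam_distance(u: NormalizedShape, v: NormalizedShape) -> float:
    """BAM distance between two shapes sharing the same N."""
    return optimal_alignment(u, v).distance


def bam_distance_bruteforce(
    u: NormalizedShape, v: NormalizedShape, n_theta: int = 4096
) -> Alignment:
    """Exhaustive BAM evaluation over all shifts and a uniform angle grid.

    Independent oracle for :func:`bam_distance`: no closed-form rotation, no
    FFT.  The grid minimum upper-bounds the continuous minimum, with error
    O(1/n_theta^2) near the optimum.
    """
    if n_theta < 4:
        raise InvalidInputError(f"need n_theta >= 4, got {n_theta}")
    uz, vz = _check_pair(u, v)
    n = len(uz)
    thetas = np.arange(n_theta) * (2 * np.pi / n_theta)
    rot = np.exp(1j * thetas)
    best_obj = np.inf
    best_r, best_theta = 0, 0.0
    for r in range(n):
        shifted = np.roll(uz, -r)  # u_{j+r}
        # objective for all angles at once: sum_j |v_j - e^{i t} u_{j+r}|^2
        diffs = vz[None, :] - rot[:, None] * shifted[None, :]
        obj = np.sum(np.abs(diffs) ** 2, axis=1)
        k = int(np.argmin(obj))
        if obj[k] < best_obj:
            best_obj = float(obj[k])
            best_r, best_theta = r, float(thetas[k])
    dist = float(np.sqrt(max(best_obj, 0.0) / n))
    return Alignment(shift=best_r, theta=best_theta, distance=dist)
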