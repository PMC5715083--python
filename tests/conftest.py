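"""Shared fixtures and shape builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from glandbam import (
    AberranceConfig,
    BinConfig,
    PostprocessConfig,
    SyntheticConfig,
    compute_image_features,
    image_aberrance_table,
    normalize_shape,
    postprocess_features,
)
from glandbam.geometry import Curve
from glandbam.io import features_to_frame
from glandbam.synthetic import generate_image_mask


def polar_curve(radius_fn, n: int = 256, center=(0.0, 0.0)) -> Curve:
    """Closed curve from a polar radius function r(phi)."""
    phi = 2 * np.pi * np.arange(n) / n
    r = radius_fn(phi)
    return Curve(np.column_stack([center[0] + r * np.cos(phi),
                                  center[1] + r * np.sin(phi)]))


def ellipse_curve(a: float, b: float, angle: float = 0.0, center=(0.0, 0.0),
                  n: int = 256) -> Curve:
    t = 2 * np.pi * np.arange(n) / n
    ca, sa = np.cos(angle), np.sin(angle)
    x, y = a * np.cos(t), b * np.sin(t)
    return Curve(np.column_stack([center[0] + ca * x - sa * y,
                                  center[1] + sa * x + ca * y]))


def random_smooth_shape(rng: np.random.Generator, n_points: int = 256,
                        n_shape: int = 64, amplitude: float = 0.3):
    """A random star-shaped blob, normalized: generic test shape for the metric."""
    n_h = rng.integers(2, 6)
    orders = rng.choice(np.arange(2, 9), size=n_h, replace=False)
    amps = rng.dirichlet(np.ones(n_h)) * amplitude
    phases = rng.uniform(0, 2 * np.pi, n_h)

    def radius(phi):
        r = np.ones_like(phi)
        for k, a_k, p in zip(orders, amps, phases):
            r += a_k * np.cos(k * phi + p)
        return r

    return normalize_shape(polar_curve(radius, n_points), n_shape)


@pytest.fixture(scope="session")
def default_synthetic_study():
    """The default synthetic study: 60 images per grade, seed 0.

    Returns (features_pre, features_post, per_image_records, manifests)
    where the feature tables are DataFrames with grade labels and the
    manifests carry ground-truth per-gland roles.
    """
    cfg = SyntheticConfig(seed=0)
    acfg = AberranceConfig()
    bins = BinConfig()
    pcfg = PostprocessConfig()
    rng = np.random.default_rng(cfg.seed)
    pre, post, records_by_image, manifests = [], [], {}, {}
    for grade in ("normal", "low_grade", "high_grade"):
        for i in range(60):
            image_id = f"{grade}_{i:03d}"
            mask, manifest = generate_image_mask(grade, cfg, rng, image_id=image_id)
            records = image_aberrance_table(mask, image_id, acfg)
            f_pre = compute_image_features(records, bins, label=grade)
            records, f_post = postprocess_features(records, f_pre, pcfg, bins)
            pre.append(f_pre)
            post.append(f_post)
            records_by_image[image_id] = records
            manifests[image_id] = manifest
    return (
        features_to_frame(pre),
        features_to_frame(post),
        records_by_image,
        manifests,
    )
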