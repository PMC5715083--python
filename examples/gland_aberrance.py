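"""Score single gland boundaries: the aberrance (BAM value) of a gland.

A gland's aberrance is the BAM distance between its boundary and its
minimum-area enclosing ellipse after whitening (which turns that ellipse
into a circle).  Elliptical sections of healthy tubular crypts score ~0
regardless of eccentricity; deformed boundaries score higher.  Values for
realistic glands live in roughly [0, 0.1].
"""

import numpy as np

from glandbam import Curve, gland_aberrance


def polar(radius_fn, n=512, stretch=(1.0, 1.0)):
    phi = 2 * np.pi * np.arange(n) / n
    r = radius_fn(phi)
    return Curve(np.column_stack([stretch[0] * r * np.cos(phi),
                                  stretch[1] * r * np.sin(phi)]))


cases = {
    "circle":                     polar(lambda p: np.ones_like(p)),
    "3:1 ellipse":                polar(lambda p: np.ones_like(p), stretch=(3, 1)),
    "mild 3-lobe (amp 0.10)":     polar(lambda p: 1 + 0.10 * np.cos(3 * p)),
    "strong 3-lobe (amp 0.25)":   polar(lambda p: 1 + 0.25 * np.cos(3 * p)),
    "stretched strong 3-lobe":    polar(lambda p: 1 + 0.25 * np.cos(3 * p), stretch=(2, 1)),
    "ragged (orders 4+7)":        polar(lambda p: 1 + 0.2 * np.cos(4 * p) + 0.15 * np.sin(7 * p)),
}

for name, curve in cases.items():
    print(f"{name:28s} aberrance = {gland_aberrance(curve):.5f}")

print("\nThe two ellipses score ~0: section angle through a tubular gland "
      "does not matter.  The stretched 3-lobe scores almost the same as the "
      "unstretched one for the same reason, while deformation amplitude "
      "drives the value up.")
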