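"""Feature postprocessing: removing tangential sections and border glands.

Normal tissue images sometimes contain small tangential crypt sections and
glands clipped by the image border; both carry spuriously high BAM values
that drag the image's features toward cancer-like values.  The
postprocessing gate (opened only for images whose Regularity Index is
high, i.e. normal-looking) excludes them by area and border position and
recomputes the features.
"""

import numpy as np

from glandbam import (
    SyntheticConfig,
    compute_image_features,
    image_aberrance_table,
    postprocess_features,
)
from glandbam.synthetic import generate_image_mask

cfg = SyntheticConfig(seed=7, tangential_fraction=0.10, border_fraction=0.10)
mask, manifest = generate_image_mask("normal", cfg, np.random.default_rng(7),
                                     image_id="normal_demo")
records = image_aberrance_table(mask, "normal_demo")
pre = compute_image_features(records, label="normal")
records, post = postprocess_features(records, pre)

injected = {g["gland_id"] for g in manifest["glands"] if g["role"] != "regular"}
excluded = {r.gland_id for r in records if r.excluded}

print(f"glands: {manifest['n_glands']}  injected artifacts: {len(injected)}")
print(f"excluded by postprocessing:   {len(excluded)} "
      f"(match: {excluded == (injected & {r.gland_id for r in records})})")
print(f"mean BAM     before {pre.mean_bam:.4f}  after {post.mean_bam:.4f}")
print(f"BAM entropy  before {pre.bam_entropy:.3f}   after {post.bam_entropy:.3f}")
print("The artifacts alone carried the high BAM values; after removal the "
      "image's features return to the tight normal cluster.")
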