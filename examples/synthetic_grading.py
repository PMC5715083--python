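"""End-to-end on synthetic data: masks -> aberrance -> features -> grading.

Generates a small three-grade dataset of gland label masks, computes
per-image aberrance features, and cross-validates the SVM grader.  With
well-separated deformation regimes per grade the features separate cleanly
and accuracy is high even at this small size.
"""

import numpy as np

from glandbam import (
    GradingConfig,
    SyntheticConfig,
    compute_image_features,
    cross_validate,
    image_aberrance_table,
    postprocess_features,
)
from glandbam.io import features_to_frame
from glandbam.synthetic import generate_image_mask

cfg = SyntheticConfig(seed=42, image_size=(768, 768), glands_per_image=(10, 16))
rng = np.random.default_rng(cfg.seed)

feats = []
for grade in ("normal", "low_grade", "high_grade"):
    for i in range(6):
        image_id = f"{grade}_{i}"
        mask, _ = generate_image_mask(grade, cfg, rng, image_id=image_id)
        records = image_aberrance_table(mask, image_id)
        f = compute_image_features(records, label=grade)
        _, f = postprocess_features(records, f)
        feats.append(f)

df = features_to_frame(feats)
print(df.groupby("label")[["mean_bam", "bam_entropy", "regularity_index"]]
        .mean().round(4))

report = cross_validate(df, cfg=GradingConfig(task="three_class", feature_set="fs2",
                                              folds=3, repeats=5, seed=0))
print(f"\n3-class accuracy: {report.accuracy_mean:.1%} ± {report.accuracy_std:.1%} "
      "(mean ± sd over fold x repeat runs)")
print("Grade-wise mean BAM rises from normal to high grade while the "
      "Regularity Index falls: exactly the gradient the grader exploits.")
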