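"""The marginal focal dice loss on a hand-checkable instance.

One sample, two classes, all logits zero, labels [1, 0]. With margins off,
unit exponents, no clipping and uniform weights each class's active dice
component is 1 - 2*0.25/1.25 = 0.6, halved by the mixing weight alpha=0.5
and averaged over the two classes: the loss is exactly 0.3.
"""

import numpy as np

from mfpep import MFDLConfig, compute_class_stats, mfdl_loss

config = MFDLConfig(alpha=0.5, m_max=0.0, p_pos=1, p_neg=1,
                    clip_pos=0, clip_neg=0, use_class_weights=False)
labels = np.array([[1, 0]])
stats = compute_class_stats(labels, config)
value = float(mfdl_loss(np.zeros((1, 2)), labels, stats, config).numpy())
print(f"worked example loss: {value:.6f}  (expected 0.3)")

# Class weighting: counts 100 vs 1 with maximum margin 0.5 give weights
# proportional to the inverse square root of the counts, scaled so the
# rarest class gets exactly m_max.
Y = np.zeros((101, 2), dtype=int)
Y[:100, 0] = 1
Y[:1, 1] = 1
stats = compute_class_stats(Y, MFDLConfig(m_max=0.5))
print("class weights for counts [100, 1]:", stats.w_class, " (expected [0.05, 0.5])")
print("margins, positive side:", np.round(stats.margin_pos, 4),
      "| negative side:", np.round(stats.margin_neg, 4))
# The minority side of each class receives the full margin 0.5; the
# majority side a smaller one, shifting the decision boundary in favor of
# rare labels during training.
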