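"""Overlap metrics and the Focal Tversky loss on a toy prediction.

Shows how the Tversky index interpolates between Dice and Jaccard, how the
Threshold-Jaccard rule zeroes out unusable segmentations, and how the focal
exponent reshapes the loss.
"""

import numpy as np

from dermseg.metrics import (TverskyParams, confusion_counts, dice,
                             focal_tversky_loss, jaccard, threshold_jaccard,
                             tversky)

gt = np.zeros((8, 8), dtype=np.uint8)
gt[2:6, 2:6] = 1                      # 16-pixel lesion
pred = np.zeros_like(gt)
pred[3:7, 2:6] = 1                    # shifted down one row

c = confusion_counts(pred, gt)
print(f"TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn}")
print(f"Dice                 {dice(c):.4f}")
j = jaccard(c)
print(f"Jaccard              {j:.4f}")
print(f"Threshold Jaccard    {threshold_jaccard(j):.4f}   (zero: below the 0.65 cutoff)")
print(f"Tversky a=b=0.5      {tversky(c, 0.5, 0.5):.4f}   (= Dice)")
print(f"Tversky a=b=1        {tversky(c, 1.0, 1.0):.4f}   (= Jaccard)")
print(f"Tversky a=0.7 b=0.3  {tversky(c, 0.7, 0.3):.4f}   (false negatives cost more)")

# soft loss on a probabilistic prediction of the same scene
probs = np.where(pred == 1, 0.9, 0.05)
for gamma in (1.0, 4 / 3, 2.0):
    loss = focal_tversky_loss(probs, gt, TverskyParams(gamma=gamma))
    print(f"Focal Tversky loss, gamma={gamma:.2f}: {loss:.4f}")
print("larger gamma amplifies the penalty on poorly segmented images")
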