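"""Worked examples of the segmentation loss and evaluation metrics.

Shows the soft Dice overlap on a half-confidence prediction, the
count-based accuracy / IoU / DSC on a small confusion table, and the
area under the ROC curve for a toy probability map.
"""

import numpy as np

from sedseg import (ConfusionCounts, accuracy, confusion, dice_loss, dsc,
                    iou, roc_auc, soft_dice)

# a predictor that says 0.5 everywhere, against an all-tumor truth
a = np.full((2, 2), 0.5)
b = np.ones((2, 2))
print(f"soft Dice(0.5-everywhere, all-ones) = {soft_dice(a, b):.3f}  "
      "(= 2*2 / (1 + 4))")
print(f"training loss = 1 - smoothed Dice = {dice_loss(a, b):.3f}")

c = ConfusionCounts(tp=1, tn=97, fp=1, fn=1)
print(f"\nconfusion tp=1 tn=97 fp=1 fn=1: accuracy={accuracy(c):.3f} "
      f"iou={iou(c):.3f} dsc={dsc(c):.3f}")
print("(accuracy is inflated by the easy background pixels; IoU/DSC are the "
      "informative overlap scores)")

g = np.random.default_rng(0)
truth = np.zeros((16, 16), dtype=bool)
truth[4:10, 4:10] = True
scores = np.clip(truth * 0.6 + 0.2 * g.random((16, 16)), 0, 1)
(fpr, tpr, _), auc = roc_auc(scores, truth)
print(f"\ntoy probability map: AUC = {auc:.3f} over {len(fpr)} ROC points "
      "(1.0 = perfect ranking, 0.5 = none)")

pred = scores >= 0.5
cc = confusion(pred, truth)
print(f"thresholded at 0.5: iou={iou(cc):.3f} dsc={dsc(cc):.3f}")
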