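"""The re-weighting primitives on hand-sized arrays.

Shows the soft Dice loss, the segmentation-ability score used as a
central aggregation weight, and the lesion-volume loss weight.
"""

import numpy as np

from fedmsrw import segmentation_ability, soft_dice_loss
from fedmsrw.federation import loss_weight

# an 8-voxel patch: 4 lesion voxels, prediction uniformly 0.5
pred = np.full(8, 0.5)
target = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)

loss = soft_dice_loss(pred, target)
ability = segmentation_ability(pred, target)
print(f"soft Dice loss          : {loss:.4f}")          # 1 - 4/6 = 0.3333
print(f"segmentation ability    : {ability.value:.4f}")  # 0.5 * (1-loss) = 0.3333

# lesion-free patch: the ability is undefined, reported absent
empty = segmentation_ability(pred, np.zeros(8))
print(f"empty ground truth      : absent ({empty.reason_absent})")

# two clients with lesion-volume ratios 0.01 and 0.03: the low-burden
# client trains with a 2x loss weight, the high-burden one with 2/3
vr = [0.01, 0.03]
for i in range(2):
    print(f"loss weight client {i}    : {loss_weight(vr, i):.4f}")
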