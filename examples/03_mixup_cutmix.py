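"""Soft-label augmentation: MixUp blending and CutMix patch transplanting.

Shows the two mixing operators on toy images and verifies their defining
identities: MixUp's convex pixel/label combination, and CutMix's exact
agreement between the surviving-area fraction and the label weight.
"""

import numpy as np

from lmnet import cutmix, mixup, sample_lambda

rng = np.random.default_rng(3)
x1 = np.zeros((1, 3, 8, 8), dtype=np.float32)        # an all-black image
x2 = np.ones((1, 3, 8, 8), dtype=np.float32)         # an all-white image
y1 = np.array([[1.0, 0.0]], dtype=np.float32)
y2 = np.array([[0.0, 1.0]], dtype=np.float32)

lam = sample_lambda(alpha=1.0, rng=rng)
mixed = mixup(x1, y1, x2, y2, lam)
print(f"MixUp:  lambda={lam:.3f}  pixel value={mixed.images[0,0,0,0]:.3f} "
      f"(= 1 - lambda: the white image carries weight 1 - lambda)  "
      f"soft label={np.round(mixed.soft_labels[0], 3)}")

cut = cutmix(x1, y1, x2, y2, alpha=1.0, rng=rng)
area = cut.mask.mean()
print(f"CutMix: patch area fraction={area:.3f}  lambda={cut.lambda_:.3f} "
      f"(= 1 - area)  soft label={np.round(cut.soft_labels[0], 3)}")
# every CutMix output pixel comes from exactly one source image:
assert set(np.unique(cut.images)) <= {0.0, 1.0}
print("every output pixel belongs to exactly one source image")
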