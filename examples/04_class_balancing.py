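"""Class balancing: how the published training counts arise from the raw ones.

Rarer classes get larger integer multipliers (rotation / blur / contrast
copies, the original counting as one), pushing the per-class training
sizes toward balance.
"""

from lmnet.augment import RPDD_MULTIPLIERS, build_balance_plan
from lmnet.datagen import RPDD_TABLE, rpdd_original_counts

originals = rpdd_original_counts()
plan = build_balance_plan(originals, multipliers=RPDD_MULTIPLIERS)
augmented = plan.augmented_counts(originals)

print(f"{'class':<30s} {'raw':>6s} {'xm':>4s} {'balanced':>9s} {'published':>10s}")
for cls, m in zip(originals, plan.multipliers.values()):
    published_train = RPDD_TABLE[cls][1]
    print(f"{cls:<30s} {originals[cls]:>6d} x{m:<3d} {augmented[cls]:>9d} "
          f"{published_train:>10d}")
print("balanced counts reproduce the published training column exactly:",
      all(augmented[c] == RPDD_TABLE[c][1] for c in originals))
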