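"""The study's split arithmetic, from 32 dishes per cut to the printed sizes.

Per cut: a stratified validation third (3 dishes per ratio), the remainder
split 3:1 train:test, then count-driven augmentation to 1575/525/700 images.
The mixed-part dataset is the union of the three cuts with tripled targets.
"""

from mincenet.datasets import DEFAULT_FILL_TARGETS, build_mixed_manifest, split_single_part
from mincenet.synthetic import PARTS, generate_sample_metadata

metas = generate_sample_metadata(8)
print(f"{len(metas)} samples in the full design\n")

manifests = []
for part in PARTS:
    man = split_single_part([m for m in metas if m.part == part], seed=42)
    manifests.append(man)
    print(f"{part:10s} source dishes per split: {man.counts()}  "
          f"-> fill targets {man.fill_targets}")

mixed = build_mixed_manifest(manifests)
print(f"\nmixed      source dishes per split: {mixed.counts()}  "
      f"-> fill targets {mixed.fill_targets}")
print(f"\nstudy defaults: {DEFAULT_FILL_TARGETS} per part "
      f"(train:test exactly 3:1); materialize_splits() writes the images.")
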