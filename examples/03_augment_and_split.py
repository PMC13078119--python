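"""The dataset expansion protocol: x5 augmentation and a 7:2:1 split.

Every image keeps its original plus four augmented copies, the operators
drawn without replacement from {rotation, gaussian noise, salt-and-pepper,
brightness, exposure}; per-class counts scale exactly by five. The split is
stratified by class with largest-remainder rounding.
"""

import tempfile

from yolosda import datakit as dk

root = tempfile.mkdtemp(prefix="leafdata_")
manifest = dk.write_dataset(root, n_scenes=18, seed=0, size=128)
print(f"original: {len(manifest)} images, per class "
      f"{list(manifest.per_class_counts().values())}")

expanded = dk.expand_dataset(manifest, factor=5, seed=0,
                             out_dir=root + "/expanded")
print(f"expanded: {len(expanded)} images, per class "
      f"{list(expanded.per_class_counts().values())} (exactly x5)")

split = dk.split_dataset(expanded, ratios=(7, 2, 1), seed=0)
sizes = {s: len(split.subset(s)) for s in ("train", "val", "test")}
print(f"7:2:1 split: {sizes} — disjoint, stratified, seed-reproducible")
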