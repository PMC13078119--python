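"""Generate a synthetic leaf-disease scene with exact box labels.

Each scene composites leaf-shaped objects with class-conditional lesion
patterns (spot density/colour, chlorosis) on a cluttered background; the
label file lists one normalized 'class cx cy w h' row per leaf. The same
seed always reproduces the same pixels and labels.
"""

from yolosda import datakit as dk

img, labels = dk.generate_scene(seed=42, n_objects=5, size=640)
print(f"scene: {img.shape[1]}x{img.shape[0]} RGB, {len(labels)} objects")
for lb in labels:
    x1, y1, x2, y2 = (int(v) for v in lb.to_xyxy(640, 640))
    print(f"  {dk.CLASS_NAMES[lb.class_id]:>20s}  "
          f"box [{x1:3d},{y1:3d},{x2:3d},{y2:3d}]  "
          f"(cx={lb.cx:.3f} cy={lb.cy:.3f} w={lb.w:.3f} h={lb.h:.3f})")

from PIL import Image

Image.fromarray(img).save("scene_example.png")
print("saved scene_example.png — lesion spots distinguish the six classes")
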