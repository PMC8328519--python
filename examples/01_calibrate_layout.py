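"""Calibrate a six-item layout to published chance distances.

The encoded coordinates behind a study's chance baselines are often not
published; what is published is the geometry they imply. This script builds
a layout whose chance levels match the printed values — 348 px (items vs
screen center), 267 px (items vs their own centroid), 270 px (centroid vs
screen center) — and prints the check.
"""

from gistmem import calibrate_layout, chance_baselines
from gistmem.synthetic import load_preset

targets, _, n_items, screen = load_preset("exp1", seed=0)
layout = calibrate_layout(targets, n_items, screen, seed=0)

b = chance_baselines(layout)
print(f"calibrated {n_items} items on a {screen.width:.0f}x{screen.height:.0f} screen")
for label, point in zip(layout.labels, layout.points):
    print(f"  {label}: ({point.x:7.1f}, {point.y:7.1f})")
print(f"item error if clicking screen center : {b.item_vs_screen_center:7.2f} px (target 348)")
print(f"item error if clicking encoded center: {b.item_vs_encoded_center:7.2f} px (target 267)")
print(f"gist error if clicking screen center : {b.gist_vs_screen_center:7.2f} px (target 270)")
print("These are the error levels a strategy-free responder would achieve;")
print("observed errors are interpreted relative to them.")
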