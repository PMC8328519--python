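"""Estimate how strongly a spatial outlier is weighted in a reported center.

On an eight-item layout with one far-flung item, the reported center can sit
anywhere on the segment between the local center (outlier ignored, weight 0)
and the outlier itself (weight 1); equal weighting of all items corresponds
to 1/8 = 0.125. This script simulates a participant who over-weights the
outlier (true weight 0.25) and recovers the weight by grid search.
"""

import numpy as np

from gistmem import Point, calibrate_layout, estimate_outlier_weight, weighted_center_for
from gistmem.synthetic import load_preset

targets, _, n_items, screen = load_preset("exp2", seed=0)
layout = calibrate_layout(targets, n_items, screen, seed=0)

rng = np.random.default_rng(5)
true_w = 0.25
base = weighted_center_for(layout, true_w)
reported = Point(base.x + rng.normal(0, 5), base.y + rng.normal(0, 5))

fit = estimate_outlier_weight(reported, layout)
print(f"true outlier weight      : {true_w}")
print(f"estimated outlier weight : {fit.estimated_weight}")
print(f"distance at the optimum  : {fit.min_distance:.1f} px")
print(f"equal-weight benchmark   : {fit.equal_weight_benchmark}")
print("An estimate above the benchmark means the outlier pulls the reported")
print("center more than an average item would.")
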