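"""Outlier-weight estimation from the reported center (weighted-centroid grid search).

On a layout with one designated spatial outlier, the reported center can be
modelled as a weighted centroid in which the outlier carries weight ``w``
and the remaining ``n - 1`` items share the rest equally::

    center(w) = w * outlier + (1 - w) / (n - 1) * sum(other items)

Because the non-outlier items enter only through their centroid, ``center(w)``
traces the straight segment from the local center (``w = 0``) through the
global centroid (``w = 1/n``) to the outlier itself (``w = 1``). The weight
is estimated by evaluating the distance from the reported center to
``center(w)`` on an 81-point grid over [0, 1] (step 0.0125) and taking the
argmin; the equal-weight benchmark ``1/n`` (0.125 for eight items) marks no
over- or under-weighting.

As printed, the shared non-outlier weight at ``w = 0`` is ``1/(n-1)``
(about 0.143 for eight items), slightly above the benchmark 0.125; the
formula is implemented exactly as stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Layout, Point

__all__ = ["OutlierWeightFit", "weight_grid", "weighted_center_for", "estimate_outlier_weight"]

GRID_SIZE = 81  # weights 0, 0.0125, ..., 1


def weight_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, GRID_SIZE)


@dataclass(frozen=True)
class OutlierWeightFit:
    weight_grid: np.ndarray
    distances: np.ndarray
    estimated_weight: float
    min_distance: float
    equal_weight_benchmark: float


def weighted_center_for(layout: Layout, outlier_weight: float) -> Point:
    """The candidate center with the outlier at weight ``w`` and the rest equal."""
    if layout.outlier_label is None:
        raise ValueError("weighted center requires a layout with a designated outlier")
    if not (0.0 <= outlier_weight <= 1.0):
        raise ValueError(f"outlier weight must be in [0, 1], got {outlier_weight}")
    coords = layout.coords()
    k = layout.outlier_index
    others = np.delete(coords, k, axis=0)
    w_other = (1.0 - outlier_weight) / (layout.n_items - 1)
    c = outlier_weight * coords[k] + w_other * others.sum(axis=0)
    return Point(float(c[0]), float(c[1]))


def estimate_outlier_weight(reported_center: Point, layout: Layout) -> OutlierWeightFit:
    """Grid-search the outlier weight that best explains one reported center.

    Ties (equidistant grid points) resolve toward the smaller weight,
    conservative against inferring outlier over-weighting; exact ties are
    measure-zero on continuous reports.
    """
    if layout.outlier_label is None:
        raise ValueError("outlier weight estimation requires a designated outlier")
    grid = weight_grid()
    coords = layout.coords()
    k = layout.outlier_index
    others_sum = np.delete(coords, k, axis=0).sum(axis=0)
    n = layout.n_items
    # centers for all grid weights at once: (81, 2)
    centers = grid[:, None] * coords[k] + ((1.0 - grid) / (n - 1))[:, None] * others_sum
    dists = np.hypot(centers[:, 0] - reported_center.x, centers[:, 1] - reported_center.y)
    best = int(np.argmin(dists))  # first minimum = smallest weight on ties
    return OutlierWeightFit(
        weight_grid=grid,
        distances=dists,
        estimated_weight=float(grid[best]),
        min_distance=float(dists[best]),
        equal_weight_benchmark=1.0 / n,
    )
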