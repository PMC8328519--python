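"""Error measurements, chance baselines, and the gist-based bias statistic.

Three error measures describe one participant-session:

* item error — mean distance between each retrieved item and its encoded
  location (how well individual locations are remembered);
* gist error — distance between the explicitly reported center and the true
  center (centroid) of the encoded items;
* estimated-center error — distance between the centroid of the retrieved
  items and the true center (what the gist would be if assembled purely
  from item memories).

The bias statistic quantifies, per item, the signed displacement of the
retrieval toward a reference center, normalized by that item's error::

    bias = (d(encoded, center) - d(retrieved, center)) / d(encoded, retrieved)

By the triangle inequality the value lies in [-1, 1]: +1 means the retrieval
moved straight toward the center, -1 straight away. A participant's bias is
the unweighted mean over items. Four reference centers are supported: the
participant's reported center, the centroid of encoded items, a centroid
weighted by item accuracy, and (on outlier layouts) the local center that
excludes the outlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    Layout,
    Point,
    accuracy_weighted_centroid,
    centroid,
    dist,
)
from .study_data import RetrievalRecord

__all__ = [
    "ErrorSummary",
    "ChanceBaselines",
    "BiasCenterSpec",
    "BiasResult",
    "error_summary",
    "chance_baselines",
    "item_bias",
    "item_bias_xy",
    "participant_bias",
    "resolve_bias_center",
]

BIAS_MODES = ("reported", "encoded_center", "accuracy_weighted", "local")


@dataclass(frozen=True)
class ErrorSummary:
    per_item_error: dict[str, float]
    item_error: float
    gist_error: float
    estimated_center_error: float


@dataclass(frozen=True)
class ChanceBaselines:
    """Geometry-only chance performance levels, in pixels.

    ``item_vs_screen_center``: mean distance from each encoded item to the
    screen center — the item error of a responder who always clicks the
    screen center. ``item_vs_encoded_center``: the same against the centroid
    of the encoded items. ``gist_vs_screen_center``: distance from the screen
    center to that centroid — the gist error of a screen-center clicker.
    """

    item_vs_screen_center: float
    item_vs_encoded_center: float
    gist_vs_screen_center: float

    def rounded(self) -> tuple[int, int, int]:
        """The three baselines rounded to integer pixels, as convention prints them."""
        return (
            round(self.item_vs_screen_center),
            round(self.item_vs_encoded_center),
            round(self.gist_vs_screen_center),
        )


@dataclass(frozen=True)
class BiasCenterSpec:
    """Which reference center the bias is measured against, and in which metric.

    ``zero_error_items`` controls the 0/0 case (retrieval exactly on the
    encoded point): ``"zero"`` counts the item with bias 0 (the numerator is
    also 0); ``"exclude"`` drops it from the participant mean.
    """

    mode: str = "reported"
    g: float = 2.0
    zero_error_items: str = "zero"

    def __post_init__(self) -> None:
        if self.mode not in BIAS_MODES:
            raise ValueError(f"unknown bias mode {self.mode!r}; expected one of {BIAS_MODES}")
        if self.zero_error_items not in ("zero", "exclude"):
            raise ValueError("zero_error_items must be 'zero' or 'exclude'")


@dataclass(frozen=True)
class BiasResult:
    per_item_bias: dict[str, float]
    participant_bias: float
    center_used: Point
    mode: str


def error_summary(record: RetrievalRecord, layout: Layout, g: float = 2.0) -> ErrorSummary:
    record.validate_against(layout)
    per_item = {
        lab: dist(record.retrieved[lab], layout.point_of(lab), g) for lab in layout.labels
    }
    true_center = layout.true_center
    est_center = centroid([record.retrieved[lab] for lab in layout.labels])
    return ErrorSummary(
        per_item_error=per_item,
        item_error=float(np.mean(list(per_item.values()))),
        gist_error=dist(record.reported_center, true_center, g),
        estimated_center_error=dist(est_center, true_center, g),
    )


def chance_baselines(layout: Layout) -> ChanceBaselines:
    """Chance error levels from the layout geometry alone (Euclidean)."""
    sc = layout.screen.center
    tc = layout.true_center
    return ChanceBaselines(
        item_vs_screen_center=float(np.mean([dist(p, sc) for p in layout.points])),
        item_vs_encoded_center=float(np.mean([dist(p, tc) for p in layout.points])),
        gist_vs_screen_center=dist(sc, tc),
    )


def item_bias(encoded: Point, retrieved: Point, center: Point, g: float = 2.0) -> float:
    """Signed, error-normalized displacement of one retrieval toward a center.

    Returns 0 for a perfect retrieval (0/0 convention: the numerator also
    vanishes). Positive values mean attraction toward the center.
    """
    err = dist(encoded, retrieved, g)
    if err == 0.0:
        return 0.0
    return (dist(encoded, center, g) - dist(retrieved, center, g)) / err


def item_bias_xy(
    encoded: np.ndarray, retrieved: np.ndarray, center: np.ndarray, g: float = 2.0
) -> np.ndarray:
    """Vectorized :func:`item_bias` on broadcastable (..., 2) coordinate arrays."""
    from .geometry import dist_xy

    err = dist_xy(encoded, retrieved, g)
    num = dist_xy(encoded, center, g) - dist_xy(retrieved, center, g)
    num, err = np.broadcast_arrays(num, err)
    out = np.zeros(err.shape)
    nz = err > 0.0
    out[nz] = num[nz] / err[nz]
    return out


def resolve_bias_center(
    record: RetrievalRecord, layout: Layout, spec: BiasCenterSpec
) -> Point:
    """The reference center a BiasCenterSpec designates, for one record."""
    if spec.mode == "reported":
        return record.reported_center
    if spec.mode == "encoded_center":
        return layout.true_center
    if spec.mode == "accuracy_weighted":
        errors = [
            dist(record.retrieved[lab], layout.point_of(lab), spec.g)
            for lab in layout.labels
        ]
        return accuracy_weighted_centroid(list(layout.points), errors)
    # local
    if layout.outlier_label is None:
        raise ValueError("local bias center requires a layout with a designated outlier")
    return layout.local_center


def participant_bias(
    record: RetrievalRecord, layout: Layout, spec: BiasCenterSpec = BiasCenterSpec()
) -> BiasResult:
    """Per-item and mean bias of one record against the center the spec selects.

    All items enter the unweighted mean, including the outlier in local mode
    (its per-item value is retained in ``per_item_bias`` so outlier-only
    analyses remain possible).
    """
    record.validate_against(layout)
    center = resolve_bias_center(record, layout, spec)
    per_item = {
        lab: item_bias(layout.point_of(lab), record.retrieved[lab], center, spec.g)
        for lab in layout.labels
    }
    if spec.zero_error_items == "exclude":
        vals = [
            b
            for lab, b in per_item.items()
            if dist(record.retrieved[lab], layout.point_of(lab), spec.g) > 0.0
        ]
        mean = float(np.mean(vals)) if vals else 0.0
    else:
        mean = float(np.mean(list(per_item.values())))
    return BiasResult(per_item_bias=per_item, participant_bias=mean, center_used=center, mode=spec.mode)
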