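"""Planar geometry primitives shared by every analysis stage.

Coordinates are continuous screen pixels with the origin at the top-left
corner and y increasing downward (the standard screen convention). All
published quantities are distances, which are invariant to this choice.

Distances are Minkowski distances with exponent ``g``; ``g = 2`` is the
Euclidean default and ``g = 1.5`` is the perceptual-space variant used in
sensitivity analyses. Only ``1 < g <= 2`` is accepted, the range in which
the g-norm is a metric and the bias statistic's [-1, 1] bound holds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Point",
    "Screen",
    "Layout",
    "dist",
    "centroid",
    "local_centroid",
    "accuracy_weighted_centroid",
]

#: Default screen, a common laptop resolution. Its half-diagonal (~783 px)
#: comfortably exceeds the 573-px outlier offset used by the 8-item design.
DEFAULT_SCREEN_WIDTH = 1366.0
DEFAULT_SCREEN_HEIGHT = 768.0


def _check_exponent(g: float) -> float:
    if not (1.0 < g <= 2.0):
        raise ValueError(f"Minkowski exponent must satisfy 1 < g <= 2, got {g}")
    return float(g)


@dataclass(frozen=True)
class Point:
    """A location on the screen, in pixels."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point coordinates must be finite, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Screen:
    """Screen bounds; a point is in-bounds iff 0 <= x <= width and 0 <= y <= height."""

    width: float = DEFAULT_SCREEN_WIDTH
    height: float = DEFAULT_SCREEN_HEIGHT

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("Screen dimensions must be positive")

    @property
    def center(self) -> Point:
        return Point(self.width / 2.0, self.height / 2.0)

    def contains(self, p: Point) -> bool:
        return 0.0 <= p.x <= self.width and 0.0 <= p.y <= self.height

    def contains_xy(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized bounds test on an (..., 2) coordinate array."""
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[..., 0] >= 0.0)
            & (xy[..., 0] <= self.width)
            & (xy[..., 1] >= 0.0)
            & (xy[..., 1] <= self.height)
        )


@dataclass(frozen=True)
class Layout:
    """Encoded item locations on a screen, with an optional designated spatial outlier.

    The layout is the source of every "true" quantity in the analysis: the
    true center (centroid of encoded items), the local center (centroid
    excluding the outlier), and the geometry-only chance baselines.
    """

    screen: Screen
    labels: tuple[str, ...]
    points: tuple[Point, ...]
    outlier_label: str | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("item labels must be unique")
        if self.outlier_label is not None and self.outlier_label not in self.labels:
            raise ValueError(f"outlier label {self.outlier_label!r} not among items")
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    @property
    def n_items(self) -> int:
        return len(self.labels)

    @property
    def outlier_index(self) -> int | None:
        return None if self.outlier_label is None else self._index[self.outlier_label]

    def point_of(self, label: str) -> Point:
        return self.points[self._index[label]]

    def coords(self) -> np.ndarray:
        """Encoded coordinates as an (n_items, 2) array, in label order."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    @property
    def true_center(self) -> Point:
        return centroid(list(self.points))

    @property
    def local_center(self) -> Point:
        if self.outlier_label is None:
            raise ValueError("local center requires a designated outlier")
        return local_centroid(list(self.points), self.outlier_index)

    # -- JSON serialization ------------------------------------------------

    def to_json(self) -> str:
        obj = {
            "screen": {"width": self.screen.width, "height": self.screen.height},
            "items": [
                {"label": lab, "x": p.x, "y": p.y}
                for lab, p in zip(self.labels, self.points)
            ],
        }
        if self.outlier_label is not None:
            obj["outlier_label"] = self.outlier_label
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Layout":
        obj = json.loads(text)
        screen = Screen(float(obj["screen"]["width"]), float(obj["screen"]["height"]))
        labels = tuple(str(it["label"]) for it in obj["items"])
        points = tuple(Point(float(it["x"]), float(it["y"])) for it in obj["items"])
        return cls(screen, labels, points, obj.get("outlier_label"))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Layout":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def dist(a: Point, b: Point, g: float = 2.0) -> float:
    """Minkowski distance (|dx|^g + |dy|^g)^(1/g) between two points, in pixels."""
    g = _check_exponent(g)
    dx, dy = abs(a.x - b.x), abs(a.y - b.y)
    if g == 2.0:
        return math.hypot(dx, dy)
    return (dx**g + dy**g) ** (1.0 / g)


def dist_xy(a: np.ndarray, b: np.ndarray, g: float = 2.0) -> np.ndarray:
    """Vectorized Minkowski distance between broadcastable (..., 2) arrays."""
    g = _check_exponent(g)
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    if g == 2.0:
        return np.hypot(d[..., 0], d[..., 1])
    return (d[..., 0] ** g + d[..., 1] ** g) ** (1.0 / g)


def centroid(points: list[Point]) -> Point:
    """Coordinate-wise arithmetic mean of a non-empty point list."""
    if not points:
        raise ValueError("centroid of an empty point list is undefined")
    xs = np.array([[p.x, p.y] for p in points], dtype=float)
    m = xs.mean(axis=0)
    return Point(float(m[0]), float(m[1]))


def local_centroid(layout_points: list[Point], outlier_index: int) -> Point:
    """Centroid of all points except the one at ``outlier_index``."""
    if len(layout_points) < 2:
        raise ValueError("local centroid requires at least two points")
    if not (0 <= outlier_index < len(layout_points)):
        raise ValueError(f"outlier index {outlier_index} out of range")
    rest = [p for i, p in enumerate(layout_points) if i != outlier_index]
    return centroid(rest)


def accuracy_weighted_centroid(encoded: list[Point], errors: list[float]) -> Point:
    """Centroid of encoded locations weighted by retrieval accuracy.

    Item i gets weight ``(1 - e_i / sum(e)) / (n - 1)``: items retrieved more
    accurately (smaller error e_i) contribute more to the center estimate.
    The weights are non-negative and sum to 1 exactly. When every error is
    zero the formula is indeterminate and the unweighted centroid — its
    limit under equal errors — is returned.
    """
    n = len(encoded)
    if n < 2:
        raise ValueError("accuracy-weighted centroid requires at least two items")
    if len(errors) != n:
        raise ValueError("errors must match encoded items in length")
    e = np.asarray(errors, dtype=float)
    if np.any(e < 0) or not np.all(np.isfinite(e)):
        raise ValueError("errors must be finite and non-negative")
    total = e.sum()
    if total == 0.0:
        return centroid(encoded)
    w = (1.0 - e / total) / (n - 1)
    xs = np.array([[p.x, p.y] for p in encoded], dtype=float)
    m = w @ xs
    return Point(float(m[0]), float(m[1]))
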