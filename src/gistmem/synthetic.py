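"""Synthetic layouts and cohorts with the statistical structure the analysis assumes.

The encoded item coordinates behind the published chance distances are not
public, so layouts are *calibrated*: a seeded constrained optimization
places ``n`` items on the screen so that the three geometry-only chance
baselines match given targets (within 0.5 px), pairwise separations stay
above a minimum, and — for outlier designs — one designated item sits at a
prescribed offset from the screen center, well away from the main cluster.

Cohorts are then generated from an explicit forward model:

* each item's retrieval error magnitude is drawn from a folded normal
  ``|N(scale, 0.3 * scale)|`` (the field reports no error distribution; the
  folded normal with CV 0.3 is a modelling choice, swappable);
* the retrieval *direction* mixes a uniform angle with the same
  distance-decreasing angle law the item-plus-gist null uses, with mixing
  weight ``lambda`` (``gist_pull``) — so the null models are correctly
  specified for generated data;
* the reported center is the outlier-weighted centroid (or the true center
  on layouts without an outlier) plus isotropic Gaussian noise;
* with probability ``swap_rate`` one random item pair's retrievals are
  exchanged, emulating misbinding.

Error scales, center noise, and pull strength are per-session (and, for
between-subject designs, per delay group), so delay-dependent error growth
and increasing gist reliance are expressible directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize

from .geometry import Layout, Point, Screen, dist
from .null_models import angle_candidates, angle_probabilities, substream, _draw_item_only
from .outlier_model import weighted_center_for
from .study_data import Cohort, RetrievalRecord

__all__ = [
    "CalibrationTargets",
    "CalibrationError",
    "GenerativeParams",
    "calibrate_layout",
    "generate_participant",
    "generate_cohort",
    "load_preset",
    "PRESETS",
]


class CalibrationError(RuntimeError):
    """Layout calibration failed (infeasible targets or no convergence)."""


@dataclass(frozen=True)
class CalibrationTargets:
    """The printed chance distances a calibrated layout must reproduce, in pixels."""

    item_vs_screen_center: float
    item_vs_encoded_center: float
    gist_vs_screen_center: float
    min_pair_separation: float = 100.0
    outlier_offset: float | None = None

    def __post_init__(self) -> None:
        t1, t2, t3 = (
            self.item_vs_screen_center,
            self.item_vs_encoded_center,
            self.gist_vs_screen_center,
        )
        if min(t1, t2, t3) <= 0:
            raise ValueError("chance-distance targets must be positive")
        # Triangle-type feasibility on the means: every pairwise bound must hold.
        if t1 > t2 + t3 or t2 > t1 + t3 or t3 > t1 + t2:
            raise CalibrationError(
                f"targets ({t1}, {t2}, {t3}) violate the triangle inequality on mean distances"
            )


def _residuals(
    xy: np.ndarray, screen: Screen, targets: CalibrationTargets, outlier_index: int | None
) -> np.ndarray:
    pts = xy.reshape(-1, 2)
    sc = np.array([screen.width / 2.0, screen.height / 2.0])
    c = pts.mean(axis=0)
    r = [
        np.hypot(*(pts - sc).T).mean() - targets.item_vs_screen_center,
        np.hypot(*(pts - c).T).mean() - targets.item_vs_encoded_center,
        np.hypot(*(c - sc)) - targets.gist_vs_screen_center,
    ]
    if outlier_index is not None:
        r.append(np.hypot(*(pts[outlier_index] - sc)) - targets.outlier_offset)
    return np.asarray(r)


def _objective(
    xy: np.ndarray,
    screen: Screen,
    targets: CalibrationTargets,
    outlier_index: int | None,
    sep_floor: float,
) -> float:
    pts = xy.reshape(-1, 2)
    res = _residuals(xy, screen, targets, outlier_index)
    f = float(np.sum(res**2))
    # soft minimum-separation penalty, with margin so the solution clears the floor
    diff = pts[:, None, :] - pts[None, :, :]
    dmat = np.hypot(diff[..., 0], diff[..., 1])
    iu = np.triu_indices(len(pts), k=1)
    f += 50.0 * float(np.sum(np.maximum(0.0, sep_floor - dmat[iu]) ** 2))
    if outlier_index is not None:
        # keep the outlier a genuine spatial outlier: at least its screen-center
        # offset away from the centroid of the remaining items
        rest = np.delete(pts, outlier_index, axis=0).mean(axis=0)
        gap = np.hypot(*(pts[outlier_index] - rest))
        f += float(np.maximum(0.0, targets.outlier_offset - gap) ** 2)
    return f


def calibrate_layout(
    targets: CalibrationTargets,
    n_items: int,
    screen: Screen = Screen(),
    seed: int = 0,
    max_restarts: int = 200,
) -> Layout:
    """Place ``n_items`` on the screen so the chance baselines hit the targets.

    Deterministic given ``(targets, n_items, screen, seed)``: seeded random
    restarts of an L-BFGS-B minimization of the squared target residuals
    plus separation penalties. Succeeds when every target residual is below
    0.05 px (an order of magnitude inside the 0.5 px reporting tolerance)
    and every pairwise separation strictly exceeds the minimum.
    """
    if n_items < 2:
        raise ValueError("a layout needs at least two items")
    has_outlier = targets.outlier_offset is not None
    if has_outlier:
        half_diag = np.hypot(screen.width, screen.height) / 2.0
        if targets.outlier_offset >= half_diag:
            raise CalibrationError(
                f"outlier offset {targets.outlier_offset} exceeds the screen half-diagonal"
            )
    outlier_index = n_items - 1 if has_outlier else None
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xCA11]))
    margin = 5.0
    bounds = [(margin, screen.width - margin), (margin, screen.height - margin)] * n_items
    sc = np.array([screen.width / 2.0, screen.height / 2.0])
    sep_floor = targets.min_pair_separation + 2.0

    best_resid = np.inf
    for _ in range(max_restarts):
        # init: centroid at the gist offset, items on a ring of the item radius
        phi = rng.uniform(0, 2 * np.pi)
        c0 = sc + targets.gist_vs_screen_center * np.array([np.cos(phi), np.sin(phi)])
        ang = np.sort(rng.uniform(0, 2 * np.pi, size=n_items))
        pts0 = c0 + targets.item_vs_encoded_center * np.column_stack(
            [np.cos(ang), np.sin(ang)]
        )
        if has_outlier:
            for _try in range(100):
                psi = rng.uniform(0, 2 * np.pi)
                cand = sc + targets.outlier_offset * np.array([np.cos(psi), np.sin(psi)])
                if margin < cand[0] < screen.width - margin and margin < cand[1] < screen.height - margin:
                    pts0[outlier_index] = cand
                    break
        pts0 = np.clip(pts0, [margin, margin], [screen.width - margin, screen.height - margin])

        sol = minimize(
            _objective,
            pts0.ravel(),
            args=(screen, targets, outlier_index, sep_floor),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 3000, "ftol": 1e-16, "gtol": 1e-12},
        )
        pts = sol.x.reshape(-1, 2)
        res = _residuals(sol.x, screen, targets, outlier_index)
        resid = float(np.max(np.abs(res)))
        diff = pts[:, None, :] - pts[None, :, :]
        dmat = np.hypot(diff[..., 0], diff[..., 1])
        iu = np.triu_indices(n_items, k=1)
        min_sep = float(dmat[iu].min())
        if resid < 0.05 and min_sep > targets.min_pair_separation:
            best_resid = min(best_resid, resid)
            labels = tuple(f"item_{i + 1}" for i in range(n_items))
            if has_outlier:
                labels = labels[:-1] + ("outlier",)
            return Layout(
                screen=screen,
                labels=labels,
                points=tuple(Point(float(x), float(y)) for x, y in pts),
                outlier_label="outlier" if has_outlier else None,
            )
        best_resid = min(best_resid, resid)
    raise CalibrationError(
        f"calibration did not converge after {max_restarts} restarts "
        f"(best max residual {best_resid:.3g} px)"
    )


# ---------------------------------------------------------------------------
# Cohort generation


def _per(value, session: str, group: str) -> float:
    """Look up a per-session (optionally per-group) parameter value."""
    if isinstance(value, dict):
        v = value[session]
        if isinstance(v, dict):
            v = v[group]
        return float(v)
    return float(value)


@dataclass(frozen=True)
class GenerativeParams:
    """Forward-model parameters for a synthetic cohort.

    ``item_error_scale``, ``gist_error_scale`` (the reported-center noise
    sigma) and ``gist_pull`` accept a scalar, a ``{session: value}`` dict,
    or a nested ``{session: {delay_group: value}}`` dict for between-subject
    designs. ``gist_pull`` is the mixing weight lambda in [0, 1] of the
    center-attracted direction law; 0 is direction-free retrieval.
    """

    n_participants: int
    sessions: tuple[str, ...]
    delay_groups: dict[str, int]  # group name -> participant count
    item_error_scale: object = 100.0
    gist_error_scale: object = 50.0
    gist_pull: object = 0.0
    outlier_weight: float | None = None
    swap_rate: float = 0.0
    seed: int = 0
    pull_center: str = "auto"  # auto -> local centroid on outlier layouts, else global
    n_angles: int = 200

    def __post_init__(self) -> None:
        if sum(self.delay_groups.values()) != self.n_participants:
            raise ValueError("delay-group counts must sum to n_participants")
        if not (0.0 <= self.swap_rate <= 1.0):
            raise ValueError("swap_rate must be in [0, 1]")
        if self.outlier_weight is not None and not (0.0 <= self.outlier_weight <= 1.0):
            raise ValueError("outlier_weight must be in [0, 1]")
        if self.pull_center not in ("auto", "global", "local"):
            raise ValueError("pull_center must be 'auto', 'global' or 'local'")


def _pull_center(layout: Layout, params: GenerativeParams) -> Point:
    mode = params.pull_center
    if mode == "auto":
        mode = "local" if layout.outlier_label is not None else "global"
    if mode == "local":
        return layout.local_center
    return layout.true_center


def _max_radius(enc: Point, screen: Screen) -> float:
    corners = np.array(
        [[0, 0], [screen.width, 0], [0, screen.height], [screen.width, screen.height]],
        dtype=float,
    )
    return float(np.hypot(corners[:, 0] - enc.x, corners[:, 1] - enc.y).max())


def generate_participant(
    layout: Layout,
    params: GenerativeParams,
    participant_id: str,
    session: str,
    delay_group: str,
    rng: np.random.Generator | None = None,
) -> RetrievalRecord:
    """Draw one participant-session record from the forward model."""
    if rng is None:
        rng = substream(params.seed, participant_id, session)
    screen = layout.screen
    lam = _per(params.gist_pull, session, delay_group)
    e_scale = _per(params.item_error_scale, session, delay_group)
    c_sigma = _per(params.gist_error_scale, session, delay_group)
    center = _pull_center(layout, params)

    retrieved: dict[str, Point] = {}
    for lab in layout.labels:
        enc = layout.point_of(lab)
        r = abs(rng.normal(e_scale, 0.3 * e_scale)) if e_scale > 0 else 0.0
        r = min(r, 0.95 * _max_radius(enc, screen))  # keep the error circle on-screen
        if r == 0.0:
            retrieved[lab] = enc
            continue
        if lam > 0.0 and rng.random() < lam:
            probs = angle_probabilities(enc, r, center, params.n_angles, screen)
            idx = int(rng.choice(params.n_angles, p=probs))
            x, y = angle_candidates(enc, r, params.n_angles)[idx]
        else:
            x, y = _draw_item_only(rng, enc.as_array(), r, 1, screen, 10_000)[0]
        retrieved[lab] = Point(float(x), float(y))

    if layout.outlier_label is not None and params.outlier_weight is not None:
        base = weighted_center_for(layout, params.outlier_weight)
    else:
        base = layout.true_center
    for _ in range(10_000):
        c = Point(
            float(base.x + rng.normal(0.0, c_sigma)) if c_sigma > 0 else base.x,
            float(base.y + rng.normal(0.0, c_sigma)) if c_sigma > 0 else base.y,
        )
        if screen.contains(c):
            break
    else:
        raise RuntimeError("could not draw an in-bounds reported center")

    if params.swap_rate > 0.0 and rng.random() < params.swap_rate:
        i, j = rng.choice(layout.n_items, size=2, replace=False)
        a, b = layout.labels[int(i)], layout.labels[int(j)]
        retrieved[a], retrieved[b] = retrieved[b], retrieved[a]

    return RetrievalRecord(
        participant_id=participant_id,
        session=session,
        delay_group=delay_group,
        retrieved=retrieved,
        reported_center=c,
    )


def generate_cohort(layout: Layout, params: GenerativeParams) -> Cohort:
    """Seeded, reproducible cohort: all sessions for all participants.

    Participants are assigned to delay groups in declaration order; each
    (participant, session) uses its own RNG substream derived from the
    cohort seed, so regeneration is order-independent.
    """
    pids: list[tuple[str, str]] = []
    idx = 1
    for group, count in params.delay_groups.items():
        for _ in range(count):
            pids.append((f"p{idx:03d}", group))
            idx += 1
    records = [
        generate_participant(layout, params, pid, session, group)
        for pid, group in pids
        for session in params.sessions
    ]
    return Cohort(layout, records)


# ---------------------------------------------------------------------------
# Presets

PRESETS = ("exp1", "exp2")


def load_preset(name: str, seed: int = 0) -> tuple[CalibrationTargets, GenerativeParams, int, Screen]:
    """Load a shipped study preset.

    Returns ``(targets, params, n_items, screen)``: the layout-calibration
    targets (the published chance distances), the cohort generator
    parameters with the given seed, the item count, and the screen.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    text = resources.files("gistmem.presets").joinpath(f"{name}.json").read_text("utf-8")
    obj = json.loads(text)
    screen = Screen(**obj["screen"])
    t = obj["targets"]
    targets = CalibrationTargets(
        item_vs_screen_center=t["item_vs_screen_center"],
        item_vs_encoded_center=t["item_vs_encoded_center"],
        gist_vs_screen_center=t["gist_vs_screen_center"],
        min_pair_separation=t["min_pair_separation"],
        outlier_offset=t.get("outlier_offset"),
    )
    p = obj["params"]
    params = GenerativeParams(
        n_participants=p["n_participants"],
        sessions=tuple(p["sessions"]),
        delay_groups=p["delay_groups"],
        item_error_scale=p["item_error_scale"],
        gist_error_scale=p["gist_error_scale"],
        gist_pull=p["gist_pull"],
        outlier_weight=p.get("outlier_weight"),
        swap_rate=p.get("swap_rate", 0.0),
        seed=seed,
    )
    return targets, params, int(obj["n_items"]), screen
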