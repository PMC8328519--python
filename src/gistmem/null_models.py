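"""Monte Carlo null models for the bias statistic.

Because the bias statistic normalizes by each item's error, pure noise is
not bias-neutral: an item retrieved with a large error is geometrically more
likely to land at a negative-bias angle, so raw bias values cannot be
compared across error levels. The two null models below generate reference
bias distributions matched to each participant's *observed* error
magnitudes, so the observed bias can be compared against what direction-free
(or gist-attracted) retrieval with the same errors would produce.

* item-only null — each simulated retrieval sits at exactly the observed
  error radius from its encoded location, at a uniformly random angle
  (out-of-bounds draws are resampled). No gist influence.
* item-plus-gist null — the same radii, but the angle is drawn from a
  discrete distribution over candidate angles whose probability decreases
  linearly with the candidate's distance to the reference center:
  ``P_i = (d_i - max_j d_j) / sum_j (d_j - max_j d_j)`` over the in-bounds
  candidates (both numerator and denominator are non-positive, so this is
  the normalized linear decrease; the farthest in-bounds candidate gets
  probability 0).

Each simulation run redraws every item once; the run's bias is the mean
item bias against the same reference center used for the observed bias.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Layout, Point, Screen, dist
from .metrics import BiasCenterSpec, error_summary, participant_bias, resolve_bias_center
from .study_data import Cohort, RetrievalRecord

__all__ = [
    "NullConfig",
    "NullSimulationResult",
    "GeometryError",
    "angle_candidates",
    "angle_probabilities",
    "simulate_participant",
    "bias_gap_analysis",
    "substream",
]

MODELS = ("item_only", "item_plus_gist")


class GeometryError(RuntimeError):
    """A simulation could not place a point inside the screen."""


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-(participant, session, ...) RNG substream.

    Derived from the cohort-level seed plus stable hashes of the keys, so
    results do not depend on the order in which participants are processed.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode("utf-8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class NullConfig:
    n_simulations: int = 1000
    n_angles: int = 200
    seed: int = 0
    model: str = "item_only"
    screen: Screen | None = None  # defaults to the layout's screen
    max_resample: int = 10_000

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if self.n_angles < 3:
            raise ValueError("n_angles must be >= 3")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")


@dataclass
class NullSimulationResult:
    model: str
    bias_per_run: np.ndarray
    estimated_center_errors: np.ndarray
    #: simulated retrievals, (n_runs, n_items, 2); populated when requested
    points: np.ndarray | None = None

    @property
    def simulated_bias_mean(self) -> float:
        return float(self.bias_per_run.mean())

    @property
    def simulated_estimated_center_error_mean(self) -> float:
        return float(self.estimated_center_errors.mean())


def angle_candidates(encoded: Point, error: float, n_angles: int) -> np.ndarray:
    """The candidate points: centers of ``n_angles`` equal arcs on the error circle.

    Arc 0 starts at the +x axis; the phase is fixed and seed-independent.
    """
    theta = (np.arange(n_angles) + 0.5) * (2.0 * np.pi / n_angles)
    return np.column_stack(
        [encoded.x + error * np.cos(theta), encoded.y + error * np.sin(theta)]
    )


def angle_probabilities(
    encoded: Point,
    error: float,
    center: Point,
    n_angles: int = 200,
    screen: Screen | None = None,
) -> np.ndarray:
    """Angle distribution of the item-plus-gist null for one item.

    Returns a length-``n_angles`` probability vector over the candidate
    points from :func:`angle_candidates`. Out-of-bounds candidates get
    probability 0 and the distribution is renormalized over the in-bounds
    set. If the center is equidistant from every candidate (center at the
    encoded point) the distribution falls back to uniform.
    """
    if not (error > 0):
        raise ValueError("angle probabilities require a positive error radius")
    cand = angle_candidates(encoded, error, n_angles)
    if screen is not None:
        inb = screen.contains_xy(cand)
        if not inb.any():
            raise GeometryError(
                f"all {n_angles} candidate points at radius {error:.1f} around "
                f"({encoded.x:.1f}, {encoded.y:.1f}) fall outside the screen"
            )
    else:
        inb = np.ones(n_angles, dtype=bool)
    d = np.hypot(cand[:, 0] - center.x, cand[:, 1] - center.y)
    dmax = d[inb].max()
    probs = np.zeros(n_angles)
    spread = dmax - d[inb].min()
    if spread <= 1e-12 * max(1.0, dmax):
        probs[inb] = 1.0 / inb.sum()
        return probs
    w = dmax - d[inb]
    probs[inb] = w / w.sum()
    return probs


def _draw_item_only(
    rng: np.random.Generator,
    encoded: np.ndarray,
    error: float,
    n_runs: int,
    screen: Screen,
    max_resample: int,
) -> np.ndarray:
    """Uniform-angle draws at a fixed radius, rejection-resampling out-of-bounds."""
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_runs)
    pts = encoded + error * np.column_stack([np.cos(theta), np.sin(theta)])
    bad = ~screen.contains_xy(pts)
    tries = 0
    while bad.any():
        tries += 1
        if tries > max_resample:
            raise GeometryError(
                f"could not place a point at radius {error:.1f} around "
                f"({encoded[0]:.1f}, {encoded[1]:.1f}) within the screen"
            )
        theta = rng.uniform(0.0, 2.0 * np.pi, size=int(bad.sum()))
        pts[bad] = encoded + error * np.column_stack([np.cos(theta), np.sin(theta)])
        bad = ~screen.contains_xy(pts)
    return pts


def simulate_participant(
    record: RetrievalRecord,
    layout: Layout,
    center: Point,
    config: NullConfig,
    keep_points: bool = False,
) -> NullSimulationResult:
    """Simulate one participant-session under the configured null model.

    Every simulated item preserves its observed (Euclidean) error magnitude
    exactly; only the direction is random. An item retrieved with zero error
    is simulated at its encoded point and contributes bias 0. Each run also
    records the simulated estimated-center error: the distance from the
    centroid of the run's simulated retrievals to the true center.
    """
    screen = config.screen or layout.screen
    rng = substream(config.seed, record.participant_id, record.session, config.model)
    summ = error_summary(record, layout)
    enc = layout.coords()
    n_items = layout.n_items
    n_runs = config.n_simulations
    errors = np.array([summ.per_item_error[lab] for lab in layout.labels])

    sims = np.empty((n_runs, n_items, 2))
    for i, lab in enumerate(layout.labels):
        e = errors[i]
        if e == 0.0:
            sims[:, i, :] = enc[i]
        elif config.model == "item_only":
            sims[:, i, :] = _draw_item_only(rng, enc[i], e, n_runs, screen, config.max_resample)
        else:
            probs = angle_probabilities(
                layout.points[i], e, center, config.n_angles, screen
            )
            cand = angle_candidates(layout.points[i], e, config.n_angles)
            idx = rng.choice(config.n_angles, size=n_runs, p=probs)
            sims[:, i, :] = cand[idx]

    # per-run mean item bias: fixed denominators (the observed errors)
    d_enc = np.hypot(enc[:, 0] - center.x, enc[:, 1] - center.y)  # (n_items,)
    d_sim = np.hypot(sims[..., 0] - center.x, sims[..., 1] - center.y)  # (n_runs, n_items)
    contrib = np.zeros_like(d_sim)
    nz = errors > 0.0
    contrib[:, nz] = (d_enc[nz] - d_sim[:, nz]) / errors[nz]
    bias_per_run = contrib.mean(axis=1)

    tc = layout.true_center
    sim_centers = sims.mean(axis=1)  # (n_runs, 2)
    est_errors = np.hypot(sim_centers[:, 0] - tc.x, sim_centers[:, 1] - tc.y)
    return NullSimulationResult(
        model=config.model,
        bias_per_run=bias_per_run,
        estimated_center_errors=est_errors,
        points=sims if keep_points else None,
    )


def bias_gap_analysis(
    cohort: Cohort,
    spec: BiasCenterSpec = BiasCenterSpec(),
    config: NullConfig = NullConfig(),
) -> pd.DataFrame:
    """Observed bias vs both null models, per participant-session.

    Returns one row per record with the observed bias, the item-only and
    item-plus-gist simulated bias means, and the two gaps that enter the
    session/group comparisons: ``gap_item_only = observed - sim_item_only``
    (positive when retrieval is more center-attracted than direction-free
    noise) and ``gap_gist = sim_gist - observed``. Fully reproducible given
    the config seed.
    """
    rows = []
    for rec in cohort.records:
        obs = participant_bias(rec, cohort.layout, spec)
        center = obs.center_used
        sim_i = simulate_participant(
            rec, cohort.layout, center, _with_model(config, "item_only")
        )
        sim_g = simulate_participant(
            rec, cohort.layout, center, _with_model(config, "item_plus_gist")
        )
        summ = error_summary(rec, cohort.layout)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "session": rec.session,
                "delay_group": rec.delay_group,
                "observed_bias": obs.participant_bias,
                "sim_item_only_bias": sim_i.simulated_bias_mean,
                "sim_gist_bias": sim_g.simulated_bias_mean,
                "gap_item_only": obs.participant_bias - sim_i.simulated_bias_mean,
                "gap_gist": sim_g.simulated_bias_mean - obs.participant_bias,
                "observed_est_center_error": summ.estimated_center_error,
                "sim_item_only_est_center_error": sim_i.simulated_estimated_center_error_mean,
            }
        )
    return pd.DataFrame(rows)


def _with_model(config: NullConfig, model: str) -> NullConfig:
    return NullConfig(
        n_simulations=config.n_simulations,
        n_angles=config.n_angles,
        seed=config.seed,
        model=model,
        screen=config.screen,
        max_resample=config.max_resample,
    )
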