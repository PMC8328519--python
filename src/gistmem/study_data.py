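"""Cohort data model, CSV round-trip, and preprocessing.

A cohort is a set of participant-session retrieval records collected on one
layout: for every encoded item the location the participant retrieved, plus
one explicitly reported center (the gist report) per session.

Preprocessing covers the two rules applied before analysis:

* swap (misbinding) detection and correction — pairs of items whose labels
  were exchanged at retrieval are identified by a four-condition mutual
  nearest-neighbour rule and swapped back;
* participant exclusions — an out-of-scope gist report at the first session,
  performance more than 3 SD worse than the cohort mean, or (on layouts with
  a designated spatial outlier) placing the outlier among the main cluster.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Layout, Point, dist

__all__ = [
    "RetrievalRecord",
    "Cohort",
    "ExclusionReport",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "detect_swaps",
    "apply_swap_correction",
    "apply_exclusions",
]

SESSIONS = ("S1", "S2", "S3")
DELAY_GROUPS = ("24h", "1week", "1month", "within_subject")

COLUMNS = ["participant_id", "session", "delay_group", "record_type", "item_label", "x", "y"]


class SchemaError(ValueError):
    """A trials table violates the expected schema."""


@dataclass(frozen=True)
class RetrievalRecord:
    """One participant-session: retrieved item locations plus the reported center."""

    participant_id: str
    session: str
    delay_group: str
    retrieved: dict[str, Point]
    reported_center: Point

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")
        if self.delay_group not in DELAY_GROUPS:
            raise ValueError(f"unknown delay group {self.delay_group!r}")

    def validate_against(self, layout: Layout) -> None:
        if set(self.retrieved) != set(layout.labels):
            missing = set(layout.labels) - set(self.retrieved)
            extra = set(self.retrieved) - set(layout.labels)
            raise SchemaError(
                f"record {self.participant_id}/{self.session}: retrieved labels do not "
                f"match layout (missing={sorted(missing)}, unknown={sorted(extra)})"
            )

    def retrieved_coords(self, layout: Layout) -> np.ndarray:
        """Retrieved coordinates as (n_items, 2), in the layout's label order."""
        return np.array(
            [[self.retrieved[lab].x, self.retrieved[lab].y] for lab in layout.labels],
            dtype=float,
        )

    def with_retrieved(self, retrieved: dict[str, Point]) -> "RetrievalRecord":
        return RetrievalRecord(
            self.participant_id, self.session, self.delay_group, dict(retrieved),
            self.reported_center,
        )


@dataclass
class Cohort:
    layout: Layout
    records: list[RetrievalRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.participant_id, rec.session)
            if key in seen:
                raise SchemaError(f"duplicate record for {key}")
            seen.add(key)
            rec.validate_against(self.layout)

    @property
    def participant_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.participant_id not in out:
                out.append(rec.participant_id)
        return out

    def sessions_of(self, participant_id: str) -> list[RetrievalRecord]:
        return [r for r in self.records if r.participant_id == participant_id]

    def subset(self, participant_ids) -> "Cohort":
        keep = set(participant_ids)
        return Cohort(self.layout, [r for r in self.records if r.participant_id in keep])


@dataclass
class ExclusionReport:
    excluded: dict[str, str]
    retained_n: int

    def to_json(self) -> str:
        return json.dumps({"excluded": self.excluded, "retained_n": self.retained_n}, indent=2)


# ---------------------------------------------------------------------------
# CSV round-trip


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for rec in cohort.records:
        for lab in cohort.layout.labels:
            p = rec.retrieved[lab]
            rows.append((rec.participant_id, rec.session, rec.delay_group, "item", lab, p.x, p.y))
        c = rec.reported_center
        rows.append((rec.participant_id, rec.session, rec.delay_group, "center", "", c.x, c.y))
    return pd.DataFrame(rows, columns=COLUMNS)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the trials table as comma-separated UTF-8 with a header row."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path_or_frame, layout: Layout) -> Cohort:
    """Read a trials table (CSV path or DataFrame) and validate it against a layout.

    Each (participant, session) must contribute exactly one row per layout
    item (``record_type == "item"``) and exactly one center row.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, dtype={"participant_id": str, "item_label": str})
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"trials table missing columns {missing_cols}")
    df["item_label"] = df["item_label"].fillna("")

    records: list[RetrievalRecord] = []
    for (pid, session), grp in df.groupby(["participant_id", "session"], sort=True):
        groups = grp["delay_group"].unique()
        if len(groups) != 1:
            raise SchemaError(f"{pid}/{session}: inconsistent delay_group values {list(groups)}")
        items = grp[grp["record_type"] == "item"]
        centers = grp[grp["record_type"] == "center"]
        if len(centers) != 1:
            raise SchemaError(f"{pid}/{session}: expected exactly 1 center row, got {len(centers)}")
        unknown = set(items["item_label"]) - set(layout.labels)
        if unknown:
            raise SchemaError(f"{pid}/{session}: unknown item labels {sorted(unknown)}")
        dup = items["item_label"][items["item_label"].duplicated()]
        if len(dup):
            raise SchemaError(f"{pid}/{session}: duplicate item rows for {sorted(set(dup))}")
        missing = set(layout.labels) - set(items["item_label"])
        if missing:
            raise SchemaError(f"{pid}/{session}: missing item rows for {sorted(missing)}")
        retrieved = {
            str(r.item_label): Point(float(r.x), float(r.y)) for r in items.itertuples()
        }
        crow = centers.iloc[0]
        rec = RetrievalRecord(
            participant_id=str(pid),
            session=str(session),
            delay_group=str(groups[0]),
            retrieved=retrieved,
            reported_center=Point(float(crow.x), float(crow.y)),
        )
        records.append(rec)
    return Cohort(layout, records)


# ---------------------------------------------------------------------------
# Swap (misbinding) detection and correction


def detect_swaps(
    record: RetrievalRecord, layout: Layout, lens_region: bool = False
) -> list[tuple[str, str]]:
    """Identify item pairs whose retrievals were label-swapped.

    A pair (A, B) qualifies when all four conditions hold:

    1. the retrieval of A is closest to encoded B (among all encoded items);
    2. the retrieval of B is closest to encoded A;
    3. both retrievals lie within ``d(encoded A, encoded B) / 2`` of the
       encoded location each is closest to (with ``lens_region=True``, of
       *both* encoded locations — a stricter, lens-shaped region);
    4. no other retrieval lies within that range of encoded A or encoded B.

    Nearest-encoded ties are broken by layout label order (exact ties are
    measure-zero on continuous data). Returned pairs are disjoint and sorted.
    """
    record.validate_against(layout)
    enc = layout.coords()
    ret = record.retrieved_coords(layout)
    n = layout.n_items
    # dmat[i, j] = distance from retrieval of item i to encoded item j
    dmat = np.hypot(ret[:, None, 0] - enc[None, :, 0], ret[:, None, 1] - enc[None, :, 1])
    nearest = dmat.argmin(axis=1)  # first minimum = lowest label index

    pairs: list[tuple[str, str]] = []
    for i in range(n):
        j = int(nearest[i])
        if j <= i or int(nearest[j]) != i:
            continue  # not a mutual pair (or already seen as (j, i))
        half = np.hypot(*(enc[i] - enc[j])) / 2.0
        if lens_region:
            ok3 = max(dmat[i, i], dmat[i, j], dmat[j, i], dmat[j, j]) <= half
        else:
            ok3 = dmat[i, j] <= half and dmat[j, i] <= half
        if not ok3:
            continue
        others = [k for k in range(n) if k not in (i, j)]
        if any(dmat[k, i] <= half or dmat[k, j] <= half for k in others):
            continue
        pairs.append((layout.labels[i], layout.labels[j]))
    pairs.sort()
    return pairs


def apply_swap_correction(
    record: RetrievalRecord, pairs: list[tuple[str, str]]
) -> RetrievalRecord:
    """Exchange the retrieved points of each swapped pair, label-wise."""
    touched: set[str] = set()
    for a, b in pairs:
        if a in touched or b in touched or a == b:
            raise ValueError(f"overlapping or degenerate swap pairs at ({a}, {b})")
        touched.update((a, b))
    retrieved = dict(record.retrieved)
    for a, b in pairs:
        retrieved[a], retrieved[b] = retrieved[b], retrieved[a]
    return record.with_retrieved(retrieved)


def correct_cohort_swaps(cohort: Cohort, lens_region: bool = False) -> Cohort:
    """Detect and swap back misbound pairs in every record of a cohort."""
    out = []
    for rec in cohort.records:
        pairs = detect_swaps(rec, cohort.layout, lens_region=lens_region)
        out.append(apply_swap_correction(rec, pairs) if pairs else rec)
    return Cohort(cohort.layout, out)


# ---------------------------------------------------------------------------
# Participant exclusions


def apply_exclusions(cohort: Cohort, experiment: str) -> tuple[Cohort, ExclusionReport]:
    """Apply the cohort's participant-exclusion rules.

    ``experiment="exp1"`` (no outlier): first drop participants whose
    Session-1 reported-center error exceeds the gist chance baseline (the
    distance from screen center to the true center — a report that far off
    is out of the scope of the learned locations); then drop participants
    whose item or gist error at any session is more than 3 SD worse than
    the cohort mean for that session.

    ``experiment="exp2"`` (outlier layout): the gist-scope rule is *not*
    applied (a large gist error may reflect genuine outlier over-weighting);
    instead participants whose outlier-item error exceeds the distance from
    screen center to the encoded outlier are dropped (they placed the
    outlier among the main cluster), plus the same 3 SD rule.

    The 3 SD screen is computed per metric (item error, gist error) per
    session in a single pass, on the participants surviving the
    participant-local rules.
    """
    from .metrics import chance_baselines, error_summary

    if experiment not in ("exp1", "exp2"):
        raise ValueError(f"experiment must be 'exp1' or 'exp2', got {experiment!r}")
    layout = cohort.layout
    baselines = chance_baselines(layout)
    excluded: dict[str, str] = {}

    if experiment == "exp1":
        for rec in cohort.records:
            if rec.session != "S1" or rec.participant_id in excluded:
                continue
            if error_summary(rec, layout).gist_error > baselines.gist_vs_screen_center:
                excluded[rec.participant_id] = "gist_out_of_scope"
    else:
        if layout.outlier_label is None:
            raise ValueError("exp2 exclusions require a layout with a designated outlier")
        threshold = dist(layout.screen.center, layout.point_of(layout.outlier_label))
        for rec in cohort.records:
            if rec.participant_id in excluded:
                continue
            summ = error_summary(rec, layout)
            if summ.per_item_error[layout.outlier_label] > threshold:
                excluded[rec.participant_id] = "outlier_misplaced"

    survivors = [p for p in cohort.participant_ids if p not in excluded]
    # 3 SD rule: per session, per metric, one pass (no iterative re-exclusion)
    rows = [
        (rec.participant_id, rec.session, error_summary(rec, layout))
        for rec in cohort.records
        if rec.participant_id not in excluded
    ]
    if len(survivors) < 2:
        warnings.warn("fewer than 2 participants: 3 SD exclusion rule skipped")
    else:
        df = pd.DataFrame(
            [(pid, sess, s.item_error, s.gist_error) for pid, sess, s in rows],
            columns=["participant_id", "session", "item_error", "gist_error"],
        )
        for sess, grp in df.groupby("session"):
            for metric in ("item_error", "gist_error"):
                vals = grp[metric].to_numpy()
                cut = vals.mean() + 3.0 * vals.std(ddof=1)
                for pid in grp.loc[grp[metric] > cut, "participant_id"]:
                    excluded.setdefault(pid, "three_sd")

    retained = cohort.subset([p for p in cohort.participant_ids if p not in excluded])
    report = ExclusionReport(excluded=excluded, retained_n=len(retained.participant_ids))
    return retained, report
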