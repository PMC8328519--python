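"""End-to-end orchestration: preprocessing, metrics, null models, outlier fits.

`run_analysis` ties the stages into one reproducible pass over a cohort and
returns (and optionally writes) tidy tables:

* ``errors`` — one row per participant-session with the three error measures;
* ``bias`` — one row per participant-session per bias-center mode;
* ``bias_gaps`` — observed vs item-only / item-plus-gist simulated bias;
* ``outlier_weights`` — grid-search fits (outlier layouts only);
* ``error_change`` — change scores vs the first session (via `compare_sessions`).

Group-level inference beyond simple rank tests (omnibus ANOVAs, mixed
models) is deliberately left to external statistical tooling; the tables
here are shaped to feed it. No multiple-comparison correction is applied by
default; a Holm adjustment is available on the rank-test wrappers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Layout
from .metrics import BiasCenterSpec, chance_baselines, error_summary, participant_bias
from .null_models import NullConfig, bias_gap_analysis
from .outlier_model import estimate_outlier_weight
from .study_data import Cohort, apply_exclusions, correct_cohort_swaps, read_cohort

__all__ = ["RunConfig", "AnalysisResult", "run_analysis", "compare_sessions", "rank_tests"]


@dataclass(frozen=True)
class RunConfig:
    experiment: str = "exp1"  # exclusion rule set: "exp1" or "exp2"
    bias_modes: tuple[str, ...] = ("reported",)
    g: float = 2.0
    apply_exclusions: bool = True
    swap_correction: bool = True
    run_null_models: bool = True
    n_simulations: int = 1000
    n_angles: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bias_modes:
            raise ValueError("at least one bias-center mode is required")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisResult:
    tables: dict[str, pd.DataFrame]
    exclusions: dict
    config: RunConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        report = {
            "config": {**self.config.__dict__, "bias_modes": list(self.config.bias_modes)},
            "config_hash": self.config.config_hash(),
            "exclusions": self.exclusions,
            "tables": sorted(self.tables),
        }
        (outdir / "run_report.json").write_text(json.dumps(report, indent=2))


def run_analysis(cohort, layout: Layout | None = None, config: RunConfig = RunConfig()) -> AnalysisResult:
    """Run the full analysis over a cohort (object or trials-CSV path).

    Stages, in order: swap correction, participant exclusions, error
    summaries, bias per requested center mode, null-model bias gaps, and —
    when the layout designates an outlier — outlier-weight fits. With the
    null models toggled off the pass is metrics-only (no simulation cost).
    Fully reproducible from (inputs, config, seed); every output carries the
    config hash through the run report.
    """
    if not isinstance(cohort, Cohort):
        if layout is None:
            raise ValueError("a layout is required when reading a cohort from a file")
        cohort = read_cohort(cohort, layout)
    layout = cohort.layout

    exclusions: dict = {"applied": False, "excluded": {}, "retained_n": len(cohort.participant_ids)}
    if config.swap_correction:
        cohort = correct_cohort_swaps(cohort)
    if config.apply_exclusions:
        cohort, report = apply_exclusions(cohort, config.experiment)
        exclusions = {"applied": True, "excluded": report.excluded, "retained_n": report.retained_n}

    base = chance_baselines(layout)
    err_rows, bias_rows, weight_rows = [], [], []
    for rec in cohort.records:
        summ = error_summary(rec, layout, config.g)
        err_rows.append(
            {
                "participant_id": rec.participant_id,
                "session": rec.session,
                "delay_group": rec.delay_group,
                "item_error": summ.item_error,
                "gist_error": summ.gist_error,
                "estimated_center_error": summ.estimated_center_error,
            }
        )
        for mode in config.bias_modes:
            res = participant_bias(rec, layout, BiasCenterSpec(mode=mode, g=config.g))
            row = {
                "participant_id": rec.participant_id,
                "session": rec.session,
                "delay_group": rec.delay_group,
                "bias_mode": mode,
                "participant_bias": res.participant_bias,
            }
            if layout.outlier_label is not None:
                row["outlier_item_bias"] = res.per_item_bias[layout.outlier_label]
            bias_rows.append(row)
        if layout.outlier_label is not None:
            fit = estimate_outlier_weight(rec.reported_center, layout)
            weight_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "session": rec.session,
                    "estimated_weight": fit.estimated_weight,
                    "min_distance": fit.min_distance,
                    "equal_weight_benchmark": fit.equal_weight_benchmark,
                }
            )

    tables: dict[str, pd.DataFrame] = {
        "errors": pd.DataFrame(err_rows),
        "bias": pd.DataFrame(bias_rows),
        "chance_baselines": pd.DataFrame(
            [
                {
                    "item_vs_screen_center": base.item_vs_screen_center,
                    "item_vs_encoded_center": base.item_vs_encoded_center,
                    "gist_vs_screen_center": base.gist_vs_screen_center,
                }
            ]
        ),
    }
    sessions = sorted({r.session for r in cohort.records})
    if len(sessions) >= 2:
        tables["error_change"] = compare_sessions(tables["errors"])
    if config.run_null_models:
        null_cfg = NullConfig(
            n_simulations=config.n_simulations, n_angles=config.n_angles, seed=config.seed
        )
        tables["bias_gaps"] = bias_gap_analysis(
            cohort, BiasCenterSpec(mode=config.bias_modes[0], g=config.g), null_cfg
        )
    if weight_rows:
        tables["outlier_weights"] = pd.DataFrame(weight_rows)
    return AnalysisResult(tables=tables, exclusions=exclusions, config=config)


def compare_sessions(
    errors: pd.DataFrame,
    metrics: tuple[str, ...] = ("item_error", "gist_error", "estimated_center_error"),
    reference_session: str | None = None,
) -> pd.DataFrame:
    """Per-participant change scores of each error metric vs the first session.

    Returns one row per (participant, later session) with ``<metric>_change``
    columns, the construction the delay-group comparisons operate on.
    """
    sessions = sorted(errors["session"].unique())
    if len(sessions) < 2:
        raise ValueError("session comparison requires at least two sessions")
    ref = reference_session or sessions[0]
    base = errors[errors["session"] == ref].set_index("participant_id")
    rows = []
    for sess in sessions:
        if sess == ref:
            continue
        cur = errors[errors["session"] == sess].set_index("participant_id")
        common = cur.index.intersection(base.index)
        for pid in common:
            row = {
                "participant_id": pid,
                "session": sess,
                "reference_session": ref,
                "delay_group": cur.loc[pid, "delay_group"],
            }
            for m in metrics:
                if m in errors.columns:
                    row[f"{m}_change"] = float(cur.loc[pid, m] - base.loc[pid, m])
            rows.append(row)
    return pd.DataFrame(rows)


def rank_tests(
    change: pd.DataFrame, metric: str = "item_error_change", holm: bool = False
) -> pd.DataFrame:
    """Simple nonparametric wrappers on change scores.

    Within-subject session pairs get a Wilcoxon signed-rank test against
    zero change; pairs of delay groups get a two-sided Mann-Whitney U on the
    same session's change scores. ``holm=True`` applies a Holm adjustment
    across the reported p-values (off by default).
    """
    rows = []
    col = change[metric]
    for sess, grp in change.groupby("session"):
        vals = grp[metric].to_numpy()
        if len(vals) >= 5 and np.any(vals != 0):
            w = stats.wilcoxon(vals)
            rows.append(
                {"test": "wilcoxon_vs_zero", "session": sess, "groups": "all",
                 "statistic": float(w.statistic), "p_value": float(w.pvalue), "n": len(vals)}
            )
        groups = sorted(grp["delay_group"].unique())
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = grp.loc[grp["delay_group"] == groups[i], metric].to_numpy()
                b = grp.loc[grp["delay_group"] == groups[j], metric].to_numpy()
                if len(a) >= 2 and len(b) >= 2:
                    u = stats.mannwhitneyu(a, b, alternative="two-sided")
                    rows.append(
                        {"test": "mann_whitney", "session": sess,
                         "groups": f"{groups[i]} vs {groups[j]}",
                         "statistic": float(u.statistic), "p_value": float(u.pvalue),
                         "n": len(a) + len(b)}
                    )
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_value_holm"] = adj
    return out
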