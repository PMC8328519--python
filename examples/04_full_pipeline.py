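"""Run the whole analysis end to end on a synthetic two-session cohort.

The generated cohort has growing item errors and a gist pull that switches
on only at the second session — the signature of item memories degrading
into the gist over a retention interval. The pipeline applies swap
correction and exclusions, computes errors and bias, and compares the
observed bias to the item-only null at each session.
"""

from gistmem import RunConfig, calibrate_layout, run_analysis
from gistmem.synthetic import GenerativeParams, generate_cohort, load_preset

targets, _, n_items, screen = load_preset("exp1", seed=0)
layout = calibrate_layout(targets, n_items, screen, seed=0)

params = GenerativeParams(
    n_participants=30, sessions=("S1", "S2"), delay_groups={"1month": 30},
    item_error_scale={"S1": 70.0, "S2": 160.0},
    gist_error_scale={"S1": 45.0, "S2": 60.0},
    gist_pull={"S1": 0.0, "S2": 0.6},
    swap_rate=0.02, seed=21,
)
cohort = generate_cohort(layout, params)

result = run_analysis(cohort, config=RunConfig(experiment="exp1", seed=21, n_simulations=500))
print(f"retained participants: {result.exclusions['retained_n']}")

errors = result.tables["errors"].groupby("session")[["item_error", "gist_error"]].mean()
print("\nmean errors by session (px):")
print(errors.round(1).to_string())

gaps = result.tables["bias_gaps"].groupby("session")[
    ["observed_bias", "sim_item_only_bias", "gap_item_only"]
].mean()
print("\nobserved vs item-only simulated bias by session:")
print(gaps.round(3).to_string())
print("\nThe near-zero gap at S1 and the large positive gap at S2 show")
print("center-ward attraction emerging with delay, while item error grows")
print("much faster than gist error.")
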