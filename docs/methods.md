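# Methods

`gistmem` analyses spatial-memory cohorts in which participants learn a set
of item locations on a screen and later retrieve each item plus the
perceived center of the whole set. The package quantifies how item memories
degrade and drift toward the remembered gist (the set's spatial center)
over retention intervals. This note documents the models, the parameters
that matter, and the choices made where the design was genuinely open.

## Error measures and chance baselines

For a layout of `n` encoded points `e_1..e_n` on a screen and one
participant-session with retrievals `r_1..r_n` and a reported center `c`:

- **item error** = mean_i `d(r_i, e_i)`;
- **gist error** = `d(c, E)` with `E` the centroid of the encoded points;
- **estimated-center error** = `d(centroid(r), E)` — the gist a participant
  could reconstruct purely from item memories.

`d` is the Minkowski distance `(|dx|^g + |dy|^g)^(1/g)` with `g = 2`
(Euclidean) throughout unless a sensitivity analysis selects `g = 1.5`;
only `1 < g ≤ 2` is accepted, the range in which `d` is a metric.

Chance baselines come from the layout alone: the mean distance of encoded
items to the screen center (item chance for a screen-center clicker), the
mean distance of items to their own centroid (item chance for a
gist-only responder), and the distance from screen center to the centroid
(gist chance). Baselines are reported unrounded with a convenience
integer-pixel rounding, matching how such values are conventionally
printed.

## The bias statistic

Per item, against a reference center `C`:

```
bias_i = ( d(e_i, C) − d(r_i, C) ) / d(e_i, r_i)
```

The triangle inequality bounds `bias_i` to `[−1, 1]`; `+1` means the
retrieval moved straight toward `C`, `−1` straight away. A participant's
bias is the unweighted mean over items. Four reference centers are
supported: the participant's **reported** center (default), the **encoded
centroid**, an **accuracy-weighted** centroid with item weights
`(1 − err_i/Σerr)/(n−1)` (more accurate items count more; weights sum to 1
exactly), and — on outlier layouts — the **local center** excluding the
outlier. A perfect retrieval makes the statistic 0/0; it is defined as 0
(the numerator also vanishes), with an option to exclude such items from
the mean instead. The outlier item is included in local-mode averages, and
its per-item value is always reported separately so outlier-only analyses
remain possible. When all reference centers nearly coincide, participant
bias under the different centers is highly correlated (the suite checks
pairwise r > 0.9 on a synthetic cohort of 60).

The statistic is deliberately error-normalized, which creates an artifact:
for a fixed displacement direction, larger errors push the value negative
(a perpendicular displacement of 40 px at an item 100 px from the center
already scores ≈ −0.19). Raw bias values are therefore never interpreted
alone but against the null models below; the suite verifies that the
item-only expectation is non-increasing as errors scale up.

## Null models

Both nulls preserve each item's *observed* error magnitude exactly and
randomize only the direction; each of the (default) 1000 runs redraws
every item once and scores the mean item bias against the same center used
for the observed bias, plus the run's estimated-center error.

- **Item-only**: direction uniform on the circle; draws falling off-screen
  are rejection-resampled (a hard cap of 10^4 rounds raises a geometry
  error rather than looping forever).
- **Item-plus-gist**: the circle is divided into 200 candidate angles (arc
  centers, phase fixed at the +x axis; the phase is a convention with no
  published counterpart). Candidate `i` at distance `d_i` from the center
  gets probability `(d_i − max_j d_j) / Σ_j (d_j − max_j d_j)` — numerator
  and denominator are both non-positive, so this is the normalized linear
  decrease in distance; the farthest candidate gets probability 0.
  Off-screen candidates are removed and the distribution renormalized,
  which is distribution-equivalent to resampling. If the center is
  equidistant from all candidates (center at the encoded point) the
  distribution falls back to uniform.

The gist-attraction strength is exactly the linear law above, with no free
temperature parameter: the attraction level in this null is a fixed
modelling convention, not a fitted quantity, so item-plus-gist simulated
bias is an anchor, not a prediction. The quantity that carries inference
is the **gap** `observed − item-only simulated bias`: positive values mean
more center-ward attraction than direction-free noise with identical
errors can produce.

RNG: every (participant, session, model) gets its own substream derived
from the cohort seed via CRC-32 of the keys into a `SeedSequence`, so
results are independent of processing order and bit-reproducible.

## Outlier-weight model

On layouts with one designated spatial outlier, the reported center is
modelled as `w·outlier + (1−w)/(n−1)·Σ others`. The candidate centers for
`w ∈ [0, 1]` trace the straight segment from the local center (`w = 0`)
through the global centroid (`w = 1/n`) to the outlier (`w = 1`). `w` is
estimated on an 81-point grid (step 0.0125) by minimizing the distance to
the reported center; ties resolve to the smaller weight (conservative
against inferring over-weighting). The equal-weight benchmark is `1/n`
computed from the layout, so six-item layouts are handled. As printed, the
shared non-outlier weight at `w = 0` is `1/(n−1)` ≈ 0.143 for eight items,
slightly above the stated 0–0.125 range; the formula is implemented as
stated and the range read as descriptive. Because the grid argmin equals
the orthogonal projection of the reported center onto the segment snapped
to the nearest grid point, the suite cross-checks it against that closed
form on random layouts. Continuous (off-grid) optimization is deliberately
not part of the headline path — the estimator is grid-based by design.

## Preprocessing

**Swap (misbinding) correction.** A pair (A, B) is flagged when the
retrievals are mutually nearest to each other's encoded locations, both lie
within `d(e_A, e_B)/2` of the encoded location each is nearest to, and no
other retrieval intrudes into that range. The "within range" condition has
two defensible readings; the default applies the radius to the nearest
(swapped partner's) location, since requiring both radii simultaneously
would conflict with the mutual-nearest geometry in most configurations —
the stricter lens-shaped reading is available via `lens_region=True`.
Nearest-encoded ties break by label order (measure-zero on continuous
data). Flagged pairs are exchanged label-wise; the suite verifies the
correction never increases the pair's summed error and is a fixed point
under re-detection.

**Exclusions.** Three rules, reported per participant with a reason:
`gist_out_of_scope` — Session-1 gist error above the gist chance baseline
(the report is outside the scope of the learned locations); applied only in
designs without an outlier, because with an outlier a large gist error can
itself be the effect of interest. `outlier_misplaced` — outlier-item error
exceeding the distance from screen center to the encoded outlier (573 px on
the calibrated eight-item layout): the outlier was placed among the main
cluster, which would spuriously inflate center-ward bias.
`three_sd` — item or gist error more than 3 SD worse than the session mean,
computed per metric per session in one pass (no iterative re-exclusion)
after the participant-local rules; with fewer than two participants the
rule is skipped with a warning. The participant-local rules are monotone in
cohort composition; the 3 SD rule is cohort-dependent by construction.

## Layout calibration

Encoded coordinates are not published for these designs; what is published
is the chance geometry. `calibrate_layout` therefore solves for item
coordinates that reproduce the three chance baselines (six items: 348/267/
270 px; eight items: 386/262/223 px with the outlier 573 px from screen
center) via seeded random restarts of an L-BFGS-B minimization of the
squared residuals, with box bounds keeping items on-screen and soft
penalties enforcing pairwise separation (> 160 px for the six-item design,
> 100 px for the eight-item design — both implied by training criteria
being less than half the shortest pair distance) and, for the outlier, a
gap to the remaining items' centroid of at least the outlier's own offset.
Success requires every residual below 0.05 px (typical residuals are
~1e-6 px), an order of magnitude inside the 0.5 px acceptance band.
Infeasible targets (triangle-inequality violations on the means, or an
outlier offset beyond the screen half-diagonal) raise a calibration error
up front. The solution is one representative of a large solution family;
every quantity the package computes from it (baselines, biases, weights)
is either constrained by the targets or invariant to the residual freedom.
The screen defaults to 1366×768 — a common laptop resolution whose
half-diagonal (~783 px) accommodates the 573 px outlier offset — and is
configurable.

## Synthetic cohorts

`generate_participant` draws, per item, an error magnitude from a folded
normal `|N(scale, 0.3·scale)|` and a direction from the mixture
`(1−λ)·uniform + λ·(item-plus-gist angle law)` toward the generative
center (the local center on outlier layouts — reflecting that gist reports
in such designs track the main cluster — otherwise the global centroid; a
flag overrides this). The reported center is the outlier-weighted centroid
(or true center) plus isotropic `N(0, σ_c)` noise; with probability
`swap_rate` one random item pair is exchanged. Out-of-bounds draws are
resampled. The error distribution is a modelling choice (no retrieval-error
distribution is published); CV 0.3 keeps magnitudes positive and
realistically dispersed. Because the generator reuses the null model's
angle law, the item-plus-gist null is correctly specified for λ = 1
cohorts, giving the test suite an exact ground truth.

Two shipped presets define the default study conditions: a six-item,
two-session, between-subject design (130 participants split 44/43/43
across 24 h / 1 week / 1 month delays, item-error scales growing with
delay faster than gist-error scales, gist pull increasing with delay,
2% swap rate) and an eight-item, three-session within-subject outlier
design (43 participants, outlier weight 0.25 — above the 0.125 benchmark —
no swaps). Session-1 error scales sit near the training criteria (80 px
and 50 px respectively); later-session scales are chosen to keep item
errors well below the item chance baselines while growing severalfold.
What the generator does *not* emulate: real participants' heavy-tailed
error distributions, spatial anisotropy, item-specific difficulty, and
any trial-order effects — so green tests certify the pipeline's
correctness on its stated model, not distributional fidelity to any real
cohort.

## Pipeline, sizes and budgets

`run_analysis` chains swap correction, exclusions, error summaries, bias
per requested center mode, the two null models, and (on outlier layouts)
the weight fits, and emits tidy CSV tables plus a JSON run report carrying
the seed and a config hash; rerunning with the same inputs is
byte-identical. `compare_sessions` produces per-participant change scores
(session k − session 1); omnibus inference (aligned-ranks ANOVAs, mixed
models) is intentionally delegated to external statistical tooling, with
only Wilcoxon / Mann-Whitney wrappers provided, uncorrected by default and
with an optional Holm adjustment. Test and example problem sizes (cohorts
of 12–40, 100–1000 simulation runs) are chosen so the full suite completes
in seconds while keeping Monte Carlo standard errors an order of magnitude
below the effects being asserted.

## Known limitations

- Calibrated layouts are representatives of an under-determined family;
  analyses that depend on higher-order layout geometry (e.g. exact item
  eccentricity profiles) are not pinned down by the published distances.
- The item-plus-gist null's attraction strength is a convention; the gap
  to the item-only null, not agreement with the gist null, is the
  interpretable quantity.
- The bias statistic's error-normalization makes single values
  uninterpretable without the matched nulls; the package never reports one
  without the other in its pipeline outputs.
- Minkowski exponents `g ≤ 1` (city-block and below) are out of scope; the
  bias bound proof requires the metric triangle inequality.
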