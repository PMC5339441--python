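# Methods

## Posture classification and bout segmentation

The detector works on a single-axis acceleration series recorded at 1 Hz on
a hind leg. While the horse stands, the measured axis is aligned with
gravity and reads near −1 g; in sternal or lateral recumbency the metacarpal
bone is horizontal and the reading sits near 0 g. Classification is a fixed
threshold at −0.75 g: samples above it are lying, samples below standing.
The threshold value itself is the classifier; no training is involved.

Three numerical conventions are not determined by the threshold rule and
were fixed as follows:

* **Equality at −0.75 g → standing.** The two strict inequalities of the
  rule leave the boundary undefined; assigning it to standing is the
  conservative choice (it cannot inflate recumbency). Exact equality is
  measure-zero for real sensors, so this only matters for synthetic input.
* **Majority smoothing.** Locomotion produces brief excursions across the
  threshold. Each sample is replaced by the majority state over the 15 s
  before and after it. The median of a binary series *is* its majority
  vote, so this is implemented as a single majority pass. The centre sample
  is included (window of 31, odd, hence tie-free in the interior); a flag
  (`include_center=False`) exposes the 30-sample variant. At the series
  edges windows are truncated without padding, and a tie under truncation
  falls back to the sample's raw state.
* **Half-open bouts.** A bout is a maximal smoothed lying run, `[start,
  end)` in whole seconds, so duration = end − start and adjacent intervals
  never share a second. Runs shorter than 30 s are discarded (30 s is
  retained, 29 s is not).

Traces with missing samples are split at gaps longer than 5 s and the
segments processed independently; shorter gaps are forward-filled. Loggers
drop occasional samples, and smoothing across an unobserved gap would
fabricate state.

Bouts whose midpoint falls inside a logged pasture-access interval are
removed. The original workflow removed the handful of pasture bouts by
manual inspection; the midpoint rule is a deterministic proxy that keeps a
bout which merely brushes a boundary. Overlapping pasture intervals are
merged with a warning.

A brute-force reference detector (explicit loops over every window) lives in
the test suite and in `scripts/acceptance.py`; the vectorised implementation
must match it exactly, which pins down every edge and tie convention above.

## Per-24 h metrics

A 72 h recording is cut into three 24 h blocks from the recording start. A
bout spanning a block boundary is split there: each fragment counts as a
bout in its own day (keeping per-day durations additive over the 72 h), the
sternal/lateral split is prorated by fragment duration, the members-present
count belongs only to the fragment containing the lie-down (a continuation
is not a lie-down event), and the termination label is inherited by all
fragments.

Percentages per horse-day: lateral recumbency relative to total recumbency;
members present averaged over lie-downs with denominator group size − 1
(the focal animal excluded — including it would cap the proportion below
100%; a flag restores the inclusive reading); forced terminations relative
to the day's bout count. Proportions with an empty denominator (no
recumbency, no bouts) are *missing*, not zero, so the modelling stage drops
them instead of biasing toward zero. The under-30-min flag marks horse-days
below the 30 min REM-sleep proxy; a second flag marks horses below 30 min
over an entire 72 h recording.

Detected bouts are joined to video-style annotations by nearest start time
within ±60 s (half the smoothing window on either side of either boundary),
since detected boundaries can shift relative to the annotated ones; the
annotated position split is prorated to the detected duration.

## Dominance rank

Each unordered pair of group members is tested once; the order is drawn by
seeded rejection sampling under the welfare constraint that no horse takes
part in more than two consecutive encounters. A horse's dominance ratio is
its wins divided by its own dyad count (group size − 1) — the only
denominator that puts every horse on [0, 1]; a ratio of exactly 0.5 is
classed low-ranking, per the stated class intervals (low 0–0.5, high
>0.5–1). The group mean ratio is exactly 0.5, since every dyad awards one
win. Ties within an encounter are not representable; the observational
protocol adjudicates a winner upstream.

## Littered-area dimensioning

The legal minimum is the dot product of the group's withers-category counts
with the per-category areas (4.0, 4.5, 5.5, 6.0, 7.5, 8.0 m² for the six
categories from <120 cm to >175 cm), computed in exact decimal arithmetic.
Treatments allocate `ratio × minimum` to litter and the rest of the fixed
1.5× footprint to rubber mats, rounded half-up to 0.1 m² — the rounding
convention that reproduces the published design table in 31 of 32 cells.
The one exception (group 8 at the half-minimum treatment, printed 10.2 m²
where 20.5 × 0.5 = 10.25 rounds to 10.3) is inconsistent with the table's
seven other half-cases and is treated as a misprint; it is excluded as a
test target and reported as the single expected mismatch. The category
schedule is data, not code, so a legislative revision is a config change.

## Mixed-model design

The four treatments form an ordered factor coded by orthonormal polynomial
contrasts (computed by QR orthogonalisation of the Vandermonde basis on
equally spaced scores; for four levels the linear column is ∝ (−3, −1, 1,
3)). Outcomes pooled over surfaces get the full cubic coding; per-surface
outcomes quadratic only. Fixed effects: the treatment polynomial, rank
status (low/high) and their interaction. Random intercepts nest the
experimental condition in the horse in the group (variance components in
`statsmodels` MixedLM, REML). If a fit fails or returns non-finite
estimates, the innermost random level is removed first, with a logged note.

Transformations: durations with zeros use log(x + 1 min); proportions use a
logit after shrinking exact 0/1 inward by 1/(2n). Both are exactly
invertible, and back-transformed estimates are medians, not means, of the
response distribution — the estimate tables flag this. Binary outcomes
(the under-30-min flags) are fitted by binomial GEE clustered on the horse
with an exchangeable working correlation and Wald χ² tests, a pragmatic
frequentist stand-in matching the χ²-style reporting such models receive.

Term tests are Wald F statistics against the residual degrees of freedom
(observations − fixed-effect columns). This is an approximation — no exact
denominator df exists for this design — and is documented as such.

**Backward reduction.** Terms are dropped one at a time while their p
exceeds 0.1, under marginality: the interaction must leave before rank or
any treatment degree it involves, and the cubic treatment term before the
quadratic before the linear. Among droppable candidates the largest p goes
first, ties broken toward the higher polynomial order. The treatment
degrees are separate single-df terms (so a cubic coding can reduce to a
quadratic or linear description), while the rank × treatment interaction is
one joint block tested and dropped as a whole. The block treatment is a
deliberate design choice: it makes "is the interaction retained?" a single
decision with the nominal type-I rate of the drop rule (≈10%), where
per-degree interaction terms would inflate the retention rate of "any
interaction term" to roughly 1 − 0.9³ ≈ 27%.

A consequence worth stating: in a model with k null terms, the probability
that *all* of them are eliminated is roughly 0.9^k, so even under a pure
single-effect truth the final model contains some extraneous term in a
third or so of replicates. The tests assert the derivable properties — the
true term is always retained and each null term survives at about the
nominal rate — rather than a higher all-clear probability that the rule
cannot deliver.

## Synthetic-study generator

The generator emulates the experiment the analysis is designed for: 8
groups with sizes (4, 4, 7, 4, 6, 6, 3, 4) — 38 horses — each exposed to
treatments with littered-area ratios 0, 0.5, 1, 1.5, recorded 72 h per
treatment at 1 Hz, standing level −1 g, lying level 0 g, Gaussian sensor
noise 0.05 g.

Defaults, chosen once as realistic study conditions:

| parameter | default | rationale |
|---|---|---|
| `bout_rate_per_24h` | 4 | polyphasic lying, a few bouts per night |
| `bout_duration_mean` | 10 min | baseline total ≈ 40 min/24 h, low end of the reported 30 min–2.7 h range for the litter-poor end of the ladder |
| `treatment_effect` | +25 min per unit ratio | tens of minutes between no-litter and 1.5× conditions |
| `rank_interaction` | +25 min per unit ratio (low-ranking only) | low-ranking horses keep gaining where high-ranking plateau |
| `forced_termination_prob` | 0.25 low / 0.05 high | forced terminations concentrated in low-ranking horses |
| `lateral_fraction` | 0.08 | untransformed lateral estimates run ≈7–13% |
| `dark_period_weight` | 0.6 | most sleep after midnight; no distribution is reported, so a two-component day/night mixture over 00:00–06:00 vs the rest |

Bout counts per day are Poisson; durations are exponential with the mean
inflated so expected *total* recumbency equals rate × mean + injected
effects (durations, not counts, carry the treatment effect). Bout-duration
distributions for real horses are not reported anywhere usable, so the
exponential is an explicit placeholder. Bouts are placed without overlap by
rejection. Latent dominance is a uniform score per horse, median-split into
low/high for effect injection, mirroring the dichotomised rank the analysis
uses.

The rendered signal models locomotion as bounded oscillation around the
standing level, clipped below −0.8 g so it can never mimic recumbency for
more than a moment, plus isolated 1–3 s spikes toward lying — long enough
to exercise the smoother, never long enough to survive it. What the
generator does **not** emulate: sensor drift and attachment artefacts,
weather/season effects, age and sex structure, inter-group synchrony of
lying, and any dependence of forced terminations on crowding. Passing
end-to-end tests therefore shows the chain is internally consistent and
recovers the injected structure at realistic noise, not that the detector
is validated on real loggers.

Determinism: every random draw descends from `SimConfig.seed` through
per-(group, treatment, horse) `default_rng` substreams, so any pipeline run
is bit-reproducible.

## Validation experiment sizes

The detector-reference comparison uses 1,000 random 2 h traces; end-to-end
recovery runs the full 8-group scenario (≈1,600 analysable bouts, 442
horse-days with recumbency). For detector-vs-truth comparisons the truth is
restricted to bouts of at least the 30 s minimum — shorter episodes are
excluded from analysis by construction, so they are not part of the
quantity the detector estimates. The stepwise power experiment uses 200
replicates of the full 38-horse study; the type-I experiment uses 200
replicates of a four-group study, since the nominal rate of the drop rule
does not depend on the sample size while the fit cost does. Measured on
these sizes: interaction retention ≈75% with the default injection,
direction agreement 100%, null retention within the 95% binomial band
around 10%.

## Known limitations

* Denominator df and the GEE stand-in for binomial mixed models are
  approximations; exact small-sample inference is out of scope.
* The stepwise rule inherits the usual caveats of p-based selection
  (post-selection inference is not corrected).
* Pasture exclusion by midpoint can keep a bout that mostly overlaps an
  access interval; the study context makes such bouts rare and short.
* The generator's exponential bout durations are a placeholder; any
  analysis sensitive to the duration distribution's shape should treat
  simulated power figures as indicative only.
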