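# Methods

This note documents the models and procedures implemented in `ciconia`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic data do and do not establish about real tag data.

## Accelerometry

Tags record 9-s tri-axial bursts (surge, sway, heave, in g) every 20 min.
ODBA is computed per burst by subtracting a **centered running mean of
4 s** from each axis and averaging the per-sample sum of absolute
residuals over the three axes. Two numerical conventions matter:

- The window width is `round(window · rate)` samples, centered and
  *truncated* at the burst edges (no padding): a constant burst maps to
  itself and ODBA for it is exactly zero. For even widths the window is
  left-heavy (⌊w/2⌋ samples before, w−1−⌊w/2⌋ after), matching the
  underlying rolling-mean implementation; the unit tests pin this down
  against a brute-force windowed mean.
- Burst ODBA is the **mean** over samples, not the sum, so values are
  comparable across burst durations and sampling rates. Consequences:
  ODBA ≥ 0, equals 0 iff the dynamic component vanishes, and is invariant
  to per-axis constant offsets and to axis permutation.

Behavior classification uses a random forest over a fixed 15-element
feature vector: per-axis mean, SD and dynamic range, ODBA, the three
pairwise axis correlations (defined as 0 when an axis is constant), the
dominant non-DC heave frequency, and the fraction of dynamic heave power
above a quarter of the sampling rate. The tags' manufacturers differ in
sensor sensitivity; the package carries a `tag_type` column through all
outputs and supports one classifier instance per tag family, but applies
no cross-calibration. The feature set is an implementation choice (the
field workflow this mirrors does not standardize one); the contract is
the fixed feature order plus seed-determinism, not the particular
learner.

Behavioral budgets are proportions of bursts per behavior, computed per
calendar day and then averaged across the days of the period, so
unequally sampled days carry equal weight. Bursts are equally spaced, so
proportion of bursts is proportion of time.

## Trajectory segmentation

Distances are great-circle (haversine, Earth radius 6371.0088 km). Track
cleaning drops duplicate timestamps (first record kept) and any fix
implying a sustained speed above 120 km/h from the last retained fix — a
deterministic greedy pass replacing the manual outlier screening used
with field data.

A **roost** is the median position of nocturnal fixes (22:00–04:00 local
solar time, longitude/15 h offset from UTC), assigned to the evening's
date; the median resists the occasional displaced fix. A **migration
bout** is a maximal run of calendar-consecutive days, each with
roost-to-roost displacement > 60 km, of length ≥ 3. Consecutive means
strictly calendar-consecutive: a day without a roost breaks a run. This
is the strictest reading of the rule; a gap-tolerant variant was
considered and rejected as the default because it changes detected
departure dates on sparse tracks in ways that are hard to audit.
Qualifying runs whose net effect moves the bird away from its first roost
form the autumn (outbound) window — first day of the first such run to
last day of the last; runs heading back form the spring window. Using net
displacement from the series origin rather than raw latitude keeps the
rule geography-agnostic.

Strategy classification follows fixed rules with two configurable
latitude lines: any roost south of the Gibraltar line (35.9° N) makes the
bird a migrant for that cycle; migrants whose wintering-period roost
centroid lies south of the Sahara line (20° N) are sub-Saharan, otherwise
Northwest African; residents are local iff every roost is within 50 km of
the nest. Latitude lines replace coastline polygons deliberately: at
roost scale the strait crossing and the desert crossing are
latitude-monotone, and the lines are configuration, not code. Strategy
labels are per annual cycle; an individual that switches between years
simply gets different labels in different cycles.

Season partitions tile the annual cycle, anchored 4 Aug – 3 Aug so that
every cycle contains exactly one wintering period. Migrant seasons come
from the detected windows (wintering = between them, breeding = the
remainder, which may wrap around the anchor and is stored as up to two
closed date segments); resident seasons use the fixed dates autumn 4
Aug–5 Sep, wintering 6 Sep–12 Dec, spring 13 Dec–22 Jan, breeding 23
Jan–3 Aug. Intervals are closed on both ends, consistent with those
printed boundaries. A validation pass rejects any partition that
overlaps or leaves gaps.

Nest occupation is the first date *d* such that *d*, *d*+1, *d*+2 each
contain at least one fix within 75 m of the nest (the radius is not
standardized anywhere; 75 m separates the nest from adjacent foraging at
typical GPS error and is configurable). The function scans whatever fix
window it is given; the CLI passes fixes from 1 October onward so the
date measures the return for breeding rather than the pre-departure
residence.

## Multievent survival model

States (Aa, Ai, Ra, LD) and events (0–3) are described in the README.
Design constants fixed at 1 and never estimated: release state
(τ_Aa), detection with an active tag (p_Aa), and dead recovery (r).
Transition composition order is **survival first, then tag fate**:

| from \ to | Aa | Ai | Ra | LD |
|---|---|---|---|---|
| Aa | φ(1−λ) | φλ | 1−φ | 0 |
| Ai | 0 | φ | 0 | 1−φ |
| Ra | 0 | 0 | 0 | 1 |
| LD | 0 | 0 | 0 | 1 |

so "recently dead with active tag" is reachable exactly when death
occurs while the tag was active; death and tag failure in the same
interval resolve to Ra (death takes precedence) — a convention, flagged
as such. Ra persists one occasion and collapses to LD, giving recovery a
single opportunity. λ is constant across groups and occasions by
default.

The likelihood is the forward algorithm conditioned on release in Aa,
with per-step renormalization for numerical stability; impossible
histories return −∞ rather than raising. Fitting maximizes the joint
log-likelihood on the logit scale with L-BFGS-B from 10 seeded uniform
(−2, 2) starts; ties break by lowest deviance then start index.
Confidence intervals are Wald on the logit scale from a central-difference
Hessian, back-transformed. Model comparison uses
QAIC = −2 logL/ĉ + 2K and QAICc = QAIC + 2K(K+1)/(n_eff − K − 1), with ĉ
supplied externally (goodness-of-fit testing that estimates it is out of
scope) and n_eff defaulting to the number of individuals, the standard
capture–recapture convention.

## Synthetic data

The generator's defaults are the study conditions the pipeline assumes:
fixes every 20 min; 9-s bursts at 1 Hz (the tags' stated schedule — at
1 Hz that is 9 samples, so spectral tests also run at 10 Hz, and the
rate is configurable); a population mix of 9:42:6:10 across
local/regional/NW-Africa/sub-Saharan; nests in southern Portugal
(38.8° N ± 30 km); wintering centroids at 31.5–34.5° N for NW-Africa and
13.5–16.5° N (Sahel) for sub-Saharan birds; migration legs averaging
150–200 km/day (randomized 0.8–1.2×, minimum three legs so every
migration satisfies the detection rule); regional movements in sub-60-km
legs to a wintering area 80–250 km from the nest; wing length
580 ± 20 mm with migration logit slope −0.04 per mm and intercept −1.29
(≈ 21 % migrants at the mean, matching the emulated population). Burst
dynamics: near-zero noise (σ = 0.01 g) for resting, broadband σ = 0.15 g
for foraging, a slow 0.04–0.12 Hz drift of amplitude ≈ 0.06 g for
soaring, and a ~3.5 Hz heave oscillation of amplitude ≈ 0.4 g with a
surge harmonic for flapping.

What the generator does **not** emulate: thermals and weather, landfill
foraging dynamics, coastlines and habitat, GPS fix failure patterns,
tag-family sensor differences, stopovers during migration, and
behavior-misclassification structure of real labeled corpora. Passing
recovery tests therefore demonstrates that the *rules and estimators are
implemented correctly and are mutually consistent*, not that the
classifier's synthetic accuracy (≈100 %) or the rule thresholds transfer
to field data — the published workflow reports ~96 % classifier accuracy
on real labeled bursts, which synthetic bursts cannot stand in for.

Encounter histories are drawn from the multievent module's own transition
and event matrices, so simulation–estimation tests are internal
consistency checks of the likelihood and optimizer; the independent
guarantee comes from the exhaustive path-enumeration oracle that the
forward algorithm is tested against.

## Problem sizes

The test suite and acceptance script use 40 annual tracks (10 per
strategy) for strategy recovery, 1000 labeled bursts (250 per class) for
the classifier, 500 and 2000 histories × 6 occasions for parameter
recovery, and 50 replicates of 150 histories for null-model selection —
sizes at which every stochastic check is stable across seeds while the
whole chain runs in about a minute on one CPU.

## Known limitations

- The migration-window rule assumes a roost can be computed for nearly
  every day; very sparse tracks (no nocturnal fixes) silently shorten
  runs. The gap-tolerant variant is future work.
- Wald intervals on the logit scale degrade near parameter boundaries
  (φ → 1); profile likelihood would be preferable there and is not
  implemented.
- `n_eff` for QAICc is the number of individuals; alternatives (total
  releases, effective sample size from the saturated model) change QAICc
  by O(1) at these sample sizes.
- The classifier is trained and evaluated per corpus; no cross-tag-type
  transfer or calibration is attempted, mirroring the carried-metadata
  design.
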