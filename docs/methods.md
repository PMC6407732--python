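# Methods notes

This note records the modelling and analysis choices behind `gazepair`:
what the procedures assume, which parameters matter and why they default
to what they do, what the synthetic-data generator does and does not
emulate, and the numerical conventions adopted where the problem left the
design open.

## Display geometry and AOI assignment

The search display is a 5 × 5 hexagonal grid of 25 elements. Cells are
hexagons with two vertical edges (the flat-to-flat direction is
horizontal), flat-to-flat diameter 4.6°, which equals the spacing of
adjacent centers, so the cells tile the plane without gaps or overlap.
Coordinates are degrees of visual angle, display-centered, y increasing
downward; elements are indexed 0–24 row-major from the top-left, rows 1
and 3 shifted right by half a cell, vertical row pitch 4.6 · cos 30°.
The middle element (id 12) sits at the origin.

Two conventions here were genuinely open and are fixed as follows:

* **Grid placement.** A half-row-offset 5 × 5 grid has a bounding box
  25.3° wide that is *not* symmetric about the middle element (offset
  rows protrude 13.8° on one side, 11.5° on the other). The box fits the
  25.8° display, but the display's pixel origin — not the element
  layout — absorbs the 0.5° of slack. We keep element 12 at the
  coordinate origin and make no claim about where the box sits on the
  physical screen.
* **Border ties.** A point on a shared border is assigned to the hexagon
  with the nearest center, ties then to the lower id. Deterministic and
  testable; the measure-zero choice cannot affect any statistic.

Pixel↔degree conversion defaults to the arc-length (radian)
approximation `deg = px · mm_per_px / distance · 180/π`, under which the
1040-px display spans 25.8°; an exact `2·atan(L/2D)` variant is provided
(`method="arctan"`). Element jitter draws, per element and axis, a
magnitude uniform in [0, 0.805°] with random sign.

## Online gaze-marker rule

Per display frame (60 Hz), samples in the trailing half-open 30-ms
window `(t − 0.03, t]` are combined binocularly (mean of valid eyes;
single-eye fallback), assigned to hexagons, and the modal hexagon is
highlighted. Cases the basic rule leaves open:

* *All samples in different hexagons*: a saccade is assumed and the
  latest sample's hexagon wins. We generalise this to every modal tie:
  among tied modal hexagons the one with the most recent supporting
  sample is chosen, which reduces to the saccade rule when all counts
  are 1.
* *No valid samples in the window*: the previous frame's highlight is
  held; at trial start nothing is highlighted.
* A modal sample outside every hexagon highlights nothing.

Highlight runs strictly shorter than 50 ms are treated as visualised
measurement error ("flicker"); the quality metric is the fraction of
frames in such runs. A run of exactly three frames at 60 Hz (50 ms) is
not flagged.

## Event layer

Fixations come from a dispersion detector (I-DT family) on the
binocular-averaged signal: maximal runs of consecutive valid samples
whose per-axis range stays within 1.0° and that last ≥ 60 ms, with the
centroid as position. Each sample is credited one nominal inter-sample
interval, so a constant 1-s stream yields a 1-s fixation. The detector is
deliberately simple — more elaborate detectors (e.g. two-means
clustering) differ mainly under data loss and extreme noise, which the
generator does not emulate — and every downstream function accepts an
externally supplied fixation list, so real detector output can be slotted
in unchanged.

Dwells merge consecutive same-hexagon fixations; fixations outside the
grid are dropped but break merging (the sequence 5, outside, 5 is two
dwells on 5 — gaze demonstrably left the cell). Transitions connect
consecutive dwells on different hexagons, with amplitude measured between
the bounding fixation centroids. Dwell rate counts *visits* per second of
search time (onset to response), reading "elements inspected per second"
as a visit rate; a unique-hexagons variant is exposed alongside since
both readings are defensible.

Precision metrics are computed within fixation episodes and averaged
across them: RMS of consecutive-sample distances, and
`sqrt(var_x + var_y)` (ddof = 1). Because the signal is
binocular-averaged, per-eye white noise of sd σ per axis yields
`mean_sd ≈ σ` (averaging halves the variance, the two axes double it);
on monocular data the same metric reads σ√2.

## Coordination metrics

**Dwell overlap** is the proportion of a searcher's dwells that land on
hexagons already durably highlighted on their screen — i.e. overlap is
judged against what the searcher could actually have seen (the partner's
highlight log), not against the partner's true dwells, and highlight runs
≤ 50 ms are excluded as flicker. A dwell overlaps when such a run's onset
precedes the dwell's onset.

**Cumulative overlap** per trial is the fraction of the 25 elements
inspected by both parties by each frame time, starting at 0 at stimulus
onset and non-decreasing up to 1 at full joint coverage. Trials end at
different times, so the aggregated curve averages only trials still
running at each time point, and the 95% band is a percentile bootstrap
(default 1,000 iterations, seeded) that resamples whole trials.

**Blind baseline.** Two searchers' individual trials are matched greedily
in order of occurrence on target location; each matched pair contributes
an artificial trial with the faster member's RT, response and
correctness (RT ties to the first searcher). This estimates the joint
performance of a non-interacting pair. For iid exponential individual
RTs the baseline mean converges to half the individual mean (minimum of
two exponentials), which the tests verify by simulation.

**Entropies.** Dwell-distribution entropy is the Shannon entropy of
per-element dwell proportions pooled over a condition's trials
(0 log 0 ≡ 0). Transition entropy is reported in two variants because
they answer different questions and have different ceilings: the
conditional form (destination unpredictability given the origin; max
log₂ 24) and the joint form over ordered pairs (max log₂ 600 = 9.23
bits). They obey `joint = conditional + H(origin marginal)`, which the
tests check against brute-force summation. The pipeline reports both per
condition × participant.

**Performance.** Error rate is the fraction of incorrect responses;
targets-per-second is correct trials divided by total search time —
defined operationally here since only the name of the measure is
standard. Heat maps sum isotropic Gaussian kernels (default σ = 1.0°) at
dwell centroids on a 0.1°-resolution raster and zero everything below
10% of the maximum.

## Statistics

Quartiles use linear interpolation between order statistics (numpy's
default), documented so printed-quartile tests are stable; whiskers end
at the most extreme data points within 1.5 · iqr of the box. PS_dep is
read literally as n₊/N with N counting *all* pairs, ties included; the
Wilcoxon test itself drops zero differences, uses mid-ranks, exact
enumeration up to 25 untied non-zero differences and the
continuity-corrected normal approximation beyond. The Kruskal–Wallis η²
transforms the tie-corrected H to an F value as the (1 − p) quantile of
F(k − 1, N − k) — the df convention behind the usual inverse-F recipe is
not standardised; this one is adopted and flagged — then
η² = F·df₁ / (F·df₁ + df₂). All-identical data short-circuit to H = 0,
η² = 0 (rank tests are undefined there). Bootstrap intervals are
percentile 2.5/97.5, seeded.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume,
not human oculomotor control. Searchers are agents that visit elements
according to a strategy; each visit is 1 + Poisson(0.5) fixations
(mean 1.5 per visit) with truncated-normal durations (mean 0.25 s,
sd 0.05 s, floor 0.06 s — plausible for active search); saccades are
instantaneous relocations, since the analyses use only amplitudes, never
kinematics. Fixation targets scatter uniformly within 0.5° of the
(jittered) element position; 120-Hz samples add isotropic Gaussian noise
per eye (default sd 0.30°/axis, matching the recording quality the
pipeline is designed for). On fixating the target an agent responds
after 0.3 s with probability 0.9 (10% chance of overlooking and
continuing); a responding agent clicks a neighbouring hexagon instead of
the target with probability 0.02, producing realistic low error rates.
Unanswered trials end after 75 visits. Element jitter is redrawn each
trial; AOI assignment always uses the fixed hexagon cells.

Strategies: `raster_full` (boustrophedon sweep from a corner, revisiting
in itinerary order when exhausted — late in trials searchers naturally
continue into their partner's side), `raster_divided` (own half of the
display first; the middle column is shared), `random_walk` (random
adjacent hexagon, preferring unvisited), `fresh_tile_competitor`
(uniformly random among tiles it has not inspected, preferring tiles
fresh to both searchers when it consults the partner's marker), and
`blind_independent` (raster that never consults the partner). In
collaborate/compete coupling, an agent choosing its next element skips
partner-highlighted elements with probability `avoid_partner_prob`; in
blind coupling agents ignore each other. The trial ends at the first
response; the other stream is truncated there.

Condition defaults (the study conditions the tests run under):
*individual* — full rasters from the top-left and top-right corners
(solo searchers share the top-first scanning habit but differ in
direction; fully opposite corners would make the min-RT blind baseline
unrealistically fast, identical corners unrealistically slow);
*collaborate* — divided rasters from opposite corners with
`avoid_partner_prob = 1`; *compete* — fresh-tile competitors with
`avoid_partner_prob = 0.3` (competitors only partially adopt fresh-tile
avoidance, which places their overlap between collaborating and blind
pairs); *blind* — independent rasters both from the top-left (a shared
scanning habit with no coordination, the high-overlap reference). Agents
do not model the instructed pre-trial central fixation: the target never
appears in the central element, and a forced shared first dwell would
contaminate the overlap measures with a constant.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: smooth pursuit and saccadic dynamics, blinks
and data loss (validity flags exist but the generator emits none),
eye-tracker drift or temporally correlated noise, learning or
point-score-driven strategy adaptation across trials, and verbal or
extra-gaze communication. Quantities that depend on human idiosyncrasy
(the actual median RTs, the 23% overlap median, the rating correlation)
are not reproduction targets; the generator is built to reproduce
*orderings* — collaborate < compete < blind in overlap, raster <
random-walk in transition entropy, baseline faster than either
individual — and parameter-recovery contracts (noise sd within 5%,
uniform-matrix entropy ceilings exactly).

## Numerical conventions and degenerate inputs

Times are seconds from stimulus onset, angles degrees, hexagon ids
0-based with −1 for "outside"/"none". Frame windows are half-open
`(t − w, t]`; run durations count frames times the frame interval;
comparisons against the 50-ms threshold are strict with a 1e-12 guard.
Empty inputs raise `UndefinedMetricError` rather than returning
sentinels (empty dwell sequences, all-zero count vectors, single-sample
precision); structurally invalid inputs (non-finite coordinates, nonzero
transition-matrix diagonals, non-monotone timestamps, unknown schema
columns) raise typed errors with location information where applicable.
All randomness flows from explicit seeds through numpy Generators;
sessions derive per-condition and per-trial seeds from the master seed
via `SeedSequence.spawn`, so any subset of a session is reproducible.

Problem sizes used by the test suite: qualitative-ordering checks run
100 trials per condition for one pair (the per-condition trial count of
the emulated design); the blind-baseline convergence check uses ~11,000
matched synthetic records; entropy oracles run on 100 random small
matrices; noise recovery pools ≈ 10⁴ samples across three simulated
trials.
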