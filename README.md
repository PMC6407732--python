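# gazepair

Analysis tools for **paired visual search with shared gaze**: two people
search the same display for a target while each sees, highlighted in real
time, which element the other is currently looking at. `gazepair`
implements the full analysis chain for such experiments — and an
agent-based simulator that generates ground-truthed paired-searcher data,
so every stage is testable without eye-tracking recordings.

The experimental setting it targets: a 5 × 5 hexagonal array of search
elements (flat-to-flat cell diameter 4.6°, element positions jittered up
to 0.805°), binocular gaze sampled at 120 Hz, a 60-Hz display that
outlines the hexagon the partner looks at, and three conditions —
searching *individually*, *collaborating* (shared reward), or *competing*
(winner takes the points).

## What it computes

* **Online AOI rule** (`gazepair.aoi`) — reconstructs, frame by frame,
  which hexagon was highlighted as the partner's gaze marker: all samples
  in the trailing 30 ms window are assigned to hexagons and the modal
  hexagon wins; if all samples disagree a saccade is assumed and the
  latest sample decides. Highlight runs shorter than 50 ms are *flicker*
  (visualised measurement error); their frame proportion is the
  data-quality metric.
* **Event layer** (`gazepair.events`) — dispersion-based fixation
  detection on the binocular-averaged signal, fixation → dwell assignment
  (consecutive fixations in one hexagon merge; a *dwell* is one AOI
  visit), transitions (saccades that cross a hexagon boundary), dwell
  rate, amplitude medians, RMS-S2S / SD precision metrics, and the
  "overlooked target" flag.
* **Coordination metrics** (`gazepair.coordination`) — the core:
  * *dwell overlap*: the proportion of a searcher's dwells landing on
    hexagons their partner had already (durably) highlighted;
  * *cumulative overlap curves*: the fraction of the 25 elements
    inspected by both parties as a function of time, aggregated across
    trials with a seeded 95% percentile bootstrap (1,000 iterations);
  * *blind baseline*: artificial non-interacting pairs built from two
    searchers' individual trials with matched target locations, taking
    the faster member's response per trial;
  * *entropy measures*: dwell-distribution entropy
    `H_d = −Σ p(x_i) log₂ p(x_i)` (how evenly looking is spread over the
    array; max log₂ 25 ≈ 4.64 bits) and transition entropy in both its
    conditional form `H_t = −Σ_i p(i) Σ_j p(j|i) log₂ p(j|i)`
    (max log₂ 24 ≈ 4.59 bits) and joint form over ordered pairs
    (max log₂ 600 = 9.23 bits) — low values mean a fixed, predictable
    scan path;
  * performance summaries (median RT, error rate, targets found per
    second), overlapping-dwell heat maps (σ = 1.0° Gaussian kernels,
    lowest 10% floored), and the overlap-vs-collaboration-rating Pearson
    correlation with its t statistic.
* **Statistics** (`gazepair.stats`) — the nonparametric conventions used
  throughout: Tukey boxplot stats, Wilcoxon signed-rank with the
  PS_dep = n₊/N effect size, Kruskal–Wallis with η² via the F transform,
  and seeded percentile bootstraps.
* **Simulator** (`gazepair.simulate`) — searchers as agents with
  strategy-dependent itineraries (division-of-labour raster, full raster,
  random walk, fresh-tile competitor, blind/independent), truncated-normal
  fixation durations, per-eye Gaussian sample noise, probabilistic target
  misses, and coupling through the partner's highlight log.
* **IO / pipeline / CLI** (`gazepair.io`, `gazepair.pipeline`,
  `gazepair.cli`) — plain-CSV schemas for gaze streams, highlight logs
  and trial logs, a YAML session manifest, and a `gazepair` command with
  `simulate`, `analyze`, `entropy`, `overlap` and `report` subcommands.

## Worked example

Simulate a 20-trial session for one pair and analyze it:

```sh
gazepair simulate --trials 20 --conditions individual,collaborate,compete \
    --seed 7 --out demo/session
gazepair analyze --manifest demo/session/manifest.yaml --out demo/results
gazepair report --results demo/results
```

`demo/results/condition_summary.csv` (values from the run above):

```
condition,median_rt_s,error_rate,targets_per_second_hz,n_trials
individual,6.247404372247002,0.025,0.14898334988661932,40
collaborate,2.317454056150077,0.05,0.32549538372551334,20
compete,3.0284272643438706,0.0,0.3154384347802476,20
blind_baseline,7.679630771221257,0.0,0.14085968093912762,11
```

Reading this: a collaborating pair found targets in roughly **half** the
median time of a single searcher (2.32 s vs 6.25 s) and more than doubled
the targets-found-per-second rate — the signature of an effective
division of labour. The blind baseline (here only 11 matched trials, so
noisy; at 100 trials per searcher it falls between collaborate and
individual) estimates what a non-interacting pair would achieve.

`demo/results/entropy.csv` separates the scanning styles:

```
condition,participant,h_dwell_bits,h_transition_conditional_bits,h_transition_joint_bits,n_dwells,n_transitions
individual,a,4.548536198496651,0.0,4.515638946503346,368,348
collaborate,a,4.144330183595066,0.21948826537001975,4.331259550988112,163,143
compete,a,4.491163039151375,2.3847350376863137,6.868398973438738,169,149
```

Raster-scanning individual and collaborating searchers have near-zero
conditional transition entropy (each hexagon has one habitual successor —
a fixed, predictable scan path), while the competitor's unsystematic
scanning drives it toward the 4.59-bit maximum. The pipeline also writes
per-trial metrics, aggregated overlap curves with bootstrap bands, and a
Kruskal–Wallis/Wilcoxon comparison table.

A uniform transition matrix hits the theoretical joint-entropy ceiling:

```sh
$ gazepair entropy --matrix uniform600.csv --variant joint
9.23
```

## Layout

```
src/gazepair/
  grid.py          hexagonal array geometry, px<->deg, point-to-hexagon
  aoi.py           online gaze-marker rule, flicker metric
  events.py        fixations, dwells, transitions, precision metrics
  coordination.py  overlap, blind baseline, entropy, performance, heat maps
  stats.py         boxplots, Wilcoxon+PS_dep, Kruskal-Wallis+eta2, bootstrap
  simulate.py      agent-based paired-searcher generator
  io.py            CSV schemas and session manifest
  pipeline.py      manifest -> tidy metric tables
  cli.py           command-line interface
docs/methods.md    modelling and analysis notes
```
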