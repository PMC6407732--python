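"""Coordination metrics for paired visual search.

The central question these metrics answer is how two searchers divide a
shared search space. Overlap quantifies redundant inspection: the
proportion of a searcher's dwells landing on hexagons their partner had
already highlighted, and, with a temporal dimension, the cumulative
fraction of elements inspected by both searchers as a trial unfolds. A
blind baseline — built from two searchers' individual trials with matched
target locations, taking the faster member's response per trial —
estimates how a non-interacting pair would perform. Entropy measures
characterise scanning order: the Shannon entropy of the dwell
distribution over elements (how evenly looking is spread) and the entropy
of element-to-element transitions (how predictable the scan path is).

Transition entropy comes in two variants. The conditional form

    H_t = - sum_i p(i) sum_j p(j|i) log2 p(j|i)

measures destination unpredictability given the origin (maximum
log2(24) ~ 4.59 bits for 25 elements); the joint form applies the Shannon
formula to the ordered-pair distribution p(i, j) and reaches log2(600) ~
9.23 bits when all ordered pairs of distinct elements are equally
frequent. Both are reported, as they answer slightly different questions;
they are related by ``joint = conditional + entropy of the origin
marginal``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

from . import aoi
from .data import HighlightLog, PairTrial, TrialRecord
from .errors import ConfigError, InvalidMatrixError, UndefinedMetricError
from .events import Dwell, build_dwells, detect_fixations

#: Default minimum highlight-run duration; shorter runs are flicker and ignored.
MIN_HIGHLIGHT = 0.050


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------


def partner_inspections(
    partner_log: HighlightLog, min_highlight: float = MIN_HIGHLIGHT
) -> dict[int, float]:
    """First time each hexagon was durably highlighted on a screen.

    Runs of ``min_highlight`` or shorter are flicker (visualised
    measurement error) and are ignored. Returns hexagon -> onset (s).
    """
    first: dict[int, float] = {}
    for h, onset, dur, _n in aoi.highlight_runs(partner_log):
        if h == aoi.NO_HIGHLIGHT or dur <= min_highlight + 1e-12:
            continue
        if h not in first:
            first[h] = onset
    return first


def own_inspections(dwells: Sequence[Dwell]) -> dict[int, float]:
    """First dwell onset per hexagon for one searcher."""
    first: dict[int, float] = {}
    for d in dwells:
        if d.hex not in first:
            first[d.hex] = d.onset
    return first


def dwell_overlap_proportion(
    own_dwells: Sequence[Dwell],
    partner_log: HighlightLog,
    min_highlight: float = MIN_HIGHLIGHT,
) -> float:
    """Proportion of a searcher's dwells landing where the partner already looked.

    A dwell overlaps iff its hexagon appears in the partner's highlight
    log in a run longer than ``min_highlight`` whose onset precedes the
    dwell's onset.
    """
    if len(own_dwells) == 0:
        raise UndefinedMetricError("overlap proportion of an empty dwell sequence")
    seen = partner_inspections(partner_log, min_highlight)
    n_overlap = sum(
        1 for d in own_dwells if d.hex in seen and seen[d.hex] < d.onset - 1e-12
    )
    return n_overlap / len(own_dwells)


@dataclass
class OverlapCurve:
    """Cumulative both-inspected element fraction on a uniform time grid."""

    time: np.ndarray
    value: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.time[-1]) if len(self.time) else 0.0


def cumulative_overlap_curve(
    inspections_a: dict[int, float],
    inspections_b: dict[int, float],
    duration: float,
    frame_rate: float = 60.0,
    n_elements: int = 25,
) -> OverlapCurve:
    """Fraction of elements inspected by both parties by each point in time.

    ``inspections_*`` map hexagon id to first-inspection time (from
    :func:`own_inspections` or :func:`partner_inspections`). The curve is
    evaluated on a display-frame grid starting at t = 0, where it is 0 by
    construction, and is non-decreasing up to 1 if both parties covered
    every element.
    """
    grid_t = np.arange(int(math.floor(duration * frame_rate + 1e-9)) + 1) / frame_rate
    both = [
        max(ta, inspections_b[h]) for h, ta in inspections_a.items() if h in inspections_b
    ]
    value = np.zeros(len(grid_t))
    if both:
        times = np.sort(np.asarray(both))
        value = np.searchsorted(times, grid_t, side="right") / n_elements
        value[grid_t <= 0] = np.searchsorted(times, 0.0, side="left") / n_elements
    return OverlapCurve(grid_t, value)


def pair_cumulative_overlap(
    pair: PairTrial,
    viewer: str = "a",
    min_highlight: float = MIN_HIGHLIGHT,
    dwells: Optional[Sequence[Dwell]] = None,
    frame_rate: float = 60.0,
) -> OverlapCurve:
    """Cumulative overlap for one participant's screen in a paired trial.

    Overlap is counted between the hexagons this viewer dwelt on and the
    hexagons durably highlighted on their screen as their partner's gaze
    marker — i.e. what the viewer could actually have seen — with the
    flicker exclusion applied. ``dwells`` may supply the viewer's dwell
    sequence (e.g. from ground truth); by default it is re-derived from
    the viewer's stream with the dispersion detector.
    """
    if viewer not in ("a", "b"):
        raise ConfigError("viewer must be 'a' or 'b'")
    own = pair.a if viewer == "a" else pair.b
    partner_log = pair.highlight_b if viewer == "a" else pair.highlight_a
    if dwells is None:
        from . import grid as grid_mod

        dwells = build_dwells(detect_fixations(own.stream), grid_mod.build_grid())
    return cumulative_overlap_curve(
        own_inspections(dwells),
        partner_inspections(partner_log, min_highlight),
        duration=pair.record.rt,
        frame_rate=frame_rate,
        n_elements=25,
    )


class AggregatedCurve(NamedTuple):
    time: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_alive: np.ndarray


def aggregate_overlap_curves(
    curves: Sequence[OverlapCurve],
    n_boot: int = 1000,
    seed=0,
    frame_rate: float = 60.0,
) -> AggregatedCurve:
    """Average overlap curves with a 95% percentile-bootstrap band.

    Trials end at different times; at each time point only trials still
    running ("alive") contribute, and the bootstrap resamples whole trials
    with replacement (percentile 2.5 / 97.5 endpoints, seeded). Times at
    which a bootstrap replicate has no alive trial yield NaN band values.
    """
    if len(curves) == 0:
        raise UndefinedMetricError("no overlap curves to aggregate")
    n_frames = max(len(c.time) for c in curves)
    time = np.arange(n_frames) / frame_rate
    mat = np.full((len(curves), n_frames), np.nan)
    for i, c in enumerate(curves):
        mat[i, : len(c.time)] = c.value
    alive = ~np.isnan(mat)
    n_alive = alive.sum(axis=0)

    def _alive_mean(rows: np.ndarray) -> np.ndarray:
        ok = ~np.isnan(rows)
        counts = ok.sum(axis=0)
        sums = np.where(ok, rows, 0.0).sum(axis=0)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    mean = _alive_mean(mat)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_frames))
    for b in range(n_boot):
        idx = rng.integers(0, len(curves), size=len(curves))
        boots[b] = _alive_mean(mat[idx])
    all_nan = np.isnan(boots).all(axis=0)
    lo = np.full(n_frames, np.nan)
    hi = np.full(n_frames, np.nan)
    if not all_nan.all():
        cols = ~all_nan
        lo[cols] = np.nanpercentile(boots[:, cols], 2.5, axis=0)
        hi[cols] = np.nanpercentile(boots[:, cols], 97.5, axis=0)
    return AggregatedCurve(time, mean, lo, hi, n_alive)


# ---------------------------------------------------------------------------
# Blind baseline
# ---------------------------------------------------------------------------


@dataclass
class BlindTrial:
    target_hex: int
    rt: float
    correct: bool
    source: str  # participant id of the faster member


@dataclass
class BlindBaseline:
    trials: list
    n_matched: int


def blind_baseline(
    trials_a: Sequence[TrialRecord],
    trials_b: Sequence[TrialRecord],
    label_a: str = "a",
    label_b: str = "b",
) -> BlindBaseline:
    """Simulated non-interacting pair from two searchers' individual trials.

    Trials of the two searchers are matched greedily, in order of
    occurrence, on target location: the k-th A-trial with target t pairs
    with the k-th B-trial with target t. Each matched pair contributes an
    artificial trial taking the response, correctness and RT of the faster
    member (ties resolve to the first searcher). Unmatched trials are
    dropped.
    """
    by_target_b: dict[int, list[TrialRecord]] = {}
    for tr in trials_b:
        by_target_b.setdefault(tr.target_hex, []).append(tr)
    used: dict[int, int] = {}
    matched = []
    for ta in trials_a:
        queue = by_target_b.get(ta.target_hex, [])
        k = used.get(ta.target_hex, 0)
        if k >= len(queue):
            continue
        tb = queue[k]
        used[ta.target_hex] = k + 1
        if ta.rt <= tb.rt:
            winner, label = ta, label_a
        else:
            winner, label = tb, label_b
        matched.append(
            BlindTrial(
                target_hex=ta.target_hex,
                rt=min(ta.rt, tb.rt),
                correct=winner.correct,
                source=label,
            )
        )
    return BlindBaseline(trials=matched, n_matched=len(matched))


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------


def dwell_distribution_entropy(counts) -> float:
    """Shannon entropy (bits) of the dwell distribution over elements.

    ``counts`` holds dwell counts per element pooled over all trials of a
    condition; zero counts contribute nothing (0 log 0 = 0).
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise UndefinedMetricError("entropy of an all-zero count vector")
    p = c[c > 0] / total
    return float(-np.sum(p * np.log2(p)))


class TransitionEntropy(NamedTuple):
    conditional: float
    joint: float


def transition_entropy(matrix) -> TransitionEntropy:
    """Conditional and joint entropy (bits) of a transition-count matrix.

    ``matrix[i, j]`` counts transitions from element i to element j pooled
    over all trials of a condition; the diagonal must be zero (a dwell
    cannot transition to itself). The conditional variant weights each
    origin's destination entropy by the origin marginal; the joint variant
    is the Shannon entropy of the ordered-pair distribution. For n
    elements the respective maxima are log2(n-1) and log2(n(n-1)).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidMatrixError("transition matrix must be square")
    if np.any(m < 0):
        raise InvalidMatrixError("transition counts must be non-negative")
    if np.any(np.diagonal(m) != 0):
        raise InvalidMatrixError("transition matrix must have a zero diagonal")
    total = m.sum()
    if total <= 0:
        raise UndefinedMetricError("entropy of an all-zero transition matrix")
    origin = m.sum(axis=1)
    p_origin = origin / total
    cond = 0.0
    for i in range(m.shape[0]):
        if origin[i] == 0:
            continue
        p_row = m[i][m[i] > 0] / origin[i]
        cond += p_origin[i] * float(-np.sum(p_row * np.log2(p_row)))
    p_joint = m[m > 0] / total
    joint = float(-np.sum(p_joint * np.log2(p_joint)))
    return TransitionEntropy(conditional=cond, joint=joint)


def transition_counts(dwell_sequences: Sequence[Sequence[Dwell]], n_elements: int = 25) -> np.ndarray:
    """Pool dwell sequences into an element-to-element transition-count matrix."""
    m = np.zeros((n_elements, n_elements))
    for dwells in dwell_sequences:
        for d1, d2 in zip(dwells, dwells[1:]):
            if d1.hex != d2.hex:
                m[d1.hex, d2.hex] += 1
    return m


def dwell_counts(dwell_sequences: Sequence[Sequence[Dwell]], n_elements: int = 25) -> np.ndarray:
    """Pool dwell sequences into per-element dwell counts."""
    c = np.zeros(n_elements)
    for dwells in dwell_sequences:
        for d in dwells:
            c[d.hex] += 1
    return c


# ---------------------------------------------------------------------------
# Performance
# ---------------------------------------------------------------------------


class PerformanceSummary(NamedTuple):
    median_rt: float
    error_rate: float
    targets_per_second: float
    n_trials: int


def performance_summary(trials: Sequence) -> PerformanceSummary:
    """Median RT, error rate, and targets found per second for one condition.

    Accepts any records with ``rt`` and ``correct`` attributes (real
    trials or blind-baseline trials). Targets per second is the number of
    correct trials divided by the total search time across all trials.
    """
    if len(trials) == 0:
        raise UndefinedMetricError("performance summary of an empty trial set")
    rts = np.array([tr.rt for tr in trials], dtype=float)
    correct = np.array([bool(tr.correct) for tr in trials])
    return PerformanceSummary(
        median_rt=float(np.median(rts)),
        error_rate=float(np.mean(~correct)),
        targets_per_second=float(correct.sum() / rts.sum()),
        n_trials=len(trials),
    )


# ---------------------------------------------------------------------------
# Heat maps and questionnaire correlation
# ---------------------------------------------------------------------------


def overlap_heatmap(
    points,
    sigma: float = 1.0,
    floor: float = 0.10,
    extent: float = 12.9,
    resolution: float = 0.1,
):
    """Gaussian-kernel density map of (overlapping) dwell locations.

    Sums isotropic Gaussian kernels of standard deviation ``sigma``
    degrees at each dwell centroid on a raster covering the display
    (``[-extent, extent]`` squared, ``resolution``-degree pixels), then
    zeroes values below ``floor`` times the maximum. Returns
    ``(x, y, density)`` with ``density[j, i]`` at ``(x[i], y[j])``.
    """
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    axis = np.arange(-extent, extent + resolution / 2, resolution)
    gx, gy = np.meshgrid(axis, axis)
    density = np.zeros_like(gx)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size:
        for px, py in pts:
            density += np.exp(-((gx - px) ** 2 + (gy - py) ** 2) / (2.0 * sigma**2))
        density[density < floor * density.max()] = 0.0
    return axis, axis, density


class CorrelationResult(NamedTuple):
    r: float
    t: float
    df: int
    p: float


def rating_overlap_correlation(overlap, ratings) -> CorrelationResult:
    """Pearson correlation between per-pair overlap and collaboration ratings.

    Returns r, the t statistic ``r * sqrt(df / (1 - r^2))`` with
    ``df = n - 2``, and the two-sided p value.
    """
    x = np.asarray(overlap, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UndefinedMetricError("correlation needs at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for a constant variable")
    r, p = sps.pearsonr(x, y)
    df = len(x) - 2
    t = r * math.sqrt(df / (1.0 - r * r)) if abs(r) < 1 else math.inf * np.sign(r)
    return CorrelationResult(float(r), float(t), df, float(p))
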