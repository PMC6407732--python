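"""Fixation, dwell, and transition construction from raw gaze streams.

Fixations are detected with a dispersion detector on the binocular-averaged
signal: maximal runs of consecutive valid samples whose bounding box stays
within a dispersion threshold and that last at least a minimum duration
become fixations, with the centroid as position. The detector is
deliberately simple; every downstream function also accepts an externally
produced fixation list, so output of a more elaborate detector (e.g. a
two-means clustering algorithm) can be slotted in unchanged.

A dwell is a maximal run of consecutive fixations inside one hexagon; a
transition is a saccade that carries gaze from one hexagon to another
(saccades within a hexagon are not transitions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from . import grid as grid_mod
from .data import GazeStream
from .errors import ConfigError, UndefinedMetricError


@dataclass(frozen=True)
class Fixation:
    onset: float
    offset: float
    x: float
    y: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Dwell:
    """A visit to one hexagon: consecutive fixations assigned to the same cell."""

    hex: int
    onset: float
    offset: float
    n_fixations: int
    # centroids of the first and last fixation of the dwell; transition
    # amplitudes are measured between these bounding fixations
    first_xy: tuple
    last_xy: tuple


@dataclass(frozen=True)
class Transition:
    from_hex: int
    to_hex: int
    amplitude: float


class EyeMovementParams(NamedTuple):
    median_fixation_duration: float
    median_saccade_amplitude: float
    dwell_rate: float
    median_transition_amplitude: float
    dwell_rate_unique: float


class PrecisionMetrics(NamedTuple):
    rms_s2s: float
    mean_sd: float


def detect_fixations(
    stream: GazeStream,
    dispersion: float = 1.0,
    min_duration: float = 0.060,
) -> list[Fixation]:
    """Dispersion-based fixation detection (I-DT style).

    Greedily grows maximal runs of consecutive valid samples whose
    per-axis range stays within ``dispersion`` degrees; runs lasting at
    least ``min_duration`` become fixations. Invalid samples split runs.
    A sample's nominal duration (one inter-sample interval) is credited to
    the run, so a constant 1-s stream yields a 1-s fixation.
    """
    if dispersion <= 0 or min_duration <= 0:
        raise ConfigError("dispersion and min_duration must be positive")
    if len(stream) == 0:
        return []
    t = stream.t
    x, y, valid = stream.binocular()
    dt = float(np.median(np.diff(t))) if len(t) > 1 else min_duration

    fixations: list[Fixation] = []
    for s, e in _valid_segments(valid):
        fixations.extend(_idt_segment(t[s:e], x[s:e], y[s:e], dispersion, min_duration, dt))
    return fixations


def _valid_segments(valid: np.ndarray):
    """Maximal index ranges [s, e) of consecutive valid samples."""
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [idx.size]))
    return [(int(idx[s]), int(idx[e - 1]) + 1) for s, e in zip(starts, ends)]


def _idt_segment(t, x, y, dispersion, min_duration, dt):
    n = len(t)
    out = []
    i = 0
    while i < n:
        xmin = xmax = x[i]
        ymin = ymax = y[i]
        j = i
        while j + 1 < n:
            nxmin, nxmax = min(xmin, x[j + 1]), max(xmax, x[j + 1])
            nymin, nymax = min(ymin, y[j + 1]), max(ymax, y[j + 1])
            if nxmax - nxmin > dispersion or nymax - nymin > dispersion:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        if t[j] - t[i] + dt >= min_duration - 1e-12:
            out.append(
                Fixation(
                    onset=float(t[i]),
                    offset=float(t[j] + dt),
                    x=float(np.mean(x[i : j + 1])),
                    y=float(np.mean(y[i : j + 1])),
                )
            )
            i = j + 1
        else:
            i += 1
    return out


def build_dwells(fixations: Sequence[Fixation], grid: grid_mod.GridSpec) -> list[Dwell]:
    """Group time-ordered fixations into hexagon dwells.

    Consecutive fixations on the same hexagon merge into one dwell.
    Fixations outside every hexagon are dropped but still break merging:
    the sequence [5, outside, 5] yields two separate dwells on 5.
    """
    dwells: list[Dwell] = []
    prev_hex = None  # hex of the immediately preceding fixation (incl. outside)
    for fx in fixations:
        h = grid_mod.assign_point_to_hexagon(fx.x, fx.y, grid)
        if h == grid_mod.OUTSIDE:
            prev_hex = grid_mod.OUTSIDE
            continue
        if dwells and prev_hex == h:
            d = dwells[-1]
            dwells[-1] = Dwell(
                hex=h,
                onset=d.onset,
                offset=fx.offset,
                n_fixations=d.n_fixations + 1,
                first_xy=d.first_xy,
                last_xy=(fx.x, fx.y),
            )
        else:
            dwells.append(
                Dwell(
                    hex=h,
                    onset=fx.onset,
                    offset=fx.offset,
                    n_fixations=1,
                    first_xy=(fx.x, fx.y),
                    last_xy=(fx.x, fx.y),
                )
            )
        prev_hex = h
    return dwells


def transitions(dwells: Sequence[Dwell]) -> list[Transition]:
    """Saccades carrying gaze between hexagons.

    One transition per pair of consecutive dwells on different hexagons;
    amplitude is the distance between the bounding fixation centroids
    (last fixation of the departed dwell, first of the entered dwell).
    """
    out = []
    for d1, d2 in zip(dwells, dwells[1:]):
        if d1.hex == d2.hex:
            continue
        out.append(
            Transition(
                from_hex=d1.hex,
                to_hex=d2.hex,
                amplitude=math.dist(d1.last_xy, d2.first_xy),
            )
        )
    return out


def eye_movement_params(
    fixations: Sequence[Fixation],
    dwells: Sequence[Dwell],
    search_duration: float,
) -> EyeMovementParams:
    """Scalar eye-movement parameters for one trial.

    Saccade amplitudes are distances between all consecutive fixation
    centroids; transition amplitudes only those crossing a hexagon
    boundary. Dwell rate is dwells (visits) per second of search time,
    from stimulus onset to the response; a unique-hexagons variant is
    returned alongside. With fewer than two fixations the saccade metrics
    are undefined and reported as NaN.
    """
    if len(fixations) == 0:
        raise UndefinedMetricError("eye-movement parameters need at least one fixation")
    if search_duration <= 0:
        raise UndefinedMetricError("search duration must be positive")
    durations = [f.duration for f in fixations]
    sacc = [
        math.dist((f1.x, f1.y), (f2.x, f2.y))
        for f1, f2 in zip(fixations, fixations[1:])
    ]
    trans = [tr.amplitude for tr in transitions(dwells)]
    return EyeMovementParams(
        median_fixation_duration=float(np.median(durations)),
        median_saccade_amplitude=float(np.median(sacc)) if sacc else float("nan"),
        dwell_rate=len(dwells) / search_duration,
        median_transition_amplitude=float(np.median(trans)) if trans else float("nan"),
        dwell_rate_unique=len({d.hex for d in dwells}) / search_duration,
    )


def precision_metrics(
    stream: GazeStream,
    fixations: Optional[Sequence[Fixation]] = None,
    dispersion: float = 1.0,
    min_duration: float = 0.060,
) -> PrecisionMetrics:
    """Gaze-precision metrics computed within fixation episodes.

    ``rms_s2s`` is the root-mean-square Euclidean distance between
    consecutive samples of the binocular-averaged signal, computed within
    each fixation episode and averaged across episodes. ``mean_sd`` is the
    mean over episodes of ``sqrt(var_x + var_y)``. For white per-eye noise
    of sd sigma per axis, binocular averaging halves the variance, so
    ``mean_sd`` estimates sigma itself (monocular data would give
    ``sigma * sqrt(2)``).

    Episodes default to the dispersion detector's fixations; pass
    ``fixations`` to use externally detected episodes.
    """
    x, y, valid = stream.binocular()
    if int(valid.sum()) < 2:
        raise UndefinedMetricError("precision metrics need at least two valid samples")
    if fixations is None:
        fixations = detect_fixations(stream, dispersion, min_duration)
    t = stream.t
    rms_vals, sd_vals = [], []
    for fx in fixations:
        sel = (t >= fx.onset - 1e-12) & (t < fx.offset - 1e-12) & valid
        if int(sel.sum()) < 2:
            continue
        xs, ys = x[sel], y[sel]
        steps2 = np.diff(xs) ** 2 + np.diff(ys) ** 2
        rms_vals.append(math.sqrt(float(np.mean(steps2))))
        sd_vals.append(math.sqrt(float(np.var(xs, ddof=1) + np.var(ys, ddof=1))))
    if not rms_vals:
        raise UndefinedMetricError("no fixation episode with two or more valid samples")
    return PrecisionMetrics(float(np.mean(rms_vals)), float(np.mean(sd_vals)))


def overlooked_target(dwells: Sequence[Dwell], target: int) -> bool:
    """Whether the target was fixated but then passed over.

    True iff the target hexagon was dwelt upon and gaze subsequently
    visited two or more distinct other hexagons before the response.
    """
    first = next((i for i, d in enumerate(dwells) if d.hex == target), None)
    if first is None:
        return False
    later = {d.hex for d in dwells[first + 1 :] if d.hex != target}
    return len(later) >= 2
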