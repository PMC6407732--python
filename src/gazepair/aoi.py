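"""Online gaze-marker reconstruction and its data-quality metric.

During paired trials each participant's display outlines, every frame,
the hexagon their partner is currently looking at. The rule operates on
the partner's streamed samples: all samples that arrived in the trailing
30 ms window (3-4 samples at 120 Hz) are mapped to hexagons, and the
modal hexagon is highlighted. If every sample in the window indicates a
different hexagon, a saccade is assumed to be in progress and the latest
sample's hexagon is shown. Highlight runs shorter than 50 ms are visible
as flicker and are treated as visualised measurement error.
"""

from __future__ import annotations

import numpy as np

from . import grid as grid_mod
from .data import GazeStream, HighlightLog
from .errors import UndefinedMetricError

#: Marker value for frames with no highlight.
NO_HIGHLIGHT = -1


def highlight_stream(
    stream: GazeStream,
    grid: grid_mod.GridSpec,
    window: float = 0.030,
    frame_rate: float = 60.0,
) -> HighlightLog:
    """Reconstruct the per-frame hexagon highlight from a gaze stream.

    Frames are at ``1/frame_rate, 2/frame_rate, ...`` up to the stream's
    duration. For each frame time ``tf`` the samples with timestamps in the
    half-open window ``(tf - window, tf]`` are combined binocularly (mean
    of valid eyes), assigned to hexagons, and the modal hexagon is
    highlighted. Among tied modal hexagons — which covers the
    all-samples-different saccade case — the one whose supporting sample is
    most recent wins. A window with no valid samples holds the previous
    frame's highlight (none at trial start). Samples falling outside the
    grid yield no highlight when modal.
    """
    if len(stream) == 0:
        return HighlightLog(np.empty(0), np.empty(0, dtype=int), frame_rate)

    t = stream.t
    x, y, valid = stream.binocular()
    hexes = np.full(len(t), NO_HIGHLIGHT, dtype=int)
    if valid.any():
        hexes[valid] = grid_mod.assign_points(x[valid], y[valid], grid)

    n_frames = int(np.floor(stream.duration * frame_rate + 1e-9))
    frame_t = (np.arange(n_frames) + 1) / frame_rate
    out = np.full(n_frames, NO_HIGHLIGHT, dtype=int)

    # Window bounds via searchsorted on the (sorted) sample timestamps.
    lo = np.searchsorted(t, frame_t - window, side="right")
    hi = np.searchsorted(t, frame_t, side="right")

    prev = NO_HIGHLIGHT
    for f in range(n_frames):
        sl = slice(lo[f], hi[f])
        v = valid[sl]
        if not v.any():
            out[f] = prev
            continue
        h = hexes[sl][v]
        # Modal hexagon; ties (including the all-distinct saccade case)
        # resolve to the candidate with the most recent supporting sample.
        counts = np.bincount(h - NO_HIGHLIGHT)
        modal_count = counts.max()
        best = NO_HIGHLIGHT
        for val in h[::-1]:  # latest first
            if counts[val - NO_HIGHLIGHT] == modal_count:
                best = int(val)
                break
        out[f] = best
        prev = out[f]
    return HighlightLog(frame_t, out, frame_rate)


def highlight_runs(log: HighlightLog):
    """Run-length encode a highlight log.

    Returns a list of ``(hex_id, onset_s, duration_s, n_frames)`` tuples,
    one per maximal run of consecutive identical highlight values
    (including no-highlight runs, ``hex_id == -1``). Onset is the time of
    the first frame of the run; duration is ``n_frames / frame_rate``.
    """
    n = len(log)
    if n == 0:
        return []
    h = log.hexes
    boundaries = np.flatnonzero(np.diff(h)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    return [
        (int(h[s]), float(log.frame_t[s]), float((e - s) / log.frame_rate), int(e - s))
        for s, e in zip(starts, ends)
    ]


def flicker_metric(log: HighlightLog, min_duration: float = 0.050) -> float:
    """Proportion of stimulus frames belonging to sub-50 ms highlight runs.

    Highlight runs (hexagon outlines) strictly shorter than ``min_duration``
    are flagged as visualised measurement error; the metric is flagged
    frames over all frames in the log. No-highlight runs are never flagged.
    """
    if len(log) == 0:
        raise UndefinedMetricError("flicker metric of an empty highlight log")
    flagged = 0
    for hex_id, _onset, dur, n_frames in highlight_runs(log):
        if hex_id != NO_HIGHLIGHT and dur < min_duration - 1e-12:
            flagged += n_frames
    return flagged / len(log)
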