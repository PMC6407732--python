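"""In-memory containers shared across modules.

Angles are degrees of visual angle, times are seconds from stimulus
onset, hexagon ids are 0-based row-major (see :mod:`gazepair.grid`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class GazeStream:
    """Timestamped binocular gaze samples for one participant-trial.

    Samples are nominally 120 Hz; timestamps must be strictly increasing.
    Validity flags mark per-eye data loss (blinks, tracking failures).
    """

    participant: str
    trial: int
    t: np.ndarray
    lx: np.ndarray
    ly: np.ndarray
    rx: np.ndarray
    ry: np.ndarray
    lvalid: np.ndarray
    rvalid: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for name in ("lx", "ly", "rx", "ry"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.lvalid = np.asarray(self.lvalid, dtype=bool)
        self.rvalid = np.asarray(self.rvalid, dtype=bool)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span covered by the stream, assuming it starts at stimulus onset."""
        if len(self.t) == 0:
            return 0.0
        dt = np.median(np.diff(self.t)) if len(self.t) > 1 else 0.0
        return float(self.t[-1] + dt)

    def binocular(self):
        """Average of the valid eyes per sample.

        Returns ``(x, y, valid)`` where ``valid`` is True when at least one
        eye is valid; monocular samples fall back to the single valid eye.
        """
        lv = self.lvalid
        rv = self.rvalid
        n = np.maximum(lv.astype(int) + rv.astype(int), 1)
        x = (np.where(lv, self.lx, 0.0) + np.where(rv, self.rx, 0.0)) / n
        y = (np.where(lv, self.ly, 0.0) + np.where(rv, self.ry, 0.0)) / n
        return x, y, lv | rv


@dataclass
class HighlightLog:
    """Frame-by-frame record of the hexagon shown as the partner's gaze marker.

    ``hexes`` holds a hexagon id per display frame, or -1 when nothing was
    highlighted (trial start, or the modal sample fell outside the grid).
    """

    frame_t: np.ndarray
    hexes: np.ndarray
    frame_rate: float = 60.0

    def __post_init__(self):
        self.frame_t = np.asarray(self.frame_t, dtype=float)
        self.hexes = np.asarray(self.hexes, dtype=int)

    def __len__(self) -> int:
        return len(self.frame_t)


@dataclass
class TrialRecord:
    """Outcome of one search trial."""

    condition: str
    target_hex: int
    responder: Optional[str]  # participant id, or None if nobody responded
    response_hex: Optional[int]
    rt: float
    correct: bool
    points_delta: int


@dataclass
class SearcherResult:
    """One simulated searcher's share of a trial, with ground truth.

    ``fixations`` and ``itinerary`` are the generator's ground truth (the
    event layer re-derives its own estimates from ``stream``).
    """

    participant: str
    stream: GazeStream
    fixations: list  # list of events.Fixation
    itinerary: list  # list of (hex_id, visit onset in s)
    record: TrialRecord


@dataclass
class PairTrial:
    """Both searchers' data for one paired trial.

    ``highlight_a`` is the marker log derived from participant a's gaze,
    i.e. what participant b saw on their screen (and vice versa).
    """

    trial: int
    condition: str
    target_hex: int
    a: SearcherResult
    b: SearcherResult
    highlight_a: HighlightLog
    highlight_b: HighlightLog
    record: TrialRecord


@dataclass
class Session:
    """A full simulated recording session for one pair of participants."""

    master_seed: int
    grid: object  # grid.GridSpec
    conditions: tuple
    #: per participant id ("a"/"b"), list of SearcherResult (individual cond.)
    individual: dict = field(default_factory=dict)
    #: per paired condition name, list of PairTrial
    pairs: dict = field(default_factory=dict)
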