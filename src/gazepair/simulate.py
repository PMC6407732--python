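"""Agent-based paired-searcher simulator.

Generates ground-truthed gaze data with the statistical structure the
analysis pipeline assumes: two searchers scan a 5 x 5 hexagonal array for
a target, each emitting 120-Hz binocular gaze samples with additive
isotropic Gaussian noise per eye. An agent's behaviour is an itinerary of
element visits; each visit is one or more fixations with truncated-normal
durations, and saccades are instantaneous jumps between fixation points
(the analyses never use saccade kinematics, only amplitudes).

Scanning strategies:

* ``raster_full`` — boustrophedon sweep over all elements from a corner;
* ``raster_divided`` — same sweep but over the searcher's own half of the
  display first (division of labour), then the remainder;
* ``random_walk`` — steps to a random neighbouring hexagon, preferring
  unvisited neighbours;
* ``fresh_tile_competitor`` — jumps to a uniformly random element it has
  not inspected yet, preferring tiles fresh to both searchers when it
  consults the partner's marker (unsystematic, high-entropy scanning);
* ``blind_independent`` — raster sweep that never consults the partner.

In ``collaborate`` and ``compete`` coupling an agent choosing its next
element skips, with probability ``avoid_partner_prob``, elements the
partner has already highlighted; in ``blind`` coupling agents ignore each
other entirely. On fixating the target an agent responds after
``response_delay`` with probability ``1 - identification_miss_prob``,
otherwise it continues searching (and may revisit the target later). The
trial ends at the first response; the other stream is truncated there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import aoi
from . import grid as grid_mod
from .data import GazeStream, HighlightLog, PairTrial, SearcherResult, Session, TrialRecord
from .errors import ConfigError
from .events import Fixation

STRATEGY_KINDS = (
    "raster_full",
    "raster_divided",
    "random_walk",
    "fresh_tile_competitor",
    "blind_independent",
)
COUPLINGS = ("collaborate", "compete", "blind")
CORNERS = ("tl", "tr", "bl", "br")
SAMPLE_RATE = 120.0


@dataclass(frozen=True)
class StrategyParams:
    """Tunable description of one searcher's behaviour.

    Durations are seconds, distances degrees. ``dwell_fixations`` is the
    mean number of fixations per element visit (1 + Poisson).
    ``fixation_scatter`` is the radius of the uniform-disc scatter of
    fixation targets around the (jittered) element position.
    ``response_error_prob`` is the chance that a responding searcher
    clicks a neighbouring hexagon instead of the target, producing the
    low error rates seen in speeded search.
    """

    kind: str = "raster_full"
    start_corner: str = "tl"
    fixation_duration_mean: float = 0.25
    fixation_duration_sd: float = 0.05
    fixation_duration_floor: float = 0.06
    dwell_fixations: float = 1.5
    identification_miss_prob: float = 0.10
    response_delay: float = 0.30
    response_error_prob: float = 0.02
    noise_sd: float = 0.30
    avoid_partner_prob: float = 0.0
    fixation_scatter: float = 0.5
    max_visits: int = 75

    def validate(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ConfigError(f"unknown strategy kind {self.kind!r}")
        if self.start_corner not in CORNERS:
            raise ConfigError(f"unknown start corner {self.start_corner!r}")
        for p in (
            self.identification_miss_prob,
            self.avoid_partner_prob,
            self.response_error_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.fixation_duration_mean <= 0 or self.fixation_duration_floor <= 0:
            raise ConfigError("fixation durations must be positive")
        if self.fixation_duration_sd < 0 or self.noise_sd < 0 or self.fixation_scatter < 0:
            raise ConfigError("spreads must be non-negative")
        if self.response_delay < 0 or self.max_visits < 1:
            raise ConfigError("invalid response_delay or max_visits")


def raster_order(grid: grid_mod.GridSpec, corner: str = "tl") -> list[int]:
    """Boustrophedon (serpentine) visit order over all elements from a corner."""
    rows = list(range(grid.n_rows))
    if corner in ("bl", "br"):
        rows.reverse()
    start_left = corner in ("tl", "bl")
    order = []
    for i, r in enumerate(rows):
        cols = list(range(grid.n_cols))
        if (i % 2 == 0) != start_left:
            cols.reverse()
        order.extend(r * grid.n_cols + c for c in cols)
    return order


def neighbor_map(grid: grid_mod.GridSpec) -> dict[int, list[int]]:
    """Adjacent elements (centers one flat-to-flat diameter apart)."""
    c = grid.centers
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    adj = np.abs(d - grid.hex_flat_to_flat) < 1e-6
    return {i: list(np.flatnonzero(adj[i])) for i in range(grid.n_elements)}


def _own_half(grid: grid_mod.GridSpec, corner: str) -> set[int]:
    """Columns on the searcher's side of the display, middle column shared."""
    c0 = grid.n_cols // 2
    if corner in ("tl", "bl"):
        cols = set(range(c0 + 1))
    else:
        cols = set(range(c0, grid.n_cols))
    return {
        r * grid.n_cols + c for r in range(grid.n_rows) for c in range(grid.n_cols) if c in cols
    }


class _Agent:
    """Mutable state of one simulated searcher during a trial."""

    def __init__(self, participant, params, grid, target, element_pos, rng, consult_partner):
        params.validate()
        self.participant = participant
        self.p = params
        self.grid = grid
        self.target = target
        self.element_pos = element_pos  # (n_elements, 2) jittered positions
        self.rng = rng
        self.consult_partner = consult_partner and params.kind != "blind_independent"
        self.now = 0.0
        self.visits: list[tuple[int, float]] = []  # (element, onset)
        self.visited: set[int] = set()
        self.fix_elements: list[int] = []  # element of each fixation
        self.fixations: list[Fixation] = []
        self.response_time: float | None = None
        self.response_hex: int | None = None
        self.done = False
        self.order = raster_order(grid, params.start_corner)
        if params.kind == "raster_divided":
            own = _own_half(grid, params.start_corner)
            self.order = [e for e in self.order if e in own] + [
                e for e in self.order if e not in own
            ]
        self._neighbors = neighbor_map(grid)
        self.current: int | None = None

    # -- element choice ---------------------------------------------------

    def _choose(self, partner_visible: set[int]) -> int:
        p = self.p
        avoid: set[int] = set()
        if self.consult_partner and partner_visible and self.rng.random() < p.avoid_partner_prob:
            avoid = partner_visible
        unvisited = [e for e in self.order if e not in self.visited]
        if p.kind in ("raster_full", "raster_divided", "blind_independent"):
            pool = [e for e in unvisited if e not in avoid] or unvisited
            if pool:
                return pool[0]
            # everything visited: revisit in itinerary order
            return self.order[len(self.visits) % len(self.order)]
        if p.kind == "random_walk":
            here = self.current if self.current is not None else self.order[0]
            if self.current is None:
                return here
            nb = self._neighbors[here]
            fresh = [e for e in nb if e not in self.visited and e not in avoid]
            if not fresh:
                fresh = [e for e in nb if e not in self.visited]
            pool = fresh or nb
            return int(self.rng.choice(pool))
        if p.kind == "fresh_tile_competitor":
            fresh = [e for e in unvisited if e not in avoid] or unvisited
            if not fresh:
                return self.order[len(self.visits) % len(self.order)]
            if self.current is None:
                return fresh[0]
            return int(self.rng.choice(fresh))
        raise ConfigError(f"unknown strategy kind {p.kind!r}")  # pragma: no cover

    # -- one element visit ------------------------------------------------

    def _fix_duration(self) -> float:
        p = self.p
        return max(
            p.fixation_duration_floor,
            self.rng.normal(p.fixation_duration_mean, p.fixation_duration_sd),
        )

    def step(self, partner_visible: set[int]) -> None:
        p = self.p
        elem = self._choose(partner_visible)
        onset = self.now
        self.visits.append((elem, onset))
        self.visited.add(elem)
        self.current = elem
        n_fix = 1 + (self.rng.poisson(p.dwell_fixations - 1.0) if p.dwell_fixations > 1 else 0)
        base = self.element_pos[elem]
        for _ in range(n_fix):
            if p.fixation_scatter > 0:
                r = p.fixation_scatter * math.sqrt(self.rng.random())
                th = self.rng.uniform(0.0, 2.0 * math.pi)
                fx, fy = base[0] + r * math.cos(th), base[1] + r * math.sin(th)
            else:
                fx, fy = float(base[0]), float(base[1])
            dur = self._fix_duration()
            self.fixations.append(Fixation(self.now, self.now + dur, fx, fy))
            self.fix_elements.append(elem)
            self.now += dur
        if elem == self.target and self.rng.random() >= p.identification_miss_prob:
            self.response_time = onset + p.response_delay
            # keep fixating the target until the response is given
            if self.response_time > self.now:
                last = self.fixations[-1]
                self.fixations[-1] = replace(last, offset=self.response_time)
                self.now = self.response_time
            if self.rng.random() < p.response_error_prob:
                self.response_hex = int(self.rng.choice(self._neighbors[self.target]))
            else:
                self.response_hex = self.target
            self.done = True
        elif len(self.visits) >= p.max_visits:
            self.done = True


def _run_agents(agents: list[_Agent], coupling: str) -> float:
    """Step agents on a shared clock until the first response (or visit cap).

    Agents are advanced in time order so that partner visibility is
    causal: the set of elements the partner has started inspecting by the
    stepping agent's current clock is complete when consulted. Returns the
    trial end time.
    """
    consult = coupling in ("collaborate", "compete")
    while True:
        earliest = min(
            (a.response_time for a in agents if a.response_time is not None),
            default=math.inf,
        )
        active = [a for a in agents if not a.done and a.now < earliest]
        if not active:
            break
        ag = min(active, key=lambda a: a.now)
        visible: set[int] = set()
        if consult and len(agents) > 1:
            partner = agents[1] if ag is agents[0] else agents[0]
            visible = {e for e, onset in partner.visits if onset <= ag.now}
        ag.step(visible)
    responses = [a.response_time for a in agents if a.response_time is not None]
    if responses:
        return min(responses)
    return max(a.now for a in agents)


def _truncate(agent: _Agent, rt: float) -> tuple[list[Fixation], list[tuple[int, float]]]:
    """Clip an agent's ground truth at the trial end time."""
    fixations, elements = [], []
    for fx, e in zip(agent.fixations, agent.fix_elements):
        if fx.onset >= rt - 1e-12:
            break
        fixations.append(replace(fx, offset=min(fx.offset, rt)))
        elements.append(e)
    itinerary = []
    for fx, e in zip(fixations, elements):
        if not itinerary or itinerary[-1][0] != e:
            itinerary.append((e, fx.onset))
    return fixations, itinerary


def _synthesize_stream(
    participant: str,
    trial: int,
    fixations: list[Fixation],
    rt: float,
    noise_sd: float,
    rng: np.random.Generator,
    sample_rate: float = SAMPLE_RATE,
) -> GazeStream:
    """120-Hz binocular samples around the fixation points, noise per eye."""
    n = int(math.ceil(rt * sample_rate - 1e-9))
    t = np.arange(n) / sample_rate
    onsets = np.array([f.onset for f in fixations])
    idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(fixations) - 1)
    x = np.array([fixations[i].x for i in idx])
    y = np.array([fixations[i].y for i in idx])
    noise = rng.normal(0.0, noise_sd, size=(4, n)) if noise_sd > 0 else np.zeros((4, n))
    valid = np.ones(n, dtype=bool)
    return GazeStream(
        participant=participant,
        trial=trial,
        t=t,
        lx=x + noise[0],
        ly=y + noise[1],
        rx=x + noise[2],
        ry=y + noise[3],
        lvalid=valid,
        rvalid=valid.copy(),
    )


def _check_target(grid: grid_mod.GridSpec, target: int) -> None:
    center = grid.n_elements // 2
    if not 0 <= target < grid.n_elements or target == center:
        raise ConfigError(
            f"target must be an element id other than the central one ({center}), got {target}"
        )


def _element_positions(grid: grid_mod.GridSpec, offsets) -> np.ndarray:
    if offsets is None:
        return grid.centers
    return grid.centers + np.asarray(offsets)


def simulate_searcher(
    strategy: StrategyParams,
    grid: grid_mod.GridSpec,
    target: int,
    partner_highlights: HighlightLog | None = None,
    seed=0,
    condition: str = "individual",
    participant: str = "a",
    trial: int = 0,
    element_offsets=None,
) -> SearcherResult:
    """Simulate one searcher working a trial alone.

    If ``partner_highlights`` is given (a pre-recorded marker log), the
    agent consults it when choosing elements, skipping highlighted ones
    with ``avoid_partner_prob``; otherwise it searches independently.
    """
    _check_target(grid, target)
    rng = np.random.default_rng(seed)
    pos = _element_positions(grid, element_offsets)
    agent = _Agent(participant, strategy, grid, target, pos, rng, partner_highlights is not None)

    if partner_highlights is not None:
        runs = [
            (h, onset)
            for h, onset, dur, _n in aoi.highlight_runs(partner_highlights)
            if h != aoi.NO_HIGHLIGHT and dur > 0.050
        ]
        runs.sort(key=lambda r: r[1])
    else:
        runs = []

    while not agent.done:
        visible = {h for h, onset in runs if onset <= agent.now}
        agent.step(visible)

    rt = agent.response_time if agent.response_time is not None else agent.now
    fixations, itinerary = _truncate(agent, rt)
    stream = _synthesize_stream(participant, trial, fixations, rt, strategy.noise_sd, rng)
    responded = agent.response_time is not None
    record = TrialRecord(
        condition=condition,
        target_hex=target,
        responder=participant if responded else None,
        response_hex=agent.response_hex,
        rt=rt,
        correct=bool(responded and agent.response_hex == target),
        points_delta=(300 if agent.response_hex == target else -600) if responded else 0,
    )
    return SearcherResult(participant, stream, fixations, itinerary, record)


def simulate_pair(
    strategies: tuple[StrategyParams, StrategyParams],
    coupling: str,
    grid: grid_mod.GridSpec,
    target: int,
    seed=0,
    trial: int = 0,
    condition: str | None = None,
    element_offsets=None,
) -> PairTrial:
    """Simulate both searchers of a pair concurrently on a shared clock."""
    if coupling not in COUPLINGS:
        raise ConfigError(f"unknown coupling {coupling!r}")
    _check_target(grid, target)
    condition = condition or coupling
    rng_a, rng_b = np.random.default_rng(seed).spawn(2)
    pos = _element_positions(grid, element_offsets)
    agents = [
        _Agent("a", strategies[0], grid, target, pos, rng_a, True),
        _Agent("b", strategies[1], grid, target, pos, rng_b, True),
    ]
    if coupling == "blind":
        for ag in agents:
            ag.consult_partner = False
    rt = _run_agents(agents, coupling)

    results = []
    for ag, strat in zip(agents, strategies):
        fixations, itinerary = _truncate(ag, rt)
        stream = _synthesize_stream(ag.participant, trial, fixations, rt, strat.noise_sd, ag.rng)
        results.append((ag, SearcherResult(ag.participant, stream, fixations, itinerary, None)))

    responders = [
        ag for ag, _ in results if ag.response_time is not None and ag.response_time <= rt + 1e-12
    ]
    if responders:
        winner = min(responders, key=lambda a: a.response_time)
        record = TrialRecord(
            condition=condition,
            target_hex=target,
            responder=winner.participant,
            response_hex=winner.response_hex,
            rt=rt,
            correct=winner.response_hex == target,
            points_delta=300 if winner.response_hex == target else -600,
        )
    else:
        record = TrialRecord(condition, target, None, None, rt, False, 0)
    for _, res in results:
        res.record = record
    (_, res_a), (_, res_b) = results
    return PairTrial(
        trial=trial,
        condition=condition,
        target_hex=target,
        a=res_a,
        b=res_b,
        highlight_a=aoi.highlight_stream(res_a.stream, grid),
        highlight_b=aoi.highlight_stream(res_b.stream, grid),
        record=record,
    )


def default_strategies(condition: str) -> tuple[StrategyParams, StrategyParams]:
    """The study conditions emulated by the generator.

    Collaborators run a division-of-labour raster from opposite corners
    and always avoid elements their partner has highlighted; competitors
    greedily seek fresh tiles, consulting the partner's marker on most
    decisions; blind and individual searchers scan independently.
    """
    if condition == "individual":
        # Solo searchers share the top-first scanning habit but differ in
        # horizontal direction; fully opposite corners would make the
        # min-RT blind baseline unrealistically fast (anti-correlated
        # coverage), identical corners unrealistically slow.
        return (
            StrategyParams(kind="raster_full", start_corner="tl"),
            StrategyParams(kind="raster_full", start_corner="tr"),
        )
    if condition == "collaborate":
        return (
            StrategyParams(kind="raster_divided", start_corner="tl", avoid_partner_prob=1.0),
            StrategyParams(kind="raster_divided", start_corner="br", avoid_partner_prob=1.0),
        )
    if condition == "compete":
        return (
            StrategyParams(kind="fresh_tile_competitor", start_corner="tl", avoid_partner_prob=0.3),
            StrategyParams(kind="fresh_tile_competitor", start_corner="br", avoid_partner_prob=0.3),
        )
    if condition == "blind":
        return (
            StrategyParams(kind="blind_independent", start_corner="tl"),
            StrategyParams(kind="blind_independent", start_corner="tl"),
        )
    raise ConfigError(f"unknown condition {condition!r}")


def draw_target(grid: grid_mod.GridSpec, rng: np.random.Generator) -> int:
    """Uniform random target element, never the central element."""
    center = grid.n_elements // 2
    ids = [i for i in range(grid.n_elements) if i != center]
    return int(rng.choice(ids))


def simulate_session(
    n_trials: int,
    conditions=("individual", "collaborate", "compete"),
    strategies=None,
    seed=0,
    grid: grid_mod.GridSpec | None = None,
) -> Session:
    """Simulate a full session (``n_trials`` per condition) for one pair.

    ``strategies`` maps condition name to a pair of
    :class:`StrategyParams`; missing conditions use
    :func:`default_strategies`. In the individual condition the two
    participants search independently with independent random targets per
    trial, which is what the blind-baseline construction matches on. All
    randomness descends from the master seed.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    grid = grid or grid_mod.build_grid()
    strategies = dict(strategies or {})
    master = np.random.SeedSequence(seed)
    session = Session(master_seed=seed, grid=grid, conditions=tuple(conditions))

    for cond, cond_ss in zip(conditions, master.spawn(len(conditions))):
        strat = strategies.get(cond, default_strategies(cond))
        trial_seeds = cond_ss.spawn(n_trials)
        if cond == "individual":
            session.individual = {"a": [], "b": []}
            for i, tss in enumerate(trial_seeds):
                t_ss_a, t_ss_b, j_ss = tss.spawn(3)
                rng_t = np.random.default_rng(j_ss)
                offsets = grid_mod.jitter_elements(grid, rng_t)
                for participant, st, sseed in (("a", strat[0], t_ss_a), ("b", strat[1], t_ss_b)):
                    rng_p = np.random.default_rng(sseed)
                    target = draw_target(grid, rng_p)
                    res = simulate_searcher(
                        st,
                        grid,
                        target,
                        seed=rng_p,
                        condition=cond,
                        participant=participant,
                        trial=i,
                        element_offsets=offsets,
                    )
                    session.individual[participant].append(res)
        else:
            coupling = "blind" if cond == "blind" else cond
            trials = []
            for i, tss in enumerate(trial_seeds):
                rng_t = np.random.default_rng(tss)
                target = draw_target(grid, rng_t)
                offsets = grid_mod.jitter_elements(grid, rng_t)
                trials.append(
                    simulate_pair(
                        strat,
                        coupling,
                        grid,
                        target,
                        seed=rng_t,
                        trial=i,
                        condition=cond,
                        element_offsets=offsets,
                    )
                )
            session.pairs[cond] = trials
    return session
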