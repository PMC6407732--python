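import numpy as np
import pytest

from gazepair import events
from gazepair.errors import ConfigError
from gazepair.simulate import (
    StrategyParams,
    default_strategies,
    draw_target,
    raster_order,
    simulate_pair,
    simulate_searcher,
    simulate_session,
)


def deterministic_params(**overrides):
    base = dict(
        kind="raster_full",
        noise_sd=0.0,
        fixation_scatter=0.0,
        identification_miss_prob=0.0,
        dwell_fixations=1.0,
        fixation_duration_sd=0.0,
    )
    base.update(overrides)
    return StrategyParams(**base)


class TestSoloSearcher:
    def test_raster_visits_elements_in_fixed_order(self, grid):
        res = simulate_searcher(deterministic_params(), grid, target=24, seed=0)
        order = raster_order(grid, "tl")
        visited = [h for h, _ in res.itinerary]
        assert visited == order[: len(visited)]
        assert visited[-1] == 24

    def test_rt_increases_with_raster_distance_to_target(self, grid):
        order = raster_order(grid, "tl")
        rts = []
        for target in (order[3], order[10], order[20]):
            res = simulate_searcher(deterministic_params(), grid, target=target, seed=1)
            rts.append(res.record.rt)
        assert rts[0] < rts[1] < rts[2]

    def test_same_seed_reproduces_stream_exactly(self, grid):
        kw = dict(strategy=StrategyParams(), grid=grid, target=17, seed=42)
        a = simulate_searcher(**kw)
        b = simulate_searcher(**kw)
        for field in ("t", "lx", "ly", "rx", "ry"):
            assert np.array_equal(getattr(a.stream, field), getattr(b.stream, field))
        assert a.record == b.record

    def test_certain_miss_with_visit_cap_ends_unanswered(self, grid):
        params = deterministic_params(identification_miss_prob=1.0, max_visits=30)
        res = simulate_searcher(params, grid, target=5, seed=0)
        assert res.record.responder is None
        assert not res.record.correct
        assert res.record.points_delta == 0
        assert 5 in {h for h, _ in res.itinerary}  # fixated but never reported
        assert len(res.itinerary) == 30

    def test_target_in_center_rejected(self, grid):
        with pytest.raises(ConfigError):
            simulate_searcher(StrategyParams(), grid, target=12, seed=0)

    def test_noise_free_trial_dwells_match_itinerary(self, grid):
        res = simulate_searcher(deterministic_params(), grid, target=19, seed=3)
        fx = events.detect_fixations(res.stream)
        dwells = events.build_dwells(fx, grid)
        assert [d.hex for d in dwells] == [h for h, _ in res.itinerary]
        assert len(fx) == len(res.fixations)


class TestPairs:
    def test_blind_identical_rasters_trace_identical_paths(self, grid):
        strat = deterministic_params()
        pt = simulate_pair((strat, strat), "blind", grid, target=23, seed=0)
        seq_a = [h for h, _ in pt.a.itinerary]
        seq_b = [h for h, _ in pt.b.itinerary]
        n = min(len(seq_a), len(seq_b))
        assert seq_a[:n] == seq_b[:n]

    def test_full_avoidance_from_opposite_corners_gives_no_shared_elements(self, grid):
        strats = (
            deterministic_params(avoid_partner_prob=1.0, start_corner="tl"),
            deterministic_params(avoid_partner_prob=1.0, start_corner="br"),
        )
        pt = simulate_pair(strats, "collaborate", grid, target=7, seed=0)
        seen_a = {h for h, _ in pt.a.itinerary}
        seen_b = {h for h, _ in pt.b.itinerary}
        assert seen_a & seen_b == set()

    def test_competing_pair_is_no_slower_than_either_solo(self, grid):
        strats = (
            deterministic_params(kind="fresh_tile_competitor", start_corner="tl"),
            deterministic_params(kind="fresh_tile_competitor", start_corner="br"),
        )
        for target in (3, 11, 24):
            pt = simulate_pair(strats, "compete", grid, target=target, seed=9)
            solo_a = simulate_searcher(strats[0], grid, target, seed=9)
            solo_b = simulate_searcher(strats[1], grid, target, seed=9)
            assert pt.record.rt <= min(solo_a.record.rt, solo_b.record.rt) + 1e-9

    def test_nonresponder_stream_truncated_at_trial_end(self, grid):
        pt = simulate_pair(default_strategies("collaborate"), "collaborate", grid, 7, seed=4)
        assert pt.a.stream.t[-1] <= pt.record.rt
        assert pt.b.stream.t[-1] <= pt.record.rt

    def test_unknown_coupling_rejected(self, grid):
        with pytest.raises(ConfigError):
            simulate_pair(default_strategies("collaborate"), "telepathy", grid, 7, seed=0)


class TestSession:
    def test_trial_counts_per_condition(self):
        sess = simulate_session(3, conditions=("individual", "collaborate"), seed=0)
        assert len(sess.individual["a"]) == 3
        assert len(sess.individual["b"]) == 3
        assert len(sess.pairs["collaborate"]) == 3

    def test_single_trial_session(self):
        sess = simulate_session(1, conditions=("compete",), seed=0)
        assert len(sess.pairs["compete"]) == 1

    def test_session_is_seed_deterministic(self):
        s1 = simulate_session(2, conditions=("collaborate",), seed=5)
        s2 = simulate_session(2, conditions=("collaborate",), seed=5)
        for t1, t2 in zip(s1.pairs["collaborate"], s2.pairs["collaborate"]):
            assert np.array_equal(t1.a.stream.lx, t2.a.stream.lx)
            assert t1.record == t2.record

    def test_targets_never_center_and_nearly_uniform(self, grid):
        rng = np.random.default_rng(0)
        draws = np.array([draw_target(grid, rng) for _ in range(10_000)])
        assert not np.any(draws == 12)
        counts = np.bincount(draws, minlength=25)
        # exact multinomial: each non-center id has p = 1/24
        expected = 10_000 / 24
        sd = np.sqrt(10_000 * (1 / 24) * (23 / 24))
        assert np.all(np.abs(counts[np.arange(25) != 12] - expected) < 5 * sd)

    def test_invalid_strategy_params_rejected(self):
        with pytest.raises(ConfigError):
            StrategyParams(kind="psychic").validate()
        with pytest.raises(ConfigError):
            StrategyParams(avoid_partner_prob=1.5).validate()
        with pytest.raises(ConfigError):
            StrategyParams(fixation_duration_mean=-0.1).validate()


class TestBehaviouralEnvelope:
    def test_parameter_recovery_of_sample_noise(self, grid):
        # The event layer's precision metric recovers the generator's
        # per-eye noise sd via binocular averaging.
        params = StrategyParams(
            noise_sd=0.2, identification_miss_prob=1.0, max_visits=75, dwell_fixations=2.0
        )
        res = simulate_searcher(params, grid, target=24, seed=8)
        m = events.precision_metrics(res.stream, fixations=res.fixations)
        assert m.mean_sd == pytest.approx(0.2, rel=0.05)

    def test_random_walk_moves_between_adjacent_elements(self, grid):
        params = deterministic_params(kind="random_walk", identification_miss_prob=1.0, max_visits=40)
        res = simulate_searcher(params, grid, target=24, seed=2)
        seq = [h for h, _ in res.itinerary]
        d = np.linalg.norm(
            grid.centers[np.array(seq[1:])] - grid.centers[np.array(seq[:-1])], axis=1
        )
        assert np.allclose(d, 4.6, atol=1e-6)
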