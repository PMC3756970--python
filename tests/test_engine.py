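import math

import numpy as np
import pytest
from scipy import stats

from invadrift.config import ModelConfig, per_cycle_hazards
from invadrift.engine import (
    EngineError,
    PopulationKernel,
    SimulationState,
    TransitFields,
    attempt_settlement,
    neighbor_scores,
    run_simulation,
    step_month,
    trace_transit,
)

from conftest import SCENARIO_ORIGIN, make_uniform_stack

E, N = 4, 1  # neighbor-vector indices (order NW,N,NE,W,E,SW,S,SE)


class TestNeighborScores:
    def test_due_east_current_favors_east_neighbor(self):
        stack = make_uniform_stack(speed=1.0, direction=90.0)
        p = neighbor_scores(stack, (5, 5), 6, ModelConfig())
        assert p[E] == max(p)
        assert p[E] > max(np.delete(p, E))

    def test_slack_water_gives_uniform_eighths(self):
        stack = make_uniform_stack(speed=0.0)
        p = neighbor_scores(stack, (5, 5), 6, ModelConfig())
        assert np.allclose(p, 1 / 8)

    def test_static_weights_divide_mass_when_current_is_slack(self):
        # only the two northern-row neighbors sit inside the SST range
        stack = make_uniform_stack(speed=0.0, sst=25.0)
        stack.sst[:, :4, :] = 25.0
        stack.sst[:, 5:, :] = 40.0   # too hot south of row 4
        stack.sst[:, 4, :] = 40.0
        stack.sst[:, 4, 5] = 40.0
        # cell (5,5): NW,N,NE in row 4 -> make only N and NE tolerable
        stack.sst[:, 4, 5] = 25.0
        stack.sst[:, 4, 6] = 25.0
        stack.sst[:, 4, 4] = 40.0
        p = neighbor_scores(stack, (5, 5), 6, ModelConfig())
        assert p[1] == p[2] > p[0]          # N and NE share the largest mass
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_probabilities_sum_to_one_everywhere(self, synth_stack, default_config):
        fields = TransitFields(synth_stack, default_config)
        marine_interior = synth_stack.marine_mask & ~fields.dead_end
        sums = fields.probs.sum(axis=-1)[:, marine_interior]
        assert np.all(np.abs(sums - 1.0) < 1e-12)

    def test_isolated_cell_rejected(self):
        land = np.ones((5, 5), dtype=bool)
        land[2, 2] = False
        stack = make_uniform_stack(nrows=5, ncols=5, land_mask=land)
        with pytest.raises(EngineError, match="no marine neighbor"):
            neighbor_scores(stack, (2, 2), 1, ModelConfig())


class TestTraceTransit:
    def test_dwell_arithmetic_at_equator(self):
        # 6-arc-min cell at the equator is ~11,120 m wide; at 0.5 m/s the
        # per-cell dwell is ~0.257 d, so the clock lands in [D, D + dwell)
        stack = make_uniform_stack(nrows=40, ncols=40, speed=0.5, direction=45.0,
                                   lat_min=-2.0)
        cfg = ModelConfig()
        rng = np.random.default_rng(0)
        k = trace_transit(stack, (20, 20), 1, cfg, rng)
        dwell = 11_120 / (0.5 * 86_400)
        assert 40.0 <= k.elapsed_transit < 40.0 + dwell * 1.01

    def test_stagnant_water_floors_speed(self):
        # floored speed 0.01 m/s caps dwell at ~12.9 d: settlement within
        # ceil(40 / 12.9) = 4 hops of the origin
        stack = make_uniform_stack(nrows=20, ncols=20, speed=0.0, lat_min=-1.0)
        cfg = ModelConfig()
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = trace_transit(stack, (10, 10), 1, cfg, rng)
            assert max(abs(k.current_cell[0] - 10), abs(k.current_cell[1] - 10)) <= 4

    def test_uniform_jet_carries_kernels_downstream(self, uniform_jet_stack):
        cfg = ModelConfig()
        rng = np.random.default_rng(2)
        north = 0
        for _ in range(1000):
            k = trace_transit(uniform_jet_stack, (35, 10), 1, cfg, rng)
            north += k.current_cell[0] < 35
        assert north / 1000 > 0.95

    def test_land_origin_rejected(self):
        land = np.zeros((5, 5), dtype=bool)
        land[0, 0] = True
        stack = make_uniform_stack(nrows=5, ncols=5, land_mask=land)
        with pytest.raises(EngineError):
            trace_transit(stack, (0, 0), 1, ModelConfig(), np.random.default_rng(0))


class TestAttemptSettlement:
    def test_certain_survival_in_habitable_cell(self):
        stack = make_uniform_stack()
        cfg = ModelConfig(propagule_mortality=0.0)
        rng = np.random.default_rng(0)
        fields = TransitFields(stack, cfg)
        assert all(attempt_settlement((5, 5), 6, stack, cfg, rng, fields) == "settled"
                   for _ in range(100))

    def test_survivor_dies_in_deep_cell(self):
        stack = make_uniform_stack(depth=50.0)
        cfg = ModelConfig(propagule_mortality=0.0)
        rng = np.random.default_rng(0)
        fields = TransitFields(stack, cfg)
        assert attempt_settlement((5, 5), 6, stack, cfg, rng, fields) == "dead"

    def test_empirical_settle_rate_matches_transport_survival(self):
        # binomial check at 1e5 draws against p = exp(-Zp*D) = exp(-8)
        stack = make_uniform_stack()
        cfg = ModelConfig()
        fields = TransitFields(stack, cfg)
        rng = np.random.default_rng(3)
        n = 100_000
        hits = sum(attempt_settlement((5, 5), 6, stack, cfg, rng, fields) == "settled"
                   for _ in range(n))
        p = math.exp(-8.0)
        se = math.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 3 * se


class TestStepMonth:
    def _state(self, stack, cfg, populations):
        return SimulationState(config=cfg, stack=stack,
                               fields=TransitFields(stack, cfg),
                               rng=np.random.default_rng(0),
                               populations=populations)

    def test_promotion_at_breeding_age_emits_nothing_that_cycle(self):
        stack = make_uniform_stack()
        cfg = ModelConfig(adult_mortality=0.0)
        juvenile = PopulationKernel(cell=(5, 5), settlement_cycle=0, age=17)
        state = self._state(stack, cfg, [juvenile])
        step_month(state)
        assert juvenile.breeding and juvenile.age == 18
        assert not any(e.kind == "spawn" for e in state.events)
        assert any(e.kind == "promote" for e in state.events)

    def test_calendar_month_wraps_december_to_january(self):
        stack = make_uniform_stack()
        cfg = ModelConfig(starting_month=12, adult_mortality=0.0)
        state = self._state(stack, cfg, [])
        assert state.calendar_month == 12
        step_month(state)
        assert state.calendar_month == 1
        assert state.cycle_stats[0].calendar_month == 12

    def test_kernel_count_conservation(self, scenario_runs):
        for res in scenario_runs:
            for s in res.cycle_stats:
                assert s.alive_end == s.alive_start + s.settled - s.deaths


class TestRunSimulation:
    def test_zero_months_returns_only_founder(self, synth_stack, default_config):
        res = run_simulation(default_config, synth_stack, SCENARIO_ORIGIN, months=0,
                             seed=0)
        assert res.events == []
        assert res.total_settled() == 0
        assert res.establishment_cycle[res.origin] == 0

    def test_same_seed_reproduces_event_log(self, synth_stack, scenario_config):
        a = run_simulation(scenario_config, synth_stack, SCENARIO_ORIGIN,
                           months=24, seed=11)
        b = run_simulation(scenario_config, synth_stack, SCENARIO_ORIGIN,
                           months=24, seed=11)
        assert a.events == b.events
        assert np.array_equal(a.settled_count, b.settled_count)

    def test_land_origin_rejected(self, synth_stack, default_config):
        with pytest.raises(EngineError, match="land"):
            run_simulation(default_config, synth_stack, (26.217, -80.9), months=1)

    def test_extinction_when_transport_survival_vanishes(self, synth_stack):
        # survival exp(-40) < 1e-9: a 78-month run never settles a kernel
        cfg = ModelConfig(propagule_mortality=1.0, founder_immortal=True)
        res = run_simulation(cfg, synth_stack, SCENARIO_ORIGIN, months=78, seed=5)
        assert res.total_settled() == 0
        assert not any(e.kind == "settle" for e in res.events)

    def test_settlement_centroid_downstream_of_origin(self, uniform_jet_stack):
        # northward jet at the grid maximum with dominant current weight:
        # pooled settlement over 20 replicates sits north of the origin
        cfg = ModelConfig(propagule_mortality=0.05, founder_immortal=True)
        origin = (35, 10)
        pooled = np.zeros_like(uniform_jet_stack.depth)
        for rep in range(20):
            res = run_simulation(cfg, uniform_jet_stack, origin, months=12,
                                 seed=100 + rep)
            pooled += res.settled_count
        assert pooled.sum() > 0
        rows = np.nonzero(pooled)[0]
        weights = pooled[np.nonzero(pooled)]
        centroid_row = float((rows * weights).sum() / weights.sum())
        assert centroid_row < origin[0]

    def test_no_event_on_land_and_no_settlement_outside_ranges(
            self, scenario_runs, synth_stack, scenario_config):
        cfg = scenario_config
        for res in scenario_runs:
            for e in res.events:
                r, c = e.cell
                assert not synth_stack.land_mask[r, c]
                if e.kind == "settle":
                    m = e.calendar_month - 1
                    assert cfg.sst_range[0] <= synth_stack.sst[m, r, c] <= cfg.sst_range[1]
                    assert (cfg.cc_range[0] <= synth_stack.chlorophyll[m, r, c]
                            <= cfg.cc_range[1])
                    assert cfg.depth_range[0] <= synth_stack.depth[r, c] <= cfg.depth_range[1]

    def test_adult_lifetimes_follow_the_monthly_hazard(self):
        # with spawning off, a founder's lifetime is geometric with
        # p = 1 - exp(-Z/12); chi-square against that distribution
        stack = make_uniform_stack()
        cfg = ModelConfig(adult_mortality=2.4, spawns_per_cycle=0)
        _, p = per_cycle_hazards(cfg)
        lifetimes = []
        for i in range(2000):
            res = run_simulation(cfg, stack, (5, 5), months=80, seed=i)
            deaths = [e.cycle for e in res.events if e.kind == "death"]
            if deaths:
                lifetimes.append(deaths[0])
        lifetimes = np.array(lifetimes)
        assert len(lifetimes) > 1950  # truncation at 80 cycles is negligible
        kmax = 15
        observed = np.bincount(np.minimum(lifetimes, kmax + 1), minlength=kmax + 2)[1:]
        expected = np.array(
            [p * (1 - p) ** (k - 1) for k in range(1, kmax + 1)]
            + [(1 - p) ** kmax]) * len(lifetimes)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=kmax)
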