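import itertools

import numpy as np
import pytest
from scipy import stats

from invadrift.engine import SimulationResult
from invadrift.environment import GridSpec
from invadrift.validation import (
    ValidationError,
    common_step_count,
    critical_value,
    quadrant_sequence,
    representative_sequence,
    run_null_model,
    select_representative_model,
    spearman_rho,
    validation_report,
)

from conftest import make_uniform_stack


def result_with_establishments(cells_cycles, grid=None):
    """Minimal SimulationResult carrying only an establishment raster."""
    grid = grid or GridSpec(lat_min=24, lat_max=30, lon_min=-81, lon_max=-75)
    est = np.full((grid.n_rows, grid.n_cols), np.nan)
    for (r, c), cycle in cells_cycles:
        est[r, c] = cycle
    return SimulationResult(grid=grid, events=[], settled_count=np.zeros_like(est),
                            establishment_cycle=est, cycle_stats=[], months=0,
                            seed=None, config_hash="", origin=(0, 0))


class TestQuadrantSequence:
    def test_ordered_by_establishment_cycle(self):
        # three well-separated cells establishing at cycles 20, 28, 37
        res = result_with_establishments([((0, 0), 28), ((30, 30), 20), ((59, 59), 37)])
        seq = quadrant_sequence(res)
        assert [cyc for _, cyc in seq.steps] == [20, 28, 37]

    def test_empty_result_gives_empty_sequence(self):
        assert quadrant_sequence(result_with_establishments([])).n_steps == 0

    def test_quadrant_counted_once_at_first_cycle(self):
        # two cells in the same 0.5-degree quadrant at cycles 5 and 9
        res = result_with_establishments([((0, 0), 9), ((1, 1), 5)])
        seq = quadrant_sequence(res)
        assert seq.n_steps == 1
        assert seq.steps[0][1] == 5


class TestRepresentativeSequence:
    def test_identical_members_reproduce_themselves(self):
        seqs = [["A", "B", "C"]] * 20
        assert representative_sequence(seqs, 3) == ["A", "B", "C"]

    def test_stepwise_mode(self):
        seqs = [["A", "B"], ["A", "C"], ["A", "B"]]
        assert representative_sequence(seqs, 2) == ["A", "B"]

    def test_tie_takes_lexicographically_smallest(self):
        seqs = [["A", "B"], ["A", "C"]]
        assert representative_sequence(seqs, 2) == ["A", "B"]

    def test_inferred_steps_is_count_common_to_all(self):
        seqs = [["A", "B", "C"], ["A", "C", "D"], ["C", "A", "E"]]
        assert common_step_count(seqs) == 2  # {A, C}
        assert len(representative_sequence(seqs)) == 2

    def test_zero_steps_rejected(self):
        with pytest.raises(ValidationError):
            representative_sequence([["A"], ["B"]])


class TestRepresentativeModel:
    def test_exact_match_wins(self):
        rep = ["A", "B", "C"]
        seqs = [["B", "A", "C"], ["A", "B", "C"], ["C", "B", "A"]]
        assert select_representative_model(seqs, rep) == 1

    def test_tie_goes_to_lowest_index(self):
        rep = ["A", "B"]
        seqs = [["A", "C"], ["A", "D"], ["A", "B"]]
        # scores 1, 1, 2 -> index 2; then force a tie
        assert select_representative_model(seqs, rep) == 2
        assert select_representative_model(seqs[:2], rep) == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, L = 6, 5
            seqs = [list(rng.permutation(L)) for _ in range(n)]
            rep = list(rng.permutation(L))
            scores = [sum(a == b for a, b in zip(s, rep)) for s in seqs]
            assert select_representative_model(seqs, rep) == int(np.argmax(scores))


class TestSpearman:
    def test_identical_orderings_give_one(self):
        seq = list("ABCDEFGH")
        assert spearman_rho(seq, seq) == 1.0

    def test_reversed_ordering_gives_minus_one(self):
        seq = list("ABCDEFGHIJ")
        assert spearman_rho(seq, seq[::-1]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks (1..5) vs (2,1,4,3,5): rho = 1 - 6*4/120 = 0.8
        a = ["q1", "q2", "q3", "q4", "q5"]
        b = ["q2", "q1", "q4", "q3", "q5"]
        assert spearman_rho(a, b) == pytest.approx(0.8)

    def test_too_few_common_quadrants_rejected(self):
        with pytest.raises(ValidationError, match="common"):
            spearman_rho(["A", "B", "C"], ["A", "B", "X"])

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_rank_formula_exhaustively(self, n):
        base = list(range(n))
        for perm in itertools.permutations(base):
            d2 = sum((base.index(q) - perm.index(q)) ** 2 for q in base)
            expected = 1 - 6 * d2 / (n * (n * n - 1))
            assert spearman_rho(base, list(perm)) == pytest.approx(expected)

    def test_agrees_with_scipy_on_aligned_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = list(rng.permutation(9))
            b = list(rng.permutation(9))
            expected = stats.spearmanr(
                [a.index(q) for q in range(9)], [b.index(q) for q in range(9)]
            ).statistic
            assert spearman_rho(a, b) == pytest.approx(expected)


class TestCriticalValue:
    def test_published_two_tailed_values(self):
        assert critical_value(10, 0.05, True) == 0.65
        assert critical_value(12, 0.05, True, mc_draws=1_000_000, seed=3) == 0.59

    def test_monotone_in_n_and_alpha(self):
        values = [critical_value(n, 0.05, True) for n in range(5, 11)]
        assert values == sorted(values, reverse=True)
        assert critical_value(8, 0.10, True) <= critical_value(8, 0.05, True)

    def test_degenerate_alpha_returns_support_minimum(self):
        # alpha ~ 1: smallest achievable |rho| with tail <= alpha, just above 0
        assert critical_value(5, 0.9999, True) == pytest.approx(0.1)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            critical_value(3)


class TestNullModel:
    def strip(self):
        return make_uniform_stack(nrows=1, ncols=3, lat_min=0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_three_cell_strip_closes_in_two_cycles(self, seed):
        res = run_null_model(self.strip(), (0, 1), seed=seed)
        est = res.establishment_cycle[0]
        assert est[1] == 0
        assert res.months in (1, 2)
        assert max(est[0], est[2]) <= 2

    def test_same_seed_identical_occupancy_order(self, synth_stack):
        a = run_null_model(synth_stack, (26.217, -80.083), seed=3, max_cycles=30)
        b = run_null_model(synth_stack, (26.217, -80.083), seed=3, max_cycles=30)
        assert np.array_equal(a.establishment_cycle, b.establishment_cycle,
                              equal_nan=True)

    def test_occupancy_grows_monotonically_to_closure(self):
        stack = make_uniform_stack(nrows=8, ncols=8, lat_min=0.0)
        res = run_null_model(stack, (4, 4), seed=0)
        est = res.establishment_cycle
        assert not np.isnan(est).any()  # full occupancy
        counts = [int((est <= k).sum()) for k in range(res.months + 1)]
        assert counts == sorted(counts)
        assert counts[-1] == 64

    def test_disconnected_component_warns(self):
        land = np.zeros((5, 5), dtype=bool)
        land[:, 2] = True  # wall splits the strip
        stack = make_uniform_stack(nrows=5, ncols=5, land_mask=land, lat_min=0.0)
        with pytest.warns(UserWarning, match="disconnected"):
            res = run_null_model(stack, (2, 0), seed=0)
        assert np.isnan(res.establishment_cycle[:, 3:]).all()


class TestValidationReport:
    def test_identical_members_perfectly_self_correlated(self):
        times = [0, 5, 9, 14, 20, 30]
        cells = [((0, 0), 0), ((10, 10), 5), ((20, 20), 9), ((30, 30), 14),
                 ((40, 40), 20), ((50, 50), 30)]
        members = [result_with_establishments(cells) for _ in range(4)]
        # one null realization visiting the same quadrants in reverse order
        nulls = [result_with_establishments(
            [(cell, t) for (cell, _), t in zip(cells, reversed(times))])]
        rep = validation_report(members, nulls, mc_draws=100_000)
        assert rep.mean_rho_members_vs_rm == pytest.approx(1.0)
        assert rep.n_steps == 6
        assert rep.significant_members

    def test_requires_two_members(self):
        res = result_with_establishments([((0, 0), 0)])
        with pytest.raises(ValidationError):
            validation_report([res], [])

    def test_member_order_does_not_change_representative_sequence(
            self, scenario_runs, null_runs):
        fwd = validation_report(scenario_runs, null_runs[:2], mc_draws=50_000)
        rev = validation_report(list(reversed(scenario_runs)), null_runs[:2],
                                mc_draws=50_000)
        assert fwd.representative_sequence == rev.representative_sequence
        assert fwd.n_steps == rev.n_steps
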