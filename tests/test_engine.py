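"""Simulation engine: probability algebra, stepping rules, updates, replication."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import windshift as ws
from windshift.engine import (
    SimulationState,
    _log_miss_stack,
    colonization_probability,
)
from windshift.kernels import ring_offsets
from conftest import make_config, make_stack, ring1_log_miss


def state_from(suitable, occupied, rng=None):
    stack = make_stack([np.asarray(suitable)])
    state = SimulationState.initial(stack, rng)
    state.occupied = np.array(occupied, dtype=bool)
    return state


class TestProbabilityAlgebra:
    def test_p_disp_examples(self):
        assert ws.p_disp(0.3, 1) == pytest.approx(0.3)  # identity at one seed
        assert ws.p_disp(0.0, 5) == 0.0
        assert ws.p_disp(0.1, 2) == pytest.approx(0.19)
        with pytest.raises(ValueError):
            ws.p_disp(0.1, 0)

    def test_p_col_examples(self):
        assert ws.p_col([]) == 0.0
        assert ws.p_col([(0.37, 1.0)]) == pytest.approx(0.37)
        assert ws.p_col([(0.5, 1.0), (0.5, 1.0)]) == pytest.approx(0.75)

    @given(
        probs=st.lists(st.floats(0, 1), min_size=1, max_size=6),
        extra=st.floats(0.01, 1),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_p_col_monotone_in_contributions(self, probs, extra):
        base = [(p, 1.0) for p in probs]
        assert ws.p_col(base + [(extra, 1.0)]) >= ws.p_col(base)
        assert 0.0 <= ws.p_col(base) <= 1.0


class TestDispersalStep:
    def test_certain_ring1_kernel_colonizes_exactly_the_moore_neighbours(self):
        suitable = np.ones((5, 5))
        occupied = np.zeros((5, 5), dtype=bool)
        occupied[2, 2] = True
        state = state_from(suitable, occupied)
        rng = np.random.default_rng(0)
        new = ws.dispersal_step(state, ring1_log_miss((5, 5)), 10, rng)
        expected = np.zeros((5, 5), dtype=bool)
        expected[1:4, 1:4] = True
        expected[2, 2] = False
        np.testing.assert_array_equal(new, expected)
        assert np.all(state.colonized_year[new] == 0)

    def test_null_kernel_changes_nothing(self):
        suitable = np.ones((5, 5))
        occupied = np.zeros((5, 5), dtype=bool)
        occupied[2, 2] = True
        state = state_from(suitable, occupied)
        before = state.occupied.copy()
        new = ws.dispersal_step(state, np.zeros((10, 5, 5)), 10, np.random.default_rng(0))
        assert not new.any()
        np.testing.assert_array_equal(state.occupied, before)

    def test_one_step_probability_equals_p_disp_for_single_source(self):
        """On a 5x5 grid with one source and P_mat = 1, the analytic P_col of
        every cell equals p_disp of its distance class (Eqs. 1-3 collapse)."""
        params = ws.wald_params(H=10.0, U_H=3.0, Vt=0.01, h=0.3, sigma_w=0.6)
        kernel = ws.discretize_kernel(params, 1000.0, 10)
        traits = ws.SpeciesTraits(Vt=0.01, H=10.0, successful_seeds=3)
        log_miss = np.log1p(
            -np.array([ws.p_disp(p, 3) for p in kernel.p_seed()])
        ).reshape(-1, 1, 1) * np.ones((1, 5, 5))
        occupied = np.zeros((5, 5), dtype=bool)
        occupied[2, 2] = True
        state = state_from(np.ones((5, 5)), occupied)
        pcol = colonization_probability(state, log_miss, 10)
        for r in range(5):
            for c in range(5):
                if (r, c) == (2, 2):
                    continue
                j = int(round(np.hypot(r - 2, c - 2)))
                assert pcol[r, c] == pytest.approx(
                    ws.p_disp(kernel.p_seed()[j - 1], 3), rel=1e-12
                )

    def test_two_sources_combine_multiplicatively(self):
        log_miss = np.zeros((10, 3, 3))
        log_miss[0] = np.log1p(-0.5)  # ring-1 p_disp = 0.5 everywhere
        occupied = np.zeros((3, 3), dtype=bool)
        occupied[0, 0] = occupied[0, 2] = True
        state = state_from(np.ones((3, 3)), occupied)
        pcol = colonization_probability(state, log_miss, 10)
        assert pcol[0, 1] == pytest.approx(0.75)  # two class-1 sources
        assert pcol[1, 0] == pytest.approx(0.5)  # one class-1 source


class TestLddStep:
    def test_zero_probability_is_a_no_op(self):
        occupied = np.zeros((5, 5), dtype=bool)
        occupied[0, 0] = True
        state = state_from(np.ones((5, 5)), occupied)
        new = ws.ldd_step(state, 0.0, 1000.0, 1000.0, np.random.default_rng(0))
        assert not new.any()

    def test_certain_ldd_fills_all_far_cells_in_one_step(self):
        # single source; every other suitable cell farther than 10 km
        suitable = np.ones((3, 30))
        occupied = np.zeros((3, 30), dtype=bool)
        occupied[1, 0] = True
        state = state_from(suitable, occupied)
        new = ws.ldd_step(state, 1.0, 10000.0, 1000.0, np.random.default_rng(0))
        cols = np.arange(30)
        dist = np.hypot(*np.meshgrid(np.arange(3) - 1, cols, indexing="ij")) * 1000.0
        expected = (dist > 10000.0) & suitable.astype(bool)
        np.testing.assert_array_equal(new, expected)

    def test_no_sources_means_no_ldd(self):
        state = state_from(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))
        new = ws.ldd_step(state, 1.0, 0.0, 1000.0, np.random.default_rng(0))
        assert not new.any()

    def test_ldd_probability_raises_colonization_across_a_gap(self):
        """On a landscape whose newly suitable area lies beyond the 10-km LDD
        floor, raising p_ldd strictly increases mean colonizations (matched
        seeds); it is inert on contiguous landscapes where nothing is ever
        that far from a source."""
        base = np.zeros((40, 6))
        base[25:] = 1  # occupied block
        withgap = base.copy()
        withgap[:8] = 1  # newly suitable strip, 17 rows beyond the front
        stack = make_stack([base, withgap, withgap, withgap, withgap])
        means = []
        for p_ldd in (0.0, 1e-2, 1e-1):
            traits = ws.SpeciesTraits(Vt=0.03, H=1.0, p_ldd=p_ldd)
            config = make_config(stack, traits, replicates=6, seed=4)
            result = ws.run_simulation(config, keep_states=False)
            means.append(result.mean_effective_colonizations())
        assert means[0] == 0.0  # unreachable without LDD (gap > d_max and > 10 km)
        assert means[0] < means[1] < means[2]

    def test_ldd_mean_matches_binomial_expectation(self):
        suitable = np.ones((2, 40))
        occupied = np.zeros((2, 40), dtype=bool)
        occupied[:, 0] = True
        eligible = 2 * (40 - 11)  # columns 12..39 are farther than 10 cells
        p = 0.3
        rng = np.random.default_rng(42)
        counts = []
        for _ in range(400):
            state = state_from(suitable, occupied)
            counts.append(int(ws.ldd_step(state, p, 10000.0, 1000.0, rng).sum()))
        mean = np.mean(counts)
        se = np.sqrt(eligible * p * (1 - p) / 400)
        assert abs(mean - eligible * p) < 4 * se


class TestEnvironmentUpdate:
    def test_unchanged_suitability_is_identity(self):
        grid = np.ones((4, 4))
        state = state_from(grid, np.ones((4, 4), dtype=bool))
        before = state.copy()
        ws.apply_environment_update(state, grid, 1)
        np.testing.assert_array_equal(state.occupied, before.occupied)
        assert not state.lost_ever.any()
        assert not state.newly_suitable.any()

    def test_occupied_cell_turning_unsuitable_is_lost(self):
        state = state_from(np.ones((2, 2)), np.ones((2, 2), dtype=bool))
        nxt = np.array([[0, 1], [1, 1]])
        ws.apply_environment_update(state, nxt, 1)
        assert not state.occupied[0, 0]
        assert state.lost_ever[0, 0]
        assert not state.colonized_then_extinct[0, 0]  # initial, not colonized

    def test_colonized_then_unsuitable_counts_as_effective_and_extinct(self):
        suitable = np.array([[1, 1, 1]])
        occupied = np.array([[1, 0, 0]], dtype=bool)
        state = state_from(suitable, occupied)
        state.newly_suitable[0, 1] = True  # became suitable earlier in the run
        state.year = 12
        state.colonize(np.array([[0, 1, 0]], dtype=bool))
        ws.apply_environment_update(state, np.array([[1, 0, 1]]), 2)
        assert state.colonized_then_extinct[0, 1]
        assert state.ever_colonized[0, 1]  # still an effective colonization
        assert not state.occupied[0, 1]

    def test_newly_suitable_cells_are_tagged_with_first_slice(self):
        state = state_from(np.array([[1, 0]]), np.array([[1, 0]], dtype=bool))
        ws.apply_environment_update(state, np.array([[1, 1]]), 3)
        assert state.newly_suitable[0, 1]
        assert state.newly_suitable_slice[0, 1] == 3
        ws.apply_environment_update(state, np.array([[1, 1]]), 4)
        assert state.newly_suitable_slice[0, 1] == 3  # first tag sticks


class TestRunSimulation:
    def test_zero_years_returns_initial_census(self):
        stack = make_stack([np.ones((4, 4))])
        config = make_config(stack, years=0, replicates=2)
        result = ws.run_simulation(config)
        for rep in result.replicates:
            assert rep.occupied_at_end == 16
            assert rep.effective_colonizations == 0
            assert rep.newly_suitable_total == 0

    def test_identical_seed_gives_bit_identical_results(self):
        stack = make_stack(
            [np.ones((8, 8)),
             np.vstack([np.zeros((2, 8)), np.ones((6, 8))]),
             np.vstack([np.zeros((4, 8)), np.ones((4, 8))])],
        )
        traits = ws.SpeciesTraits(Vt=0.01, H=10.0, p_ldd=1e-2)
        a = ws.run_simulation(make_config(stack, traits, replicates=3, seed=9))
        b = ws.run_simulation(make_config(stack, traits, replicates=3, seed=9))
        assert a.to_frame().equals(b.to_frame())
        for ra, rb in zip(a.replicates, b.replicates):
            np.testing.assert_array_equal(ra.state.occupied, rb.state.occupied)

    def test_climate_driven_loss_is_identical_across_replicates(self):
        slices = [np.ones((10, 10)), np.ones((10, 10)), np.ones((10, 10))]
        slices[1][:3] = 0
        slices[2][:5] = 0
        stack = make_stack(slices)
        traits = ws.SpeciesTraits(Vt=0.01, H=10.0, p_ldd=1e-1)
        result = ws.run_simulation(make_config(stack, traits, replicates=4, seed=2))
        losses = {r.lost_total for r in result.replicates}
        assert losses == {50}  # 5 rows x 10 cols, purely climate-driven

    def test_never_colonizes_unsuitable_or_nodata(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, 7] = True
        slices = [np.zeros((10, 10)), np.ones((10, 10)), np.ones((10, 10))]
        slices[0][:, :2] = 1
        slices[1][:, 5] = 0  # a permanently unsuitable stripe until the end
        stack = make_stack(slices, nodata_mask=mask)
        traits = ws.SpeciesTraits(Vt=0.005, H=10.0, successful_seeds=50, p_ldd=1e-1)
        result = ws.run_simulation(make_config(stack, traits, replicates=3, seed=5))
        for rep in result.replicates:
            occ = rep.state.occupied
            assert not occ[mask].any()
            assert not (occ & ~rep.state.suitable).any()

    def test_front_advances_one_ring_per_year(self):
        """Deterministic ring-1 spread matches an independent dilation oracle."""
        n = 13
        occupied = np.zeros((n, n), dtype=bool)
        occupied[n // 2, n // 2] = True
        state = state_from(np.ones((n, n)), occupied)
        rng = np.random.default_rng(0)
        offs = ring_offsets(1)[0]
        oracle = occupied.copy()
        for t in range(1, 5):
            ws.dispersal_step(state, ring1_log_miss((n, n)), 10, rng)
            grown = oracle.copy()
            for r, c in zip(*np.nonzero(oracle)):  # brute-force dilation
                for dr, dc in offs:
                    if 0 <= r + dr < n and 0 <= c + dc < n:
                        grown[r + dr, c + dc] = True
            oracle = grown
            np.testing.assert_array_equal(state.occupied, oracle)


class TestTimelag:
    @staticmethod
    def corridor_config(gap=25, width=5, head=10, tail=30, p_ldd=0.0):
        """Suitability constant until the final slice adds `gap` rows beyond the front."""
        n_rows = head + gap + tail
        base = np.zeros((n_rows, width))
        base[head + gap:] = 1
        final = base.copy()
        final[head:head + gap] = 1
        stack = make_stack([base, base, base, base, final])
        traits = ws.SpeciesTraits(Vt=0.01, H=10.0, p_ldd=p_ldd)
        return make_config(stack, traits, replicates=1, seed=0)

    def test_corridor_lag_is_exactly_the_gap_length(self):
        config = self.corridor_config(gap=7)
        result = ws.run_simulation(config)
        state = result.replicates[0].state
        lag, censored = ws.run_timelag_single(
            config, state, log_miss=ring1_log_miss(state.occupied.shape)
        )
        assert (lag, censored) == (7, False)

    def test_already_colonized_horizon_returns_zero(self):
        config = self.corridor_config(gap=5)
        result = ws.run_simulation(config)
        state = result.replicates[0].state
        state.ever_colonized |= state.newly_suitable  # pretend all were reached
        lag, censored = ws.run_timelag_single(config, state)
        assert (lag, censored) == (0, False)

    def test_null_kernel_without_ldd_is_censored(self):
        config = self.corridor_config(gap=5)
        result = ws.run_simulation(config)
        state = result.replicates[0].state
        lag, censored = ws.run_timelag_single(
            config, state, max_years=50,
            log_miss=np.zeros((10,) + state.occupied.shape),
        )
        assert (lag, censored) == (50, True)
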