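import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumorgame import (
    FateProbabilities,
    PayoffMatrix,
    SelectionError,
    SimulationConfig,
    apply_necrosis,
    choose_site,
    draw_fates,
    game_increments,
    initialize_world,
    invasion_probability,
    place_offspring,
    proliferation_probability,
    run_simulation,
    step_world,
    move_invader,
)
from tumorgame.world import WorldState


def make_state(L=5, phi=1.0, rho=0.0):
    z = lambda: np.zeros((L, L), dtype=np.int64)
    return WorldState(
        t=0,
        n_prolif=z(),
        n_invasive=z(),
        n_necrotic=z(),
        phi=np.full((L, L), float(phi)),
        rho_ecm=np.full((L, L), float(rho)),
    )


class TestApplyNecrosis:
    def test_starved_grid_cells_all_die(self):
        state = make_state()
        state.n_prolif[2, 2] = 2
        state.n_invasive[2, 2] = 1
        state.phi[2, 2] = 0.01
        out = apply_necrosis(state, phi_c=0.05)
        assert out.n_prolif[2, 2] == 0 and out.n_invasive[2, 2] == 0
        assert out.n_necrotic[2, 2] == 3

    def test_threshold_is_strict(self):
        state = make_state()
        state.n_prolif[1, 1] = 4
        state.phi[1, 1] = 0.05
        out = apply_necrosis(state, phi_c=0.05)
        assert out.n_prolif[1, 1] == 4 and out.n_necrotic[1, 1] == 0

    def test_necrotic_cells_are_absorbing(self):
        state = make_state(phi=0.0)
        state.n_necrotic[3, 3] = 5
        out = apply_necrosis(state, phi_c=0.05)
        assert out.n_necrotic[3, 3] == 5


class TestGameIncrements:
    def test_empty_neighborhood_is_zero(self):
        g = game_increments(0, 0, PayoffMatrix.from_magnitudes(0.5, 0.5))
        assert g.delta_p == 0.0 and g.delta_i == 0.0

    def test_single_invasive_partner_gives_beta_ii(self):
        g = game_increments(0, 1, PayoffMatrix.from_magnitudes(alpha_pp=0.5, beta_ii=0.1))
        assert g.delta_i == pytest.approx(0.1)
        assert g.delta_p == 0.0

    def test_mean_aggregation_hand_value(self):
        payoff = PayoffMatrix(a_pp=-0.1, a_pi=0.0, b_ip=0.0, b_ii=0.1)
        g = game_increments(3, 1, payoff, "mean")
        assert g.delta_p == pytest.approx((3 * -0.1 + 0) / 4)  # -0.075
        assert g.delta_i == pytest.approx((0 + 0.1) / 4)  # 0.025

    def test_sum_aggregation_is_identity(self):
        payoff = PayoffMatrix(a_pp=-0.1, b_ii=0.1)
        g = game_increments(3, 2, payoff, "sum")
        assert g.delta_p == pytest.approx(-0.3) and g.delta_i == pytest.approx(0.2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            game_increments(-1, 0, PayoffMatrix())

    @given(n_p=st.integers(0, 50), n_i=st.integers(0, 50))
    @settings(deadline=None, max_examples=50)
    def test_mean_increments_bounded_by_largest_entry(self, n_p, n_i):
        payoff = PayoffMatrix(a_pp=-0.4, a_pi=0.2, b_ip=-0.1, b_ii=0.3)
        g = game_increments(n_p, n_i, payoff, "mean")
        assert abs(g.delta_p) <= 0.4 + 1e-12
        assert abs(g.delta_i) <= 0.3 + 1e-12


class TestFateProbabilities:
    def test_saturating_forms_at_reference_points(self):
        # phi = N_T * theta puts the argument at 1: 1 - 1/e and 1/e
        assert proliferation_probability(0.6, 2, 0.3) == pytest.approx(1 - math.exp(-1))
        assert invasion_probability(0.6, 2, 0.3) == pytest.approx(math.exp(-1))

    def test_extremes_at_zero_nutrient(self):
        assert proliferation_probability(0.0, 3, 0.3) == 0.0
        assert invasion_probability(0.0, 3, 0.3) == 1.0

    def test_increment_clamping(self):
        assert proliferation_probability(0.6, 1, 0.2, delta_p=0.5) == 1.0
        assert invasion_probability(1.0, 1, 1.0, delta_i=-2.0) == 0.0

    def test_monotone_in_nutrient_and_crowding(self):
        ps = [proliferation_probability(phi, 2, 0.1) for phi in (0.1, 0.3, 0.7)]
        assert ps == sorted(ps)
        qs = [invasion_probability(0.4, n, 0.1) for n in (1, 3, 9)]
        assert qs == sorted(qs)

    @pytest.mark.parametrize("func", [proliferation_probability, invasion_probability])
    def test_invalid_shape_parameter(self, func):
        with pytest.raises(ValueError):
            func(0.5, 1, 0.0)

    def test_normalization_sums_to_one(self):
        p = FateProbabilities.from_raw(0.3, 0.2)
        assert p.normalized and p.p_prolif + p.p_invade == pytest.approx(1.0)

    def test_double_zero_means_hold(self):
        p = FateProbabilities.from_raw(0.0, 0.0)
        assert not p.normalized and p.p_prolif == p.p_invade == 0.0


class TestDrawFates:
    def test_degenerate_probability(self, rng):
        p = FateProbabilities.from_raw(0.0, 0.7)
        assert draw_fates(p, 12, rng) == (0, 12)

    def test_hold_state_draws_nothing(self, rng):
        assert draw_fates(FateProbabilities.from_raw(0.0, 0.0), 9, rng) == (0, 0)

    def test_binomial_concentration(self, rng):
        p = FateProbabilities.from_raw(0.5, 0.5)
        k, m = draw_fates(p, 10000, rng)
        assert k + m == 10000
        assert abs(k / 10000 - 0.5) < 4 * math.sqrt(0.25 / 10000)


class TestChooseSite:
    def test_minimum_count_wins(self, rng):
        assert choose_site([((0, 0), 5, 0.9), ((0, 1), 2, 0.1)], rng) == (0, 1)

    def test_nutrient_breaks_count_ties(self, rng):
        assert choose_site([((0, 0), 3, 0.4), ((0, 1), 3, 0.7)], rng) == (0, 1)

    def test_full_ties_broken_uniformly(self):
        rng = np.random.default_rng(123)
        sites = [(0, 0), (0, 1), (0, 2)]
        cands = [(s, 1, 0.5) for s in sites]
        counts = {s: 0 for s in sites}
        n = 30000
        for _ in range(n):
            counts[choose_site(cands, rng)] += 1
        for s in sites:
            assert abs(counts[s] / n - 1 / 3) < 4 * math.sqrt((1 / 3) * (2 / 3) / n)
        chi2 = sum((c - n / 3) ** 2 / (n / 3) for c in counts.values())
        assert chi2 < 9.21  # chi-square(2) critical value at alpha = 0.01

    def test_empty_candidates_raise(self, rng):
        with pytest.raises(SelectionError):
            choose_site([], rng)

    @given(st.lists(st.tuples(st.integers(0, 20), st.floats(0, 1)), min_size=1, max_size=9),
           st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=60)
    def test_selection_is_lexicographically_optimal(self, entries, seed):
        rng = np.random.default_rng(seed)
        cands = [((0, i), count, phi) for i, (count, phi) in enumerate(entries)]
        chosen = choose_site(cands, rng)
        key = {site: (count, -phi) for site, count, phi in cands}
        assert key[chosen] == min(key.values())


class TestPlacementOps:
    def test_offspring_stays_when_all_neighbors_blocked(self, rng):
        state = make_state(rho=0.8)
        state.rho_ecm[2, 2] = 0.0
        state.n_prolif[2, 2] = 1
        target = place_offspring(state, (2, 2), rng)
        assert target == (2, 2)
        assert state.n_prolif[2, 2] == 2

    def test_offspring_prefers_empty_eligible_neighbor(self, rng):
        state = make_state(rho=0.8)
        state.rho_ecm[2, 2] = 0.0
        state.rho_ecm[1, 2] = 0.0
        state.n_prolif[2, 2] = 3  # current grid crowded
        state.phi[1, 2] = 0.9
        target = place_offspring(state, (2, 2), rng)
        assert target == (1, 2)
        assert state.n_prolif.sum() == 4  # exactly one daughter added

    def test_invader_stays_when_blocked(self, rng):
        state = make_state(rho=0.5)
        state.rho_ecm[2, 2] = 0.0
        state.n_invasive[2, 2] = 1
        assert move_invader(state, (2, 2), rng) == (2, 2)
        assert state.n_invasive[2, 2] == 1

    def test_invader_moves_and_conserves_count(self, rng):
        state = make_state(rho=0.5)
        state.rho_ecm[2, 2] = 0.0
        state.rho_ecm[3, 3] = 0.0
        state.n_invasive[2, 2] = 2
        target = move_invader(state, (2, 2), rng)
        assert target == (3, 3)
        assert state.n_invasive[2, 2] == 1 and state.n_invasive[3, 3] == 1


class TestStepWorld:
    def founder_config(self):
        # theta = 1 puts a lone cell in fully mixed territory:
        # base_p = 1 - 1/e, base_i = 1/e, so p(divide) = 1 - 1/e after normalization
        return SimulationConfig(
            L=5, t_max=1, D=0.0, k=0.0, gamma=0.0, theta_p=1.0, theta_i=1.0,
            phi_c=0.01, payoff=PayoffMatrix(), n_sub=1, seed=0,
        )

    def founder_state(self):
        state = make_state(L=5, phi=1.0, rho=0.0)
        state.n_prolif[2, 2] = 1
        return state

    def test_single_founder_two_outcome_distribution(self):
        """One synchronous step of a lone founder either divides (2 cells) or
        migrates (1 cell); the division frequency over 10000 replicates must
        match the hand-computed normalized probability 1 - 1/e."""
        config = self.founder_config()
        p_divide = (1 - math.exp(-1))
        divisions = 0
        for seed in range(10000):
            rng = np.random.default_rng(seed)
            out = step_world(self.founder_state(), config, rng)
            total = int(out.total_cells().sum())
            assert total in (1, 2)
            if total == 2:
                assert out.n_prolif[2, 2] >= 1  # parent kept its grid
                divisions += 1
            else:
                assert out.n_invasive.sum() == 1  # migrated with invasive label
        freq = divisions / 10000
        assert abs(freq - p_divide) < 4 * math.sqrt(p_divide * (1 - p_divide) / 10000)

    def test_fully_necrotic_state_is_frozen(self):
        config = self.founder_config()
        state = make_state(L=5, phi=1.0, rho=0.3)
        state.n_necrotic[2, 2] = 7
        state.rho_ecm[2, 2] = 0.0
        out = step_world(state, config, np.random.default_rng(0))
        np.testing.assert_array_equal(out.n_necrotic, state.n_necrotic)
        assert out.n_prolif.sum() == 0 and out.n_invasive.sum() == 0

    def test_same_seed_identical_successor(self):
        config = self.founder_config()
        a = step_world(self.founder_state(), config, np.random.default_rng(9))
        b = step_world(self.founder_state(), config, np.random.default_rng(9))
        for f in ("n_prolif", "n_invasive", "n_necrotic", "phi", "rho_ecm"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))


class TestTrajectoryInvariants:
    def test_total_and_necrotic_counts_nondecreasing(self, step_sequence):
        _, states = step_sequence
        totals = [int(s.total_cells().sum()) for s in states]
        necrotics = [int(s.n_necrotic.sum()) for s in states]
        assert totals == sorted(totals)
        assert necrotics == sorted(necrotics)
        assert (np.diff([s.n_necrotic for s in states], axis=0) >= 0).all()

    def test_occupancy_ecm_exclusivity_every_step(self, step_sequence):
        _, states = step_sequence
        for s in states:
            occupied = s.total_cells() > 0
            assert (s.rho_ecm[occupied] == 0.0).all()

    def test_nutrient_bounds_and_boundary_every_step(self, step_sequence):
        _, states = step_sequence
        for s in states[1:]:
            assert s.phi.min() >= 0.0 and s.phi.max() <= 1.0
            assert (s.phi[0, :] == 1.0).all() and (s.phi[:, -1] == 1.0).all()


class TestRunSimulation:
    def test_zero_length_run_returns_initial_state(self):
        result = run_simulation(SimulationConfig(L=21, t_max=0, seed=1))
        assert len(result.records) == 1
        assert result.final_state.t == 0
        assert result.halt_reason == "t_max"

    def test_generous_nutrients_reach_edge_before_t_max(self):
        config = SimulationConfig(L=11, t_max=100, k=0.0, gamma=0.9, seed=4)
        result = run_simulation(config)
        assert result.halted_early and result.halt_reason == "edge_contact"
        assert result.final_state.t < 100

    def test_records_cover_every_cycle(self, smoke_result):
        ts = [r.t for r in smoke_result.records]
        assert ts == list(range(smoke_result.final_state.t + 1))

    def test_snapshots_at_configured_times(self):
        config = SimulationConfig(L=41, t_max=12, snapshot_times=(3, 7), seed=8)
        result = run_simulation(config)
        assert set(result.snapshots) == {3, 7}
        assert result.snapshots[3].t == 3
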