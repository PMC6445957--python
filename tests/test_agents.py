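"""Cell-agent rules: filopodia, sensing, tip selection, movement, Dll4 exchange."""

import numpy as np
import pytest

from angiosprout.agents import (
    DIRECTIONS,
    BehaviorParams,
    ECAgent,
    apply_vegf_exchange,
    choose_move_direction,
    deposit,
    filopodia_step,
    gradient_direction,
    is_tip,
    move_tip,
    neighbor_dll4,
    secrete_svegfr1,
    sense_and_bind,
    sensing_radius,
    sensing_window,
    tip_state,
)
from angiosprout.fields import Field


@pytest.fixture()
def behavior():
    return BehaviorParams(
        a_star=2.0, d_star=40.0, filopodia_ext_rate=0.4, filopodia_ret_rate=0.2,
        filopodia_max=4.0, vegfr2a_setpoint=100.0, p_dev=0.2, move_rate=1.0,
    )


class TestFilopodia:
    def test_no_activity_retracts_strictly(self, behavior):
        length = filopodia_step(1.5, 0.0, behavior, 0.5)
        assert length < 1.5

    def test_saturated_activity_clips_at_max(self, behavior):
        length = filopodia_step(behavior.filopodia_max, 1e6, behavior, 1.0)
        assert length == behavior.filopodia_max

    def test_never_negative(self, behavior):
        assert filopodia_step(0.05, 0.0, behavior, 10.0) == 0.0

    def test_alternating_activity_matches_hand_computation(self, behavior):
        # extend 0.4/h above the setpoint, retract 0.2/h at or below it
        length, dt = 1.0, 0.5
        activities = [200.0, 0.0, 200.0, 200.0, 50.0, 0.0]
        expected = length
        for act in activities:
            expected += (0.4 if act > 100.0 else -0.2) * dt
            expected = min(max(expected, 0.0), 4.0)
            length = filopodia_step(length, act, behavior, dt)
            assert length == pytest.approx(expected)

    def test_sensing_radius_is_one_plus_filopodia(self):
        assert sensing_radius(0.0) == 1
        assert sensing_radius(1.9) == 2
        assert sensing_radius(3.0) == 4

    def test_invalid_behavior_params_rejected(self):
        with pytest.raises(ValueError):
            BehaviorParams(a_star=0.0)
        with pytest.raises(ValueError):
            BehaviorParams(p_dev=0.6)


class TestTipCriteria:
    @pytest.mark.parametrize(
        "v2m,v1m,filo,d4m,expected",
        [
            (10.0, 5.0, 3.0, 41.0, True),   # all three strict criteria hold
            (5.0, 5.0, 3.0, 41.0, False),   # mRNA tie fails the strict test
            (10.0, 5.0, 2.0, 41.0, False),  # filopodia exactly at A*
            (10.0, 5.0, 3.0, 40.0, False),  # dll4 mRNA exactly at D*
            (4.0, 5.0, 3.0, 41.0, False),
            (10.0, 5.0, 1.0, 100.0, False),
        ],
    )
    def test_truth_table(self, behavior, v2m, v1m, filo, d4m, expected):
        assert tip_state(v2m, v1m, d4m, filo, behavior) is expected

    def test_is_tip_reads_agent_state(self, model, behavior):
        s = np.zeros(model.n_species)
        s[model.species_index("vegfr2_mRNA")] = 50.0
        s[model.species_index("vegfr1_mRNA")] = 10.0
        s[model.species_index("dll4_mRNA")] = 90.0
        agent = ECAgent(id=0, row=3, col=3, state=s, filopodia=3.0)
        assert is_tip(agent, behavior, model)
        agent.filopodia = 1.0
        assert not is_tip(agent, behavior, model)


class TestGradient:
    def test_eastward_increase_selects_east(self, rng):
        grid = np.tile(np.arange(9, dtype=float), (9, 1))
        assert gradient_direction(4, 4, 2, grid, rng) == (0, 1)

    def test_uniform_field_gives_none(self, rng):
        grid = np.full((9, 9), 7.0)
        assert gradient_direction(4, 4, 2, grid, rng) is None

    def test_two_equal_maxima_split_evenly(self, rng):
        # symmetric double peak east and west: each should win about half
        grid = np.zeros((9, 9))
        grid[4, 1] = grid[4, 7] = 50.0
        counts = {(0, 1): 0, (0, -1): 0}
        for _ in range(4000):
            d = gradient_direction(4, 4, 3, grid, rng)
            counts[d] += 1
        frac = counts[(0, 1)] / 4000
        assert 0.45 < frac < 0.55


class TestMovement:
    def test_deviation_distribution(self, rng):
        # main direction with probability 1-2p, each 45-degree neighbor with p
        n, p = 10_000, 0.2
        counts = {d: 0 for d in DIRECTIONS}
        for _ in range(n):
            counts[choose_move_direction((0, 1), p, rng)] += 1
        assert counts[(0, 1)] / n == pytest.approx(0.6, abs=0.03)
        assert counts[(-1, 1)] / n == pytest.approx(0.2, abs=0.02)
        assert counts[(1, 1)] / n == pytest.approx(0.2, abs=0.02)

    def test_no_gradient_uniform_over_eight(self, rng):
        counts = {d: 0 for d in DIRECTIONS}
        for _ in range(8000):
            counts[choose_move_direction(None, 0.2, rng)] += 1
        for d in DIRECTIONS:
            assert counts[d] / 8000 == pytest.approx(0.125, abs=0.02)

    def _pair(self):
        tip = ECAgent(id=0, row=5, col=5, state=np.zeros(3), phenotype="tip")
        stalk = ECAgent(id=1, row=5, col=4, state=np.array([1.0, 2.0, 3.0]))
        occupancy = {tip.pos: tip, stalk.pos: stalk}
        return tip, stalk, occupancy

    def test_deterministic_move_spawns_stalk_copy(self, rng):
        tip, stalk, occupancy = self._pair()
        out = move_tip(tip, (0, 1), occupancy, rng, grid_shape=(11, 11), p_dev=0.0)
        assert out.moved
        assert tip.pos == (5, 6)
        assert out.vacated == (5, 5)
        new = occupancy[(5, 5)]
        assert new is not stalk and new.phenotype == "non-tip"
        np.testing.assert_array_equal(new.state, stalk.state)
        new.state[0] = 99.0  # the copy must be independent of the parent
        assert stalk.state[0] == 1.0

    def test_occupied_target_blocks_the_move(self, rng):
        tip, stalk, occupancy = self._pair()
        blocker = ECAgent(id=2, row=5, col=6, state=np.zeros(3))
        occupancy[blocker.pos] = blocker
        out = move_tip(tip, (0, 1), occupancy, rng, grid_shape=(11, 11), p_dev=0.0)
        assert not out.moved
        assert tip.pos == (5, 5)

    def test_no_nontip_neighbor_blocks_the_move(self, rng):
        tip = ECAgent(id=0, row=5, col=5, state=np.zeros(3), phenotype="tip")
        other = ECAgent(id=1, row=5, col=4, state=np.zeros(3), phenotype="tip")
        occupancy = {tip.pos: tip, other.pos: other}
        out = move_tip(tip, (0, 1), occupancy, rng, grid_shape=(11, 11), p_dev=0.0)
        assert not out.moved

    def test_grid_edge_blocks_the_move(self, rng):
        tip = ECAgent(id=0, row=0, col=0, state=np.zeros(3), phenotype="tip")
        stalk = ECAgent(id=1, row=1, col=0, state=np.zeros(3))
        occupancy = {tip.pos: tip, stalk.pos: stalk}
        out = move_tip(tip, (-1, 0), occupancy, rng, grid_shape=(11, 11), p_dev=0.0)
        assert not out.moved


class TestDll4Exchange:
    def test_isolated_agent_receives_nothing(self, model):
        a = ECAgent(id=0, row=5, col=5, state=model.initial_amounts.copy())
        assert neighbor_dll4(a, {a.pos: a}, model, (11, 11)) == 0.0

    def test_single_neighbor_single_contact_full_share(self, model):
        i = model.species_index("dll4")
        a = ECAgent(id=0, row=5, col=5, state=np.zeros(model.n_species))
        b = ECAgent(id=1, row=5, col=6, state=np.zeros(model.n_species))
        b.state[i] = 8.0
        occ = {a.pos: a, b.pos: b}
        assert neighbor_dll4(a, occ, model, (11, 11)) == pytest.approx(8.0)

    def test_three_cell_row_shares_split_by_contacts(self, model):
        # A - B - C in a row: B receives all of A's and C's ligand (each has
        # only B as contact); A receives half of B's (B touches A and C)
        i = model.species_index("dll4")
        agents = []
        for j, col in enumerate((4, 5, 6)):
            ag = ECAgent(id=j, row=5, col=col, state=np.zeros(model.n_species))
            ag.state[i] = 10.0 * (j + 1)
            agents.append(ag)
        occ = {ag.pos: ag for ag in agents}
        a, b, c = agents
        assert neighbor_dll4(b, occ, model, (11, 11)) == pytest.approx(10.0 + 30.0)
        assert neighbor_dll4(a, occ, model, (11, 11)) == pytest.approx(20.0 / 2)
        assert neighbor_dll4(c, occ, model, (11, 11)) == pytest.approx(20.0 / 2)


class TestVegfExchange:
    def test_zero_vegf_in_radius_leaves_field_untouched(self, model, behavior):
        vegf = Field.uniform("vegf", (9, 9), 0.0)
        agent = ECAgent(id=0, row=4, col=4, state=model.initial_amounts.copy())
        sense_and_bind(agent, vegf, model, behavior, 0.5)
        assert vegf.total() == 0.0

    def test_no_free_receptors_leaves_field_untouched(self, model, behavior):
        vegf = Field.uniform("vegf", (9, 9), 30.0)
        s = model.initial_amounts.copy()
        for name in ("mvegfr1", "vegfr2", "mvegfr1_bound", "vegfr2_bound",
                     "vegfr2_active", "vegfr1_mRNA", "vegfr2_mRNA",
                     "svegfr1_internal"):
            s[model.species_index(name)] = 0.0
        agent = ECAgent(id=0, row=4, col=4, state=s)
        before = vegf.total()
        sense_and_bind(agent, vegf, model, behavior, 0.1)
        assert vegf.total() == pytest.approx(before, rel=1e-9)

    def test_field_loss_equals_agent_gain_without_dissociation(self, model, behavior):
        p = model.default_params.copy()
        for name in ("koff_mvegfr1", "koff_vegfr2", "k_deg_mvegfr1_bound",
                     "k_deg_vegfr2_bound"):
            p[model.param_index[name]] = 0.0
        vegf = Field.uniform("vegf", (9, 9), 30.0)
        agent = ECAgent(id=0, row=4, col=4, state=model.initial_amounts.copy(),
                        filopodia=1.0)
        bound_idx = [model.species_index(n) for n in ("mvegfr1_bound", "vegfr2_bound")]
        before_field = vegf.total()
        before_bound = agent.state[bound_idx].sum()
        sense_and_bind(agent, vegf, model, behavior, 0.5, params=p)
        gained = agent.state[bound_idx].sum() - before_bound
        lost = before_field - vegf.total()
        assert lost == pytest.approx(gained, rel=1e-6)

    def test_depletion_capped_by_site_content(self):
        grid = np.zeros((5, 5))
        grid[2, 2] = 4.0
        apply_vegf_exchange(grid, 2, 2, 1, -100.0)
        assert grid.min() >= 0.0
        assert grid.sum() == pytest.approx(0.0)


class TestSecretion:
    def test_empty_pool_deposits_nothing(self, model, behavior):
        sv = Field.uniform("sv", (9, 9), 0.0)
        s = model.initial_amounts.copy()
        s[model.species_index("svegfr1_internal")] = 0.0
        agent = ECAgent(id=0, row=4, col=4, state=s)
        secrete_svegfr1(agent, sv, model, behavior, 1.0)
        assert sv.total() == 0.0

    def test_zero_export_rate_keeps_pool(self, model, behavior):
        p = model.default_params.copy()
        p[model.param_index["k_export"]] = 0.0
        sv = Field.uniform("sv", (9, 9), 0.0)
        agent = ECAgent(id=0, row=4, col=4, state=model.initial_amounts.copy())
        pool = agent.state[model.species_index("svegfr1_internal")]
        secrete_svegfr1(agent, sv, model, behavior, 1.0, params=p)
        assert agent.state[model.species_index("svegfr1_internal")] == pool
        assert sv.total() == 0.0

    def test_internal_loss_equals_field_gain(self, model, behavior):
        sv = Field.uniform("sv", (9, 9), 0.0)
        agent = ECAgent(id=0, row=4, col=4, state=model.initial_amounts.copy())
        i = model.species_index("svegfr1_internal")
        before = agent.state[i]
        secrete_svegfr1(agent, sv, model, behavior, 0.5)
        assert before - agent.state[i] == pytest.approx(sv.total())

    def test_deposit_window_clipped_at_border(self):
        grid = np.zeros((5, 5))
        deposit(grid, 0, 0, 1, 8.0)
        assert grid.sum() == pytest.approx(8.0)
        assert np.count_nonzero(grid) == 4
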