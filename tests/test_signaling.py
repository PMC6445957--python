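"""Intracellular model: Hill laws, mass-action rates, and the Euler integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from angiosprout.signaling import (
    RingSystem,
    SignalingModel,
    TranscriptionParams,
    hill_repression,
    hill_transcription,
)


class TestHillLaws:
    @pytest.mark.parametrize(
        "mod,expected",
        [(0.0, 2.0), (1.0, 6.0), (1e9, pytest.approx(10.0, rel=1e-6))],
    )
    def test_activating_anchor_points(self, mod, expected):
        # basal rate v_max/a, half effect at m0, saturation at v_max
        p = TranscriptionParams(v_max=10.0, a=5.0, m0=1.0)
        assert hill_transcription(mod, p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "mod,expected",
        [(0.0, 10.0), (1.0, 6.0), (1e9, pytest.approx(2.0, rel=1e-6))],
    )
    def test_repressing_anchor_points(self, mod, expected):
        p = TranscriptionParams(v_max=10.0, a=5.0, m0=1.0, mode="repressing")
        assert hill_repression(mod, p) == pytest.approx(expected)

    def test_fold_change_one_is_constitutive(self):
        p = TranscriptionParams(v_max=7.0, a=1.0, m0=3.0)
        for mod in (0.0, 0.5, 3.0, 50.0):
            assert hill_transcription(mod, p) == pytest.approx(7.0)
            assert hill_repression(mod, p) == pytest.approx(7.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        v_max=st.floats(0.1, 1e3),
        a=st.floats(1.0, 100.0),
        m0=st.floats(1e-2, 1e3),
        h=st.floats(0.5, 4.0),
        mods=st.lists(st.floats(0.0, 1e4), min_size=2, max_size=8),
    )
    def test_bounds_and_monotonicity(self, v_max, a, m0, h, mods):
        p = TranscriptionParams(v_max=v_max, a=a, m0=m0, h=h)
        rates = [hill_transcription(m, p) for m in sorted(mods)]
        for r in rates:
            assert v_max / a - 1e-9 <= r <= v_max + 1e-9
        assert all(b >= a_ - 1e-9 for a_, b in zip(rates, rates[1:]))
        rep = [hill_repression(m, p) for m in sorted(mods)]
        assert all(b <= a_ + 1e-9 for a_, b in zip(rep, rep[1:]))

    @pytest.mark.parametrize(
        "kwargs",
        [dict(v_max=1, a=0.5, m0=1), dict(v_max=1, a=2, m0=0.0),
         dict(v_max=1, a=2, m0=1, h=0), dict(v_max=-1, a=2, m0=1)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TranscriptionParams(**kwargs)

    def test_negative_modifier_rejected(self):
        p = TranscriptionParams(v_max=1.0, a=2.0, m0=1.0)
        with pytest.raises(ValueError):
            hill_transcription(-0.1, p)


class TestReactionRates:
    def test_trans_binding_is_mass_action(self, model):
        # kt * notch1 * dll4_nb with kt=0.1, notch1=10, dll4_nb=5 -> 5.0/h
        s = np.zeros(model.n_species)
        s[model.species_index("notch1")] = 10.0
        p = model.default_params.copy()
        p[model.param_index["kt"]] = 0.1
        r = model.reaction_rates(s, dll4_nb=5.0, params=p)
        assert r[model.reaction_ids.index("trans_binding")] == pytest.approx(5.0)

    @pytest.mark.parametrize("zero_species", ["notch1", "dll4"])
    def test_cis_binding_needs_both_reactants(self, model, zero_species):
        s = model.initial_amounts.copy()
        s[model.species_index(zero_species)] = 0.0
        r = model.reaction_rates(s)
        assert r[model.reaction_ids.index("cis_binding")] == 0.0

    def test_state_length_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="variables"):
            model.reaction_rates(np.zeros(model.n_species + 1))

    def test_negative_amounts_rejected(self, model):
        s = model.initial_amounts.copy()
        s[0] = -1.0
        with pytest.raises(ValueError):
            model.reaction_rates(s)

    def test_steady_state_matches_reference_integration(self, model):
        """Isolated cell without VEGF or neighbor ligand: forward Euler lands
        on the same steady state as an independent stiff integrator."""
        T = 600.0
        s = model.initial_amounts.copy()
        for _ in range(int(T / 0.2)):
            s, _ = model.euler_step(s, 0.2)
        sol = solve_ivp(
            lambda t, y: model.rhs(np.maximum(y, 0.0)), (0.0, T),
            model.initial_amounts, method="LSODA", rtol=1e-10, atol=1e-10,
        )
        ref = np.maximum(sol.y[:, -1], 0.0)
        scale = np.maximum(ref, 1e-3 * ref.max())
        assert np.all(np.abs(s - ref) / scale < 1e-3)


class TestEulerStep:
    def test_single_step_of_pure_decay(self, decay):
        # x' = -0.01 x, dt = 1 h: 100 -> 99
        s, _ = decay.euler_step(np.array([100.0]), 1.0)
        assert s[0] == pytest.approx(99.0)

    def test_zero_dt_is_identity(self, model):
        s0 = model.initial_amounts.copy()
        s, fx = model.euler_step(s0, 0.0, dll4_nb=5.0, vegf_local=100.0)
        np.testing.assert_array_equal(s, s0)
        assert fx.vegf_net == 0.0 and fx.dll4_consumed == 0.0

    def test_negative_dt_rejected(self, model):
        with pytest.raises(ValueError):
            model.euler_step(model.initial_amounts, -0.1)

    def test_trajectories_stay_nonnegative(self, model, rng):
        for _ in range(5):
            s = model.initial_amounts * rng.lognormal(0.0, 0.5, model.n_species)
            for _ in range(100):
                s, _ = model.euler_step(s, 0.5, dll4_nb=rng.uniform(0, 200),
                                        vegf_local=rng.uniform(0, 500))
                assert np.all(s >= 0.0)

    def test_convergence_is_first_order(self, birth_death):
        """Halving dt roughly halves the error against a reference solution."""
        T = 10.0
        ref = solve_ivp(lambda t, y: birth_death.rhs(y), (0, T),
                        birth_death.initial_amounts, rtol=1e-11, atol=1e-11).y[:, -1]

        def err(dt):
            s = birth_death.initial_amounts.copy()
            for _ in range(int(round(T / dt))):
                s, _ = birth_death.euler_step(s, dt)
            return np.abs(s - ref).max()

        e1, e2, e3 = err(0.4), err(0.2), err(0.1)
        order21 = np.log2(e1 / e2)
        order32 = np.log2(e2 / e3)
        assert 0.7 < order21 < 1.3
        assert 0.7 < order32 < 1.3

    def test_exchange_fluxes_book_balance(self, model):
        s0 = model.initial_amounts.copy()
        s, fx = model.euler_step(s0, 0.5, dll4_nb=80.0, vegf_local=300.0)
        assert 0.0 <= fx.dll4_consumed <= 80.0
        assert fx.vegf_net >= -300.0
        assert fx.svegfr1_exported >= 0.0

    def test_two_cell_perturbation_diverges_to_opposite_fates(self, model):
        """Symmetric pair plus a 1% notch1 perturbation: lateral inhibition
        amplifies the difference until one cell has VEGFR2 mRNA dominance
        and its neighbor the reverse."""
        ring = RingSystem(model, n=2, seed=0)
        ring.states[0, model.species_index("notch1")] *= 1.01
        ring.run(500.0, dt=0.2)
        v2 = ring.species("vegfr2_mRNA")
        v1 = ring.species("vegfr1_mRNA")
        high = v2 > v1
        assert high.sum() == 1


class TestLateralInhibitionProperties:
    def test_ring_alternates_vegfr2(self, model):
        ring = RingSystem(model, n=6, seed=3, perturb=0.02)
        ring.run(400.0, dt=0.2)
        high = ring.species("vegfr2_mRNA") > ring.species("vegfr1_mRNA")
        assert high.sum() == 3
        assert all(high[i] != high[(i + 1) % 6] for i in range(6))

    def test_kt_zero_abolishes_trans_nicd(self, model):
        p = model.default_params.copy()
        p[model.param_index["kt"]] = 0.0
        s = model.initial_amounts.copy()
        for _ in range(400):
            s, _ = model.euler_step(s, 0.25, dll4_nb=150.0, vegf_local=396.0,
                                    params=p)
        assert s[model.species_index("nicd")] < 1e-6

    def test_ring_of_two_equals_two_cell_fixture(self):
        from angiosprout.modelio import make_fixture

        a = make_fixture("two_cell", {"perturb": 0.01}, seed=5)
        b = make_fixture("ring_n", {"n": 2, "perturb": 0.01}, seed=5)
        np.testing.assert_array_equal(a.states, b.states)
        assert a.neighbors == b.neighbors
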