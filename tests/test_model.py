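"""Circuit model: regulatory input, sigmoid, RHS terms, division, solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gencircuit import model as M
from gencircuit import _fastsim


def make_params(**overrides):
    base = dict(W=np.array([[0.0, -0.02], [-0.02, 0.0]]),
                m=np.array([0.05, 0.03]), h=np.array([-2.5, -2.5]),
                R=np.array([15.0, 25.0]), D_base=np.array([0.1, 0.15]),
                decay=np.log(2.0) / np.array([10.0, 12.0]))
    base.update(overrides)
    return M.GeneCircuitParams(**base)


class TestRegulatoryInput:
    def test_zero_concentrations_return_threshold(self):
        params = make_params()
        u = M.regulatory_input(params, np.zeros(2), 0.0)
        np.testing.assert_array_equal(u, params.h)

    def test_fixed_threshold_value_passes_through(self):
        params = make_params(W=np.zeros((2, 2)), m=np.zeros(2))
        u = M.regulatory_input(params, np.array([3.0, 4.0]), 2.0)
        np.testing.assert_allclose(u, [-2.5, -2.5])

    def test_hand_computed_dot_product(self):
        # W row (1,2) . conc (3,4) + m 0.5 * bcd 2 + h (-1) = 3+8+1-1 = 11
        params = M.GeneCircuitParams(
            W=np.array([[1.0, 2.0], [0.0, 0.0]]), m=np.array([0.5, 0.0]),
            h=np.array([-1.0, 0.0]), R=np.ones(2), D_base=np.zeros(2),
            decay=np.ones(2))
        u = M.regulatory_input(params, np.array([3.0, 4.0]), 2.0)
        assert u[0] == pytest.approx(11.0)

    def test_dimension_mismatch_names_field(self):
        with pytest.raises(M.CircuitError, match="conc_i"):
            M.regulatory_input(make_params(), np.zeros(3), 0.0)


class TestSigmoid:
    def test_midpoint_is_half(self):
        assert M.sigmoid(0.0) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert M.sigmoid(1e12) == pytest.approx(1.0)
        assert M.sigmoid(-1e12) == pytest.approx(0.0)

    def test_closed_form_at_one(self):
        assert M.sigmoid(1.0) == pytest.approx(0.5 * (1 / np.sqrt(2) + 1))

    def test_rejects_non_finite(self):
        with pytest.raises(M.CircuitError):
            M.sigmoid(np.nan)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-1e6, 1e6), st.floats(1e-9, 1e6))
    def test_strictly_increasing_and_bounded(self, u, du):
        lo, hi = M.sigmoid(u), M.sigmoid(u + du)
        assert 0.0 < lo < 1.0 and 0.0 < hi <= 1.0
        assert hi > lo or hi == pytest.approx(lo)  # saturated tails


class TestCircuitRhs:
    def test_uniform_field_in_mitosis_is_pure_decay(self):
        params = make_params()
        conc = np.full((5, 2), 7.0)
        state = M.EmbryoState(conc=conc, bcd=np.ones(5))
        rhs = M.circuit_rhs(state, params, M.MITOSIS)
        np.testing.assert_allclose(rhs, -params.decay * conc)

    def test_exponential_decay_term(self):
        params = make_params(R=np.full(2, 1e-12), D_base=np.zeros(2))
        conc = np.array([[4.0, 2.0]])
        state = M.EmbryoState(conc=conc, bcd=np.zeros(1))
        rhs = M.circuit_rhs(state, params, M.MITOSIS)
        np.testing.assert_allclose(rhs, -params.decay * conc)

    def test_discrete_laplacian_with_zero_flux_ends(self):
        d = 0.2
        params = M.GeneCircuitParams(
            W=np.zeros((1, 1)), m=np.zeros(1), h=np.zeros(1),
            R=np.array([1e-12]), D_base=np.array([d]), decay=np.array([1e-12]))
        state = M.EmbryoState(conc=np.array([[0.0], [1.0], [0.0]]),
                              bcd=np.zeros(3))
        rhs = M.circuit_rhs(state, params, M.MITOSIS)
        np.testing.assert_allclose(rhs.ravel(), [d, -2 * d, d], atol=1e-11)

    def test_production_off_during_mitosis(self):
        params = make_params()
        state = M.EmbryoState(conc=np.full((3, 2), 5.0), bcd=np.ones(3))
        inter = M.circuit_rhs(state, params, M.INTERPHASE)
        mito = M.circuit_rhs(state, params, M.MITOSIS)
        production = inter - mito
        assert np.all(production > 0)  # R * sigmoid > 0
        with pytest.raises(M.CircuitError):
            M.circuit_rhs(state, params, M.DIVISION)


class TestDivision:
    def test_concentrations_copied_and_counter_incremented(self):
        conc = np.arange(6.0).reshape(1, 6)
        state = M.EmbryoState(conc=conc, bcd=np.array([2.0]), n_div=0)
        new = M.apply_division(state)
        assert new.n_nuclei == 2 and new.n_div == 1
        np.testing.assert_array_equal(new.conc[0], conc[0])
        np.testing.assert_array_equal(new.conc[1], conc[0])

    def test_effective_diffusion_quadruples(self):
        params = make_params()
        state = M.EmbryoState(conc=np.ones((2, 2)), bcd=np.ones(2), n_div=0)
        after = M.apply_division(state)
        ratio = (4.0 ** after.n_div) / (4.0 ** state.n_div)
        assert ratio == 4.0

    def test_double_division_quadruples_nuclei_and_mass(self):
        state = M.EmbryoState(conc=np.array([[3.0, 1.0]]), bcd=np.array([1.0]))
        twice = M.apply_division(M.apply_division(state))
        assert twice.n_nuclei == 4 and twice.n_div == 2
        np.testing.assert_allclose(twice.conc.sum(axis=0),
                                   4 * state.conc.sum(axis=0))


class TestIntegrateInterval:
    def test_zero_rhs_keeps_state_constant(self):
        params = make_params(R=np.full(2, 1e-12), D_base=np.zeros(2),
                             decay=np.full(2, 1e-12))
        state = M.EmbryoState(conc=np.array([[5.0, 2.0]]), bcd=np.zeros(1))
        out = M.integrate_interval(state, params, M.MITOSIS, 0.0, 50.0)
        np.testing.assert_allclose(out.conc, state.conc, rtol=1e-6)

    @pytest.mark.parametrize("method", ["bulirsch-stoer", "RK45"])
    def test_decay_matches_closed_form(self, decay_only_params, method):
        state = M.EmbryoState(conc=np.array([[8.0, 3.0]]), bcd=np.zeros(1))
        out = M.integrate_interval(state, decay_only_params, M.MITOSIS,
                                   0.0, 25.0, tol=1e-6, method=method)
        expected = state.conc * np.exp(-decay_only_params.decay * 25.0)
        np.testing.assert_allclose(out.conc, expected, rtol=1e-4)

    def test_halving_tolerance_never_increases_error(self, decay_only_params):
        state = M.EmbryoState(conc=np.array([[8.0, 3.0]]), bcd=np.zeros(1))
        expected = state.conc * np.exp(-decay_only_params.decay * 25.0)
        errs = []
        for tol in (1e-2, 1e-4, 1e-6, 1e-8):
            out = M.integrate_interval(state, decay_only_params, M.MITOSIS,
                                       0.0, 25.0, tol=tol, atol=tol * 1e-3)
            errs.append(np.max(np.abs(out.conc - expected)))
        assert errs == sorted(errs, reverse=True) or errs[-1] < 1e-10

    def test_rejects_reversed_interval(self, decay_only_params):
        state = M.EmbryoState(conc=np.ones((1, 2)), bcd=np.zeros(1))
        with pytest.raises(M.CircuitError):
            M.integrate_interval(state, decay_only_params, M.MITOSIS, 5.0, 5.0)


def two_phase_schedule():
    return M.MitoticSchedule(phases=(
        M.Phase(M.INTERPHASE, 0.0, 16.0), M.Phase(M.MITOSIS, 16.0, 20.0),
        M.Phase(M.DIVISION, 20.0, 20.0), M.Phase(M.INTERPHASE, 20.0, 36.0)))


class TestSimulate:
    def test_half_life_halves_concentration(self, decay_only_params):
        # ln2/decay = 10 min for gene 0: concentration halves every 10 min.
        schedule = M.MitoticSchedule(phases=(M.Phase(M.MITOSIS, 0.0, 30.0),))
        init = M.EmbryoState(conc=np.array([[8.0, 8.0]]), bcd=np.zeros(1))
        traj = M.simulate(decay_only_params, init, schedule, [10.0, 20.0, 30.0],
                          tol=1e-8, atol=1e-10)
        values = np.array([s.conc[0, 0] for s in traj.states])
        np.testing.assert_allclose(values, [4.0, 2.0, 1.0], rtol=1e-5)

    def test_decay_only_matches_closed_form_at_every_output(self, decay_only_params):
        schedule = M.MitoticSchedule(phases=(M.Phase(M.MITOSIS, 0.0, 40.0),))
        init = M.EmbryoState(conc=np.array([[5.0, 9.0]]), bcd=np.zeros(1))
        times = [4.0, 17.5, 33.0]
        traj = M.simulate(decay_only_params, init, schedule, times,
                          tol=1e-7, atol=1e-10)
        for s in traj.states:
            expected = init.conc * np.exp(-decay_only_params.decay * s.time)
            np.testing.assert_allclose(s.conc, expected, rtol=1e-5)

    def test_division_doubles_all_subsequent_outputs(self):
        params = make_params()
        init = M.EmbryoState(conc=np.zeros((4, 2)), bcd=np.linspace(9, 1, 4))
        traj = M.simulate(params, init, two_phase_schedule(), [10.0, 25.0, 36.0])
        assert [s.n_nuclei for s in traj.states] == [4, 8, 8]

    def test_output_at_division_instant_is_post_division(self):
        params = make_params()
        init = M.EmbryoState(conc=np.zeros((2, 2)), bcd=np.array([4.0, 1.0]))
        traj = M.simulate(params, init, two_phase_schedule(), [20.0])
        assert traj.states[0].n_nuclei == 4
        assert traj.states[0].n_div == 1

    def test_bit_identical_on_repeat(self):
        params = make_params()
        init = M.EmbryoState(conc=np.zeros((4, 2)), bcd=np.linspace(9, 1, 4))
        a = M.simulate(params, init, two_phase_schedule(), [10.0, 36.0])
        b = M.simulate(params, init, two_phase_schedule(), [10.0, 36.0])
        for sa, sb in zip(a.states, b.states):
            np.testing.assert_array_equal(sa.conc, sb.conc)

    def test_diffusion_conserves_mass_without_production_or_decay(self):
        params = make_params(R=np.full(2, 1e-12), decay=np.full(2, 1e-12))
        conc0 = np.array([[10.0, 0.0], [0.0, 5.0], [2.0, 2.0], [1.0, 8.0]])
        schedule = M.MitoticSchedule(phases=(M.Phase(M.MITOSIS, 0.0, 30.0),))
        init = M.EmbryoState(conc=conc0, bcd=np.zeros(4))
        traj = M.simulate(params, init, schedule, [30.0], tol=1e-8, atol=1e-10)
        np.testing.assert_allclose(traj.states[0].conc.sum(axis=0),
                                   conc0.sum(axis=0), rtol=1e-6)

    def test_concentrations_stay_non_negative(self):
        params = make_params()
        init = M.EmbryoState(conc=np.zeros((4, 2)), bcd=np.linspace(9, 1, 4))
        traj = M.simulate(params, init, two_phase_schedule(), [10.0, 28.0, 36.0])
        for s in traj.states:
            assert np.all(s.conc >= -1e-6)


class TestFastPath:
    def test_fast_path_matches_reference_simulation(self):
        params = make_params()
        schedule = two_phase_schedule()
        bcd0 = np.linspace(9.0, 1.0, 4)
        bcd_by_epoch = {0: bcd0, 1: np.repeat(bcd0, 2)}
        times = [10.0, 28.0, 36.0]
        init = M.EmbryoState(conc=np.zeros((4, 2)), bcd=bcd0)
        traj = M.simulate(params, init, schedule, times, tol=1e-6, atol=1e-9,
                          bcd_by_epoch=bcd_by_epoch)
        kinds, t0s, t1s, prods, rec_t, rec_nd = _fastsim.build_plan(schedule, times)
        bcd_stack = np.zeros((2, 8))
        bcd_stack[0, :4] = bcd0
        bcd_stack[1] = bcd_by_epoch[1]
        out = np.full((3, 8, 2), np.nan)
        ok = _fastsim.run_plan(params.W, params.m, params.h, params.R,
                               params.D_base, params.decay, np.zeros((4, 2)),
                               bcd_stack, kinds, t0s, t1s, prods,
                               1e-6, 1e-9, out)
        assert ok == 1
        for k, s in enumerate(traj.states):
            np.testing.assert_allclose(out[k, :s.n_nuclei], s.conc,
                                       rtol=1e-4, atol=1e-6)

    def test_bulirsch_stoer_agrees_with_scipy_on_full_circuit(self):
        params = make_params()
        init = M.EmbryoState(conc=np.zeros((4, 2)), bcd=np.linspace(9, 1, 4))
        a = M.integrate_interval(init, params, M.INTERPHASE, 0.0, 16.0,
                                 tol=1e-8, atol=1e-10)
        b = M.integrate_interval(init, params, M.INTERPHASE, 0.0, 16.0,
                                 tol=1e-9, atol=1e-11, method="DOP853")
        np.testing.assert_allclose(a.conc, b.conc, rtol=1e-6)
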