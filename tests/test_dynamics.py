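import numpy as np
import pytest

from pecircuit import (
    ConnectivitySpec,
    ModelParams,
    NetworkState,
    PopulationSpec,
    StimulusPhase,
    assign_preferred_stimuli,
    grouped_input_vector,
    grouped_weight_matrix,
    linear_steady_state,
    run_to_steady_state,
    sample_connectivity,
)
from pecircuit.dynamics import (
    dendritic_calcium,
    dendritic_synaptic_input,
    somatic_synaptic_input,
    total_somatic_current,
)
from pecircuit.stimuli import PhaseInputs, phase_inputs

from conftest import homogenize_all_pathways


def _zero_weights(conn):
    out = conn.copy()
    for w in out.weights.values():
        w[...] = 0.0
    return out


class TestCurrents:
    def test_somatic_input_reduces_to_background_without_weights(self, conn_small):
        conn = _zero_weights(conn_small)
        n = conn.pop.n_pc
        x = np.full(n, 28.0)
        i = somatic_synaptic_input(conn, np.ones(n), np.ones(conn.pop.n_pv),
                                   np.ones(conn.pop.n_nonmartinotti), x)
        np.testing.assert_allclose(i, 28.0)

    def test_somatic_input_arithmetic(self, conn_small):
        conn = _zero_weights(conn_small)
        conn.weights["EP"][0, 0] = 2.0
        r_p = np.zeros(conn.pop.n_pv)
        r_p[0] = 3.0
        i = somatic_synaptic_input(
            conn, np.zeros(conn.pop.n_pc), r_p,
            np.zeros(conn.pop.n_nonmartinotti), np.full(conn.pop.n_pc, 28.0),
        )
        assert i[0] == pytest.approx(28.0 - 6.0)

    def test_somatic_recurrence_is_linear_in_rates(self, conn_small):
        n = conn_small.pop.n_pc
        x = np.zeros(n)
        r = np.abs(np.random.default_rng(0).normal(size=n))
        r_p = np.zeros(conn_small.pop.n_pv)
        r_nm = np.zeros(conn_small.pop.n_nonmartinotti)
        one = somatic_synaptic_input(conn_small, r, r_p, r_nm, x)
        two = somatic_synaptic_input(conn_small, 2 * r, r_p, r_nm, x)
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    def test_dendritic_input_and_branch_validation(self, conn_small):
        r_e = np.ones(conn_small.pop.n_pc)
        r_m = np.zeros(conn_small.pop.n_martinotti)
        x = np.zeros(conn_small.pop.n_pc)
        i = dendritic_synaptic_input(conn_small, 0, r_e, r_m, x)
        np.testing.assert_allclose(i, conn_small.weights["D1E"].sum(axis=1))
        with pytest.raises(ValueError, match="branch"):
            dendritic_synaptic_input(conn_small, 5, r_e, r_m, x)

    def test_strong_martinotti_inhibition_makes_input_negative(self, conn_small):
        r_e = np.zeros(conn_small.pop.n_pc)
        r_m = np.full(conn_small.pop.n_martinotti, 50.0)
        i = dendritic_synaptic_input(conn_small, 0, r_e, r_m,
                                     np.full(conn_small.pop.n_pc, 1.0))
        assert (i[conn_small.masks["D1M"].any(axis=1)] < 0).any()

    def test_calcium_threshold_strict(self, params):
        assert dendritic_calcium(np.array([30.0]), params)[0] == 7.0
        assert dendritic_calcium(np.array([0.0]), params)[0] == 0.0
        # exactly at threshold: H(0) = 0, no event
        assert dendritic_calcium(np.array([28.0]), params)[0] == 0.0

    def test_total_somatic_current(self, params):
        i = total_somatic_current(
            np.array([10.0]), np.array([[20.0]]), np.array([[0.0]]), params
        )
        assert i[0] == pytest.approx(0.69 * 10 + 0.27 * 20)
        # negative dendritic brackets are rectified away
        i = total_somatic_current(
            np.array([10.0]), np.array([[-5.0]]), np.array([[0.0]]), params
        )
        assert i[0] == pytest.approx(0.69 * 10)
        # two identical branches contribute twice one branch's term
        i2 = total_somatic_current(
            np.array([10.0]), np.array([[20.0], [20.0]]), np.zeros((2, 1)), params
        )
        assert i2[0] == pytest.approx(0.69 * 10 + 2 * 0.27 * 20)


class TestSteadyState:
    def test_isolated_cell_fixed_point(self, params):
        """Closed form: with constant current I and no recurrence, r* = I - Theta."""
        pop = PopulationSpec(n_pc=4, n_pv=2, n_som=2, n_vip=2, n_groups=1,
                             martinotti_fraction=0.5)
        conn = _zero_weights(sample_connectivity(pop, ConnectivitySpec(), seed=0))
        target_current = 20.0
        inputs = PhaseInputs(
            x_e=np.full(4, target_current / (1 - params.lambda_e)),
            x_d=np.zeros((1, 4)),
            x_p=np.zeros(2), x_s=np.zeros(2), x_v=np.zeros(2),
        )
        for method in ("euler", "relax"):
            steady = run_to_steady_state(conn, inputs, params, method=method)
            np.testing.assert_allclose(steady.r_e, target_current - 14.0, atol=1e-4)

    def test_zero_drive_decays_to_silence(self, params, conn_small):
        conn = _zero_weights(conn_small)
        pop = conn.pop
        inputs = PhaseInputs(
            x_e=np.zeros(pop.n_pc), x_d=np.zeros((1, pop.n_pc)),
            x_p=np.zeros(pop.n_pv), x_s=np.zeros(pop.n_som), x_v=np.zeros(pop.n_vip),
        )
        init = NetworkState(
            h_e=np.full(pop.n_pc, 14.0), h_p=np.zeros(pop.n_pv),
            h_s=np.zeros(pop.n_som), h_v=np.zeros(pop.n_vip),
        )
        steady = run_to_steady_state(conn, inputs, params, init=init)
        np.testing.assert_allclose(steady.r_e, 0.0, atol=1e-6)

    def test_rates_nonnegative_and_converged(self, conn_small, bank_small, params):
        phase = StimulusPhase(P=[0.0], S=[1.0])
        steady = run_to_steady_state(conn_small, phase, params, bank_small)
        assert steady.converged
        for r in (steady.r_e, steady.r_p, steady.r_s, steady.r_v):
            assert (r >= 0).all()

    def test_independent_of_initial_condition(self, conn_small, bank_small, params, rng):
        phase = StimulusPhase(P=[0.0], S=[0.0])
        a = run_to_steady_state(conn_small, phase, params, bank_small)
        init = NetworkState(
            h_e=rng.normal(0, 5, conn_small.pop.n_pc),
            h_p=rng.normal(0, 5, conn_small.pop.n_pv),
            h_s=rng.normal(0, 5, conn_small.pop.n_som),
            h_v=rng.normal(0, 5, conn_small.pop.n_vip),
        )
        b = run_to_steady_state(conn_small, phase, params, bank_small, init=init)
        np.testing.assert_allclose(a.r_e, b.r_e, atol=1e-6)

    def test_euler_agrees_with_relaxation(self, conn_small, bank_small, params):
        phase = StimulusPhase(P=[0.0], S=[0.0], duration=1.0)
        relax = run_to_steady_state(conn_small, phase, params, bank_small)
        euler = run_to_steady_state(conn_small, phase, params, bank_small,
                                    method="euler")
        assert euler.converged
        np.testing.assert_allclose(euler.r_e, relax.r_e, atol=1e-3)

    def test_euler_step_consistency(self, conn_small, bank_small):
        """Halving dt changes the converged steady state only marginally."""
        phase = StimulusPhase(P=[0.0], S=[0.0], duration=0.6)
        coarse = run_to_steady_state(conn_small, phase, ModelParams(dt=2e-4),
                                     bank_small, method="euler")
        fine = run_to_steady_state(conn_small, phase, ModelParams(dt=1e-4),
                                   bank_small, method="euler")
        assert np.max(np.abs(coarse.r_e - fine.r_e)) < 1e-3

    def test_steady_state_zeroes_the_drive(self, conn_small, bank_small, params):
        """At the fixed point -h + drive = 0 componentwise."""
        phase = StimulusPhase(P=[0.0], S=[2.0])
        steady = run_to_steady_state(conn_small, phase, params, bank_small,
                                     relax_tol=1e-11)
        assert steady.residual < 1e-10


class TestLinearSteadyState:
    def test_scalar_inversion(self):
        # 1x1 case: W = [w - 1], r = s / (1 - w)
        w, s = 0.42, 5.0
        r = linear_steady_state(np.array([[w - 1.0]]), np.array([s]))
        assert r[0] == pytest.approx(s / (1 - w))

    def test_zero_input_gives_zero(self):
        w = np.array([[-1.0, 0.2], [0.1, -1.0]])
        np.testing.assert_allclose(linear_steady_state(w, np.zeros(2)), 0.0)

    def test_singular_matrix_rejected(self):
        with pytest.raises(np.linalg.LinAlgError, match="cond"):
            linear_steady_state(np.array([[0.0, 0.0], [0.0, -1.0]]), np.ones(2))

    def test_oracle_equivalence_with_simulator(self, params):
        """On a group-homogeneous linear-regime network (calcium off, all
        rectifiers interior) the full simulator equals the grouped linear
        solver to <= 1e-6 relative error."""
        pop = PopulationSpec(n_pc=40, n_pv=8, n_som=20, n_vip=8, n_groups=1,
                             martinotti_fraction=0.7)
        conn = homogenize_all_pathways(
            sample_connectivity(pop, ConnectivitySpec(), seed=1)
        )
        # exact homogeneity requires every neuron to have afferents on every pathway
        assert all(m.sum(axis=1).min() > 0 for m in conn.masks.values())
        bank = assign_preferred_stimuli(pop, feature_space=((0.0,),))
        lin_params = params.with_(c_amp=0.0)
        phase = StimulusPhase(P=[0.0], S=[0.0])
        steady = run_to_steady_state(conn, phase, lin_params, bank, relax_tol=1e-12)
        # interior regime: every rate positive, every dendritic bracket positive
        assert (steady.r_e > 0).all() and (steady.r_p > 0).all()
        assert (steady.r_s > 0).all() and (steady.r_v > 0).all()
        assert (steady.i_d_syn > 0).all()

        grouped = grouped_weight_matrix(conn, pop, lin_params, bank.som_groups)
        inputs = phase_inputs(phase, bank, lin_params, pop)
        s_vec = grouped_input_vector(inputs, pop, lin_params, bank.som_groups)
        z = linear_steady_state(grouped.matrix, s_vec)
        sim = np.array([
            steady.r_e.mean(),               # E0
            steady.dendritic_activity[0].mean(),  # D1:0
            steady.r_p.mean(),               # P
            steady.r_s[pop.martinotti_mask].mean(),
            steady.r_s[~pop.martinotti_mask].mean(),
            steady.r_v.mean(),
        ])
        np.testing.assert_allclose(z, sim, rtol=1e-6)
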