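"""Reaction-diffusion model: normalization, Euler stepping, diffusion kernel,
closed-form steady states and the documented wild-type dynamic behaviours."""

import dataclasses

import numpy as np
import pytest

from gapswitch.core import C_MAX, GAP_GENES, AxisGrid, GradientSet
from gapswitch.dynamics import (ConfigError, DegenerateCueError, ModelParams,
                                Trajectory, diffuse, euler_step, normalizers,
                                run_simulation, synthesis_field)


class TestModelParams:
    def test_coupled_rate_convention(self):
        p = ModelParams.coupled(0.1, K=0.05)
        assert p.alpha == pytest.approx(0.1 * C_MAX)
        assert p.beta == pytest.approx(0.1)

    def test_node_specific_affinities_default_to_global(self):
        p = ModelParams(K=0.05)
        assert p.hb_rep_array.K == p.K
        assert p.kr_rep_array.K == p.K
        p2 = ModelParams(K=0.05, K1=0.3, K2=0.7)
        assert p2.hb_rep_array.K == 0.3
        assert p2.kr_rep_array.K == 0.7

    def test_validation(self):
        with pytest.raises(ConfigError):
            ModelParams(K=-1.0)
        with pytest.raises(ConfigError):
            ModelParams(K=0.05, D=-1.0)
        with pytest.raises(ConfigError):
            ModelParams(K=0.05, disabled_links=frozenset({"Foo->Bar"}))


class TestNormalizers:
    def test_unit_peak_after_normalization(self, wt_inputs, ref_params):
        """max_x omega_A * P_A(x, 0) = 1 for every gap gene."""
        from gapswitch.dynamics import _Context, _initial_state
        omega = normalizers(wt_inputs, ref_params)
        ctx = _Context(wt_inputs, ref_params)
        pot0 = ctx.potentials(_initial_state(wt_inputs))
        for i, gene in enumerate(("Hb", "Kr", "Kni", "Gt")):
            assert omega[gene] * pot0[i].max() == pytest.approx(1.0, rel=1e-12)

    def test_synthesis_peaks_at_alpha(self, wt_inputs, ref_params):
        """After normalization the t=0 synthesis field peaks at alpha."""
        omega = normalizers(wt_inputs, ref_params)
        params = ref_params.with_omega(omega)
        state0 = GradientSet({"Hb": wt_inputs["Hb_mat"],
                              "Kr": np.zeros(100), "Kni": np.zeros(100),
                              "Gt": np.zeros(100)}, grid=wt_inputs.grid)
        for gene in GAP_GENES:
            field = synthesis_field(state0, wt_inputs, params, gene)
            assert field.max() == pytest.approx(params.alpha, rel=1e-12)
            assert np.all(field >= 0)

    def test_degenerate_cue_raises(self, wt_inputs, ref_params):
        """Zeroed Bcd input makes Hb unactivatable at t=0."""
        broken = wt_inputs.copy()
        broken.set("Bcd", np.zeros(100))
        broken.set("Tll", np.zeros(100))
        with pytest.raises(DegenerateCueError):
            normalizers(broken, ref_params)

    def test_unknown_gene_in_synthesis_field(self, wt_inputs, ref_params_norm):
        state0 = GradientSet({g: np.zeros(100) for g in GAP_GENES},
                             grid=wt_inputs.grid)
        with pytest.raises(KeyError):
            synthesis_field(state0, wt_inputs, ref_params_norm, "Eve")


class TestDiffuse:
    def test_zero_diffusion_is_identity(self):
        v = np.random.default_rng(0).random(100)
        np.testing.assert_array_equal(diffuse(v, 0.0, 2.2, 5.0), v)

    def test_uniform_profile_unchanged(self):
        v = np.full(100, 7.0)
        np.testing.assert_allclose(diffuse(v, 20.0, 2.2, 5.0), v)

    def test_delta_spike_matches_heat_kernel(self):
        """An interior delta relaxes to the analytic Gaussian of standard
        deviation sqrt(2 D dt) expressed in grid units."""
        n = 100
        v = np.zeros(n)
        v[50] = 1.0
        D, dt, dx = 22.727, 2.2, 5.0
        sigma = np.sqrt(2 * D * dt) / dx
        out = diffuse(v, D, dt, dx)
        k = np.arange(n) - 50
        analytic = np.exp(-k**2 / (2 * sigma**2)) / (np.sqrt(2 * np.pi) * sigma)
        np.testing.assert_allclose(out, analytic, atol=1e-4)

    def test_mass_conserved(self):
        v = np.random.default_rng(3).random(100) * 50
        assert diffuse(v, 30.0, 2.2, 5.0).sum() == pytest.approx(v.sum())


class TestEulerStep:
    def test_pure_decay_example(self, wt_inputs, ref_params_norm):
        """With synthesis suppressed, A=10, beta=0.1, dt=2.2 gives 7.8."""
        params = dataclasses.replace(
            ref_params_norm, beta=0.1, D=0.0,
            null_genes=frozenset(GAP_GENES))
        state = GradientSet({g: np.full(100, 10.0) for g in GAP_GENES},
                            grid=wt_inputs.grid)
        out = euler_step(state, wt_inputs, params, dt=2.2)
        for gene in GAP_GENES:
            np.testing.assert_allclose(out[gene], 7.8)

    def test_stability_guard(self, wt_inputs, ref_params_norm):
        params = dataclasses.replace(ref_params_norm, beta=0.5)
        state = GradientSet({g: np.zeros(100) for g in GAP_GENES},
                            grid=wt_inputs.grid)
        with pytest.raises(ConfigError):
            euler_step(state, wt_inputs, params, dt=2.2)

    def test_geometric_convergence_to_fixed_point(self, wt_inputs, ref_params):
        """With constant synthesis and D=0 the linear recursion converges to
        S/beta with ratio (1 - beta dt) per step."""
        beta, dt = ref_params.beta, 2.2
        S = 1.0
        target = S / beta
        a = 0.0
        errors = [abs(a - target)]
        for _ in range(5):
            a = a + dt * (S - beta * a)
            errors.append(abs(a - target))
        for e0, e1 in zip(errors, errors[1:]):
            assert e1 / e0 == pytest.approx(1 - beta * dt, rel=1e-12)


class TestRunSimulation:
    def test_trajectory_shape_and_invariants(self, wt_trajectory):
        traj = wt_trajectory
        assert len(traj.states) == 41
        assert np.all(np.diff(traj.times) > 0)
        for state in traj.states:
            for gene in GAP_GENES:
                v = state[gene]
                assert np.all(np.isfinite(v))
                assert np.all(v >= 0) and np.all(v <= C_MAX)

    def test_initial_condition(self, wt_inputs, wt_trajectory):
        np.testing.assert_array_equal(wt_trajectory.initial["Hb"],
                                      wt_inputs["Hb_mat"])
        for gene in ("Kr", "Kni", "Gt"):
            assert np.all(wt_trajectory.initial[gene] == 0)

    def test_inputs_untouched(self, wt_inputs, ref_params):
        before = {g: wt_inputs[g].copy() for g in wt_inputs.genes}
        run_simulation(wt_inputs, ref_params, n_steps=5)
        for g, v in before.items():
            np.testing.assert_array_equal(wt_inputs[g], v)

    def test_missing_input_gene(self, wt_inputs, ref_params):
        partial = GradientSet({"Bcd": wt_inputs["Bcd"]}, grid=wt_inputs.grid)
        with pytest.raises(KeyError):
            run_simulation(partial, ref_params)

    def test_unrepressed_steady_state_matches_closed_form(
            self, wt_inputs, ref_params):
        """With the four mutual-repression links removed and D=0, every gene
        relaxes to the fixed point alpha*omega*P_cue/beta (clipped at C_max),
        evaluated self-consistently at the steady state."""
        toggles = frozenset({"Kni-|Hb", "Hb-|Kni", "Gt-|Kr", "Kr-|Gt"})
        params = dataclasses.replace(ref_params, D=0.0, disabled_links=toggles)
        params = params.with_omega(normalizers(wt_inputs, params))
        traj = run_simulation(wt_inputs, params, n_steps=3000)
        final = traj.final
        for gene in GAP_GENES:
            field = synthesis_field(final, wt_inputs, params, gene)
            closed = np.minimum(field / params.beta, C_MAX)
            np.testing.assert_allclose(final[gene], closed, atol=0.02)

    def test_kni_stripe_shifts_anteriorly(self, wt_trajectory):
        """The simulated wild-type Kni stripe moves anteriorly between
        one-third of the run and the final state."""
        early = wt_trajectory.at_fraction(1 / 3)
        final = wt_trajectory.final
        assert np.argmax(final["Kni"]) < np.argmax(early["Kni"])

    def test_double_bcd_shifts_kr_kni_posteriorly(self, wt_inputs,
                                                  ref_params_norm,
                                                  wt_trajectory):
        """Doubling the Bcd amplitude moves the final Kr and Kni peaks
        posteriorly relative to wild type."""
        boosted = wt_inputs.copy()
        boosted.set("Bcd", 2.0 * wt_inputs["Bcd"])
        traj4x = run_simulation(boosted, ref_params_norm)
        for gene in ("Kr", "Kni"):
            assert (np.argmax(traj4x.final[gene])
                    > np.argmax(wt_trajectory.final[gene]))

    def test_trajectory_export_tidy(self, wt_trajectory):
        frame = wt_trajectory.to_frame()
        assert list(frame.columns) == ["time", "gene", "x_percent_el", "conc_nM"]
        assert len(frame) == 41 * 4 * 100


class TestTrajectory:
    def test_times_must_increase(self):
        gs = GradientSet({g: np.zeros(100) for g in GAP_GENES})
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.0]), [gs, gs])
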