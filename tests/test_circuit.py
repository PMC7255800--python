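"""Unit and property tests for the trial-by-trial circuit model."""

import numpy as np
import pytest
from scipy.optimize import brentq

from pursuitcircuit import (
    CircuitState,
    ModelParams,
    TrialSpec,
    TrialType,
    cs_probability,
    ftn_input_tuning,
    ftn_output,
    internal_error,
    pc_rate,
    pf_rates,
    run_session,
    step_trial,
    update_ftn_weights,
    update_pf_weights,
)
from pursuitcircuit.workbench import clamp_specs, learning_block_specs


def probe(speed=20.0):
    return TrialSpec(TrialType.PROBE, 0.0, speed)


def learning(speed=20.0, instruction=30.0):
    return TrialSpec(TrialType.LEARNING, 0.0, speed, instruction, 90.0)


class TestPrimitives:
    @pytest.mark.parametrize(
        "speed,r,expected",
        [(20.0, 1.0, (20.0, -20.0)), (0.0, 1.0, (0.0, 0.0)), (15.0, 2.0, (30.0, -30.0))],
    )
    def test_pf_rates_linear_and_opponent(self, speed, r, expected):
        params = ModelParams(r=r)
        assert pf_rates(speed, params) == expected

    def test_pf_rates_rejects_negative_speed(self, re_params):
        with pytest.raises(ValueError):
            pf_rates(-1.0, re_params)

    def test_pc_rate_cancels_at_baseline(self, re_params):
        state = CircuitState.initial(re_params)
        assert pc_rate(state, 20.0, re_params) == re_params.pc0

    def test_pc_rate_hand_evaluation(self, re_params):
        state = CircuitState(w=(0.55, 1.0), v=(0.0,) * re_params.n_inputs)
        # 0.55*20 - 1.0*20 + 50 = 41
        assert pc_rate(state, 20.0, re_params) == pytest.approx(41.0, abs=1e-12)

    def test_pc_rate_zero_speed_gives_background(self, re_params):
        state = CircuitState(w=(0.3, 1.7), v=(0.0,) * re_params.n_inputs)
        assert pc_rate(state, 0.0, re_params) == re_params.pc0

    def test_cs_probability_values(self, re_params):
        # saturates at 30% for large errors; zero at zero error
        assert cs_probability(1e6, re_params) == pytest.approx(0.3, abs=1e-12)
        assert cs_probability(0.0, re_params) == 0.0
        expected = 0.6 / (1.0 + np.exp(-0.21 * 30.0)) - 0.3
        assert cs_probability(30.0, re_params) == pytest.approx(expected, abs=1e-15)
        assert cs_probability(30.0, re_params) == pytest.approx(0.2989, abs=5e-5)

    def test_cs_probability_monotone_and_clamped(self, re_params):
        errors = np.linspace(-50, 50, 101)
        probs = [cs_probability(e, re_params) for e in errors]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert all(p == 0.0 for e, p in zip(errors, probs) if e <= 0)

    def test_update_pf_weights_depression_and_decay(self):
        params = ModelParams()  # alpha_pf=0.85, beta=1.5, w0=1
        state = CircuitState(w=(1.0, 1.0), v=(0.0,) * params.n_inputs)
        w1, w2 = update_pf_weights(state, (20.0, -20.0), 0.3, params)
        assert w1 == pytest.approx(0.55, abs=1e-12)  # 1 - 1.5*0.3
        assert w2 == pytest.approx(1.0, abs=1e-12)   # negative PF: decay only

    def test_update_pf_weights_decay_only_branch(self):
        params = ModelParams()
        state = CircuitState(w=(0.55, 1.0), v=(0.0,) * params.n_inputs)
        w1, _ = update_pf_weights(state, (20.0, -20.0), 0.0, params)
        assert w1 == pytest.approx(0.6175, abs=1e-12)  # 0.55 - 0.15*(0.55-1)

    def test_update_pf_weights_baseline_fixed_point(self, re_params):
        state = CircuitState.initial(re_params)
        assert update_pf_weights(state, (20.0, -20.0), 0.0, re_params) == \
            (re_params.w0, re_params.w0)

    def test_ftn_tuning_peak_and_antipreferred(self, re_params):
        tuning = ftn_input_tuning(0.0, re_params.pref_speeds[4], re_params)
        i = 4
        expected = np.cos(np.deg2rad(re_params.pref_dirs[i]))
        assert tuning[i] == pytest.approx(expected, abs=1e-12)
        assert np.all(np.abs(tuning) <= 1.0)

    def test_ftn_tuning_one_sigma_falloff(self):
        params = ModelParams(n_inputs=1, pref_speeds=(10.0,), pref_dirs=(0.0,))
        tuning = ftn_input_tuning(0.0, 10.0 + params.sigma, params)
        assert tuning[0] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_ftn_output_single_site_reduction(self, re_params):
        state = CircuitState.initial(re_params)
        in_vec = np.zeros(re_params.n_inputs)
        assert ftn_output(state, -9.0, in_vec) == 9.0
        assert ftn_output(state, 0.0, in_vec) == 0.0

    def test_ftn_output_dot_product(self):
        params = ModelParams(n_inputs=2, pref_speeds=(0.0, 10.0), pref_dirs=(0.0, 180.0))
        state = CircuitState(w=(1.0, 1.0), v=(0.5, 0.0))
        assert ftn_output(state, 0.0, np.array([1.0, -1.0])) == 0.5

    def test_ftn_output_rejects_length_mismatch(self, re_params):
        state = CircuitState.initial(re_params)
        with pytest.raises(ValueError):
            ftn_output(state, 0.0, np.zeros(re_params.n_inputs + 1))

    def test_update_ftn_weights_hebbian(self):
        params = ModelParams(n_inputs=1, pref_speeds=(10.0,), pref_dirs=(0.0,),
                             eta=7e-4)
        state = CircuitState(w=(1.0, 1.0), v=(0.0,))
        v = update_ftn_weights(state, -9.0, np.array([1.0]), params)
        assert v[0] == pytest.approx(6.3e-3, abs=1e-15)

    def test_update_ftn_weights_no_teaching_without_pc_modulation(self, re_params):
        state = CircuitState.initial(re_params)
        in_vec = ftn_input_tuning(0.0, 20.0, re_params)
        assert update_ftn_weights(state, 0.0, in_vec, re_params) == state.v
        # and with eta = 0 transfer is disabled entirely
        off = re_params.with_(eta=0.0)
        assert update_ftn_weights(state, -9.0, in_vec, off) == state.v

    def test_internal_error_values(self):
        params = ModelParams(gamma=62.0)
        c = params.c
        assert internal_error(30.0, 0.0, 20.0, params) == 30.0
        # 30 - 5 - 62*5/20 = 9.5
        assert internal_error(30.0, 5.0 / c, 20.0, params) == pytest.approx(9.5, abs=1e-12)
        no_fb = ModelParams(gamma=0.0)
        assert internal_error(30.0, 5.0 / c, 20.0, no_fb) == pytest.approx(25.0, abs=1e-12)

    def test_internal_error_guards_zero_speed(self):
        params = ModelParams(gamma=62.0)
        with pytest.raises(ValueError):
            internal_error(30.0, 5.0 / params.c, 0.0, params)


class TestTrialSpecValidation:
    def test_instruction_only_on_learning_trials(self):
        with pytest.raises(ValueError):
            TrialSpec(TrialType.PROBE, 0.0, 20.0, instruction_speed=30.0)

    def test_learning_requires_positive_pursuit(self):
        with pytest.raises(ValueError):
            TrialSpec(TrialType.LEARNING, 0.0, 0.0, 30.0)

    def test_unknown_trial_type_rejected(self):
        with pytest.raises(ValueError):
            TrialSpec("mystery", 0.0, 20.0)


class TestTrialEngine:
    def test_single_trial_learning_chain(self, single_site):
        """Learning then probe from baseline matches the hand-chained scalar
        oracle: probe response = c * beta * P(CS|I) * r * speed."""
        state = CircuitState.initial(single_site)
        state, first = step_trial(state, learning(20.0, 30.0), single_site)
        assert first.learned_response == 0.0
        _, res = step_trial(state, probe(20.0), single_site)
        p = 0.6 / (1.0 + np.exp(-0.21 * 30.0)) - 0.3
        expected = 0.0625 * 1.5 * p * 1.0 * 20.0
        assert res.learned_response == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.5604, abs=5e-4)

    def test_result_internal_consistency(self, re_params):
        state = CircuitState.initial(re_params)
        for spec in learning_block_specs(30, 20.0, 30.0):
            state, res = step_trial(state, spec, re_params)
            assert res.ftn_total == pytest.approx(
                res.ftn_input_component - res.pc_component, rel=1e-12, abs=1e-12
            )
            assert res.learned_response == pytest.approx(
                re_params.c * res.ftn_total, rel=1e-12, abs=1e-12
            )
            assert 0.0 <= res.p_cs <= 0.3

    def test_error_clamp_decays_by_alpha(self, single_site):
        state = CircuitState.initial(single_site)
        for spec in learning_block_specs(5, 20.0, 30.0):
            state, _ = step_trial(state, spec, single_site)
        clamp = TrialSpec(TrialType.ERROR_CLAMP, 0.0, 20.0)
        state, r1 = step_trial(state, clamp, single_site)
        _, r2 = step_trial(state, clamp, single_site)
        assert r2.learned_response == pytest.approx(
            single_site.alpha_pf * r1.learned_response, rel=1e-12
        )
        assert r1.internal_error == 0.0 and r1.p_cs == 0.0

    def test_probe_from_baseline_is_zero(self, re_params):
        state = CircuitState.initial(re_params)
        _, res = step_trial(state, probe(20.0), re_params)
        assert res.learned_response == 0.0

    def test_stochastic_mode_requires_rng_and_matches_expectation(self, single_site):
        state = CircuitState.initial(single_site)
        with pytest.raises(ValueError):
            step_trial(state, learning(), single_site, mode="stochastic")
        # mean stochastic single-trial update equals the expected-mode update
        rng = np.random.default_rng(0)
        _, det = step_trial(*[state, learning()], single_site)
        deltas = []
        for _ in range(4000):
            new, _ = step_trial(state, learning(), single_site,
                                mode="stochastic", rng=rng)
            deltas.append(1.0 - new.w[0])
        expected_delta = single_site.beta * det.p_cs
        sem = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert np.mean(deltas) == pytest.approx(expected_delta, abs=4 * sem)

    def test_unknown_mode_rejected(self, re_params):
        state = CircuitState.initial(re_params)
        with pytest.raises(ValueError):
            step_trial(state, probe(), re_params, mode="nope")


class TestRunSession:
    def test_fixed_point_of_learning_block(self, single_site):
        """The 100-trial tail matches the root of the learning/forgetting
        balance equation (1-alpha)*dw = beta*P(CS | I - c*r*speed*dw)."""
        p = single_site
        series, _ = run_session(learning_block_specs(400, 20.0, 30.0), p)

        def balance(dw):
            y = p.c * p.r * 20.0 * dw
            return (1 - p.alpha_pf) * dw - p.beta * cs_probability(30.0 - y, p)

        dw_star = brentq(balance, 0.0, 10.0, xtol=1e-14)
        y_star = p.c * p.r * 20.0 * dw_star
        assert series.learned_responses[-1] == pytest.approx(y_star, abs=1e-9)

    def test_clamp_phase_geometric(self, single_site):
        specs = learning_block_specs(20, 20.0, 30.0) + clamp_specs(10, 20.0)
        series, _ = run_session(specs, single_site)
        clamp = series.of_type("error_clamp")["learned_response"].to_numpy()
        ratios = clamp[1:] / clamp[:-1]
        assert np.allclose(ratios, single_site.alpha_pf, rtol=1e-12)

    def test_non_learning_session_stays_at_zero(self, re_params):
        specs = [probe(15.0)] * 5 + [TrialSpec(TrialType.BASELINE, 0.0, 20.0)] * 5
        series, _ = run_session(specs, re_params)
        assert np.all(series.learned_responses == 0.0)

    def test_empty_session_rejected(self, re_params):
        with pytest.raises(ValueError):
            run_session([], re_params)

    def test_stochastic_session_is_seed_reproducible(self, re_params):
        specs = learning_block_specs(50, 20.0, 30.0)
        s1, _ = run_session(specs, re_params, mode="stochastic", rng_seed=42)
        s2, _ = run_session(specs, re_params, mode="stochastic", rng_seed=42)
        assert np.array_equal(s1.learned_responses, s2.learned_responses)


class TestCircuitInvariants:
    def test_single_site_reduction_is_exact(self, single_site):
        """With eta = gamma = 0 and v = 0, the full machinery equals a
        scalar transcription of the fast-plasticity recursion bitwise."""
        specs = learning_block_specs(60, 20.0, 25.0) + clamp_specs(5, 20.0)
        series, _ = run_session(specs, single_site)

        p = single_site
        w1, w2 = p.w0, p.w0
        expected = []
        for spec in specs:
            pf1, pf2 = p.r * spec.pursuit_speed, -p.r * spec.pursuit_speed
            pc_comp = (w1 * pf1 + w2 * pf2 + p.pc0) - p.pc0
            ftn = 0.0 - pc_comp
            y = p.c * ftn
            expected.append(y)
            if spec.trial_type == TrialType.LEARNING:
                e = spec.instruction_speed - p.c * ftn
                pcs = max(0.0, 0.6 / (1.0 + np.exp(-p.tau * e)) - 0.3)
            else:
                pcs = 0.0
            w1 = w1 - (1 - p.alpha_pf) * (w1 - p.w0) - (p.beta * pcs if pf1 > 0 else 0)
            w2 = w2 - (1 - p.alpha_pf) * (w2 - p.w0) - (p.beta * pcs if pf2 > 0 else 0)
        assert list(series.learned_responses) == expected

    def test_expression_linear_in_probe_speed(self, single_site):
        state = CircuitState.initial(single_site)
        for spec in learning_block_specs(7, 20.0, 30.0):
            state, _ = step_trial(state, spec, single_site)
        speeds = np.array([5.0, 10.0, 15.0, 20.0])
        responses = np.array(
            [step_trial(state, probe(s), single_site)[1].learned_response
             for s in speeds]
        )
        gains = responses / speeds
        assert np.allclose(gains, gains[0], rtol=1e-12)

    def test_acquisition_independent_of_learning_speed(self, single_site):
        """The complex-spike depression is gated by PF sign, not magnitude:
        the single-trial weight change is identical at 5-20 deg/s."""
        deltas = []
        for speed in (5.0, 10.0, 15.0, 20.0):
            state = CircuitState.initial(single_site)
            new, _ = step_trial(state, learning(speed, 30.0), single_site)
            deltas.append(single_site.w0 - new.w[0])
        assert np.allclose(deltas, deltas[0], rtol=1e-15)

    def test_retention_fit_recovers_alpha_pf(self, single_site):
        from pursuitcircuit import fit_retention

        specs = learning_block_specs(20, 20.0, 30.0) + clamp_specs(10, 20.0)
        series, _ = run_session(specs, single_site)
        clamp = series.of_type("error_clamp")["learned_response"].to_numpy()
        fit = fit_retention(clamp[1:], clamp[0])
        assert fit.params["retention"] == pytest.approx(
            single_site.alpha_pf, abs=1e-9
        )

    def test_full_model_asymptote_below_instruction_and_linear(self, re_params):
        from pursuitcircuit import fit_linear
        from pursuitcircuit.analysis import asymptotic_learning

        instructions = [5.0, 10.0, 15.0, 20.0, 25.0, 30.0]
        full_asym, site_asym = [], []
        for instr in instructions:
            f, _ = run_session(learning_block_specs(100, 20.0, instr), re_params)
            s, _ = run_session(
                learning_block_specs(100, 20.0, instr), re_params.single_site()
            )
            full_asym.append(asymptotic_learning(f))
            site_asym.append(asymptotic_learning(s))
        assert all(a < i for a, i in zip(full_asym, instructions))
        r2_full = fit_linear(instructions, full_asym).r2
        r2_site = fit_linear(instructions, site_asym).r2
        assert r2_full > r2_site

    def test_memory_transfers_from_pc_to_ftn_inputs(self, re_params):
        series, _ = run_session(
            learning_block_specs(1000, 20.0, 30.0), re_params
        )
        d = series.data
        ftn_in = d["ftn_input_component"].to_numpy()[1:]  # trial 0 is all-zero
        pc_contrib = -d["pc_component"].to_numpy()[1:]
        frac = ftn_in / (ftn_in + pc_contrib)
        assert np.all(np.diff(frac[50:]) >= -1e-12)
        peak = pc_contrib.argmax()
        assert peak < 100
        assert pc_contrib[-1] < 0.1 * pc_contrib[peak]

    def test_late_generalization_flattens_for_slow_learning_speed(self, re_params):
        """Early in an interleaved session the probe response scales with
        probe speed; late it is largely speed-independent when learning used
        the slowest speed, and increasing when learning used the fastest."""
        from pursuitcircuit.paradigms import ParadigmConfig, make_generalization_session

        late_profiles = {}
        for learn_speed in (5.0, 20.0):
            cfg = ParadigmConfig(
                paradigm="long_generalization", pursuit_speeds=(learn_speed,),
                instruction_speeds=(30.0,), probe_speed_set=(5.0, 10.0, 15.0, 20.0),
                n_pairs=1000, rng_seed=11, allowed_dirs=(0.0, 180.0),
            )
            series, _ = run_session(
                make_generalization_session(cfg), re_params
            )
            probes = series.of_type("probe")
            early = probes.iloc[:100].groupby("pursuit_speed")["learned_response"].mean()
            late = probes.iloc[-200:].groupby("pursuit_speed")["learned_response"].mean()
            late_profiles[learn_speed] = late.to_numpy()
            if learn_speed == 5.0:
                ev = early.to_numpy()
                assert ev.std() / ev.mean() > 0.3  # early: scales with speed
        flat = late_profiles[5.0]
        assert flat.std() / flat.mean() < 0.15  # late: largely identical
        rising = late_profiles[20.0]
        assert np.all(np.diff(rising) > 0)  # increasing below 20 deg/s
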