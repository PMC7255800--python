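# pursuitcircuit

A trial-by-trial model of the cerebellar circuit that learns smooth-pursuit
eye-movement direction, together with the behavioral paradigms, analysis
statistics, synthetic-data generators, and alternative state-space models
needed to study it end to end.

## The scientific problem

When a pursuit target abruptly acquires an orthogonal velocity component (an
"instruction") partway through a trial, primates learn within a single trial
to anticipate the direction change: on the next trial the eye already moves
in the learning direction ~250 ms after motion onset. This learned response

* saturates as a sigmoid of the single-trial error, yet becomes **linear**
  in instruction magnitude after 100 repeated learning trials;
* is forgotten at ~15% per trial early in learning (retention 0.85 in
  error-clamp trials) but is retained almost perfectly (≈0.95) after 1000
  trials;
* generalizes linearly with pursuit speed after one trial, but becomes
  largely speed-independent late in long learning sessions.

No single learning process reproduces this set of observations. The package
implements a circuit-level account with three interacting mechanisms,
expressed as a per-trial update model:

1. **Fast plasticity** at the parallel-fiber → Purkinje-cell (PF→PC)
   synapse.  Two opponent PFs fire linearly with pursuit eye speed,
   `PF¹ = rĖ, PF² = −rĖ`; the PC rate is `PCₙ = wₙ¹PF¹ + wₙ²PF² + PC₀`.
   A complex spike (probability
   `P(CS|Eₙ) = 0.6/(1+e^(−τEₙ)) − 0.3`, saturating at 30%) depresses the
   active PF weight by β, and learned weight changes decay back to baseline
   with per-trial retention α_PF = 0.85.
2. **Slow transfer** to floccular target neurons (FTNs) in the vestibular
   nucleus.  FTN output is `FTNₙ = Σᵢ vᵢ·INᵢ − (PCₙ − PC₀)` with
   speed-tuned, direction-selective input axons
   `INᵢ = cos(θₑ−θᵢ)·exp(−(Ė−sᵢ)²/2σ²)`.  The PC's learned modulation acts
   as a Hebbian teacher, `vᵢ ← vᵢ + η(PC₀−PCₙ)INᵢ`, with no forgetting
   term — this site is the long-term store.
3. **Recurrent inhibition** of the inferior olive: the internal error that
   drives climbing-fiber responses is
   `Eₙ = Iₙ − cFTNₙ − γ·cFTNₙ/Ė`, so accumulated learning suppresses its
   own teaching signal.  This limits asymptotic learning and linearizes the
   asymptote-vs-instruction curve.

The single-plasticity-site model is the special case η = γ = 0; the
rejected alternatives (a single state-space learner with retention α, and a
fast/slow two-process learner) are implemented in
`pursuitcircuit.alternatives` to demonstrate that both inherit the
single-trial sigmoid and therefore fail to linearize asymptotic learning.

## Worked example

```python
from pursuitcircuit import MONKEY_RE, run_session, fit_retention, asymptotic_learning
from pursuitcircuit.workbench import learning_block_specs, clamp_specs

params = MONKEY_RE   # fitted slope tau=0.21, transfer eta=7.15e-4, inhibition gamma=62.2
specs = learning_block_specs(n_trials=100, pursuit_speed=20.0, instruction_speed=30.0)
series, _ = run_session(specs, params, mode="expected")
print(f"learned response, trial 1:   {series.learned_responses[0]:.3f} deg/s")
print(f"learned response, trial 10:  {series.learned_responses[9]:.3f} deg/s")
print(f"asymptote (trials 76-100):   {asymptotic_learning(series):.3f} deg/s")

single_site = params.single_site()
specs = learning_block_specs(20, 20.0, 30.0) + clamp_specs(10, 20.0)
series, _ = run_session(specs, single_site)
clamp = series.of_type("error_clamp")["learned_response"].to_numpy()
fit = fit_retention(clamp[1:], clamp[0])
print(f"error-clamp retention:       {fit.params['retention']:.3f} per trial")
```

prints

```
learned response, trial 1:   0.000 deg/s
learned response, trial 10:  2.946 deg/s
asymptote (trials 76-100):   5.186 deg/s
error-clamp retention:       0.850 per trial
```

The first trial expresses nothing (expression precedes acquisition within a
trial); learning accumulates to a ~5.2 deg/s asymptote for a 30 deg/s
instruction — well short of full compensation, because recurrent inhibition
throttles the error signal — and the error-clamp decay of the single-site
model recovers the 0.85 retention constant exactly.

A `pursuitcircuit` command-line tool wraps the same machinery
(`simulate`, `synth`, `analyze`, `fit`, `reproduce`); see
`pursuitcircuit --help`.

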