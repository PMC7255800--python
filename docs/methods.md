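# Methods

## Model

The model advances in discrete trials; there is no within-trial dynamics.
Each trial carries a pursuit direction (cardinal), a pursuit speed Ė
(deg/s), and — on learning trials — an orthogonal instruction of magnitude
I (deg/s). Eye speed is identified with target speed (tracking gain 1)
everywhere Ė appears, and the learned response is one-dimensional: the eye
velocity component along the learning direction at the time the instruction
would occur.

Within a trial the order of events is **express → error → fast update →
slow update**. The learned response is read out from the pre-update state,
because the behavioral measurement window (225–275 ms after motion onset)
closes before any instruction-driven visual feedback can move the eye.
Plastic updates then apply in sequence:

* Fast site (PF→PC): both weights relax toward baseline,
  `wⁱ ← wⁱ − (1−α_PF)(wⁱ−w₀)`, and the weight of the PF with positive
  firing is additionally depressed by `β·P(CS|Eₙ)` (expected mode) or by β
  when a Bernoulli complex spike is drawn (stochastic mode). The depression
  is gated by the *sign* of PF firing only — this is what makes single-trial
  acquisition independent of pursuit speed in the learning trial, while
  expression remains proportional to probe speed.
* Negative internal errors produce no complex spikes (the probability is
  clamped at zero): only instructions in the direction that drives complex
  spikes are modeled, and un-learning happens solely through the α_PF
  relaxation. For the same reason washout trials extinguish the fast
  memory through decay but leave the slow store untouched.
* Slow site (FTN inputs): `vᵢ ← vᵢ + η(PC₀−PCₙ)INᵢ` on every trial with
  nonzero PC modulation, including probe and error-clamp trials, because
  the teacher is the Purkinje cell's learned modulation, not the error. A
  flag (`transfer_on_all_trials=False`) restricts transfer to learning
  trials for sensitivity analyses; the default is active everywhere.
* Error-clamp trials force the internal error to zero (the target is yoked
  to the eye) while the α_PF relaxation still applies, isolating intrinsic
  forgetting.

## Parameters

| name | default | units | role |
|------|---------|-------|------|
| r | 1 | Hz per deg/s | PF gain; pure scaling |
| w₀ | 1 | — | baseline PF→PC weight |
| α_PF | 0.85 | per trial | fast-site retention; 15%/trial forgetting |
| β | 1.5 | — | PF depression per complex spike |
| c | 0.0625 | deg/s per Hz | FTN-rate → eye-velocity gain |
| σ | 7.5 | deg/s | width of FTN-input speed tuning |
| τ | 0.21 (RE), 0.118 (YO) | per deg/s | CS-probability sigmoid slope, fitted per animal |
| η | 7.15·10⁻⁴ (RE), 6.95·10⁻⁴ (YO) | — | PC→FTN teaching rate (CI midpoints) |
| γ | 62.2 (RE), 51.9 (YO) | — | recurrent-inhibition gain (CI midpoints) |
| PC₀ | 50 | Hz | background PC rate; cancels in every baseline-subtracted quantity |

r, w₀, β, c only set the mapping from firing rates to deg/s; the
behaviorally meaningful constants are α_PF, τ, η, γ, σ. The 50 FTN input
axons alternate preferred directions 0°/180° and tile preferred speeds
evenly on [0, 50] deg/s. Only the fitted point values of η and γ are
needed; since the joint fit is published as confidence intervals, the
interval midpoints are the package defaults.

The modeled axon axis is 0°/180°. The preferred directions of the FTN
input population are defined relative to the session's pursuit axis
("equal or opposite to pursuit"), so accumulating-learning sessions are
simulated on the 0°/180° axis without loss of generality; a session on the
90°/270° axis would engage an equivalent population that the
two-PF/one-axis model does not carry. Paradigm generators accept
`allowed_dirs` for this purpose, and the dual-trial design (which
randomizes directions precisely so that learning cannot accumulate) is
simulated with a circuit-state reset before each learning/probe pair —
the trial-granular expression of that independence.

## Analyses

* **Learned response**: mean unmasked learning-direction velocity in the
  225–275 ms window; a fully masked window flags the trial as missing.
* **Saccade removal**: samples where 2-D eye speed > 20 deg/s *and* 2-D
  acceleration > 1250 deg/s² are masked, each contiguous run padded by
  10 ms on both sides. Thresholds apply to absolute eye motion (not
  residual from target).
* **Single-trial sigmoid**: `Y(E) = a/(1+e^(−τE)) − a/2`, least squares
  with 5 fixed multi-starts inside a ∈ (0, 5], τ ∈ (0, 1] (the amplitude
  bound can be widened for multi-deg/s asymptote curves). Case-resampling
  bootstrap (refits started from the point estimate) gives 95% intervals.
* **Retention**: clamp responses are normalized and fitted as `y_k = λᵏ`
  (no offset — the data are normalized to the last fully learned state, so
  the curve must pass through 1 at k = 0). In the model's trial order the
  first clamp trial expresses the final learned state before any error-free
  forgetting; it therefore serves as the "trial 0" normalizer and the
  remaining clamp trials as the decay, which makes the fitted λ equal α_PF
  to machine precision in the single-site model.
* **AIC**: Gaussian, additive constant dropped: `n·ln(RSS/n) + 2k`.
  Comparisons are only made between fits of the same data.
* **Expression ratio**: per learning→probe pair, either the probe response
  normalized by the mean probe response at the pair's learning speed
  (single-trial generalization convention) or by the response expressed in
  the preceding learning trial (long-session convention); zero and
  undefined denominators are excluded and counted.
* **(η, γ) fit**: bounded Nelder–Mead over η ∈ [0, 0.01], γ ∈ [0, 200]
  with 5 seeded restarts on a pooled per-trial SSE between observed
  learning-block trial-courses and expected-mode simulations; η is scaled
  by 10⁻⁴ inside the simplex so both parameters move on comparable
  footing. Bootstrap resamples whole sessions within each instruction
  magnitude.

## Synthetic data

The generator produces what the analyses assume and nothing more:

* Trial series: the circuit in stochastic mode (Bernoulli complex spikes)
  plus additive Gaussian measurement noise on the learned response
  (default SD 0.3 deg/s, a stand-in chosen to give realistic-looking
  trial-to-trial scatter; the true behavioral noise magnitude is not
  normative here).
* Traces: 1 kHz velocity with raised-cosine transitions — pursuit ramp
  after a 100 ms latency, anticipatory learned response rising from
  200 ms to hold its value through the measurement window, a visually
  driven component 100 ms after the 250 ms instruction on learning trials,
  and Poisson-count saccade transients (30 ms, 40 deg/s peak, ≥100 ms
  apart) that exceed both detection thresholds. Only the
  measurement-window mean is contractual; the transition shapes are
  cosmetic.

What passing tests on synthetic data do **not** show: anything about
oculomotor latencies, saccade kinematics, or noise spectra of real eye
traces; the generator has no pursuit-gain variability, no blinks, and its
saccades are stereotyped. The synthetic route validates the *pipeline*
(estimators recover what generated the data), not the biology.

## Numerical conventions

* Expected-update mode is the default for fitting and quantitative
  targets (the behavioral quantities being modeled are across-experiment
  averages); stochastic mode is for data synthesis.
* Fixed points of the alternative models are found by bisection on
  Y ∈ [0, I] (the printed closed forms contain the asymptotic error
  implicitly); simulations agree with the roots to < 10⁻⁶ deg/s.
* The γ feedback term divides by pursuit speed; learning trials therefore
  require Ė > 0, which every paradigm satisfies. Zero-speed non-learning
  trials are legal and express nothing.
* Seeds: every stochastic path takes an explicit seed; paradigm
  generation, synthesis, and stochastic simulation are bit-reproducible
  given it.

## Problem sizes

Reproduction targets run at the scale of the behavioral designs: 20
learning + 10 clamp trials for retention, 100-trial blocks for asymptotes
(six instruction magnitudes for the linearity regression), 50 deterministic
dual-trial pairs for expression ratios, and 400 synthetic trials per error
magnitude (seven magnitudes) for sigmoid recovery — a few sessions' worth
of data per magnitude, matching typical session counts of 750–1500 pairs.
Parameter-recovery coverage checks use 50 seeded replicates with reduced
per-replicate sizes (40 trials per magnitude, 60 bootstrap resamples);
(η, γ) recovery uses 60-trial blocks at two magnitudes.

## Known limitations

* Washout extinguishes only the fast site; no plasticity rule is modeled
  for un-learning the slow store, so long washout phases leave residual
  FTN-input memory. This mirrors the model's scope, not a claim about the
  animal.
* The model is one learning axis at a time; interactions between
  interleaved learning directions are out of scope.
* Potentiation at the fast site exists only as relaxation toward baseline;
  instructions opposite the depressing direction are not modeled.
* The retention constant measured after very long learning reflects the
  mixture of sites, not a fitted per-site constant; the package measures
  it the same way the analyses do (exponential fit to clamp decays).
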