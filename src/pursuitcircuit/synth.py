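"""Synthetic behavioral data with the statistical structure the analyses
assume.

Two levels of synthesis are provided.  ``synth_series`` wraps the circuit
model in stochastic mode (Bernoulli complex spikes) and adds Gaussian
measurement noise to per-trial learned responses.  ``synth_trace`` renders
a single trial as a 1 kHz eye-velocity trace: a pursuit-direction ramp, a
learning-direction anticipatory response rising ahead of the measurement
window, a visually driven component after the instruction on learning
trials, Poisson-count saccade artifacts that exceed both detection
thresholds, and per-sample Gaussian noise.

Trace shapes use raised-cosine transitions; only the mean over the
225-275 ms measurement window is contractual (it equals the requested
learned response when noise is disabled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import TrialSpec, TrialType, run_session
from .analysis import EyeTrace, LEARNED_RESPONSE_WINDOW_MS
from .params import ModelParams
from .series import BehavioralSeries

__all__ = ["NoiseModel", "synth_series", "synth_trace", "synth_single_trial_dataset"]


@dataclass(frozen=True)
class NoiseModel:
    """Noise and timing parameters of the synthetic data generator.

    ``response_sd`` is the trial-to-trial Gaussian noise on the learned
    response (deg/s); ``trace_sd`` the per-sample velocity noise;
    ``saccade_rate`` the expected number of injected saccades per trial.
    Latencies (ms): pursuit onset ~100 ms after target motion, the
    anticipatory learned response beginning ~200 ms, and the visually
    driven reaction to the instruction ~100 ms after the 250 ms
    instruction time.
    """

    response_sd: float = 0.3
    trace_sd: float = 0.0
    saccade_rate: float = 0.0
    pursuit_onset_latency: float = 100.0
    learned_onset: float = 200.0
    visual_response_latency: float = 100.0

    def __post_init__(self) -> None:
        if self.response_sd < 0 or self.trace_sd < 0 or self.saccade_rate < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if min(self.pursuit_onset_latency, self.learned_onset,
               self.visual_response_latency) < 0:
            raise ValueError("latencies must be >= 0")


def synth_series(
    specs: list[TrialSpec],
    params: ModelParams,
    noise: NoiseModel,
    seed: int,
    mode: str = "stochastic",
    reset_each_pair: bool = False,
    subject: str = "synthetic",
    paradigm: str = "",
) -> BehavioralSeries:
    """Simulate a session (stochastic mode by default) and add measurement
    noise to the per-trial learned responses.

    With ``reset_each_pair=True`` each consecutive (learning, probe) pair
    is simulated from a reset circuit state, emulating the randomized
    pursuit/instruction directions of the dual-trial design that prevent
    learning from accumulating across pairs.  Bit-reproducible given the
    seed; with ``mode='expected'`` and zero noise the output equals the
    deterministic session exactly.
    """
    circuit_seed, noise_seed = np.random.SeedSequence(seed).spawn(2)
    noise_rng = np.random.default_rng(noise_seed)
    if reset_each_pair:
        if len(specs) % 2 != 0:
            raise ValueError("pairwise reset requires an even number of trials")
        frames = []
        for k in range(0, len(specs), 2):
            sub_seed = int(circuit_seed.generate_state(1)[0] + k) % (2**31)
            part, _ = run_session(
                specs[k : k + 2], params, mode=mode, rng_seed=sub_seed
            )
            frame = part.data.copy()
            frame["trial_index"] += k
            frames.append(frame)
        data = pd.concat(frames, ignore_index=True)
    else:
        series, _ = run_session(
            specs, params, mode=mode,
            rng_seed=int(circuit_seed.generate_state(1)[0]) % (2**31),
        )
        data = series.data.copy()
    if noise.response_sd > 0:
        data["learned_response"] = data["learned_response"].to_numpy() + \
            noise_rng.normal(0.0, noise.response_sd, size=len(data))
    return BehavioralSeries(
        data=data, subject=subject, paradigm=paradigm, seed=seed,
        meta={"mode": mode, "response_sd": noise.response_sd},
    )


def _raised_cosine(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Smooth 0->1 transition between t0 and t1 (ms)."""
    if t1 <= t0:
        return (t >= t0).astype(float)
    x = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def synth_trace(
    spec: TrialSpec,
    learned_response: float,
    noise: NoiseModel,
    seed: int,
    duration_ms: float = 850.0,
    sample_rate: float = 1000.0,
) -> EyeTrace:
    """Render one trial as an eye-velocity trace.

    The learning-direction velocity rises with a raised cosine from
    ``learned_onset`` and holds ``learned_response`` throughout the
    225-275 ms measurement window; on learning trials a visually driven
    component toward the instruction velocity starts
    ``visual_response_latency`` after the 250 ms instruction.  Saccades are
    injected as brief high-velocity transients (count drawn Poisson with
    mean ``saccade_rate``) engineered to exceed both detection thresholds.
    """
    if not np.isfinite(learned_response):
        raise ValueError("learned_response must be finite")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_ms, 1000.0 / sample_rate)

    onset = noise.pursuit_onset_latency
    v_p = spec.pursuit_speed * _raised_cosine(t, onset, onset + 80.0)

    win_lo, _ = LEARNED_RESPONSE_WINDOW_MS
    v_l = learned_response * _raised_cosine(t, noise.learned_onset, win_lo)
    if TrialType(spec.trial_type) is TrialType.LEARNING and spec.instruction_speed > 0:
        visual_onset = 250.0 + noise.visual_response_latency
        v_l = v_l + (spec.instruction_speed - learned_response) * _raised_cosine(
            t, visual_onset, visual_onset + 120.0
        )

    n_saccades = rng.poisson(noise.saccade_rate)
    centers: list[float] = []
    while len(centers) < n_saccades:
        # saccades are separated by a >= 100 ms inter-saccadic interval
        center = rng.uniform(60.0, duration_ms - 60.0)
        if all(abs(center - c) >= 100.0 for c in centers):
            centers.append(center)
    for center in centers:
        # 30 ms transient, 40 deg/s peak: exceeds both detection thresholds
        width = 30.0
        lo, hi = center - width / 2, center + width / 2
        bump = 40.0 * _raised_cosine(t, lo, center) * (1 - _raised_cosine(t, center, hi))
        v_l = v_l + bump

    if noise.trace_sd > 0:
        v_p = v_p + rng.normal(0.0, noise.trace_sd, size=len(t))
        v_l = v_l + rng.normal(0.0, noise.trace_sd, size=len(t))

    return EyeTrace(t=t, v_pursuit=v_p, v_learning=v_l, sample_rate=sample_rate)


def synth_single_trial_dataset(
    a: float,
    tau: float,
    error_magnitudes,
    n_per_magnitude: int,
    response_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic single-trial learning data for parameter-recovery tests.

    Responses are drawn as the saturating sigmoid mean
    ``a/(1+exp(-tau*E)) - a/2`` plus Gaussian noise.
    """
    if n_per_magnitude < 1:
        raise ValueError("n_per_magnitude must be >= 1")
    rng = np.random.default_rng(seed)
    errors = np.repeat(np.asarray(error_magnitudes, dtype=float), n_per_magnitude)
    mean = a / (1.0 + np.exp(-tau * errors)) - a / 2.0
    responses = mean + rng.normal(0.0, response_sd, size=len(errors))
    return errors, responses
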