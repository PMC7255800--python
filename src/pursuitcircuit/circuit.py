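"""Trial-by-trial cerebellar circuit model of pursuit direction learning.

The circuit couples three mechanisms:

1. **Fast plasticity** at the parallel-fiber (PF) to Purkinje-cell (PC)
   synapse.  Two PFs with opposite preferred directions fire linearly with
   eye speed in the pursuit direction; complex spikes depress the weight of
   the PF that fired, and learned weight changes relax back to baseline at
   rate ``1 - alpha_pf`` per trial.
2. **Slow Hebbian transfer** at the non-Purkinje inputs to floccular target
   neurons (FTNs).  The learned modulation of the PC acts as a teaching
   signal that potentiates speed- and direction-tuned FTN input axons; this
   site has no forgetting term, so its memory is effectively permanent.
3. **Recurrent inhibition** of the inferior olive: the circuit output
   subtracts from the physical error, attenuating the complex-spike teaching
   signal as learning accumulates and linearizing asymptotic learning.

The single-plasticity-site model is the special case ``eta = gamma = 0``
with all FTN input weights zero.

Within a trial the order of events mirrors the behavioral measurement: the
learned response is read out *before* the instruction arrives, so expression
always uses the pre-update state, then the error, complex-spike probability
and weight updates follow.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .params import ModelParams
from .series import BehavioralSeries

__all__ = [
    "TrialType",
    "TrialSpec",
    "TrialResult",
    "CircuitState",
    "CS_PROBABILITY_CEILING",
    "pf_rates",
    "pc_rate",
    "cs_probability",
    "update_pf_weights",
    "ftn_input_tuning",
    "ftn_output",
    "update_ftn_weights",
    "internal_error",
    "step_trial",
    "run_session",
]

#: The complex-spike probability saturates at 30% for large errors.
CS_PROBABILITY_CEILING = 0.3

CARDINAL_DIRS = (0.0, 90.0, 180.0, 270.0)


class TrialType(str, enum.Enum):
    BASELINE = "baseline"
    LEARNING = "learning"
    PROBE = "probe"
    ERROR_CLAMP = "error_clamp"
    WASHOUT = "washout"


@dataclass(frozen=True)
class TrialSpec:
    """Stimulus description of one trial.

    ``instruction_dir`` is the orthogonal instruction direction relative to
    the pursuit direction (+90 or -90 deg); it is ignored on trials without
    an instruction.
    """

    trial_type: TrialType
    pursuit_dir: float = 0.0
    pursuit_speed: float = 20.0
    instruction_speed: float = 0.0
    instruction_dir: float = 90.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trial_type", TrialType(self.trial_type))
        if self.pursuit_dir not in CARDINAL_DIRS:
            raise ValueError(f"pursuit_dir must be one of {CARDINAL_DIRS}")
        if self.pursuit_speed < 0:
            raise ValueError("pursuit_speed must be >= 0")
        if self.instruction_speed < 0:
            raise ValueError("instruction_speed must be >= 0")
        if self.trial_type is not TrialType.LEARNING and self.instruction_speed != 0:
            raise ValueError("instruction_speed must be 0 on non-learning trials")
        if self.trial_type is TrialType.LEARNING and self.pursuit_speed <= 0:
            raise ValueError("learning trials require pursuit_speed > 0")
        if self.instruction_dir not in (90.0, -90.0):
            raise ValueError("instruction_dir must be +90 or -90 deg")


@dataclass(frozen=True)
class TrialResult:
    """Per-trial model outputs.

    ``learned_response`` (deg/s) is the readout before any within-trial
    plasticity; ``internal_error`` is the olivary error after recurrent
    inhibition; ``physical_error`` is instruction minus learned response.
    ``pc_component`` is the learned PC modulation (PC_n - PC0, Hz) and
    ``ftn_input_component`` the weighted sum of FTN input axons (Hz).
    """

    learned_response: float
    internal_error: float
    physical_error: float
    p_cs: float
    pc_component: float
    ftn_input_component: float
    ftn_total: float


@dataclass(frozen=True)
class CircuitState:
    """Mutable-by-replacement per-trial state: PF and FTN-input weights."""

    w: tuple[float, float]
    v: tuple[float, ...]
    trial_index: int = 0

    @classmethod
    def initial(cls, params: ModelParams) -> "CircuitState":
        return cls(w=(params.w0, params.w0), v=(0.0,) * params.n_inputs)

    @property
    def v_array(self) -> np.ndarray:
        cached = getattr(self, "_v_array", None)
        if cached is None:
            cached = np.asarray(self.v, dtype=float)
            object.__setattr__(self, "_v_array", cached)
        return cached


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def pf_rates(pursuit_speed: float, params: ModelParams) -> tuple[float, float]:
    """Firing of the two parallel fibers, linear in pursuit eye speed.

    The two PFs have opposite preferred directions, so with equal weights
    their weighted sum cancels and the PC does not modulate with pursuit.
    """
    if pursuit_speed < 0:
        raise ValueError("pursuit_speed must be >= 0")
    rate = params.r * pursuit_speed
    return (rate, -rate)


def pc_rate(state: CircuitState, pursuit_speed: float, params: ModelParams) -> float:
    """Purkinje-cell rate: weighted PF contributions plus background PC0."""
    pf1, pf2 = pf_rates(pursuit_speed, params)
    w1, w2 = state.w
    return w1 * pf1 + w2 * pf2 + params.pc0


def cs_probability(internal_error: float, params: ModelParams) -> float:
    """Probability of a complex spike given the internal error.

    A sigmoid of the error with slope ``tau``, offset so that zero error
    gives zero probability and saturating at 30% for large errors.  Negative
    errors are clamped to zero probability: only instructions in the
    direction that evokes complex spikes drive learning (no potentiation
    channel beyond the relaxation toward baseline weights).
    """
    if not np.isfinite(internal_error):
        raise ValueError("internal_error must be finite")
    p = 2 * CS_PROBABILITY_CEILING / (1.0 + np.exp(-params.tau * internal_error)) \
        - CS_PROBABILITY_CEILING
    return max(0.0, p)


def update_pf_weights(
    state: CircuitState,
    active_pf_signals: tuple[float, float],
    p_cs: float,
    params: ModelParams,
) -> tuple[float, float]:
    """One application of the PF plasticity rule.

    Each weight relaxes toward baseline by ``(1 - alpha_pf)`` of its learned
    change; the PF whose firing was positive is additionally depressed by
    ``beta * p_cs``.  The depression does not scale with the PF rate — only
    the sign of the rate gates it.
    """
    if not 0.0 <= p_cs <= CS_PROBABILITY_CEILING:
        raise ValueError("p_cs must be within [0, 0.3]")
    new = []
    for w_i, pf_i in zip(state.w, active_pf_signals):
        w_next = w_i - (1.0 - params.alpha_pf) * (w_i - params.w0)
        if pf_i > 0:
            w_next -= params.beta * p_cs
        new.append(w_next)
    return (new[0], new[1])


@lru_cache(maxsize=512)
def _tuning_cached(
    pursuit_dir: float, pursuit_speed: float, params: ModelParams
) -> np.ndarray:
    theta_i = np.asarray(params.pref_dirs, dtype=float)
    s_i = np.asarray(params.pref_speeds, dtype=float)
    direction = np.cos(np.deg2rad(pursuit_dir - theta_i))
    speed = np.exp(-((pursuit_speed - s_i) ** 2) / (2.0 * params.sigma**2))
    out = direction * speed
    out.flags.writeable = False  # shared across calls
    return out


def ftn_input_tuning(
    pursuit_dir: float, pursuit_speed: float, params: ModelParams
) -> np.ndarray:
    """Firing of the FTN input axons for a given eye-movement vector.

    Each axon is cosine-tuned for direction (preferred direction 0 or 180
    deg) and Gaussian-tuned for speed around its preferred speed with common
    width ``sigma``; responses are bounded in [-1, 1].  The returned array
    is read-only (results are cached across trials).
    """
    if params.n_inputs <= 0:
        raise ValueError("n_inputs must be > 0")
    return _tuning_cached(float(pursuit_dir), float(pursuit_speed), params)


def ftn_output(state: CircuitState, pc_component: float, in_vector: np.ndarray) -> float:
    """FTN rate: weighted sum of input axons minus the learned PC modulation.

    With all input weights zero this reduces to the single-site readout
    FTN_n = -(PC_n - PC0).
    """
    v = state.v_array
    in_vector = np.asarray(in_vector, dtype=float)
    if in_vector.shape != v.shape:
        raise ValueError(
            f"input vector length {in_vector.shape} does not match weights {v.shape}"
        )
    return float(v @ in_vector) - pc_component


def update_ftn_weights(
    state: CircuitState,
    pc_component: float,
    in_vector: np.ndarray,
    params: ModelParams,
) -> tuple[float, ...]:
    """Hebbian transfer: learned PC modulation teaches the FTN input weights.

    ``v_i += eta * (PC0 - PC_n) * IN_i``.  There is no forgetting term at
    this site — retention is essentially perfect, which is what makes it the
    long-term store.
    """
    v = state.v_array + params.eta * (-pc_component) * np.asarray(in_vector, float)
    return tuple(v)


def internal_error(
    instruction_speed: float,
    ftn_rate: float,
    pursuit_speed: float,
    params: ModelParams,
) -> float:
    """Olivary error after recurrent inhibition.

    ``E_n = I_n - c*FTN_n - gamma * c*FTN_n / pursuit_speed``.  The feedback
    term is normalized by eye speed in the pursuit direction so inhibition
    scales with the PF weight change rather than the raw output.  With
    ``gamma = 0`` the internal error equals the physical error.
    """
    learned = params.c * ftn_rate
    err = instruction_speed - learned
    if params.gamma > 0.0:
        if pursuit_speed <= 0.0 and learned != 0.0:
            raise ValueError(
                "recurrent inhibition requires pursuit_speed > 0 on learning trials"
            )
        if learned != 0.0:
            err -= params.gamma * learned / pursuit_speed
    return err


# ---------------------------------------------------------------------------
# Trial engine
# ---------------------------------------------------------------------------

def step_trial(
    state: CircuitState,
    spec: TrialSpec,
    params: ModelParams,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
    transfer_on_all_trials: bool = True,
) -> tuple[CircuitState, TrialResult]:
    """Run one trial: express, compute error, update PF weights, update v.

    Expression precedes acquisition: the learned response is measured in a
    window that ends before any instruction-driven visual feedback, so it is
    computed from the pre-update state.

    ``mode='expected'`` applies the mean depression ``beta * p_cs``
    (deterministic; used for fitting and quantitative targets);
    ``mode='stochastic'`` draws a Bernoulli complex spike per trial.

    Error-clamp trials force the internal error to zero (the target is yoked
    to the eye, removing any error that could drive unlearning) while the
    passive weight decay still applies.  The Hebbian transfer to FTN inputs
    is PC-driven rather than error-driven and by default applies on every
    trial with nonzero PC modulation; set ``transfer_on_all_trials=False``
    to restrict it to learning trials.
    """
    if mode not in ("expected", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "stochastic" and rng is None:
        raise ValueError("stochastic mode requires an rng")
    ttype = TrialType(spec.trial_type)

    # --- expression (pre-update state) ---
    pf = pf_rates(spec.pursuit_speed, params)
    pc = pc_rate(state, spec.pursuit_speed, params)
    pc_component = pc - params.pc0
    in_vec = ftn_input_tuning(spec.pursuit_dir, spec.pursuit_speed, params)
    ftn_input_component = float(state.v_array @ in_vec)
    ftn = ftn_output(state, pc_component, in_vec)
    learned_response = params.c * ftn

    # --- error and complex-spike probability ---
    physical_error = spec.instruction_speed - params.c * ftn
    if ttype is TrialType.LEARNING:
        e_n = internal_error(spec.instruction_speed, ftn, spec.pursuit_speed, params)
        p_cs = cs_probability(e_n, params)
    else:
        # no instruction (or clamped error): nothing drives the olive
        e_n = 0.0
        p_cs = 0.0

    # --- fast plasticity ---
    if mode == "expected":
        w_next = update_pf_weights(state, pf, p_cs, params)
    else:
        # Bernoulli complex spike; a spike depresses the active PF by beta
        w_next = update_pf_weights(state, pf, 0.0, params)
        if rng.random() < p_cs:
            w_next = tuple(
                w - params.beta if pf_i > 0 else w
                for w, pf_i in zip(w_next, pf)
            )

    # --- slow transfer ---
    if transfer_on_all_trials or ttype is TrialType.LEARNING:
        v_next = update_ftn_weights(state, pc_component, in_vec, params)
    else:
        v_next = state.v

    new_state = CircuitState(w=w_next, v=v_next, trial_index=state.trial_index + 1)
    result = TrialResult(
        learned_response=learned_response,
        internal_error=e_n,
        physical_error=physical_error,
        p_cs=p_cs,
        pc_component=pc_component,
        ftn_input_component=ftn_input_component,
        ftn_total=ftn,
    )
    return new_state, result


def run_session(
    specs: list[TrialSpec],
    params: ModelParams,
    mode: str = "expected",
    rng_seed: int | None = None,
    transfer_on_all_trials: bool = True,
    subject: str = "",
    paradigm: str = "",
) -> tuple[BehavioralSeries, list[TrialResult]]:
    """Fold the trial engine over an ordered trial list from a reset state.

    Deterministic given ``rng_seed`` and ``mode``.  The returned series
    records per-trial PC and FTN-input components so the transfer of the
    motor memory between sites can be inspected.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    rng = np.random.default_rng(rng_seed) if mode == "stochastic" else None
    state = CircuitState.initial(params)
    results: list[TrialResult] = []
    rows = []
    for i, spec in enumerate(specs):
        state, res = step_trial(
            state, spec, params, mode=mode, rng=rng,
            transfer_on_all_trials=transfer_on_all_trials,
        )
        results.append(res)
        rows.append(
            {
                "trial_index": i,
                "trial_type": TrialType(spec.trial_type).value,
                "pursuit_dir": spec.pursuit_dir,
                "pursuit_speed": spec.pursuit_speed,
                "instruction_speed": spec.instruction_speed,
                "instruction_dir": spec.instruction_dir,
                "learned_response": res.learned_response,
                "pc_component": res.pc_component,
                "ftn_input_component": res.ftn_input_component,
                "p_cs": res.p_cs,
                "internal_error": res.internal_error,
            }
        )
    series = BehavioralSeries(
        data=pd.DataFrame(rows),
        subject=subject,
        paradigm=paradigm,
        seed=rng_seed,
        meta={"mode": mode},
    )
    return series, results
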