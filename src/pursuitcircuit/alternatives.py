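"""Rejected state-space alternatives to the circuit model.

Two standard trial-by-trial learners are implemented for comparison with
the circuit model:

* a **single-process** learner ``x[n+1] = alpha*x[n] + dY(e[n])`` whose
  output is the state itself, and
* a **two-independent-process** learner with a fast state driven by the
  saturating single-trial learning function and a slow state with a small
  linear learning rate and high retention.

Both inherit the saturating single-trial learning function ``dY(e)`` (the
sigmoid fitted to single-trial data), and both therefore predict a
sigmoid-shaped — not linear — relationship between asymptotic learning and
instruction magnitude, which is the failure that motivates the recurrent
circuit model.

Asymptotes are computed as numeric fixed points (the printed closed forms
involve the unknown asymptotic error implicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import SigmoidFit

__all__ = [
    "StateSpaceParams",
    "StateTrajectory",
    "single_process_step",
    "single_process_asymptote",
    "two_process_step",
    "two_process_asymptote",
    "simulate_single_process",
    "simulate_two_process",
]


@dataclass(frozen=True)
class StateSpaceParams:
    """Parameters of the alternative learners.

    ``alpha`` is the single-process retention; ``alpha_f``/``alpha_s`` the
    fast and slow retentions of the two-process learner (``alpha_s`` must
    exceed ``alpha_f``); ``eta_s`` the slow linear learning rate; and
    ``delta_fn`` the saturating single-trial learning function.
    """

    alpha: float = 0.85
    alpha_f: float = 0.85
    alpha_s: float = 0.96
    eta_s: float = 1e-3
    delta_fn: SigmoidFit = field(default_factory=lambda: SigmoidFit(a=1.35, tau=0.21))

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_f", "alpha_s"):
            val = getattr(self, name)
            if not 0.0 < val <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {val}")
        if self.eta_s < 0:
            raise ValueError("eta_s must be >= 0")
        if self.alpha_s <= self.alpha_f:
            raise ValueError("the slow process must retain better: alpha_s > alpha_f")


@dataclass
class StateTrajectory:
    """Per-trial hidden states and output, all in deg/s of learned response."""

    y: np.ndarray
    x: np.ndarray | None = None
    x_f: np.ndarray | None = None
    x_s: np.ndarray | None = None


def single_process_step(x: float, error: float, params: StateSpaceParams) -> float:
    """One trial of the single-process learner: x' = alpha*x + dY(e)."""
    return params.alpha * x + float(params.delta_fn(error))


def two_process_step(
    x_f: float, x_s: float, error: float, params: StateSpaceParams
) -> tuple[float, float]:
    """One trial of the two-independent-process learner."""
    return (
        params.alpha_f * x_f + float(params.delta_fn(error)),
        params.alpha_s * x_s + params.eta_s * error,
    )


def simulate_single_process(
    instruction: float, n_trials: int, params: StateSpaceParams
) -> StateTrajectory:
    """Closed-loop simulation: the error on each trial is I - Y."""
    x = 0.0
    xs = np.empty(n_trials)
    for n in range(n_trials):
        xs[n] = x
        x = single_process_step(x, instruction - x, params)
    return StateTrajectory(y=xs.copy(), x=xs)


def simulate_two_process(
    instruction: float, n_trials: int, params: StateSpaceParams
) -> StateTrajectory:
    x_f = x_s = 0.0
    xf = np.empty(n_trials)
    xs_arr = np.empty(n_trials)
    for n in range(n_trials):
        xf[n], xs_arr[n] = x_f, x_s
        x_f, x_s = two_process_step(x_f, x_s, instruction - (x_f + x_s), params)
    return StateTrajectory(y=xf + xs_arr, x_f=xf, x_s=xs_arr)


def single_process_asymptote(instruction: float, params: StateSpaceParams) -> float:
    """Fixed point of Y = alpha*Y + dY(I - Y), solved by bisection on [0, I]."""
    if params.alpha >= 1.0:
        raise ValueError("no fixed point when alpha = 1 (perfect retention)")
    if instruction == 0.0:
        return 0.0

    def resid(y: float) -> float:
        return params.alpha * y + float(params.delta_fn(instruction - y)) - y

    # resid(0) = dY(I) > 0; resid(I) = (alpha-1)*I < 0 for I > 0
    return float(brentq(resid, 0.0, instruction, xtol=1e-12))


def two_process_asymptote(instruction: float, params: StateSpaceParams) -> float:
    """Numeric fixed point of the coupled fast/slow system.

    At the fixed point, e = I - Y, x_f = dY(e)/(1-alpha_f),
    x_s = eta_s*e/(1-alpha_s), and Y = x_f + x_s.  In the limit
    ``eta_s -> 0`` this reduces to the single-process asymptote with
    retention ``alpha_f``.
    """
    if instruction == 0.0:
        return 0.0
    a_f, a_s, eta_s = params.alpha_f, params.alpha_s, params.eta_s
    if a_f >= 1.0 or (eta_s > 0 and a_s >= 1.0):
        raise ValueError("asymptote requires retention < 1 in each active process")

    def resid(y: float) -> float:
        e = instruction - y
        total = float(params.delta_fn(e)) / (1.0 - a_f)
        if eta_s > 0:
            total += eta_s * e / (1.0 - a_s)
        return total - y

    # resid(0) > 0 and resid(I) < 0 as above
    return float(brentq(resid, 0.0, instruction, xtol=1e-12))
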