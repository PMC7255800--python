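"""Model parameters for the cerebellar pursuit-learning circuit.

The circuit has a small number of constants that set the scale of firing
rates and eye velocities (``r``, ``w0``, ``c``), the fast-plasticity rule at
the parallel-fiber to Purkinje-cell synapse (``alpha_pf``, ``beta``, ``tau``),
the slow Hebbian transfer to floccular-target-neuron (FTN) inputs (``eta``),
the recurrent inhibition of the olivary error signal (``gamma``), and the
speed tuning of the non-Purkinje FTN input axons (``sigma``, ``pref_speeds``,
``pref_dirs``).

Two fitted per-animal parameter sets are shipped: ``MONKEY_RE`` and
``MONKEY_YO`` hold the single-trial sigmoid fits (amplitude ``a`` and slope
``tau``) together with the confidence-interval midpoints for ``eta`` and
``gamma`` estimated from 100-trial learning blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "SigmoidFit",
    "MONKEY_RE",
    "MONKEY_YO",
    "default_pref_dirs",
    "default_pref_speeds",
    "load_params",
    "dump_params",
]


def default_pref_speeds(n_inputs: int = 50) -> tuple[float, ...]:
    """Preferred speeds of the FTN input axons, evenly spaced on [0, 50] deg/s."""
    return tuple(np.linspace(0.0, 50.0, n_inputs))


def default_pref_dirs(n_inputs: int = 50) -> tuple[float, ...]:
    """Preferred directions alternating between 0 and 180 degrees."""
    return tuple(0.0 if i % 2 == 0 else 180.0 for i in range(n_inputs))


@dataclass(frozen=True)
class ModelParams:
    """All constants of the circuit model in one validated record.

    Parameters
    ----------
    r : float
        Parallel-fiber gain converting eye velocity (deg/s) to firing (Hz).
    w0 : float
        Baseline parallel-fiber to Purkinje-cell synaptic weight.
    alpha_pf : float
        Per-trial retention of learned PF-weight changes, in (0, 1].
        ``1 - alpha_pf`` of the learned change is forgotten each trial.
    beta : float
        PF-weight depression caused by one complex spike.
    c : float
        Gain converting FTN firing (Hz) to eye velocity (deg/s).
    sigma : float
        Width (deg/s) of the Gaussian speed tuning of FTN input axons.
    tau : float
        Slope of the sigmoid linking error size to complex-spike probability
        (per deg/s); fitted per animal.
    eta : float
        Rate of the Purkinje-cell-taught Hebbian plasticity at FTN inputs.
        ``eta = 0`` disables memory transfer (single-site model).
    gamma : float
        Gain of recurrent inhibition of the olivary error signal.
        ``gamma = 0`` disables the feedback loop.
    n_inputs : int
        Number of non-Purkinje input axons onto the FTN.
    pref_speeds, pref_dirs : tuple of float
        Preferred speed (deg/s) and direction (deg, 0 or 180) of each axon.
    pc0 : float
        Background Purkinje-cell rate (Hz).  Arbitrary: it cancels in every
        baseline-subtracted quantity.
    """

    r: float = 1.0
    w0: float = 1.0
    alpha_pf: float = 0.85
    beta: float = 1.5
    c: float = 0.0625
    sigma: float = 7.5
    tau: float = 0.21
    eta: float = 0.0
    gamma: float = 0.0
    n_inputs: int = 50
    pref_speeds: tuple[float, ...] = field(default_factory=default_pref_speeds)
    pref_dirs: tuple[float, ...] = field(default_factory=default_pref_dirs)
    pc0: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_pf <= 1.0:
            raise ValueError(f"alpha_pf must be in (0, 1], got {self.alpha_pf}")
        for name in ("beta", "c", "r", "sigma", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.eta < 0 or self.gamma < 0:
            raise ValueError("eta and gamma must be >= 0")
        if len(self.pref_speeds) != self.n_inputs or len(self.pref_dirs) != self.n_inputs:
            raise ValueError(
                "pref_speeds and pref_dirs must each have n_inputs entries"
            )
        if any(d not in (0.0, 180.0) for d in self.pref_dirs):
            raise ValueError("pref_dirs entries must be 0 or 180 degrees")
        object.__setattr__(self, "pref_speeds", tuple(float(s) for s in self.pref_speeds))
        object.__setattr__(self, "pref_dirs", tuple(float(d) for d in self.pref_dirs))

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def single_site(self) -> "ModelParams":
        """The single-plasticity-site special case (eta = gamma = 0)."""
        return self.with_(eta=0.0, gamma=0.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pref_speeds"] = list(d["pref_speeds"])
        d["pref_dirs"] = list(d["pref_dirs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        for key in ("pref_speeds", "pref_dirs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SigmoidFit:
    """A fitted single-trial learning sigmoid: Y(E) = a/(1+exp(-tau*E)) - a/2."""

    a: float
    tau: float

    def __call__(self, error):
        error = np.asarray(error, dtype=float)
        return self.a / (1.0 + np.exp(-self.tau * error)) - self.a / 2.0


# Per-animal fitted values.  eta and gamma are the midpoints of the reported
# 95% confidence intervals from the joint fit to 100-trial learning blocks.
MONKEY_RE = ModelParams(
    tau=0.21,
    eta=(5.1e-4 + 9.2e-4) / 2.0,
    gamma=(55.9 + 68.5) / 2.0,
)
MONKEY_YO = ModelParams(
    tau=0.118,
    eta=(4.5e-4 + 9.4e-4) / 2.0,
    gamma=(38.8 + 65.0) / 2.0,
)

#: Single-trial learning sigmoid fits per animal.
SINGLE_TRIAL_FITS = {
    "RE": SigmoidFit(a=1.35, tau=0.21),
    "YO": SigmoidFit(a=1.25, tau=0.118),
}


def load_params(path: str | Path) -> ModelParams:
    """Load parameters from a YAML or JSON file; missing keys take defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return ModelParams.from_dict(data)


def dump_params(params: ModelParams, path: str | Path) -> None:
    """Write parameters to YAML or JSON depending on the file suffix."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
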