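"""Generators for the behavioral trial sequences.

Four designs are covered:

* **dual_trial** — alternating learning/probe pairs with the pursuit
  direction of each pair drawn from the cardinal axes and the instruction
  direction drawn from +/-90 deg, with the constraint that consecutive
  pairs never repeat the same (pursuit, instruction) direction combination.
  Randomized directions prevent learning from accumulating across pairs.
* **learning_block** — baseline trials, then a block of identical learning
  trials, then at least as many washout trials; consecutive blocks never
  repeat the same direction combination.
* **error_clamp_probe** — learning trials followed by error-clamp trials
  that measure retention in the absence of error; a long form alternates
  clamp blocks with "top-up" runs of learning trials.
* **long_generalization** — dual-trial pairs with a fixed pursuit direction
  and fixed learning-trial parameters for the whole session, probing with
  randomized pursuit speeds so the generalization of accumulated learning
  can be tracked.

All generators are bit-reproducible given the configured seed and emit
validated :class:`~pursuitcircuit.circuit.TrialSpec` streams.  Session
timing (fixation 400-800 ms, 250 ms of pursuit before the instruction,
400 ms instruction) is carried as metadata for the trace synthesizer; the
trial-granular model needs only speeds and directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit import CARDINAL_DIRS, TrialSpec, TrialType

__all__ = [
    "ParadigmConfig",
    "SESSION_TIMING",
    "make_dual_trial_session",
    "make_learning_block",
    "make_error_clamp_probe",
    "make_generalization_session",
    "specs_to_frame",
    "frame_to_specs",
    "save_specs",
    "load_specs",
]

#: Trial timing metadata (ms), recorded for the trace synthesizer.
SESSION_TIMING = {
    "fixation_ms": (400, 800),
    "pre_instruction_ms": 250,
    "instruction_ms": 400,
    "trial_motion_ms": 850,
}


@dataclass(frozen=True)
class ParadigmConfig:
    """Configuration for one behavioral session design."""

    paradigm: str = "dual_trial"
    pursuit_speeds: tuple[float, ...] = (20.0,)
    instruction_speeds: tuple[float, ...] = (30.0,)
    probe_speed_set: tuple[float, ...] = (20.0,)
    n_pairs: int = 100
    n_trials: int = 100
    n_baseline: int = 20
    n_washout: int | None = None
    n_clamp: int = 10
    n_topup_cycles: int = 0
    learn_to_probe_ratio: int = 0
    allowed_dirs: tuple[float, ...] = CARDINAL_DIRS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for group in (self.pursuit_speeds, self.instruction_speeds, self.probe_speed_set):
            if any(s < 0 for s in group):
                raise ValueError("speeds must be >= 0")
        for name in ("n_pairs", "n_trials"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "ParadigmConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        for key in ("pursuit_speeds", "instruction_speeds", "probe_speed_set", "allowed_dirs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("pursuit_speeds", "instruction_speeds", "probe_speed_set", "allowed_dirs"):
            d[key] = list(d[key])
        return d


def _draw_direction_pairs(rng: np.random.Generator, n: int, allowed_dirs) -> list[tuple[float, float]]:
    """Draw n (pursuit_dir, instruction_dir) combinations, never repeating
    the same combination on consecutive draws."""
    allowed_dirs = tuple(allowed_dirs)
    combos = [(d, s) for d in allowed_dirs for s in (90.0, -90.0)]
    if len(combos) < 2:
        raise ValueError("need at least two direction combinations to avoid repeats")
    out: list[tuple[float, float]] = []
    prev = None
    for _ in range(n):
        while True:
            combo = combos[rng.integers(len(combos))]
            if combo != prev:
                break
        out.append(combo)
        prev = combo
    return out


def make_dual_trial_session(config: ParadigmConfig) -> list[TrialSpec]:
    """Alternating learning/probe pairs with randomized directions.

    Pursuit speed of the learning trial, instruction speed, and probe
    pursuit speed are each drawn uniformly from the configured sets.
    """
    if not config.instruction_speeds:
        raise ValueError("instruction_speeds must be nonempty")
    rng = np.random.default_rng(config.rng_seed)
    dirs = _draw_direction_pairs(rng, config.n_pairs, config.allowed_dirs)
    specs: list[TrialSpec] = []
    for pursuit_dir, instr_dir in dirs:
        learn_speed = float(rng.choice(config.pursuit_speeds))
        instr_speed = float(rng.choice(config.instruction_speeds))
        probe_speed = float(rng.choice(config.probe_speed_set))
        specs.append(
            TrialSpec(
                trial_type=TrialType.LEARNING,
                pursuit_dir=pursuit_dir,
                pursuit_speed=learn_speed,
                instruction_speed=instr_speed,
                instruction_dir=instr_dir,
            )
        )
        specs.append(
            TrialSpec(
                trial_type=TrialType.PROBE,
                pursuit_dir=pursuit_dir,
                pursuit_speed=probe_speed,
                instruction_dir=instr_dir,
            )
        )
    return specs


def make_learning_block(config: ParadigmConfig) -> list[TrialSpec]:
    """Baseline trials, a block of identical learning trials, then washout.

    The washout count defaults to the learning count and must not be
    smaller (learning must be extinguished before the next block).
    """
    n_washout = config.n_trials if config.n_washout is None else config.n_washout
    if n_washout < config.n_trials:
        raise ValueError("washout count must be >= learning count")
    rng = np.random.default_rng(config.rng_seed)
    (pursuit_dir, instr_dir), = _draw_direction_pairs(rng, 1, config.allowed_dirs)
    pursuit_speed = float(config.pursuit_speeds[0])
    instr_speed = float(config.instruction_speeds[0])
    specs = [
        TrialSpec(TrialType.BASELINE, pursuit_dir, pursuit_speed)
        for _ in range(config.n_baseline)
    ]
    if instr_speed > 0:
        specs += [
            TrialSpec(TrialType.LEARNING, pursuit_dir, pursuit_speed,
                      instr_speed, instr_dir)
            for _ in range(config.n_trials)
        ]
    else:
        # a zero-magnitude instruction degenerates to a probe trial
        specs += [
            TrialSpec(TrialType.PROBE, pursuit_dir, pursuit_speed)
            for _ in range(config.n_trials)
        ]
    specs += [
        TrialSpec(TrialType.WASHOUT, pursuit_dir, pursuit_speed)
        for _ in range(n_washout)
    ]
    return specs


def make_error_clamp_probe(config: ParadigmConfig) -> list[TrialSpec]:
    """Learning trials followed by error-clamp retention probes.

    Short form (``n_topup_cycles = 0``): ``n_trials`` learning trials then
    ``n_clamp`` error-clamp trials.  Long form: the initial learning run is
    followed by repeated cycles of [clamp block, 20-trial learning top-up].
    """
    rng = np.random.default_rng(config.rng_seed)
    (pursuit_dir, instr_dir), = _draw_direction_pairs(rng, 1, config.allowed_dirs)
    pursuit_speed = float(config.pursuit_speeds[0])
    instr_speed = float(config.instruction_speeds[0])

    def learning(n):
        return [
            TrialSpec(TrialType.LEARNING, pursuit_dir, pursuit_speed,
                      instr_speed, instr_dir)
            for _ in range(n)
        ]

    def clamp(n):
        return [
            TrialSpec(TrialType.ERROR_CLAMP, pursuit_dir, pursuit_speed)
            for _ in range(n)
        ]

    specs = learning(config.n_trials)
    if config.n_topup_cycles == 0:
        specs += clamp(config.n_clamp)
    else:
        for _ in range(config.n_topup_cycles):
            specs += clamp(config.n_clamp) + learning(20)
    return specs


def make_generalization_session(config: ParadigmConfig) -> list[TrialSpec]:
    """Long dual-trial session with a fixed direction and fixed learning
    parameters, probing generalization across pursuit speeds.

    Learning trials all use ``pursuit_speeds[0]`` and
    ``instruction_speeds[0]``; each probe's pursuit speed is drawn uniformly
    from ``probe_speed_set``.  With ``learn_to_probe_ratio = k > 0`` the
    session intersperses one probe per ``k`` learning trials instead of
    strict alternation.
    """
    if not config.probe_speed_set:
        raise ValueError("probe_speed_set must be nonempty")
    rng = np.random.default_rng(config.rng_seed)
    (pursuit_dir, instr_dir), = _draw_direction_pairs(rng, 1, config.allowed_dirs)
    learn_speed = float(config.pursuit_speeds[0])
    instr_speed = float(config.instruction_speeds[0])

    def learning():
        return TrialSpec(TrialType.LEARNING, pursuit_dir, learn_speed,
                         instr_speed, instr_dir)

    def probe():
        return TrialSpec(
            TrialType.PROBE, pursuit_dir,
            float(rng.choice(config.probe_speed_set)),
            instruction_dir=instr_dir,
        )

    specs: list[TrialSpec] = []
    if config.learn_to_probe_ratio > 0:
        k = config.learn_to_probe_ratio
        for _ in range(config.n_pairs):
            specs += [learning() for _ in range(k)]
            specs.append(probe())
    else:
        for _ in range(config.n_pairs):
            specs.append(learning())
            specs.append(probe())
    return specs


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

SPEC_COLUMNS = [
    "trial_index",
    "trial_type",
    "pursuit_dir",
    "pursuit_speed",
    "instruction_speed",
    "instruction_dir",
]


def specs_to_frame(specs: list[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_index": np.arange(len(specs)),
            "trial_type": [TrialType(s.trial_type).value for s in specs],
            "pursuit_dir": [s.pursuit_dir for s in specs],
            "pursuit_speed": [s.pursuit_speed for s in specs],
            "instruction_speed": [s.instruction_speed for s in specs],
            "instruction_dir": [s.instruction_dir for s in specs],
        }
    )


def frame_to_specs(frame: pd.DataFrame) -> list[TrialSpec]:
    return [
        TrialSpec(
            trial_type=TrialType(row.trial_type),
            pursuit_dir=float(row.pursuit_dir),
            pursuit_speed=float(row.pursuit_speed),
            instruction_speed=float(row.instruction_speed),
            instruction_dir=float(row.instruction_dir),
        )
        for row in frame.itertuples()
    ]


def save_specs(specs: list[TrialSpec], path: str | Path) -> None:
    specs_to_frame(specs).to_csv(path, index=False)


def load_specs(path: str | Path) -> list[TrialSpec]:
    return frame_to_specs(pd.read_csv(path))
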