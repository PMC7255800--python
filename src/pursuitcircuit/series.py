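"""Trial-level behavioral series: the interchange unit between simulation,
synthesis, and analysis.

A :class:`BehavioralSeries` is a thin wrapper around a pandas DataFrame with
one row per trial (trial index, trial type, pursuit direction and speed,
instruction direction and speed, learned response in deg/s) plus session
metadata (subject label, paradigm name, seed).  It round-trips losslessly
through CSV with a ``#``-prefixed JSON metadata header line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["BehavioralSeries", "SERIES_COLUMNS"]

SERIES_COLUMNS = [
    "trial_index",
    "trial_type",
    "pursuit_dir",
    "pursuit_speed",
    "instruction_speed",
    "instruction_dir",
    "learned_response",
]


@dataclass
class BehavioralSeries:
    """Ordered per-trial learned responses with paradigm metadata."""

    data: pd.DataFrame
    subject: str = ""
    paradigm: str = ""
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SERIES_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"series is missing columns: {missing}")
        idx = self.data["trial_index"].to_numpy()
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("trial_index must be strictly increasing")
        lr = self.data["learned_response"].to_numpy(dtype=float)
        if not np.all(np.isfinite(lr)):
            raise ValueError("learned_response must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def learned_responses(self) -> np.ndarray:
        return self.data["learned_response"].to_numpy(dtype=float)

    def of_type(self, trial_type: str) -> pd.DataFrame:
        return self.data[self.data["trial_type"] == trial_type]

    def to_csv(self, path: str | Path) -> None:
        header = {
            "subject": self.subject,
            "paradigm": self.paradigm,
            "seed": self.seed,
            **self.meta,
        }
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BehavioralSeries":
        path = Path(path)
        with path.open() as fh:
            first = fh.readline()
            meta = json.loads(first[1:].strip()) if first.startswith("#") else {}
            if not first.startswith("#"):
                fh.seek(0)
            data = pd.read_csv(fh)
        return cls(
            data=data,
            subject=meta.pop("subject", ""),
            paradigm=meta.pop("paradigm", ""),
            seed=meta.pop("seed", None),
            meta=meta,
        )
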