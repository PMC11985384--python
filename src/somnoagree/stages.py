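"""Sleep-stage vocabulary and the 30-second-epoch hypnogram container.

A hypnogram is the standard clinical representation of a night of sleep:
one categorical label per 30-second epoch, drawn from wakefulness (WAKE),
the three non-REM stages (N1, N2, N3) and REM sleep.  A sixth label,
INVALID, marks epochs rejected for technical reasons (high lead impedance,
connectivity gaps, unscoreable reference data); INVALID never counts as
sleep and is excluded pairwise from agreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

EPOCH_SECONDS = 30.0

__all__ = [
    "EPOCH_SECONDS",
    "StageLabel",
    "Hypnogram",
    "SLEEP_STAGES",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
]


class StageLabel(IntEnum):
    """The five AASM sleep stages plus a technical-rejection label."""

    WAKE = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4
    INVALID = 5

    @property
    def is_sleep(self) -> bool:
        return self in (StageLabel.N1, StageLabel.N2, StageLabel.N3, StageLabel.REM)


#: The five physiological stages, in canonical confusion-matrix order.
SLEEP_STAGES = (StageLabel.WAKE, StageLabel.N1, StageLabel.N2, StageLabel.N3, StageLabel.REM)

# Compact stage vocabulary used in CSV files.
_STAGE_TO_STR = {
    StageLabel.WAKE: "W",
    StageLabel.N1: "N1",
    StageLabel.N2: "N2",
    StageLabel.N3: "N3",
    StageLabel.REM: "R",
    StageLabel.INVALID: "INV",
}
_STR_TO_STAGE = {v: k for k, v in _STAGE_TO_STR.items()}


@dataclass
class Hypnogram:
    """A sequence of 30-s epoch stage labels.

    Parameters
    ----------
    labels
        Integer stage codes (``StageLabel`` values), one per epoch.
    start_time
        Recording start in seconds (an offset on the recording timeline).
    truth
        Optional uncorrupted labels kept alongside after artifact
        injection, for ground-truth evaluation.
    """

    labels: np.ndarray
    start_time: float = 0.0
    truth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("hypnogram must hold at least one epoch")
        if not np.all((self.labels >= 0) & (self.labels <= 5)):
            raise ValueError("labels must be StageLabel codes in 0..5")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def n_epochs(self) -> int:
        return len(self)

    @property
    def duration_s(self) -> float:
        return len(self) * EPOCH_SECONDS

    def stage_mask(self, stage: StageLabel) -> np.ndarray:
        return self.labels == int(stage)

    @property
    def sleep_mask(self) -> np.ndarray:
        """Boolean mask of epochs scored as any sleep stage."""
        return (self.labels >= StageLabel.N1) & (self.labels <= StageLabel.REM)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels != StageLabel.INVALID

    def to_strings(self) -> list[str]:
        return [_STAGE_TO_STR[StageLabel(int(c))] for c in self.labels]


def write_hypnogram_csv(h: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram as ``epoch_index,stage`` CSV (vocabulary W/N1/N2/N3/R/INV)."""
    df = pd.DataFrame({"epoch_index": np.arange(len(h)), "stage": h.to_strings()})
    df.to_csv(path, index=False)


def read_hypnogram_csv(path: str | Path, start_time: float = 0.0) -> Hypnogram:
    df = pd.read_csv(path)
    if "stage" not in df.columns:
        raise ValueError(f"{path}: expected a 'stage' column")
    try:
        codes = np.array([int(_STR_TO_STAGE[s]) for s in df["stage"].astype(str)], dtype=np.int8)
    except KeyError as exc:  # unknown vocabulary entry
        raise ValueError(f"{path}: unknown stage symbol {exc}") from None
    if "epoch_index" in df.columns:
        order = np.argsort(df["epoch_index"].to_numpy())
        codes = codes[order]
    return Hypnogram(codes, start_time=start_time)
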