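"""Sleep continuity/architecture parameters and the data-adequacy rule.

Definitions (all on 30-s epochs):

* TRT — total recording time, the sum of non-rejected (non-INVALID) epochs.
* TST — total sleep time, the sum of epochs in any sleep stage.
* SE  — sleep efficiency, ``TST / TRT * 100``.
* SOL — sleep onset latency, time from the start of the recording to the
  first epoch of the first run of at least three consecutive sleep epochs.
* WASO — wake time after the sleep-onset point.

A device-vs-reference comparison is *technically adequate* when at least
30 minutes of overlapping TST (epochs scored sleep by both and valid in
both) were obtained.

Conventions for rejected epochs: an INVALID epoch is a measurement gap,
not physiology — it does not break a candidate run of three consecutive
sleep epochs, but it does not count toward the run either, and it
contributes to no stage-time total.  SOL is wall-clock time, so epochs of
any kind elapsed before sleep onset count toward it.  When no qualifying
sleep run exists, SOL and WASO are undefined (``None``) and excluded from
cohort aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stages import EPOCH_SECONDS, Hypnogram, StageLabel

__all__ = ["ContinuityParams", "continuity_params", "overlapping_tst", "adequacy"]

_MIN = EPOCH_SECONDS / 60.0  # minutes per epoch


@dataclass
class ContinuityParams:
    trt_min: float
    tst_min: float
    se_pct: float
    sol_min: float | None
    waso_min: float | None
    wake_min: float
    n1_min: float
    n2_min: float
    n3_min: float
    rem_min: float

    def stage_minutes(self) -> dict[str, float]:
        return {
            "wake": self.wake_min,
            "n1": self.n1_min,
            "n2": self.n2_min,
            "n3": self.n3_min,
            "rem": self.rem_min,
        }


def _sleep_onset_epoch(labels: np.ndarray) -> int | None:
    """Index of the first epoch of the first run of >=3 consecutive sleep epochs.

    INVALID epochs inside a run neither break nor extend it.
    """
    sleep = (labels >= StageLabel.N1) & (labels <= StageLabel.REM)
    invalid = labels == StageLabel.INVALID
    run_start: int | None = None
    run_len = 0
    for i in range(labels.size):
        if sleep[i]:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len >= 3:
                return run_start
        elif invalid[i]:
            continue  # gap: neither breaks nor extends
        else:
            run_len = 0
            run_start = None
    return None


def continuity_params(h: Hypnogram) -> ContinuityParams:
    """Compute TRT/TST/SE/SOL/WASO and per-stage minutes for one hypnogram."""
    labels = h.labels
    valid = h.valid_mask
    if not np.any(valid):
        raise ValueError("all epochs INVALID: continuity parameters undefined")

    trt = float(valid.sum()) * _MIN
    tst = float(h.sleep_mask.sum()) * _MIN
    se = 100.0 * tst / trt

    onset = _sleep_onset_epoch(labels)
    if onset is None:
        sol: float | None = None
        waso: float | None = None
    else:
        sol = onset * _MIN  # wall-clock minutes from recording start
        after = labels[onset:]
        waso = float(np.sum(after == StageLabel.WAKE)) * _MIN

    return ContinuityParams(
        trt_min=trt,
        tst_min=tst,
        se_pct=se,
        sol_min=sol,
        waso_min=waso,
        wake_min=float(np.sum(labels == StageLabel.WAKE)) * _MIN,
        n1_min=float(np.sum(labels == StageLabel.N1)) * _MIN,
        n2_min=float(np.sum(labels == StageLabel.N2)) * _MIN,
        n3_min=float(np.sum(labels == StageLabel.N3)) * _MIN,
        rem_min=float(np.sum(labels == StageLabel.REM)) * _MIN,
    )


def overlapping_tst(reference: Hypnogram, device: Hypnogram) -> float:
    """Minutes of epochs scored sleep by BOTH hypnograms and valid in both."""
    if len(reference) != len(device):
        raise ValueError("hypnograms must be epoch-aligned and of equal length")
    both_sleep = reference.sleep_mask & device.sleep_mask
    return float(both_sleep.sum()) * _MIN


def adequacy(reference: Hypnogram, device: Hypnogram, threshold_min: float = 30.0) -> bool:
    """True when at least ``threshold_min`` minutes of overlapping TST exist."""
    return overlapping_tst(reference, device) >= threshold_min
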