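"""Minimal EDF I/O for single-channel biopotential records.

Reading goes through MNE.  Writing is a small, self-contained EDF
(European Data Format) encoder for the one case this package produces —
a single channel at a fixed rate in µV — with 1-s data records and
16-bit samples scaled over the signal's physical range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import BiopotentialRecord

__all__ = ["write_edf", "read_edf"]


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(record: BiopotentialRecord, path: str | Path, label: str = "BioPot") -> None:
    """Write a single-channel record as EDF (µV, 1-s data records).

    The sampling rate must be a whole number of samples per second; the
    trace is truncated to whole seconds (records here are whole epochs,
    so nothing is lost in practice).
    """
    fs = record.sampling_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = record.samples
    n_rec = x.size // spr
    if n_rec < 1:
        raise ValueError("record shorter than one EDF data record (1 s)")
    x = x[: n_rec * spr]

    pmin, pmax = float(x.min()), float(x.max())
    if pmax == pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((x - pmin) * gain + dmin).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 + 256), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field("1", 4),
            # signal header
            _field(label, 16),
            _field("", 80),
            _field("uV", 8),
            _field(f"{pmin:.6g}", 8),
            _field(f"{pmax:.6g}", 8),
            _field(str(dmin), 8),
            _field(str(dmax), 8),
            _field("", 80),
            _field(str(spr), 8),
            _field("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def read_edf(path: str | Path) -> BiopotentialRecord:
    """Read channel 0 of an EDF file into a µV BiopotentialRecord."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0] * 1e6  # MNE returns volts
    return BiopotentialRecord(samples=data, sampling_rate=float(raw.info["sfreq"]))
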