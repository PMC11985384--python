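"""Raw biopotential → masked 30-s spectrogram epochs.

The conditioning chain mirrors common practice for single-lead sleep
EEG: bandpass 0.5–35 Hz, downsample to 100 Hz, then robust-normalize the
whole-night trace (subtract the median, divide by the interquartile
range).  Each 30-s epoch is then turned into a time-frequency image with
2-s Hamming windows at 50% overlap and log-power scaling
``20 * log10 |X|``; epochs rejected upstream (impedance/connectivity)
are nulled to the log-domain floor and masked so the classifier sees a
dedicated "invalid" pattern while the sequence structure is preserved.

Numerical conventions: windows are fully contained in their epoch (so an
epoch is independently maskable), giving 29 frames x 101 bins per epoch
at 100 Hz; magnitudes are clipped at 1e-8 before the log, making the
floor value exactly -160.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import fft as spfft
from scipy import signal as sps

TARGET_FS = 100.0
WINDOW_S = 2.0
HOP_S = 1.0
LOG_CLIP = 1e-8
#: Log-power value assigned to rejected epochs (= 20*log10(LOG_CLIP)).
LOG_FLOOR = 20.0 * np.log10(LOG_CLIP)
FRAMES_PER_EPOCH = 29  # (30 - 2)/1 + 1
BINS = 101  # one-sided rFFT bins for a 200-sample window

__all__ = [
    "BiopotentialRecord",
    "SpectrogramEpochs",
    "condition_signal",
    "spectrogram_epochs",
    "LOG_FLOOR",
    "FRAMES_PER_EPOCH",
    "BINS",
]


@dataclass
class BiopotentialRecord:
    """A single-channel amplitude series in µV."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class SpectrogramEpochs:
    """Per-epoch log-power time-frequency grids with a validity mask.

    ``values`` has shape (epochs, frames, bins); masked epochs hold the
    floor constant in every cell.
    """

    values: np.ndarray
    bin_frequencies: np.ndarray
    frame_times: np.ndarray
    valid_mask: np.ndarray
    floor: float = LOG_FLOOR

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be (epochs, frames, bins)")
        if self.valid_mask.shape != (self.values.shape[0],):
            raise ValueError("valid_mask must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return int(self.values.shape[0])

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            values=self.values,
            bin_frequencies=self.bin_frequencies,
            frame_times=self.frame_times,
            valid_mask=self.valid_mask,
            floor=np.array(self.floor),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SpectrogramEpochs":
        with np.load(path) as z:
            return cls(
                values=z["values"],
                bin_frequencies=z["bin_frequencies"],
                frame_times=z["frame_times"],
                valid_mask=z["valid_mask"],
                floor=float(z["floor"]),
            )


def condition_signal(record: BiopotentialRecord) -> BiopotentialRecord:
    """Bandpass, resample to 100 Hz, robust-normalize.

    The bandpass is an 8th-order Butterworth (0.5–35 Hz) applied
    forward-backward (zero phase, so epoch boundaries are not skewed);
    resampling is polyphase with the exact rational ratio; normalization
    (median 0, IQR 1) is applied last, on the 100 Hz trace.
    """
    if record.duration_s < 30.0:
        raise ValueError("record must be at least 30 s long")
    if record.sampling_rate < 80.0:
        raise ValueError("sampling_rate must be >= 80 Hz")
    q75_in, q25_in = np.percentile(record.samples, [75, 25])
    if q75_in == q25_in:
        raise ValueError("constant signal: interquartile range is zero, cannot normalize")
    sos = sps.butter(8, [0.5, 35.0], btype="bandpass", fs=record.sampling_rate, output="sos")
    x = sps.sosfiltfilt(sos, record.samples)

    if record.sampling_rate != TARGET_FS:
        from fractions import Fraction

        frac = Fraction(TARGET_FS / record.sampling_rate).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)

    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        raise ValueError("constant signal: interquartile range is zero, cannot normalize")
    x = (x - med) / iqr
    return BiopotentialRecord(samples=x, sampling_rate=TARGET_FS, start_time=record.start_time)


def spectrogram_epochs(
    record: BiopotentialRecord,
    invalid_epochs: list[int] | np.ndarray = (),
) -> SpectrogramEpochs:
    """Epoch a conditioned 100 Hz record into log-power spectrogram grids.

    Each 30-s epoch yields 29 frames (2-s Hamming window, 1-s hop, all
    windows inside the epoch) of 101 one-sided spectral magnitudes,
    log-scaled as ``20*log10(max(|X|, 1e-8))``.  Epochs listed in
    ``invalid_epochs`` are set to the floor constant and masked out.
    """
    if record.sampling_rate != TARGET_FS:
        raise ValueError("record must be conditioned to 100 Hz first")
    spe = int(round(30.0 * TARGET_FS))
    n_epochs = record.samples.size // spe
    if n_epochs < 1:
        raise ValueError("record shorter than one 30-s epoch")

    win_len = int(round(WINDOW_S * TARGET_FS))
    hop = int(round(HOP_S * TARGET_FS))
    window = np.hamming(win_len)
    x = record.samples[: n_epochs * spe].reshape(n_epochs, spe)
    # frame index arithmetic: frames fully inside the epoch
    starts = np.arange(FRAMES_PER_EPOCH) * hop
    idx = starts[:, None] + np.arange(win_len)[None, :]
    frames = x[:, idx] * window  # (epochs, frames, win_len)
    mags = np.abs(spfft.rfft(frames, axis=-1))  # (epochs, frames, 101)
    values = 20.0 * np.log10(np.maximum(mags, LOG_CLIP))

    valid = np.ones(n_epochs, dtype=bool)
    invalid_epochs = np.asarray(invalid_epochs, dtype=int)
    if invalid_epochs.size:
        if invalid_epochs.min() < 0 or invalid_epochs.max() >= n_epochs:
            raise ValueError("invalid epoch index out of range")
        valid[invalid_epochs] = False
        values[invalid_epochs] = LOG_FLOOR

    return SpectrogramEpochs(
        values=values,
        bin_frequencies=np.fft.rfftfreq(win_len, d=1.0 / TARGET_FS),
        frame_times=(starts + win_len / 2.0) / TARGET_FS,
        valid_mask=valid,
    )
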