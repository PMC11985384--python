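"""Synthetic sleep-study cohorts with known ground truth.

Real validation data for a forehead biopotential sleep stager cannot be
redistributed, so every downstream stage of the pipeline is exercised on
synthetic patients instead: a first-order Markov chain produces a
30-s-epoch hypnogram with realistic dwell structure, a stage-conditioned
signal model produces the single-lead biopotential trace, and a paired
pulse-rate (PR) generator produces the reference/device trace pair whose
relative shift and linear clock stretch the synchronization module must
recover.

The signal model is deliberately minimal: a sum of band-limited Gaussian
noise components (delta/theta/alpha/sigma/beta) whose relative power is
modulated per epoch by the current stage, plus additive event templates —
spindle-band bursts in N2 and, in REM, biphasic deflections of opposite
polarity emulating the eye-movement signature of an electrode placed
diagonally across the lateral cross-section of the eye.  This exposes
exactly the spectral and event features the classifier and the test
oracles need, and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .stages import EPOCH_SECONDS, SLEEP_STAGES, Hypnogram, StageLabel

__all__ = [
    "ArchitectureSpec",
    "SignalRecipe",
    "PRRecipe",
    "PRPair",
    "BANDS",
    "generate_hypnogram",
    "synthesize_biopotential",
    "generate_pr_pair",
    "inject_invalid",
    "default_architecture",
    "default_recipe",
    "source_montage_recipe",
    "default_pr_recipe",
]

#: Frequency bands (Hz) used throughout: EEG convention with a spindle
#: (sigma) band overlapping alpha/beta.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (11.0, 16.0),
    "beta": (16.0, 35.0),
}
BAND_NAMES = tuple(BANDS)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Markov-chain description of sleep architecture.

    ``transition_matrix`` holds per-epoch transition probabilities over the
    five physiological stages in order WAKE, N1, N2, N3, REM.
    """

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    epochs_total: int
    seed: int = 0

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        init = np.asarray(self.initial_distribution, dtype=float)
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(self, "initial_distribution", init)
        if tm.shape != (5, 5):
            raise ValueError("transition_matrix must be 5x5")
        if np.any(tm < 0) or np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must be non-negative and sum to 1")
        if init.shape != (5,) or np.any(init < 0) or abs(init.sum() - 1.0) > 1e-12:
            raise ValueError("initial_distribution must be a 5-vector summing to 1")
        if self.epochs_total < 1:
            raise ValueError("epochs_total must be >= 1")


@dataclass(frozen=True)
class SignalRecipe:
    """Stage-conditioned spectral content of the synthetic biopotential.

    ``band_power`` maps each stage to relative power weights over the five
    bands (dimensionless; the generated per-band amplitude is proportional
    to the square root of the weight).  ``emg_level`` is the per-stage RMS
    (µV) of an additive broadband muscle-tone component.  REM epochs carry
    paired opposite-polarity deflection events at ``rem_deflection_rate``
    events per minute.
    """

    band_power: dict[StageLabel, tuple[float, ...]]
    emg_level: dict[StageLabel, float]
    rem_deflection_rate: float = 5.0  # events / min
    rem_deflection_amplitude: float = 120.0  # µV
    spindle_rate: float = 4.0  # bursts / min in N2
    spindle_amplitude: float = 25.0  # µV
    scale_uv: float = 30.0  # total RMS of the band mixture, µV
    sampling_rate: float = 256.0  # Hz

    def __post_init__(self) -> None:
        if self.sampling_rate <= 70.0:
            raise ValueError("sampling_rate must exceed 70 Hz (2x the top band)")
        for stage in SLEEP_STAGES:
            w = np.asarray(self.band_power[stage], dtype=float)
            if w.shape != (5,) or np.any(w < 0) or not np.any(w > 0):
                raise ValueError(f"band weights for {stage.name} must be >=0, not all zero")

    def weights(self, stage: StageLabel) -> np.ndarray:
        return np.asarray(self.band_power[stage], dtype=float)


@dataclass(frozen=True)
class PRRecipe:
    """Pulse-rate trace model: baseline + stage modulation + variability.

    Variability has a slow component (sympathovagal drift, centred near
    0.03 Hz) and a faster respiratory-sinus-arrhythmia-like component near
    0.25 Hz; the fast component is what gives the synchronization
    objective sub-second curvature.
    """

    baseline_bpm: float = 65.0
    variability_bpm: float = 4.0
    stage_offset_bpm: dict[StageLabel, float] = field(
        default_factory=lambda: {
            StageLabel.WAKE: 6.0,
            StageLabel.N1: 2.0,
            StageLabel.N2: 0.0,
            StageLabel.N3: -3.0,
            StageLabel.REM: 3.0,
        }
    )
    sample_interval_s: float = 1.0
    noise_bpm: float = 1.0

    def __post_init__(self) -> None:
        if not (40.0 <= self.baseline_bpm <= 120.0):
            raise ValueError("baseline_bpm must lie in [40, 120]")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")


def default_architecture(epochs_total: int, seed: int = 0) -> ArchitectureSpec:
    """Default nightly architecture: long N2 runs, brief N1, sticky W/N3/REM."""
    tm = np.array(
        [
            #  W     N1     N2     N3    REM
            [0.920, 0.060, 0.015, 0.000, 0.005],  # WAKE
            [0.100, 0.550, 0.330, 0.000, 0.020],  # N1
            [0.020, 0.020, 0.900, 0.040, 0.020],  # N2
            [0.010, 0.005, 0.060, 0.920, 0.005],  # N3
            [0.030, 0.020, 0.040, 0.000, 0.910],  # REM
        ]
    )
    init = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    return ArchitectureSpec(tm, init, epochs_total, seed)


def default_recipe(sampling_rate: float = 256.0) -> SignalRecipe:
    """High-contrast forehead-montage recipe (band order delta..beta)."""
    return SignalRecipe(
        band_power={
            StageLabel.WAKE: (0.6, 0.6, 3.0, 0.4, 1.8),
            StageLabel.N1: (1.0, 2.6, 1.0, 0.4, 0.5),
            StageLabel.N2: (1.6, 1.6, 0.5, 2.4, 0.3),
            StageLabel.N3: (5.5, 1.0, 0.3, 0.3, 0.2),
            StageLabel.REM: (1.0, 1.6, 0.8, 0.3, 0.9),
        },
        emg_level={
            StageLabel.WAKE: 12.0,
            StageLabel.N1: 4.0,
            StageLabel.N2: 2.5,
            StageLabel.N3: 1.5,
            StageLabel.REM: 1.0,
        },
        sampling_rate=sampling_rate,
    )


def source_montage_recipe(sampling_rate: float = 256.0) -> SignalRecipe:
    """A related but distinct central-electrode-like montage.

    Used as the source corpus for transfer learning: spindles and delta are
    more prominent, eye-movement deflections are strongly attenuated (a
    central derivation barely sees them), and muscle tone differs.
    """
    return SignalRecipe(
        band_power={
            StageLabel.WAKE: (0.8, 0.8, 2.2, 0.5, 2.2),
            StageLabel.N1: (1.2, 2.2, 0.8, 0.5, 0.6),
            StageLabel.N2: (2.0, 1.4, 0.4, 3.2, 0.3),
            StageLabel.N3: (6.5, 1.0, 0.2, 0.4, 0.2),
            StageLabel.REM: (1.2, 1.8, 0.6, 0.3, 1.1),
        },
        emg_level={
            StageLabel.WAKE: 8.0,
            StageLabel.N1: 3.0,
            StageLabel.N2: 2.0,
            StageLabel.N3: 1.5,
            StageLabel.REM: 1.2,
        },
        rem_deflection_amplitude=15.0,
        spindle_amplitude=40.0,
        sampling_rate=sampling_rate,
    )


def default_pr_recipe() -> PRRecipe:
    return PRRecipe()


# ---------------------------------------------------------------------------
# hypnogram generation


def generate_hypnogram(spec: ArchitectureSpec) -> Hypnogram:
    """Sample a hypnogram from the Markov chain in ``spec``.

    Reproducible: the same spec (including seed) yields the identical
    label sequence.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.empty(spec.epochs_total, dtype=np.int8)
    cum_init = np.cumsum(spec.initial_distribution)
    cum_tm = np.cumsum(spec.transition_matrix, axis=1)
    u = rng.random(spec.epochs_total)
    labels[0] = np.searchsorted(cum_init, u[0], side="right")
    for i in range(1, spec.epochs_total):
        labels[i] = np.searchsorted(cum_tm[labels[i - 1]], u[i], side="right")
    return Hypnogram(np.minimum(labels, 4))


# ---------------------------------------------------------------------------
# biopotential synthesis


def _band_noise(n: int, lo: float, hi: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _biphasic_deflection(n: int) -> np.ndarray:
    """Two adjacent half-sine lobes of opposite polarity, peak amplitude 1."""
    half = n // 2
    t = np.linspace(0.0, np.pi, half, endpoint=False)
    lobe = np.sin(t)
    out = np.zeros(n)
    out[:half] = lobe
    out[half : 2 * half] = -lobe
    return out


def synthesize_biopotential(hypnogram: Hypnogram, recipe: SignalRecipe, seed: int):
    """Render a single-channel biopotential trace for ``hypnogram``.

    Returns a :class:`somnoagree.preprocess.BiopotentialRecord` of
    ``n_epochs * 30 s`` at ``recipe.sampling_rate``, in µV.  Per-stage
    band-power fractions follow ``recipe.band_power``; N2 epochs carry
    spindle-band bursts and REM epochs carry paired opposite-polarity
    deflection events at ``rem_deflection_rate`` per minute.
    """
    from .preprocess import BiopotentialRecord  # local import to avoid a cycle

    if np.any(~hypnogram.valid_mask):
        raise ValueError("hypnogram passed to the synthesizer must not contain INVALID epochs")
    fs = recipe.sampling_rate
    spe = int(round(EPOCH_SECONDS * fs))  # samples per epoch
    n = spe * len(hypnogram)
    if n == 0:
        raise ValueError("empty hypnogram")
    rng = np.random.default_rng(seed)

    # Whole-record band noises, amplitude-modulated per epoch by the stage
    # weights.  Amplitude ∝ sqrt(weight) so that measured band POWER
    # fractions match the recipe's relative weights.
    weight_table = np.stack([recipe.weights(s) for s in SLEEP_STAGES])  # (5 stages, 5 bands)
    weight_table = weight_table / weight_table.sum(axis=1, keepdims=True)
    amp_per_epoch = recipe.scale_uv * np.sqrt(weight_table[hypnogram.labels])  # (epochs, bands)
    x = np.zeros(n)
    for b, (lo, hi) in enumerate(BANDS.values()):
        noise = _band_noise(n, lo, hi, fs, rng)
        gain = np.repeat(amp_per_epoch[:, b], spe)
        x += gain * noise

    # Broadband muscle tone (16–40 Hz, clipped at Nyquist margin).
    emg_hi = min(40.0, 0.45 * fs)
    emg = _band_noise(n, 16.0, emg_hi, fs, rng)
    emg_gain = np.array([recipe.emg_level[s] for s in SLEEP_STAGES])[hypnogram.labels]
    x += np.repeat(emg_gain, spe) * emg

    # N2 spindle bursts: 1-s 13 Hz Hann-windowed packets.
    burst_len = int(round(1.0 * fs))
    t_burst = np.arange(burst_len) / fs
    spindle = np.sin(2 * np.pi * 13.0 * t_burst) * np.hanning(burst_len)
    for e in np.flatnonzero(hypnogram.labels == StageLabel.N2):
        for _ in range(rng.poisson(recipe.spindle_rate * EPOCH_SECONDS / 60.0)):
            start = e * spe + rng.integers(0, spe - burst_len)
            x[start : start + burst_len] += recipe.spindle_amplitude * spindle

    # REM eye-movement deflections: adjacent lobes of opposite polarity.
    defl_len = int(round(0.8 * fs))
    template = _biphasic_deflection(defl_len)
    for e in np.flatnonzero(hypnogram.labels == StageLabel.REM):
        for _ in range(rng.poisson(recipe.rem_deflection_rate * EPOCH_SECONDS / 60.0)):
            start = e * spe + rng.integers(0, spe - defl_len)
            x[start : start + defl_len] += recipe.rem_deflection_amplitude * template

    return BiopotentialRecord(samples=x, sampling_rate=fs, start_time=hypnogram.start_time)


# ---------------------------------------------------------------------------
# pulse-rate pair


@dataclass
class PRPair:
    """A reference/device pulse-rate trace pair with recorded ground truth."""

    reference: "PRTrace"
    device: "PRTrace"
    true_shift_s: float
    true_stretch: float


def _smooth(x: np.ndarray, sigma_samples: float) -> np.ndarray:
    if sigma_samples <= 0:
        return x
    m = int(4 * sigma_samples)
    k = np.exp(-0.5 * (np.arange(-m, m + 1) / sigma_samples) ** 2)
    k /= k.sum()
    return np.convolve(np.pad(x, m, mode="edge"), k, mode="valid")


def generate_pr_pair(
    hypnogram: Hypnogram,
    recipe: PRRecipe,
    true_shift_s: float,
    true_stretch: float,
    seed: int,
) -> PRPair:
    """Generate a reference PR trace plus a clock-skewed device copy.

    The device trace equals the reference pulse-rate process resampled
    through ``t -> true_stretch * t + true_shift_s`` plus independent
    Gaussian noise of ``recipe.noise_bpm``; the reference trace carries no
    added noise (it plays the role of the ground-truth PSG-side trace).
    """
    from .sync import PRTrace  # local import to avoid a cycle

    if true_stretch <= 0:
        raise ValueError("stretch must be positive")
    if abs(true_stretch - 1.0) > 0.01:
        raise ValueError("|stretch - 1| must be <= 0.01")
    if abs(true_shift_s) > 600.0:
        raise ValueError("|shift| must be <= 600 s")
    rng = np.random.default_rng(seed)
    dt = recipe.sample_interval_s
    duration = hypnogram.duration_s
    t_ref = np.arange(0.0, duration, dt)
    n = t_ref.size

    # Stage-driven slow modulation, smoothed over ~1 min.
    offsets = np.array(
        [recipe.stage_offset_bpm.get(s, 0.0) for s in SLEEP_STAGES], dtype=float
    )
    stage_series = offsets[
        np.minimum(hypnogram.labels, 4)[np.minimum((t_ref / EPOCH_SECONDS).astype(int), len(hypnogram) - 1)]
    ]
    stage_series = _smooth(stage_series, 60.0 / dt / 4.0)

    # Variability: slow drift + RSA-like fast component.
    fs_pr = 1.0 / dt
    slow = _band_noise(n, 0.01, 0.05, fs_pr, rng) * recipe.variability_bpm
    fast = _band_noise(n, 0.15, min(0.35, 0.45 * fs_pr), fs_pr, rng) * (recipe.variability_bpm / 2.0)
    clean = recipe.baseline_bpm + stage_series + slow + fast

    ref_vals = np.clip(clean, 40.0, 120.0)

    # Device clock time t maps to reference time stretch*t + shift; keep
    # only device samples whose warped time lies inside the reference span.
    t_dev_all = np.arange(0.0, duration, dt)
    warped = true_stretch * t_dev_all + true_shift_s
    keep = (warped >= 0.0) & (warped <= t_ref[-1])
    t_dev = t_dev_all[keep]
    dev_clean = np.interp(true_stretch * t_dev + true_shift_s, t_ref, clean)
    dev_vals = dev_clean + rng.standard_normal(t_dev.size) * recipe.noise_bpm
    dev_vals = np.clip(dev_vals, 40.0, 120.0)

    return PRPair(
        reference=PRTrace(times=t_ref, values=ref_vals),
        device=PRTrace(times=t_dev, values=dev_vals),
        true_shift_s=true_shift_s,
        true_stretch=true_stretch,
    )


# ---------------------------------------------------------------------------
# artifact injection


def inject_invalid(hypnogram: Hypnogram, fraction: float, seed: int) -> Hypnogram:
    """Relabel a Bernoulli(``fraction``) subset of epochs as INVALID.

    The uncorrupted labels are retained on the result's ``truth``
    attribute for ground-truth evaluation.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = hypnogram.labels.copy()
    hit = rng.random(labels.size) < fraction
    labels[hit] = StageLabel.INVALID
    return Hypnogram(labels, start_time=hypnogram.start_time, truth=hypnogram.labels.copy())
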