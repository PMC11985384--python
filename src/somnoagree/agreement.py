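"""Agreement statistics for epoch-by-epoch sleep staging comparisons.

This is the endpoint engine of the pipeline: reference-by-device
confusion matrices over doubly-valid epochs, the N1+N2 → Light-Sleep
collapse, one-vs-rest stage metrics (sensitivity, specificity, accuracy,
Cohen's kappa), overall multi-class accuracy and kappa, normal-
approximation confidence intervals for proportions, Bland-Altman paired
statistics with Fisher-z Pearson intervals, and the kappa-precision
sample-size rule.

Statistics are pooled over epochs across all patients (not averaged per
patient): at ~8e4 pooled epochs the binomial half-widths are a few
thousandths, which is the regime these devices are validated in.
Confidence intervals for kappa treat the kappa coefficient itself as the
proportion in the binomial formula — a deliberate, documented
interpretation that matches how such half-widths are conventionally
reported alongside pooled agreement tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .stages import Hypnogram, StageLabel

__all__ = [
    "ConfusionMatrix",
    "StageMetrics",
    "PairedStats",
    "build_confusion",
    "collapse4",
    "stage_metrics",
    "overall_metrics",
    "proportion_ci",
    "paired_stats",
    "sample_size_kappa",
    "load_reference_confusion",
    "read_confusion_csv",
    "write_confusion_csv",
    "agreement_report",
]

STAGE_NAMES_5 = ("Wake", "N1", "N2", "N3", "REM")
STAGE_NAMES_4 = ("Wake", "Light", "N3", "REM")


@dataclass
class ConfusionMatrix:
    """Reference-stage (rows) × device-stage (columns) epoch counts."""

    counts: np.ndarray
    labels: tuple[str, ...] = STAGE_NAMES_5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class StageMetrics:
    sensitivity: float | None
    specificity: float
    accuracy: float
    kappa: float
    sensitivity_ci: float | None
    specificity_ci: float
    accuracy_ci: float
    kappa_ci: float


@dataclass
class PairedStats:
    """Paired per-patient reference-vs-device comparison (Bland-Altman)."""

    n: int
    mean_ref: float
    mean_dev: float
    mean_ref_ci: float
    mean_dev_ci: float
    bias: float  # mean(reference - device)
    bias_ci: float
    pearson_r: float | None
    pearson_ci: tuple[float, float] | None
    loa_low: float
    loa_high: float


def build_confusion(reference: Hypnogram, device: Hypnogram) -> ConfusionMatrix:
    """Count epochs by (reference stage, device stage) over doubly-valid epochs."""
    if len(reference) != len(device):
        raise ValueError("hypnograms must be epoch-aligned and of equal length")
    keep = reference.valid_mask & device.valid_mask
    counts = np.zeros((5, 5))
    r = reference.labels[keep]
    d = device.labels[keep]
    np.add.at(counts, (r, d), 1.0)
    return ConfusionMatrix(counts)


def collapse4(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Combine N1 and N2 into Light Sleep; Wake/N3/REM margins are untouched."""
    if cm.labels != STAGE_NAMES_5:
        raise ValueError("collapse4 expects a 5-stage matrix")
    groups = ([0], [1, 2], [3], [4])
    out = np.zeros((4, 4))
    for i, ri in enumerate(groups):
        for j, cj in enumerate(groups):
            out[i, j] = cm.counts[np.ix_(ri, cj)].sum()
    return ConfusionMatrix(out, labels=STAGE_NAMES_4)


def proportion_ci(p: float, n: float, level: float = 0.95) -> float:
    """Normal-approximation half-width ``z * sqrt(p(1-p)/n)`` for a proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    z = spstats.norm.ppf(0.5 + level / 2.0)
    return float(z * np.sqrt(p * (1.0 - p) / n))


def _kappa_from_2x2(tp: float, fp: float, fn: float, tn: float) -> float:
    t = tp + fp + fn + tn
    po = (tp + tn) / t
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / t**2
    if pe == 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def stage_metrics(cm: ConfusionMatrix, stage: int | StageLabel | str) -> StageMetrics:
    """One-vs-rest metrics for one stage of a (possibly collapsed) matrix.

    ``stage`` may be a row index, a :class:`StageLabel`, or a label string
    from ``cm.labels``.  Sensitivity is ``None`` (flagged undefined) when
    the stage never occurs in the reference.
    """
    if isinstance(stage, str):
        i = cm.labels.index(stage)
    elif isinstance(stage, StageLabel):
        i = cm.labels.index(STAGE_NAMES_5[int(stage)])
    else:
        i = int(stage)
    c = cm.counts
    t = cm.total
    if t == 0:
        raise ValueError("empty confusion matrix")
    tp = c[i, i]
    fn = c[i].sum() - tp
    fp = c[:, i].sum() - tp
    tn = t - tp - fn - fp
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    acc = (tp + tn) / t
    kappa = _kappa_from_2x2(tp, fp, fn, tn)
    return StageMetrics(
        sensitivity=sens,
        specificity=float(spec),
        accuracy=float(acc),
        kappa=float(kappa),
        sensitivity_ci=None if sens is None else proportion_ci(sens, t),
        specificity_ci=proportion_ci(spec, t),
        accuracy_ci=proportion_ci(acc, t),
        kappa_ci=float("nan") if np.isnan(kappa) else proportion_ci(np.clip(kappa, 0.0, 1.0), t),
    )


def overall_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Multi-class accuracy and Cohen's kappa with half-widths.

    ``kappa = (Po - Pe) / (1 - Pe)`` with the chance agreement ``Pe`` from
    the products of row and column marginal proportions.
    """
    t = cm.total
    if t == 0:
        raise ValueError("empty confusion matrix")
    po = float(np.trace(cm.counts) / t)
    pe = float((cm.counts.sum(axis=1) / t) @ (cm.counts.sum(axis=0) / t))
    if pe == 1.0:
        kappa = float("nan")
        kappa_ci = float("nan")
    else:
        kappa = (po - pe) / (1.0 - pe)
        kappa_ci = proportion_ci(np.clip(kappa, 0.0, 1.0), t)
    return {
        "accuracy": po,
        "accuracy_ci": proportion_ci(po, t),
        "kappa": kappa,
        "kappa_ci": kappa_ci,
    }


def paired_stats(pairs: np.ndarray | list[tuple[float, float]], level: float = 0.95) -> PairedStats:
    """Bland-Altman and correlation statistics for per-patient value pairs.

    ``pairs`` holds (reference, device) rows.  Bias is
    ``mean(reference - device)``; limits of agreement are
    ``bias ± 1.96 * SD(differences)``; the Pearson interval uses the
    Fisher z-transform.  Mean/bias half-widths are ``z * SEM``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (reference, device) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    ref, dev = arr[:, 0], arr[:, 1]
    n = arr.shape[0]
    z = spstats.norm.ppf(0.5 + level / 2.0)
    diff = ref - dev
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))

    if ref.std(ddof=1) == 0 or dev.std(ddof=1) == 0:
        r = None
        r_ci = None
    else:
        r = float(np.corrcoef(ref, dev)[0, 1])
        if n > 3:  # Fisher z interval needs n - 3 > 0
            zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
            hw = z / np.sqrt(n - 3)
            r_ci = (float(np.tanh(zr - hw)), float(np.tanh(zr + hw)))
        else:
            r_ci = None

    return PairedStats(
        n=n,
        mean_ref=float(ref.mean()),
        mean_dev=float(dev.mean()),
        mean_ref_ci=float(z * ref.std(ddof=1) / np.sqrt(n)),
        mean_dev_ci=float(z * dev.std(ddof=1) / np.sqrt(n)),
        bias=bias,
        bias_ci=float(z * sd / np.sqrt(n)),
        pearson_r=r,
        pearson_ci=r_ci,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def sample_size_kappa(
    max_ci_width: float = 0.1,
    kappa0: float = 0.3,
    epochs_per_patient: int = 30,
    level: float = 0.95,
) -> int:
    """Smallest patient count giving a kappa CI width <= ``max_ci_width``.

    Uses the kappa-as-proportion convention of this module: the full CI
    width is ``2 z sqrt(kappa0 (1-kappa0) / n_epochs)`` where ``n_epochs``
    pools ``epochs_per_patient`` stage epochs per patient.
    """
    if not 0.0 < kappa0 < 1.0:
        raise ValueError("kappa0 must lie in (0, 1)")
    if epochs_per_patient < 1:
        raise ValueError("epochs_per_patient must be >= 1")
    if max_ci_width <= 0:
        raise ValueError("max_ci_width must be positive")
    z = spstats.norm.ppf(0.5 + level / 2.0)
    n_epochs = (2.0 * z) ** 2 * kappa0 * (1.0 - kappa0) / max_ci_width**2
    return int(np.ceil(n_epochs / epochs_per_patient))


# ---------------------------------------------------------------------------
# I/O and reporting


def write_confusion_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.counts, index=list(cm.labels), columns=list(cm.labels)).to_csv(path)


def read_confusion_csv(path: str | Path) -> ConfusionMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = tuple(df.columns)
    return ConfusionMatrix(df.to_numpy(float), labels=labels)


def load_reference_confusion() -> ConfusionMatrix:
    """The pooled 5-stage confusion matrix from the clinical validation of
    the forehead single-lead device against in-lab PSG (106 patients,
    81 786 doubly-valid epochs), shipped with the package as a printed-
    table input."""
    with resources.files("somnoagree.data").joinpath("reference_confusion.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return ConfusionMatrix(df.to_numpy(float), labels=tuple(df.columns))


def agreement_report(cm: ConfusionMatrix) -> dict:
    """Stage-wise + overall endpoint table for a 5-stage confusion matrix."""
    cm4 = collapse4(cm)
    out: dict = {
        "overall_5stage": overall_metrics(cm),
        "overall_4stage": overall_metrics(cm4),
        "stages": {},
        "total_epochs": cm.total,
    }
    for name in STAGE_NAMES_5:
        m = stage_metrics(cm, name)
        out["stages"][name] = m.__dict__
    out["stages"]["Light"] = stage_metrics(cm4, "Light").__dict__
    return out
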