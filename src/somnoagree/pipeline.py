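"""End-to-end study orchestration.

``run_synthetic_study`` mirrors the flow of a device-validation trial on
a synthetic cohort: generate each patient's ground-truth hypnogram,
biopotential trace and pulse-rate pair; reject a fraction of device
epochs; preprocess to masked spectrogram epochs; run patient-wise
k-fold cross-validation of the staging model; apply the 30-min
overlapping-TST adequacy rule; and pool the survivors into the
agreement endpoint table, the continuity-parameter comparison with
Bland-Altman statistics, and an exclusion ledger (included + excluded
always totals the cohort).

``evaluate_recordings`` is the single-recording path: EDF + reference
hypnogram + PR trace pair + trained model → synchronized, predicted,
and scored report.

All randomness derives from one master seed through named substreams,
so the same config yields byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import agreement, hypnometrics
from .preprocess import condition_signal, spectrogram_epochs
from .ssm import ModelConfig, ModelParams, TrainSchedule, crossvalidate, predict
from .stages import Hypnogram, StageLabel, read_hypnogram_csv
from .sync import SyncModel, estimate_sync, read_pr_csv
from .synthgen import (
    PRRecipe,
    SignalRecipe,
    default_architecture,
    default_pr_recipe,
    default_recipe,
    generate_hypnogram,
    generate_pr_pair,
    inject_invalid,
    synthesize_biopotential,
)

__all__ = ["StudyConfig", "SyntheticPatient", "generate_patient", "run_synthetic_study",
           "evaluate_recordings"]

#: Named substreams derived from the master seed (order is part of the contract).
_STREAMS = ("hypnogram", "signal", "pr", "invalid", "cv", "syncshift")


@dataclass
class StudyConfig:
    n_patients: int = 20
    epochs_per_patient: int = 120
    invalid_fraction: float = 0.03
    cv_folds: int = 10
    adequacy_min: float = 30.0
    run_sync: bool = True
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    schedule: TrainSchedule = field(default_factory=lambda: TrainSchedule(iterations=150, batch_size=32))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        model = ModelConfig(**raw.pop("model", {}))
        schedule = TrainSchedule(**raw.pop("schedule", {}))
        return cls(model=model, schedule=schedule, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _substream(master_seed: int, stream: str, index: int) -> int:
    # stable per-stage seeds below 2**31
    base = np.random.SeedSequence([master_seed, _STREAMS.index(stream), index])
    return int(base.generate_state(1)[0] % (2**31))


@dataclass
class SyntheticPatient:
    patient_id: str
    reference: Hypnogram  # ground-truth (PSG-side) labels
    device_labels: Hypnogram  # reference labels with device-rejected epochs INVALID
    spectrogram: "object"
    true_shift_s: float
    true_stretch: float
    pr_pair: "object"


def generate_patient(
    config: StudyConfig,
    index: int,
    recipe: SignalRecipe | None = None,
    pr_recipe: PRRecipe | None = None,
) -> SyntheticPatient:
    """Generate one patient: hypnogram, signal, PR pair, rejected epochs."""
    recipe = recipe or default_recipe()
    pr_recipe = pr_recipe or default_pr_recipe()
    hyp = generate_hypnogram(
        default_architecture(config.epochs_per_patient, seed=_substream(config.seed, "hypnogram", index))
    )
    record = synthesize_biopotential(hyp, recipe, seed=_substream(config.seed, "signal", index))

    rng = np.random.default_rng(_substream(config.seed, "syncshift", index))
    true_shift = float(rng.uniform(-600.0, 600.0))
    true_stretch = float(rng.uniform(0.998, 1.002))
    pr_pair = generate_pr_pair(hyp, pr_recipe, true_shift, true_stretch,
                               seed=_substream(config.seed, "pr", index))

    device_labels = inject_invalid(hyp, config.invalid_fraction,
                                   seed=_substream(config.seed, "invalid", index))
    invalid_idx = np.flatnonzero(device_labels.labels == StageLabel.INVALID)
    spec = spectrogram_epochs(condition_signal(record), invalid_epochs=invalid_idx)
    return SyntheticPatient(
        patient_id=f"P{index:03d}",
        reference=hyp,
        device_labels=device_labels,
        spectrogram=spec,
        true_shift_s=true_shift,
        true_stretch=true_stretch,
        pr_pair=pr_pair,
    )


def _continuity_row(params: "hypnometrics.ContinuityParams") -> dict:
    return {k: v for k, v in asdict(params).items()}


def _paired_table(
    per_patient: dict[str, tuple[hypnometrics.ContinuityParams, hypnometrics.ContinuityParams]]
) -> dict:
    """Table-style paired stats for continuity parameters across patients."""
    fields = ["tst_min", "se_pct", "sol_min", "waso_min",
              "wake_min", "n1_min", "n2_min", "n3_min", "rem_min"]
    out = {}
    for f in fields:
        pairs = []
        for ref, dev in per_patient.values():
            a, b = getattr(ref, f), getattr(dev, f)
            if a is None or b is None:  # SOL/WASO undefined: excluded from aggregates
                continue
            pairs.append((a, b))
        if len(pairs) >= 3:
            out[f] = asdict(agreement.paired_stats(pairs))
        else:
            out[f] = None
    return out


def run_synthetic_study(config: StudyConfig, recipe: SignalRecipe | None = None) -> dict:
    """Simulate a full validation study; returns the report dictionary."""
    patients = [generate_patient(config, i, recipe=recipe) for i in range(config.n_patients)]

    exclusions: list[dict] = []
    # adequacy is assessed on doubly-valid sleep overlap of the reference
    # vs the device-side labels (prediction cannot rescue a test with no
    # usable co-recorded sleep)
    cohort: dict[str, SyntheticPatient] = {}
    for p in patients:
        if hypnometrics.overlapping_tst(p.reference, p.device_labels) >= config.adequacy_min:
            cohort[p.patient_id] = p
        else:
            exclusions.append({"patient": p.patient_id, "stage": "adequacy",
                               "reason": "under 30 min overlapping TST"})

    report: dict = {
        "config": {"n_patients": config.n_patients,
                   "epochs_per_patient": config.epochs_per_patient,
                   "invalid_fraction": config.invalid_fraction,
                   "cv_folds": config.cv_folds,
                   "seed": config.seed},
        "exclusions": exclusions,
        "n_included": len(cohort),
        "n_excluded": len(exclusions),
    }
    if not cohort:
        report["status"] = "no adequate patients"
        return report
    if len(cohort) < config.cv_folds:
        report["status"] = f"fewer adequate patients than folds ({len(cohort)} < {config.cv_folds})"
        return report

    sync_errors = {}
    if config.run_sync:
        for pid, p in cohort.items():
            model = estimate_sync(p.pr_pair.reference, p.pr_pair.device)
            sync_errors[pid] = {
                "shift_error_s": abs(model.shift_s - p.true_shift_s),
                "stretch_error": abs(model.stretch - p.true_stretch),
            }
        report["sync"] = {
            "per_patient": sync_errors,
            "max_shift_error_s": max(v["shift_error_s"] for v in sync_errors.values()),
        }

    cv_data = {pid: (p.spectrogram, Hypnogram(p.device_labels.labels)) for pid, p in cohort.items()}
    preds = crossvalidate(cv_data, config.model, k=config.cv_folds,
                          seed=_substream(config.seed, "cv", 0), schedule=config.schedule)

    counts = np.zeros((5, 5))
    continuity: dict[str, tuple] = {}
    for pid, (pred_hyp, _) in preds.items():
        p = cohort[pid]
        counts += agreement.build_confusion(p.reference, pred_hyp).counts
        continuity[pid] = (
            hypnometrics.continuity_params(p.reference),
            hypnometrics.continuity_params(pred_hyp),
        )

    cm = agreement.ConfusionMatrix(counts)
    report["confusion_matrix"] = counts.tolist()
    report["agreement"] = agreement.agreement_report(cm)
    report["continuity"] = _paired_table(continuity)
    report["status"] = "ok"
    return report


def evaluate_recordings(
    signal_edf: str | Path,
    reference_csv: str | Path,
    params_path: str | Path,
    config: ModelConfig,
    pr_ref_csv: str | Path | None = None,
    pr_dev_csv: str | Path | None = None,
    pre_aligned: bool = False,
    invalid_csv: str | Path | None = None,
) -> dict:
    """Score one device recording against its reference hypnogram."""
    from .edf import read_edf

    record = read_edf(signal_edf)
    reference = read_hypnogram_csv(reference_csv)
    params = ModelParams.load(params_path)

    if pre_aligned:
        sync_model = SyncModel(shift_s=0.0, stretch=1.0)
    else:
        if pr_ref_csv is None or pr_dev_csv is None:
            raise ValueError("PR traces required unless pre_aligned is set")
        sync_model = estimate_sync(read_pr_csv(pr_ref_csv), read_pr_csv(pr_dev_csv))

    invalid_idx: np.ndarray = np.array([], dtype=int)
    if invalid_csv is not None:
        import pandas as pd

        invalid_idx = pd.read_csv(invalid_csv)["epoch_index"].to_numpy(int)

    spec = spectrogram_epochs(condition_signal(record), invalid_epochs=invalid_idx)
    pred, _ = predict(params, spec, config)

    # align the device epoch grid onto the reference grid via the shift
    offset = int(round(sync_model.shift_s / 30.0))
    n = min(len(reference) - max(offset, 0), len(pred) + min(offset, 0))
    if n < 1:
        raise ValueError("no epoch overlap after synchronization")
    ref_al = Hypnogram(reference.labels[max(offset, 0): max(offset, 0) + n])
    dev_al = Hypnogram(pred.labels[max(-offset, 0): max(-offset, 0) + n])

    adequate = hypnometrics.adequacy(ref_al, dev_al)
    out = {
        "sync": {"shift_s": sync_model.shift_s, "stretch": sync_model.stretch},
        "epoch_offset": offset,
        "adequate": bool(adequate),
        "overlapping_tst_min": hypnometrics.overlapping_tst(ref_al, dev_al),
    }
    if adequate:
        cm = agreement.build_confusion(ref_al, dev_al)
        out["agreement"] = agreement.agreement_report(cm)
        out["continuity_reference"] = _continuity_row(hypnometrics.continuity_params(ref_al))
        out["continuity_device"] = _continuity_row(hypnometrics.continuity_params(dev_al))
    return out


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
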