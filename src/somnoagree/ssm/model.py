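"""Sleep-staging model: training, prediction, transfer, cross-validation.

Wraps the NumPy network of :mod:`somnoagree.ssm.network` with the
clinical workflow: per-patient spectrogram/label alignment, a supervised
Invalid class for rejected epochs, transfer learning (a base model
pretrained on a source-montage corpus fine-tuned on the target montage),
and patient-wise k-fold cross-validation so that every patient is
predicted by a model that never saw them.

Deterministic contracts: tie-breaks on equal probabilities pick the
lowest stage index (WAKE < N1 < N2 < N3 < REM); masked epochs always
emit INVALID; an unmasked epoch whose argmax is the Invalid class is
assigned its runner-up physiological stage, so valid epochs always carry
a 5-stage label.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ..preprocess import SpectrogramEpochs
from ..stages import Hypnogram, StageLabel
from . import network as nn

__all__ = [
    "ModelConfig",
    "TrainSchedule",
    "ModelParams",
    "FoldPlan",
    "build_fold_plan",
    "train",
    "predict",
    "crossvalidate",
    "iterations_to_kappa",
    "pooled_kappa",
]

N_CLASSES = 6  # five stages + Invalid
_CLIP = 7.5  # standardized log-power values are clipped to ±_CLIP


@dataclass(frozen=True)
class ModelConfig:
    filterbank_size: int = 16
    epoch_hidden: int = 16
    sequence_hidden: int = 16
    attention_size: int = 16
    sequence_length: int = 20  # epochs per training sequence
    class_count: int = N_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("filterbank_size", "epoch_hidden", "sequence_hidden",
                     "attention_size", "sequence_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.class_count != N_CLASSES:
            raise ValueError("class_count must be 6 (five stages + Invalid)")

    @property
    def hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TrainSchedule:
    iterations: int = 300
    batch_size: int = 64
    learning_rate: float = 3e-3
    eval_every: int = 25


@dataclass
class ModelParams:
    """Learned parameters plus provenance and input standardization."""

    weights: dict[str, np.ndarray]
    config_hash: str
    provenance: str = "base"  # base | finetuned
    input_mean: float = 0.0
    input_std: float = 1.0
    loss_history: list[float] = field(default_factory=list, repr=False)

    def copy(self) -> "ModelParams":
        return ModelParams(
            weights={k: v.copy() for k, v in self.weights.items()},
            config_hash=self.config_hash,
            provenance=self.provenance,
            input_mean=self.input_mean,
            input_std=self.input_std,
            loss_history=list(self.loss_history),
        )

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            __config_hash=np.array(self.config_hash),
            __provenance=np.array(self.provenance),
            __input_mean=np.array(self.input_mean),
            __input_std=np.array(self.input_std),
            **self.weights,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        with np.load(path) as z:
            weights = {k: z[k] for k in z.files if not k.startswith("__")}
            return cls(
                weights=weights,
                config_hash=str(z["__config_hash"]),
                provenance=str(z["__provenance"]),
                input_mean=float(z["__input_mean"]),
                input_std=float(z["__input_std"]),
            )


# ---------------------------------------------------------------------------
# data plumbing


def _standardize(params: ModelParams, values: np.ndarray) -> np.ndarray:
    x = (values.astype(np.float32) - np.float32(params.input_mean)) / np.float32(params.input_std)
    return np.clip(x, -_CLIP, _CLIP)


def _windows(n_epochs: int, length: int) -> list[tuple[int, int]]:
    """Cover 0..n_epochs with windows of ``length`` epochs.

    Non-overlapping windows plus, when a remainder exists and the record
    is long enough, one final window ending at the last epoch (it
    overlaps its predecessor; callers that predict keep only the tail).
    """
    if n_epochs <= length:
        return [(0, n_epochs)]
    starts = list(range(0, n_epochs - length + 1, length))
    out = [(s, s + length) for s in starts]
    if out[-1][1] < n_epochs:
        out.append((n_epochs - length, n_epochs))
    return out


def _training_set(
    data: list[tuple[SpectrogramEpochs, Hypnogram]], config: ModelConfig, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (sequences, labels) arrays from per-patient epoch data."""
    L = config.sequence_length
    xs, ys = [], []
    for spec, hyp in data:
        if spec.n_epochs != len(hyp):
            raise ValueError("spectrogram epochs and hypnogram labels must align 1:1")
        vals = _standardize(params, spec.values)
        for a, b in _windows(spec.n_epochs, L):
            if b - a < L:  # short record: pad with floored (invalid) epochs
                pad = np.full((L - (b - a),) + vals.shape[1:], -_CLIP, dtype=vals.dtype)
                xs.append(np.concatenate([vals[a:b], pad], axis=0))
                ys.append(
                    np.concatenate([hyp.labels[a:b], np.full(L - (b - a), StageLabel.INVALID)])
                )
            else:
                xs.append(vals[a:b])
                ys.append(hyp.labels[a:b])
    return np.stack(xs), np.stack(ys).astype(int)


# ---------------------------------------------------------------------------
# training


def _fresh_params(config: ModelConfig, n_bins: int) -> ModelParams:
    weights = nn.init_params(
        n_bins=n_bins,
        filterbank=config.filterbank_size,
        epoch_hidden=config.epoch_hidden,
        seq_hidden=config.sequence_hidden,
        attention=config.attention_size,
        n_classes=config.class_count,
        seed=config.seed,
    )
    # float32 throughout training: halves memory traffic of the BPTT loops
    weights = {k: v.astype(np.float32) for k, v in weights.items()}
    return ModelParams(weights=weights, config_hash=config.hash)


def train(
    init: ModelParams | None,
    data: list[tuple[SpectrogramEpochs, Hypnogram]],
    config: ModelConfig,
    schedule: TrainSchedule = TrainSchedule(),
    callback=None,
) -> ModelParams:
    """Train (or fine-tune, when ``init`` is given) the staging network.

    The Invalid class is supervised exactly like the physiological
    stages: rejected epochs keep their place in each sequence with
    floor-valued spectra and the Invalid label, so the sequence-level
    layer learns to carry context across measurement gaps.

    ``callback(iteration, params)`` — optional hook evaluated every
    ``schedule.eval_every`` iterations; a truthy return stops training
    early (used for iterations-to-threshold experiments).
    """
    if not data:
        raise ValueError("no training data")
    n_bins = data[0][0].values.shape[2]
    if init is None:
        params = _fresh_params(config, n_bins)
        # input standardization from the training corpus (valid epochs only)
        vals = np.concatenate(
            [s.values[s.valid_mask].ravel() for s, _ in data if np.any(s.valid_mask)]
        )
        if vals.size == 0:
            raise ValueError("no valid epochs in training data")
        params.input_mean = float(vals.mean())
        params.input_std = float(vals.std() + 1e-12)
    else:
        if init.config_hash != config.hash:
            raise ValueError("init params were built for a different ModelConfig")
        params = init.copy()
        params.provenance = "finetuned"
    if params.weights["Wf"].shape[0] != n_bins:
        raise ValueError("spectrogram bin count does not match the model's filter bank")

    x_all, y_all = _training_set(data, config, params)
    n_seq = x_all.shape[0]
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(params.weights, lr=schedule.learning_rate)

    for it in range(1, schedule.iterations + 1):
        idx = rng.choice(n_seq, size=min(schedule.batch_size, n_seq), replace=False)
        loss, grads, _ = nn.loss_and_grads(params.weights, x_all[idx], y_all[idx])
        opt.step(params.weights, grads)
        params.loss_history.append(loss)
        if callback is not None and (it % schedule.eval_every == 0 or it == schedule.iterations):
            if callback(it, params):
                break
    return params


# ---------------------------------------------------------------------------
# prediction


def predict(params: ModelParams, spec: SpectrogramEpochs, config: ModelConfig
            ) -> tuple[Hypnogram, np.ndarray]:
    """Predict a hypnogram and per-epoch 5-stage probability vectors.

    Masked epochs emit INVALID (their probability row is NaN); on valid
    epochs the 6-class posterior is renormalized over the five
    physiological stages, so rows sum to 1 and the label is the argmax
    with lowest-stage-index tie-break.
    """
    if params.config_hash != config.hash:
        raise ValueError("params/config mismatch")
    L = config.sequence_length
    n = spec.n_epochs
    vals = _standardize(params, spec.values)
    probs6 = np.zeros((n, N_CLASSES))
    covered = np.zeros(n, dtype=bool)
    for a, b in _windows(n, L):
        w = vals[a:b]
        if b - a < L:
            w = np.concatenate(
                [w, np.full((L - (b - a),) + w.shape[1:], -_CLIP, dtype=w.dtype)], axis=0
            )
        logits, _ = nn.forward(params.weights, w[None])
        p = nn.softmax(logits[0][: b - a])
        fresh = ~covered[a:b]
        probs6[a:b][fresh] = p[fresh]
        covered[a:b] = True

    stage_probs = probs6[:, :5]
    with np.errstate(invalid="ignore"):
        stage_probs = stage_probs / stage_probs.sum(axis=1, keepdims=True)
    # argmax with lowest-index tie-break (np.argmax returns first maximum)
    labels = np.argmax(stage_probs, axis=1).astype(np.int8)
    labels[~spec.valid_mask] = StageLabel.INVALID
    stage_probs[~spec.valid_mask] = np.nan
    return Hypnogram(labels), stage_probs


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class FoldPlan:
    """Exhaustive, disjoint patient → fold assignment with sizes differing <= 1."""

    assignment: dict[str, int]
    k: int

    def fold(self, fold_index: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold_index]


def build_fold_plan(patient_ids: list[str], k: int, seed: int) -> FoldPlan:
    if k > len(patient_ids):
        raise ValueError("k exceeds the number of patients")
    rng = np.random.default_rng(seed)
    order = list(patient_ids)
    rng.shuffle(order)
    return FoldPlan({pid: i % k for i, pid in enumerate(order)}, k=k)


def pooled_kappa(pairs: list[tuple[Hypnogram, Hypnogram]]) -> float:
    """Pooled 5-stage Cohen's kappa over (reference, predicted) hypnograms."""
    from ..agreement import ConfusionMatrix, build_confusion, overall_metrics

    counts = np.zeros((5, 5))
    for ref, pred in pairs:
        counts += build_confusion(ref, pred).counts
    return overall_metrics(ConfusionMatrix(counts))["kappa"]


def crossvalidate(
    patients: dict[str, tuple[SpectrogramEpochs, Hypnogram]],
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    base: ModelParams | None = None,
    schedule: TrainSchedule = TrainSchedule(),
) -> dict[str, tuple[Hypnogram, np.ndarray]]:
    """Patient-wise k-fold cross-validation.

    Each patient is predicted exactly once, by a model adapted on the
    folds that exclude them (fine-tuned from ``base`` when given, else
    trained fresh).  Returns per-patient (predicted hypnogram, 5-stage
    probabilities).
    """
    plan = build_fold_plan(sorted(patients), k, seed)
    out: dict[str, tuple[Hypnogram, np.ndarray]] = {}
    for fold in range(k):
        held = plan.fold(fold)
        train_data = [patients[p] for p in sorted(patients) if plan.assignment[p] != fold]
        fold_config = replace(config, seed=config.seed + fold)
        params = train(base, train_data, fold_config if base is None else config,
                       schedule=schedule)
        cfg = fold_config if base is None else config
        for pid in held:
            out[pid] = predict(params, patients[pid][0], cfg)
    return out


def iterations_to_kappa(
    train_data: list[tuple[SpectrogramEpochs, Hypnogram]],
    val_data: list[tuple[SpectrogramEpochs, Hypnogram]],
    config: ModelConfig,
    threshold: float,
    init: ModelParams | None = None,
    schedule: TrainSchedule = TrainSchedule(),
) -> float:
    """First iteration count at which pooled validation kappa >= threshold.

    Returns ``inf`` when the threshold is never reached within the
    schedule.  Used to quantify the training-efficiency benefit of
    transfer learning.
    """
    hit: list[float] = []

    def cb(it: int, params: ModelParams) -> bool:
        pairs = [(hyp, predict(params, spec, config)[0]) for spec, hyp in val_data]
        if pooled_kappa(pairs) >= threshold:
            hit.append(it)
            return True
        return False

    train(init, train_data, config, schedule=schedule, callback=cb)
    return hit[0] if hit else float("inf")
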