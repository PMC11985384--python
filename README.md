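# somnoagree

A pipeline for evaluating single-lead wearable sleep-staging devices
against polysomnography (PSG), built around the validation workflow used
for forehead biopotential home-sleep-testing sensors: synthetic study
cohorts with known ground truth, signal preprocessing to spectrogram
epochs, a hierarchical recurrent sleep stager with transfer learning and
patient-wise cross-validation, pulse-rate-based time synchronization,
hypnogram-derived sleep parameters, and the full pooled
agreement-statistics battery (confusion matrices, Cohen's κ, Bland-Altman
limits of agreement).

## Who this is for

Sleep researchers and device engineers who need to (a) prototype and
stress-test the statistical endpoint machinery of a staging-device
validation study before any clinical data exist, and (b) rescore
published confusion matrices into comparable endpoint tables.

## The problem and the model

A wearable device scores each 30-second epoch of a night into one of
five stages (Wake, N1, N2, N3, REM); a concurrent PSG scored by a
technician provides the reference hypnogram. Agreement is summarized by
the pooled reference-by-device confusion matrix **C** over all
doubly-valid epochs, from which the package computes:

- overall accuracy `Po = tr(C)/N` and Cohen's kappa
  `κ = (Po − Pe)/(1 − Pe)` with chance agreement
  `Pe = Σᵢ (rowᵢ/N)(colᵢ/N)`;
- one-vs-rest stage sensitivity, specificity, accuracy and κ, plus the
  four-stage variant with N1+N2 collapsed to Light Sleep;
- normal-approximation 95% half-widths `z·√(p(1−p)/N)` for all
  proportion-scale endpoints;
- per-patient continuity parameters — TRT, TST, SE = TST/TRT·100%, sleep
  onset latency (first run of ≥3 consecutive sleep epochs), WASO — with
  Bland-Altman bias and limits of agreement `bias ± 1.96·SD(diff)` and
  Fisher-z Pearson intervals;
- the 30-minute overlapping-TST technical-adequacy rule.

The staging model itself is a hierarchical recurrent network over STFT
log-power spectrograms (2-s Hamming windows, 50% overlap,
`20·log10|X|`): a learned frequency filter bank, an epoch-level
bidirectional attention RNN over the 29 frames of each epoch, a
sequence-level bidirectional RNN over consecutive epoch embeddings, and
a softmax over six classes (five stages plus an Invalid class for
rejected epochs). It is implemented in NumPy with explicit
backpropagation and trains at desk scale on CPU. Device and reference
timelines are aligned by maximizing the normalized cross-correlation of
their pulse-rate traces over a shift and a linear clock stretch.

## Worked example

Rescoring the packaged clinical confusion matrix (106 patients, 81 786
pooled epochs, forehead single-lead device vs in-lab PSG):

```python
from somnoagree.agreement import (collapse4, load_reference_confusion,
                                  overall_metrics, stage_metrics)

cm = load_reference_confusion()
m5 = overall_metrics(cm)
m4 = overall_metrics(collapse4(cm))
print(f"5-stage: accuracy {m5['accuracy']:.3f} +/- {m5['accuracy_ci']:.3f}, "
      f"kappa {m5['kappa']:.3f} +/- {m5['kappa_ci']:.3f}")
print(f"4-stage: accuracy {m4['accuracy']:.3f} +/- {m4['accuracy_ci']:.3f}, "
      f"kappa {m4['kappa']:.3f} +/- {m4['kappa_ci']:.3f}")
rem = stage_metrics(cm, "REM")
print(f"REM: sens {rem.sensitivity:.3f}, spec {rem.specificity:.3f}, kappa {rem.kappa:.3f}")
```

prints

```
5-stage: accuracy 0.797 +/- 0.003, kappa 0.696 +/- 0.003
4-stage: accuracy 0.820 +/- 0.003, kappa 0.708 +/- 0.003
REM: sens 0.795, spec 0.975, kappa 0.780
```

i.e. the device agrees with PSG on 79.7% of epochs, substantially above
chance (κ ≈ 0.70), and REM — the stage this electrode placement was
designed for — is detected with κ 0.78. Synchronizing a clock-skewed
pulse-rate trace pair:

```python
from somnoagree.synthgen import (generate_hypnogram, default_architecture,
                                 generate_pr_pair, default_pr_recipe)
from somnoagree.sync import estimate_sync

hyp = generate_hypnogram(default_architecture(840, seed=3))        # a 7-h night
pair = generate_pr_pair(hyp, default_pr_recipe(),
                        true_shift_s=12.3, true_stretch=1.0005, seed=7)
model = estimate_sync(pair.reference, pair.device)
print(f"estimated shift {model.shift_s:.3f} s (truth 12.300), "
      f"stretch {model.stretch:.6f} (truth 1.000500)")
```

prints

```
estimated shift 12.304 s (truth 12.300), stretch 1.000500 (truth 1.000500)
```

— a 4 ms synchronization error, well inside the 100 ms requirement.

A full synthetic validation study (cohort generation → preprocessing →
patient-wise 10-fold cross-validation → adequacy filter → endpoint
report) runs from the shell:

```
somnoagree simulate --seed 0 --out report.json
```

Other subcommands (`preprocess`, `train`, `predict`, `sync`, `metrics`,
`agree`) expose the individual stages; see `somnoagree --help`.

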