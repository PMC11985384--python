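from dataclasses import replace

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as spstats

from somnoagree.stages import Hypnogram, StageLabel
from somnoagree.synthgen import (
    BANDS,
    ArchitectureSpec,
    default_architecture,
    default_pr_recipe,
    default_recipe,
    generate_hypnogram,
    generate_pr_pair,
    inject_invalid,
    synthesize_biopotential,
)
from somnoagree.sync import SyncModel, apply_sync


def constant_hypnogram(stage: StageLabel, epochs: int) -> Hypnogram:
    return Hypnogram(np.full(epochs, int(stage), dtype=np.int8))


def band_fraction(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Periodogram oracle: power in `band` over total power in 0.5-35 Hz."""
    f, p = sps.welch(x, fs=fs, nperseg=int(8 * fs))
    total = p[(f >= 0.5) & (f <= 35.0)].sum()
    return p[(f >= band[0]) & (f <= band[1])].sum() / total


class TestGenerateHypnogram:
    def test_absorbing_wake_chain_stays_wake(self):
        tm = np.eye(5)
        spec = ArchitectureSpec(tm, np.array([1.0, 0, 0, 0, 0]), epochs_total=50, seed=1)
        h = generate_hypnogram(spec)
        assert np.all(h.labels == StageLabel.WAKE)

    def test_seeded_determinism(self):
        spec = default_architecture(500, seed=7)
        a, b = generate_hypnogram(spec), generate_hypnogram(spec)
        assert np.array_equal(a.labels, b.labels)

    def test_invalid_transition_matrix_rejected(self):
        tm = np.full((5, 5), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            ArchitectureSpec(tm, np.array([1.0, 0, 0, 0, 0]), epochs_total=10)

    def test_stage_fractions_match_stationary_distribution(self):
        # oracle: stationary distribution by eigen-decomposition, with the
        # i.i.d. standard error inflated for the chain's autocorrelation
        # via the second-largest eigenvalue modulus
        spec = default_architecture(960, seed=11)
        tm = spec.transition_matrix
        w, v = np.linalg.eig(tm.T)
        order = np.argsort(-np.abs(w))
        pi = np.real(v[:, order[0]])
        pi = pi / pi.sum()
        lam2 = float(np.abs(w[order[1]]))
        inflate = np.sqrt((1 + lam2) / (1 - lam2))

        h = generate_hypnogram(spec)
        frac = np.bincount(h.labels, minlength=5) / len(h)
        se = np.sqrt(pi * (1 - pi) / len(h)) * inflate
        assert np.all(np.abs(frac - pi) <= 3 * se)


class TestSynthesizeBiopotential:
    def test_rejects_invalid_epochs_and_empty(self):
        bad = Hypnogram(np.array([0, 5], dtype=np.int8))
        with pytest.raises(ValueError, match="INVALID"):
            synthesize_biopotential(bad, default_recipe(), seed=0)

    def test_duration_and_rate(self):
        h = constant_hypnogram(StageLabel.N2, 4)
        rec = synthesize_biopotential(h, default_recipe(), seed=0)
        assert rec.sampling_rate == 256.0
        assert rec.samples.size == 4 * 30 * 256

    def test_n3_delta_fraction_matches_recipe(self):
        recipe = replace(
            default_recipe(), emg_level={s: 0.0 for s in StageLabel if s != StageLabel.INVALID}
        )
        h = constant_hypnogram(StageLabel.N3, 20)
        rec = synthesize_biopotential(h, recipe, seed=3)
        fracs = {b: band_fraction(rec.samples, rec.sampling_rate, rng) for b, rng in BANDS.items()}
        w = np.asarray(recipe.band_power[StageLabel.N3])
        target_delta = w[0] / w.sum()
        assert max(fracs, key=fracs.get) == "delta"
        assert abs(fracs["delta"] - target_delta) / target_delta < 0.10

    def test_wake_vs_n3_alpha_delta_ratio(self):
        h_w = constant_hypnogram(StageLabel.WAKE, 10)
        h_3 = constant_hypnogram(StageLabel.N3, 10)
        recipe = default_recipe()
        xw = synthesize_biopotential(h_w, recipe, seed=4).samples
        x3 = synthesize_biopotential(h_3, recipe, seed=4).samples
        fs = recipe.sampling_rate
        ratio_w = band_fraction(xw, fs, BANDS["alpha"]) / band_fraction(xw, fs, BANDS["delta"])
        ratio_3 = band_fraction(x3, fs, BANDS["alpha"]) / band_fraction(x3, fs, BANDS["delta"])
        assert ratio_w > ratio_3

    @pytest.mark.parametrize("stage", [StageLabel.WAKE, StageLabel.N3, StageLabel.REM])
    def test_dominant_band_matches_recipe_ranking(self, stage):
        recipe = replace(
            default_recipe(),
            emg_level={s: 0.0 for s in StageLabel if s != StageLabel.INVALID},
            rem_deflection_amplitude=0.0,
            spindle_amplitude=0.0,
        )
        h = constant_hypnogram(stage, 15)
        rec = synthesize_biopotential(h, recipe, seed=int(stage))
        fracs = [band_fraction(rec.samples, rec.sampling_rate, rng) for rng in BANDS.values()]
        assert int(np.argmax(fracs)) == int(np.argmax(recipe.band_power[stage]))

    def test_rem_deflection_events(self):
        # noiseless configuration: background far below the event amplitude
        recipe = replace(
            default_recipe(),
            scale_uv=0.5,
            emg_level={s: 0.0 for s in StageLabel if s != StageLabel.INVALID},
            rem_deflection_rate=5.0,
            rem_deflection_amplitude=100.0,
        )
        h = constant_hypnogram(StageLabel.REM, 20)  # 10 min
        rec = synthesize_biopotential(h, recipe, seed=9)
        x = rec.samples
        thresh = 50.0
        pos = np.flatnonzero(np.diff((x > thresh).astype(int)) == 1)
        neg = np.flatnonzero(np.diff((x < -thresh).astype(int)) == 1)
        lo, hi = spstats.poisson.interval(0.99, 50)
        assert lo <= pos.size <= hi
        # lobes come in opposite-polarity pairs: negative onset shortly
        # after each positive onset (tolerate rare overlapping events)
        paired = sum(
            bool(np.any((neg > p) & (neg < p + int(0.6 * rec.sampling_rate)))) for p in pos
        )
        assert paired >= 0.9 * pos.size
        assert abs(pos.size - neg.size) <= 2


class TestGeneratePRPair:
    def test_identity_mapping_noiseless(self):
        h = generate_hypnogram(default_architecture(40, seed=0))
        recipe = replace(default_pr_recipe(), noise_bpm=0.0)
        pair = generate_pr_pair(h, recipe, true_shift_s=0.0, true_stretch=1.0, seed=0)
        assert np.allclose(pair.device.values, pair.reference.values)

    def test_values_within_physiological_bounds(self):
        h = generate_hypnogram(default_architecture(120, seed=2))
        pair = generate_pr_pair(h, default_pr_recipe(), 30.0, 1.0005, seed=2)
        for tr in (pair.reference, pair.device):
            assert tr.values.min() >= 40.0 and tr.values.max() <= 120.0

    def test_ground_truth_invertible_noiseless(self):
        # applying the true mapping to device times lands on reference samples
        h = generate_hypnogram(default_architecture(60, seed=3))
        recipe = replace(default_pr_recipe(), noise_bpm=0.0)
        pair = generate_pr_pair(h, recipe, true_shift_s=17.0, true_stretch=1.0004, seed=3)
        truth = SyncModel(shift_s=17.0, stretch=1.0004)
        warped = apply_sync(pair.device.times, truth)
        expect = np.interp(warped, pair.reference.times, pair.reference.values)
        assert np.allclose(expect, pair.device.values, atol=1e-9)

    def test_rejects_bad_stretch(self):
        h = generate_hypnogram(default_architecture(40, seed=0))
        with pytest.raises(ValueError):
            generate_pr_pair(h, default_pr_recipe(), 0.0, -1.0, seed=0)
        with pytest.raises(ValueError):
            generate_pr_pair(h, default_pr_recipe(), 0.0, 1.05, seed=0)


class TestInjectInvalid:
    def test_fraction_zero_is_noop(self):
        h = generate_hypnogram(default_architecture(100, seed=1))
        out = inject_invalid(h, 0.0, seed=5)
        assert np.array_equal(out.labels, h.labels)

    def test_binomial_count(self):
        h = generate_hypnogram(default_architecture(1000, seed=1))
        out = inject_invalid(h, 0.1, seed=6)
        lo, hi = spstats.binom.interval(0.99, 1000, 0.1)
        n_inv = int(np.sum(out.labels == StageLabel.INVALID))
        assert lo <= n_inv <= hi
        assert np.array_equal(out.truth, h.labels)

    def test_fraction_one_all_invalid(self):
        h = generate_hypnogram(default_architecture(50, seed=1))
        out = inject_invalid(h, 1.0, seed=7)
        assert np.all(out.labels == StageLabel.INVALID)
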