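import numpy as np
import pytest

from somnoagree.agreement import (
    ConfusionMatrix,
    build_confusion,
    collapse4,
    load_reference_confusion,
    overall_metrics,
    paired_stats,
    proportion_ci,
    read_confusion_csv,
    sample_size_kappa,
    stage_metrics,
    write_confusion_csv,
)
from somnoagree.stages import Hypnogram

from .conftest import stage_codes


@pytest.fixture(scope="module")
def clinical_cm():
    return load_reference_confusion()


class TestBuildConfusion:
    def test_identical_hypnograms_diagonal(self):
        h = stage_codes("W N1 N2 N3 R N2 N2 W")
        cm = build_confusion(h, h)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert cm.total == 8

    def test_invalid_epochs_excluded_pairwise(self):
        ref = stage_codes("W N2 N2 INV")
        dev = stage_codes("W INV N2 N2")
        cm = build_confusion(ref, dev)
        assert cm.total == 2  # epochs 0 and 2 only

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_confusion(stage_codes("W"), stage_codes("W W"))


class TestCollapse4:
    def test_clinical_matrix_total_preserved(self, clinical_cm):
        cm4 = collapse4(clinical_cm)
        assert cm4.total == 81786
        assert cm4.labels == ("Wake", "Light", "N3", "REM")

    def test_unaffected_margins(self, clinical_cm):
        cm4 = collapse4(clinical_cm)
        for name in ("Wake", "N3", "REM"):
            m5 = stage_metrics(clinical_cm, name)
            m4 = stage_metrics(cm4, name)
            assert m5.sensitivity == pytest.approx(m4.sensitivity)
            assert m5.specificity == pytest.approx(m4.specificity)
            assert m5.kappa == pytest.approx(m4.kappa)

    def test_zero_matrix(self):
        cm4 = collapse4(ConfusionMatrix(np.zeros((5, 5))))
        assert np.all(cm4.counts == 0)


class TestClinicalEndpointReproduction:
    """The published endpoint table recomputed from the printed matrix."""

    def test_overall(self, clinical_cm):
        m5 = overall_metrics(clinical_cm)
        assert round(m5["accuracy"], 3) == 0.797
        assert round(m5["kappa"], 3) == 0.696
        m4 = overall_metrics(collapse4(clinical_cm))
        assert round(m4["accuracy"], 3) == 0.820
        assert round(m4["kappa"], 3) == 0.708

    @pytest.mark.parametrize(
        "stage,sens,spec,acc,kappa",
        [
            # expected values are the exact recomputation from the matrix;
            # the published table prints Wake specificity 0.938 (vs 0.937),
            # N1 kappa 0.444 (vs 0.4435) and REM specificity 0.976 (vs
            # 0.9755) — all within one unit of the last printed digit
            ("Wake", 0.842, 0.937, 0.915, 0.765),
            ("N1", 0.472, 0.971, 0.945, 0.443),
            ("N2", 0.815, 0.875, 0.844, 0.688),
            ("N3", 0.758, 0.951, 0.936, 0.615),
            ("REM", 0.795, 0.975, 0.954, 0.780),
        ],
    )
    def test_stage_rows(self, clinical_cm, stage, sens, spec, acc, kappa):
        m = stage_metrics(clinical_cm, stage)
        assert round(m.sensitivity, 3) == sens
        assert round(m.specificity, 3) == spec
        assert round(m.accuracy, 3) == acc
        assert round(m.kappa, 3) == kappa

    def test_all_printed_values_within_one_ulp(self, clinical_cm):
        printed = {
            "Wake": (0.842, 0.938, 0.915, 0.765),
            "N1": (0.472, 0.971, 0.945, 0.444),
            "N2": (0.815, 0.875, 0.844, 0.688),
            "N3": (0.758, 0.951, 0.936, 0.615),
            "REM": (0.795, 0.976, 0.954, 0.780),
        }
        for stage, (sens, spec, acc, kappa) in printed.items():
            m = stage_metrics(clinical_cm, stage)
            # Wake specificity is the documented outlier: recomputes to
            # 0.9367 against a printed 0.938 (gap 0.0013)
            spec_tol = 1.4e-3 if stage == "Wake" else 1.1e-3
            assert m.sensitivity == pytest.approx(sens, abs=1.1e-3)
            assert m.specificity == pytest.approx(spec, abs=spec_tol)
            assert m.accuracy == pytest.approx(acc, abs=1.1e-3)
            assert m.kappa == pytest.approx(kappa, abs=1.1e-3)

    def test_light_sleep_row(self, clinical_cm):
        m = stage_metrics(collapse4(clinical_cm), "Light")
        assert round(m.sensitivity, 3) == 0.824
        assert round(m.kappa, 3) == 0.666


class TestStageAndOverallProperties:
    def test_diagonal_matrix_perfect_metrics(self):
        cm = ConfusionMatrix(np.diag([5.0, 4, 3, 2, 1]))
        for name in cm.labels:
            m = stage_metrics(cm, name)
            assert (m.sensitivity, m.specificity, m.accuracy, m.kappa) == (1, 1, 1, 1)
        assert overall_metrics(cm)["kappa"] == 1.0

    def test_rank_one_matrix_zero_kappa(self):
        # a device always answering N2: agreement is pure chance
        counts = np.zeros((5, 5))
        counts[:, 2] = [10, 5, 40, 8, 12]
        m = overall_metrics(ConfusionMatrix(counts))
        assert m["kappa"] == pytest.approx(0.0, abs=1e-12)

    def test_absent_reference_stage_flagged(self):
        counts = np.zeros((5, 5))
        counts[0, 0] = 10
        counts[2, 2] = 5
        assert stage_metrics(ConfusionMatrix(counts), "REM").sensitivity is None

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            overall_metrics(ConfusionMatrix(np.zeros((5, 5))))


class TestProportionCI:
    def test_published_halfwidths(self, clinical_cm):
        n = clinical_cm.total
        assert round(proportion_ci(0.797, n), 3) == 0.003
        for kappa in (0.696, 0.444, 0.780):  # overall, N1, REM kappas
            assert round(proportion_ci(kappa, n), 3) == 0.003

    def test_closed_form_values(self):
        assert proportion_ci(0.0, 100) == 0.0
        assert proportion_ci(0.5, 9604) == pytest.approx(0.0100, abs=1e-4)

    def test_shrinks_as_inverse_sqrt_n(self):
        assert proportion_ci(0.3, 400) == pytest.approx(proportion_ci(0.3, 100) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(0.5, 0)
        with pytest.raises(ValueError):
            proportion_ci(1.5, 10)


class TestPairedStats:
    def test_identical_pairs(self):
        s = paired_stats([(300.0, 300.0), (250.0, 250.0), (400.0, 400.0)])
        assert s.bias == 0.0
        assert s.loa_low == s.loa_high == 0.0
        assert s.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        s = paired_stats([(300.0, 295.0), (250.0, 245.0), (400.0, 395.0)])
        assert s.bias == pytest.approx(5.0)
        assert s.loa_high - s.loa_low == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_margin_flags_r(self):
        s = paired_stats([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])
        assert s.pearson_r is None and s.pearson_ci is None

    def test_loa_bracket_bias(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(300, 40, 30)
        dev = ref + rng.normal(-5, 10, 30)
        s = paired_stats(np.c_[ref, dev])
        assert s.loa_low <= s.bias <= s.loa_high

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_stats([(1.0, 2.0), (2.0, 3.0)])


class TestSampleSizeKappa:
    def test_reference_case(self):
        # width 0.1 at kappa 0.3, 30 pooled N1 epochs per patient
        assert sample_size_kappa(0.1, 0.3, 30) == 11

    def test_halving_epochs_never_decreases(self):
        for e in (60, 30, 15, 8, 4):
            assert sample_size_kappa(0.1, 0.3, e) <= sample_size_kappa(0.1, 0.3, e // 2)

    def test_maximized_at_half(self):
        n_half = sample_size_kappa(0.1, 0.5, 30)
        for k0 in (0.1, 0.3, 0.7, 0.9):
            assert sample_size_kappa(0.1, k0, 30) <= n_half

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_size_kappa(0.1, 0.0, 30)
        with pytest.raises(ValueError):
            sample_size_kappa(-0.1, 0.3, 30)


def test_confusion_csv_roundtrip(tmp_path, clinical_cm):
    p = tmp_path / "cm.csv"
    write_confusion_csv(clinical_cm, p)
    back = read_confusion_csv(p)
    assert np.array_equal(back.counts, clinical_cm.counts)
    assert back.labels == clinical_cm.labels
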