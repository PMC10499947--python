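"""Confusion tallies, binary metrics, per-class/macro F1, CV harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afnet import ECGSynthConfig, generate_dataset
from afnet.metrics import (
    ConfusionCounts,
    binary_metrics,
    confusion,
    evaluate_predictions,
    f1_per_class,
    format_confusion,
    macro_f1,
    multiclass_confusions,
    tenfold_cv,
)
from afnet.nn import AFNet, DenseNetConfig, RecurrentConfig
from afnet.preprocess import segment_and_normalize
from afnet.training import TrainConfig


def _brute_force(y_true, y_pred, positive):
    """Independent per-sample recount."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive and p == positive:
            tp += 1
        elif t != positive and p == positive:
            fp += 1
        elif t != positive and p != positive:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert (c.fp, c.fn) == (0, 0)

    def test_all_predicted_positive(self):
        c = confusion([1, 0, 0, 1], [1, 1, 1, 1])
        assert c.tn == 0 and c.fp == 2

    def test_tallies_partition_n(self, rng):
        y = rng.integers(0, 2, size=57)
        p = rng.integers(0, 2, size=57)
        assert confusion(y, p).total == 57

    def test_matches_brute_force_recount(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 40))
            y = rng.integers(0, 2, size=n)
            p = rng.integers(0, 2, size=n)
            c = confusion(y, p)
            assert (c.tp, c.fp, c.tn, c.fn) == _brute_force(y, p, 1)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import confusion_matrix

        y = rng.integers(0, 2, size=500)
        p = rng.integers(0, 2, size=500)
        c = confusion(y, p)
        (tn, fp), (fn, tp) = confusion_matrix(y, p, labels=[0, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestBinaryMetrics:
    def test_quotients(self):
        acc, sens, spec = binary_metrics(ConfusionCounts(tp=50, fn=50, tn=400, fp=0))
        assert (acc, sens, spec) == (0.9, 0.5, 1.0)

    def test_sensitivity_absent_without_positives(self):
        _, sens, spec = binary_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert sens is None and spec == 0.5

    def test_role_swap_exchanges_sens_spec(self, rng):
        y = rng.integers(0, 2, size=200)
        p = rng.integers(0, 2, size=200)
        _, sens1, spec1 = binary_metrics(confusion(y, p, positive_class=1))
        _, sens0, spec0 = binary_metrics(confusion(y, p, positive_class=0))
        assert sens1 == pytest.approx(spec0) and spec1 == pytest.approx(sens0)

    def test_accuracy_identity(self, rng):
        """acc == (sens*P + spec*N) / (P + N)."""
        for _ in range(50):
            y = rng.integers(0, 2, size=100)
            p = rng.integers(0, 2, size=100)
            c = confusion(y, p)
            acc, sens, spec = binary_metrics(c)
            P, N = c.tp + c.fn, c.tn + c.fp
            if sens is None or spec is None:
                continue
            assert acc == pytest.approx((sens * P + spec * N) / (P + N))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics(ConfusionCounts())


class TestF1:
    @pytest.mark.parametrize("counts,want", [
        (ConfusionCounts(tp=1), 1.0),
        (ConfusionCounts(tp=10, fp=5, fn=5), 2 / 3),
        (ConfusionCounts(), 0.0),
    ])
    def test_per_class(self, counts, want):
        assert f1_per_class(counts) == pytest.approx(want)

    def test_matches_sklearn_f1(self, rng):
        from sklearn.metrics import f1_score

        y = rng.integers(0, 2, size=300)
        p = rng.integers(0, 2, size=300)
        assert f1_per_class(confusion(y, p)) == pytest.approx(f1_score(y, p))

    def test_macro_from_benchmark_per_class_scores(self):
        """Published per-class F1 triplets average to the published totals."""
        assert round(macro_f1(0.767, 0.198, 0.417), 3) == 0.461
        assert round(macro_f1(0.756, 0.187, 0.388), 3) == 0.444
        assert macro_f1(1.0, 1.0, 1.0) == 1.0

    def test_macro_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            macro_f1(1.2, 0.0, 0.0)

    def test_multiclass_one_vs_rest(self):
        y = ["N", "A", "O", "~", "N", "A"]
        p = ["N", "O", "O", "N", "N", "A"]
        per = multiclass_confusions(y, p)
        assert per["A"].tp == 1 and per["A"].fn == 1
        assert per["~"].tp == 0 and per["~"].fn == 1
        # noise misclassification erodes the N column (false positive for N)
        assert per["N"].fp == 1

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_f1_bounded(self, tp, fp, fn):
        assert 0.0 <= f1_per_class(ConfusionCounts(tp=tp, fp=fp, fn=fn)) <= 1.0


def test_confusion_csv_export(tmp_path):
    from afnet.metrics import write_confusion_csv

    path = write_confusion_csv(ConfusionCounts(tp=3, fp=1, tn=10, fn=2),
                               tmp_path / "cm.csv")
    lines = path.read_text().splitlines()
    assert lines[1] == "actual_non_af,10,1"
    assert lines[2] == "actual_af,2,3"


def test_confusion_rendering_row_sums(rng):
    y = rng.integers(0, 2, size=80)
    p = rng.integers(0, 2, size=80)
    c = confusion(y, p)
    text = format_confusion(c)
    assert str(c.tn) in text and str(c.tp) in text
    assert (c.tn + c.fp) == int(np.sum(y == 0))
    assert (c.fn + c.tp) == int(np.sum(y == 1))


@pytest.fixture(scope="module")
def cv_results():
    cfg = ECGSynthConfig(fs=120.0, duration_s=4.0, af_fraction=0.3, seed=21)
    segments = [segment_and_normalize(r, 480) for r in generate_dataset(40, cfg)]
    model_cfg = DenseNetConfig(k0=4, k=3, num_blocks=1, layers_per_block=2,
                               initial_kernel=3)
    rec_cfg = RecurrentConfig(feature_len=8)
    train_cfg = TrainConfig(epochs=1, batch_size=8, lr0=0.05, seed=21)
    factory = lambda f: AFNet(model_cfg, rec_cfg, seed=100 + f)  # noqa: E731
    reports, pooled = tenfold_cv(segments, factory, train_cfg, seed=21)
    return segments, reports, pooled


class TestTenfold:

    def test_fold_reports_and_pooling(self, cv_results):
        segments, reports, pooled = cv_results
        assert len(reports) == 10
        total = sum(r.confusion.total for r in reports)
        assert total == len(segments) == pooled.confusion.total
        summed = ConfusionCounts()
        for r in reports:
            summed = summed + r.confusion
        assert (summed.tp, summed.fp, summed.tn, summed.fn) == (
            pooled.confusion.tp, pooled.confusion.fp,
            pooled.confusion.tn, pooled.confusion.fn)

    def test_fold_assignment_deterministic(self):
        from afnet.metrics import _fold_assignment

        a = _fold_assignment(40, 10, seed=5)
        b = _fold_assignment(40, 10, seed=5)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)
        allidx = np.concatenate(a)
        assert len(np.unique(allidx)) == 40

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            tenfold_cv([None] * 5, lambda f: None, TrainConfig(), seed=0)


def test_evaluate_predictions_report(rng):
    y = rng.integers(0, 2, size=60)
    p = rng.integers(0, 2, size=60)
    report = evaluate_predictions(y, p, loss=0.5)
    c = report.confusion
    assert report.accuracy == pytest.approx((c.tp + c.tn) / 60)
    assert report.loss == 0.5
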