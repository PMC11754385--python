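import numpy as np
import pytest

from datbridge import classify
from datbridge.classify import (
    NC,
    PD,
    ClassifierConfig,
    VolumeClassifier,
    build_classifier,
    confusion_metrics,
    evaluate,
    predict,
    roc_auc_sweep,
    train_classifier,
)
from datbridge.volume_io import Volume


def _vol(data):
    return Volume(data=np.asarray(data, dtype=float), affine=np.eye(4))


def _toy_items(rng, n, contrast=1.0, shape=(16, 16, 16)):
    items = []
    for i in range(n):
        lab = i % 2
        data = rng.normal(1.0, 0.05, size=shape)
        data[5:9, 5:9, 5:9] += contrast * (1.5 if lab == PD else 0.5)
        items.append((_vol(data), lab))
    return items


class _StubModel(VolumeClassifier):
    """Classifier whose PD log-probability is dictated per volume id."""

    def __init__(self, scores):
        self.scores = scores
        self.grid_shape = None
        self.arch_config = {}

    def log_probs(self, vol):
        p = self.scores[id(vol)]
        return np.log(np.array([1.0 - p, p]))


class TestBuildAndPredict:
    def test_two_log_probabilities_nonpositive_and_finite(self, rng):
        model = build_classifier(seed=1)
        lp = model.log_probs(rng.random((16, 16, 16)))
        assert lp.shape == (2,)
        assert np.all(lp <= 0.0)
        assert np.isfinite(lp).all()
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-6)

    def test_forward_deterministic(self, rng):
        model = build_classifier(seed=2)
        x = rng.random((16, 16, 16))
        np.testing.assert_array_equal(model.log_probs(x), model.log_probs(x))

    def test_argmax_rule_and_tie_to_nc(self):
        vols = [_vol(np.zeros((2, 2, 2))) for _ in range(3)]
        stub = _StubModel({id(vols[0]): 0.09, id(vols[1]): 0.91, id(vols[2]): 0.5})
        assert predict(stub, vols[0])[0] == NC
        assert predict(stub, vols[1])[0] == PD
        assert predict(stub, vols[2])[0] == NC  # exact tie -> NC

    def test_grid_mismatch_rejected(self, rng):
        model = build_classifier(seed=0)
        model.grid_shape = (16, 16, 16)
        with pytest.raises(ValueError, match="grid"):
            model.log_probs(rng.random((8, 8, 8)))


class TestTrainingSchedule:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            ClassifierConfig(lr_factor=1.5)
        with pytest.raises(ValueError):
            ClassifierConfig(epochs=10, early_stop_patience=10)

    def test_single_class_training_set_rejected(self, rng):
        items = [(_vol(rng.random((8, 8, 8))), PD) for _ in range(4)]
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(items, None, ClassifierConfig(epochs=2,
                                                           early_stop_patience=1,
                                                           lr_patience=1))

    def test_plateau_halves_lr_and_early_stop_fires(self, rng, monkeypatch):
        # frozen validation metrics: loss never improves after epoch 1 and
        # accuracy never improves, so the LR halves every lr_patience epochs
        # and early stopping fires at early_stop_patience
        monkeypatch.setattr(classify, "_validate", lambda model, xv, yv: (1.0, 0.5))
        items = _toy_items(rng, 8, shape=(8, 8, 8))
        cfg = ClassifierConfig(epochs=20, early_stop_patience=7, lr_patience=3,
                               initial_lr=1e-4, seed=0, base_channels=2)
        model, trace = train_classifier(items, items[:2], cfg)
        # accuracy improves once at epoch 1 (from -inf), then stalls 7 epochs
        assert len(trace) == 8
        assert trace["lr"].iloc[0] == pytest.approx(1e-4)
        # loss "improves" at epoch 1 (from inf); plateau counting starts after
        assert trace["lr"].iloc[4] == pytest.approx(5e-5)   # one halving
        assert trace["lr"].iloc[7] == pytest.approx(2.5e-5)  # two halvings

    def test_full_schedule_smoke_finite(self, rng):
        items = _toy_items(rng, 20, shape=(8, 8, 8))
        cfg = ClassifierConfig(epochs=5, early_stop_patience=4, lr_patience=3,
                               initial_lr=1e-3, seed=1, base_channels=2)
        model, trace = train_classifier(items, None, cfg)
        assert np.isfinite(trace[["train_loss", "val_loss"]].to_numpy()).all()
        assert set(trace.columns) == {"epoch", "train_loss", "val_loss",
                                      "val_accuracy", "lr"}


class TestEvaluate:
    def _eval_items_with_scores(self, scores, labels):
        vols = [_vol(np.zeros((2, 2, 2))) for _ in scores]
        stub = _StubModel({id(v): s for v, s in zip(vols, scores)})
        return stub, list(zip(vols, labels))

    def test_perfect_separation_auc_one(self):
        stub, items = self._eval_items_with_scores(
            [0.9, 0.8, 0.2, 0.1], [PD, PD, NC, NC])
        rep = evaluate(stub, items)
        assert rep.auc == pytest.approx(1.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_constant_scores_auc_half(self):
        stub, items = self._eval_items_with_scores(
            [0.4, 0.4, 0.4, 0.4], [PD, PD, NC, NC])
        assert evaluate(stub, items).auc == pytest.approx(0.5)

    def test_three_subject_toy_matches_pair_counting(self):
        stub, items = self._eval_items_with_scores([0.7, 0.6, 0.65], [PD, NC, NC])
        rep = evaluate(stub, items)
        # concordant pairs: (0.7 vs 0.6)=1, (0.7 vs 0.65)=1 -> U/(n1*n2) = 1.0
        assert rep.auc == pytest.approx(1.0)

    def test_single_class_test_set_rejected(self):
        stub, items = self._eval_items_with_scores([0.7, 0.6], [PD, PD])
        with pytest.raises(ValueError, match="single-class"):
            evaluate(stub, items)


class TestConfusionMetrics:
    def test_reader_style_rows(self):
        rep = confusion_metrics(tp=3, fn=2, tn=5, fp=0)
        assert rep.as_percent()["npv_pct"] == 71.4
        assert rep.as_percent()["ppv_pct"] == 100.0
        rep = confusion_metrics(tp=4, fn=1, tn=1, fp=4)
        assert rep.as_percent()["ppv_pct"] == 50.0
        assert rep.as_percent()["npv_pct"] == 50.0

    def test_perfect_reader(self):
        rep = confusion_metrics(tp=5, fn=0, tn=5, fp=0).as_percent()
        assert rep["sensitivity_pct"] == rep["specificity_pct"] == 100.0
        assert rep["ppv_pct"] == rep["npv_pct"] == 100.0

    def test_undefined_metric_reported_as_none(self):
        rep = confusion_metrics(tp=0, fn=5, tn=5, fp=0)
        assert rep.ppv is None  # no positive calls
        assert rep.as_percent()["ppv_pct"] is None

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            confusion_metrics(tp=-1, fn=0, tn=1, fp=0)
        with pytest.raises(ValueError):
            confusion_metrics(tp=0, fn=0, tn=5, fp=0)


class TestAucMachinery:
    def test_sweep_auc_equals_mann_whitney_pair_counting(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 15))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # force ties sometimes
            auc, _, _ = roc_auc_sweep(labels, scores)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairs = sum(1.0 if p > q else (0.5 if p == q else 0.0)
                        for p in pos for q in neg)
            assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)
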