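"""Binary NC-vs-PD volumetric CNN classifier and diagnostic metrics.

The network is a residual-block volumetric CNN emitting two log-probabilities
(log-softmax over the two classes); the higher log-probability determines the
prediction, with exact ties resolved to NC (class 0). Training follows the
protocol of the translation study: Adam, negative log-likelihood loss,
initial learning rate 1e-4 halved when validation loss has not improved for
10 epochs, 50 epochs with early stopping when validation accuracy has not
improved for 30 ("improved" means strictly greater throughout). The headline
protocol trains on translated (synthetic SPECT-like) volumes and evaluates
on native SPECT-like volumes.

Evaluation produces an ROC by threshold sweep over the PD-class probability
(trapezoidal AUC, via scikit-learn), the confusion matrix at the argmax
rule, and sensitivity/specificity/PPV/NPV. Metrics whose denominator is zero
are reported as undefined (None), never silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve, auc as _trapezoid_auc

from . import nn
from .volume_io import Volume

logger = logging.getLogger(__name__)

NC, PD = 0, 1


@dataclass
class ClassifierConfig:
    """Training schedule (defaults follow the full-scale protocol)."""

    epochs: int = 50
    early_stop_patience: int = 30
    initial_lr: float = 1e-4
    lr_factor: float = 0.5
    lr_patience: int = 10
    seed: int = 0
    base_channels: int = 6
    val_fraction: float = 0.2
    batch_size: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must be in (0, 1)")
        if self.early_stop_patience >= self.epochs or self.lr_patience >= self.epochs:
            raise ValueError("patience values must be < epochs")


def slim_classifier_config(seed: int = 0) -> ClassifierConfig:
    """Desk-scale preset: fewer epochs and a larger constant-ish LR for the
    slim network on 32^3 phantoms; schedule mechanics are unchanged."""
    return ClassifierConfig(epochs=25, early_stop_patience=20, initial_lr=3e-3,
                            lr_patience=8, seed=seed, batch_size=6)


@dataclass
class VolumeClassifier:
    net: nn.Sequential
    arch_config: dict = field(default_factory=dict)
    grid_shape: tuple[int, int, int] | None = None

    def log_probs(self, vol: Volume | np.ndarray) -> np.ndarray:
        data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
        if self.grid_shape is not None and data.shape != tuple(self.grid_shape):
            raise ValueError(f"volume shape {data.shape} does not match training grid "
                             f"{tuple(self.grid_shape)}")
        y, _ = self.net.forward(np.asarray(data, dtype=nn.DEFAULT_DTYPE)[None])
        return y


def build_classifier(arch_config: dict | None = None, seed: int = 0) -> VolumeClassifier:
    """Residual-block volumetric network with a two-class log-softmax head."""
    cfg = {"base_channels": 6}
    cfg.update(arch_config or {})
    c = cfg["base_channels"]
    rng = np.random.default_rng(seed)
    # no instance normalization here: the diagnostic signal is the absolute
    # striatal intensity level, which per-volume normalization would erase
    # (and the spatial mean of an instance-normalized field is constant, so
    # nothing would survive the global average pooling head)
    net = nn.Sequential(
        nn.Conv3d(1, c, rng=rng), nn.LeakyReLU(0.2), nn.AvgPool2(),
        nn.Conv3d(c, 2 * c, rng=rng), nn.LeakyReLU(0.2), nn.AvgPool2(),
        nn.Residual(nn.Sequential(
            nn.Conv3d(2 * c, 2 * c, rng=rng), nn.LeakyReLU(0.2),
            nn.Conv3d(2 * c, 2 * c, rng=rng),
        )),
        nn.LeakyReLU(0.2), nn.GlobalAvgMaxPool(), nn.Linear(4 * c, 2, rng=rng),
        nn.LogSoftmax(),
    )
    return VolumeClassifier(net=net, arch_config=cfg)


def predict(model: VolumeClassifier, vol: Volume | np.ndarray) -> tuple[int, np.ndarray]:
    """Argmax of the two log-probabilities; exact tie -> NC (class 0)."""
    lp = model.log_probs(vol)
    label = PD if lp[PD] > lp[NC] else NC
    return label, lp


def train_classifier(train_set: list[tuple[Volume, int]],
                     val_set: list[tuple[Volume, int]] | None,
                     cfg: ClassifierConfig) -> tuple[VolumeClassifier, pd.DataFrame]:
    """Train with plateau LR reduction and early stopping on validation accuracy.

    If ``val_set`` is None, a stratified 80/20 split of the training data is
    used (fixed by ``cfg.seed``). The returned trace records epoch, train
    loss, val loss, val accuracy, and the learning rate in force.
    """
    if not train_set:
        raise ValueError("training set is empty")
    labels = {lab for _, lab in train_set}
    if labels != {NC, PD}:
        raise ValueError(f"training set must contain both classes, got labels {labels}")
    rng = np.random.default_rng(cfg.seed)
    if val_set is None:
        train_set, val_set = _stratified_split(train_set, cfg.val_fraction, rng)
    xs = [np.asarray(v.data, dtype=nn.DEFAULT_DTYPE)[None] for v, _ in train_set]
    ys = [lab for _, lab in train_set]
    xv = [np.asarray(v.data, dtype=nn.DEFAULT_DTYPE)[None] for v, _ in val_set]
    yv = [lab for _, lab in val_set]

    model = build_classifier({"base_channels": cfg.base_channels},
                             seed=int(rng.integers(2**31 - 1)))
    model.grid_shape = train_set[0][0].shape
    opt = nn.Adam(model.net.params(), lr=cfg.initial_lr)

    best_val_acc = -np.inf
    best_val_loss = np.inf
    epochs_no_acc = 0
    epochs_no_loss = 0
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(xs))
        tot = 0.0
        opt.zero_grad()
        pending = 0
        for i in order:
            lp, caches = model.net.forward(xs[i])
            tot += nn.nll(lp, ys[i])
            model.net.backward(nn.nll_grad(lp, ys[i]) / cfg.batch_size, caches)
            pending += 1
            if pending == cfg.batch_size:
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step()
            opt.zero_grad()
        train_loss = tot / len(xs)
        val_loss, val_acc = _validate(model, xv, yv)
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
                     "val_accuracy": val_acc, "lr": opt.lr})
        if not np.isfinite(train_loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")

        if val_acc > best_val_acc:
            best_val_acc = val_acc
            epochs_no_acc = 0
        else:
            epochs_no_acc += 1
        if val_loss < best_val_loss:
            best_val_loss = val_loss
            epochs_no_loss = 0
        else:
            epochs_no_loss += 1
            if epochs_no_loss >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                epochs_no_loss = 0
                logger.info("epoch %d: lr reduced to %.2e", epoch, opt.lr)
        if epochs_no_acc >= cfg.early_stop_patience:
            logger.info("early stop at epoch %d", epoch)
            break
    return model, pd.DataFrame(rows)


def _stratified_split(items, val_fraction, rng):
    by_class: dict[int, list] = {}
    for it in items:
        by_class.setdefault(it[1], []).append(it)
    train, val = [], []
    for lab, group in sorted(by_class.items()):
        idx = rng.permutation(len(group))
        n_val = max(1, int(round(val_fraction * len(group))))
        val.extend(group[i] for i in idx[:n_val])
        train.extend(group[i] for i in idx[n_val:])
    if not train:
        raise ValueError("training split is empty after validation split")
    return train, val


def _validate(model, xv, yv):
    tot, correct = 0.0, 0
    for x, y in zip(xv, yv):
        lp, _ = model.net.forward(x)
        tot += nn.nll(lp, y)
        pred = PD if lp[PD] > lp[NC] else NC
        correct += int(pred == y)
    return tot / len(xv), correct / len(xv)


# ---------------------------------------------------------------------------
# Diagnostic metrics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticReport:
    """AUC, the four ratio metrics (fractions; None where undefined),
    ROC points, and the confusion matrix at the argmax rule."""

    auc: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    roc_fpr: np.ndarray | None = field(default=None, repr=False)
    roc_tpr: np.ndarray | None = field(default=None, repr=False)

    def as_percent(self) -> dict[str, float | None]:
        """Display form: percentages rounded to one decimal."""
        pct = lambda v: None if v is None else round(100.0 * v, 1)
        return {"auc": None if self.auc is None else round(self.auc, 3),
                "sensitivity_pct": pct(self.sensitivity),
                "specificity_pct": pct(self.specificity),
                "ppv_pct": pct(self.ppv), "npv_pct": pct(self.npv)}


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> DiagnosticReport:
    """Sensitivity, specificity, PPV, NPV from a 2x2 confusion matrix."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be >= 0")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one positive and one negative case")
    return DiagnosticReport(
        auc=None,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def roc_auc_sweep(labels: np.ndarray, scores: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC by threshold sweep and trapezoidal AUC (PD-positive scores)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC undefined for a single-class set")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr


def evaluate(model: VolumeClassifier, test_set: list[tuple[Volume, int]]) -> DiagnosticReport:
    """Full diagnostic report on a labelled test set.

    Raises if the test set has a single class (AUC undefined).
    """
    if not test_set:
        raise ValueError("test set is empty")
    labels, scores, preds = [], [], []
    for vol, lab in test_set:
        pred, lp = predict(model, vol)
        labels.append(lab)
        scores.append(float(np.exp(lp[PD])))
        preds.append(pred)
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    auc_val, fpr, tpr = roc_auc_sweep(labels, np.asarray(scores))
    tp = int(np.sum((preds == PD) & (labels == PD)))
    fp = int(np.sum((preds == PD) & (labels == NC)))
    tn = int(np.sum((preds == NC) & (labels == NC)))
    fn = int(np.sum((preds == NC) & (labels == PD)))
    rep = confusion_metrics(tp, fp, tn, fn)
    rep.auc = auc_val
    rep.roc_fpr, rep.roc_tpr = fpr, tpr
    return rep
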