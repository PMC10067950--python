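"""Loss composition, dataset splitting and the training loop.

Three categorical cross-entropy losses are computed per subject: one per
side's mastoiditis classifier and one for the symmetry classifier.  The
symmetry loss is added to *each* side's loss and the two sums form the
training objective, so

    total = CE_right + CE_left + 2 * symmetry_weight * CE_symmetry

with ``symmetry_weight`` defaulting to 1.  Optimization is RMSprop at an
initial learning rate of 1e-4 with mini-batches of 4 and He-initialized
weights.  Epochs, patience and the checkpoint monitor are configuration:
by default the best epoch is selected by validation per-ear AUC of the
dichotomized score — the reported endpoint, applied identically to the
bilateral and single-side architectures — with validation loss available
as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import BilateralLabel, ExclusionError
from .network import BilateralSymmetryNet, SingleSideNet, BilateralPrediction
from .nn import RMSprop, iter_parameters, softmax, zero_grads

__all__ = [
    "TrainConfig",
    "LossBreakdown",
    "composite_loss",
    "single_side_loss",
    "stratified_split",
    "train_model",
    "BilateralDataset",
    "SingleSideDataset",
]

_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    optimizer: str = "rmsprop"
    batch_size: int = 4
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    split_ratio: tuple[int, int] = (5, 1)
    symmetry_weight: float = 1.0
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-7
    #: checkpoint-selection / early-stopping monitor: 'val_auc' selects the
    #: epoch with the best validation per-ear AUC of the dichotomized score
    #: (the reported endpoint, applied identically to both architectures);
    #: 'val_loss' selects on the validation objective instead.
    monitor: str = "val_auc"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if min(self.split_ratio) <= 0:
            raise ValueError("split ratio parts must be positive")
        if self.optimizer != "rmsprop":
            raise ValueError("only the rmsprop optimizer family is supported")
        if self.monitor not in ("val_auc", "val_loss"):
            raise ValueError("monitor must be 'val_auc' or 'val_loss'")


@dataclass(frozen=True)
class LossBreakdown:
    ce_right: float
    ce_left: float
    ce_symmetry: float

    @property
    def total(self) -> float:
        return self.ce_right + self.ce_left + 2.0 * self.ce_symmetry


def _ce_from_probs(probs, target: int) -> float:
    p = float(np.asarray(probs, dtype=float)[int(target)])
    return -float(np.log(max(p, _LOG_FLOOR)))


def composite_loss(pred: BilateralPrediction, label: BilateralLabel) -> LossBreakdown:
    """Per-subject loss breakdown from probability vectors."""
    if label.excluded:
        raise ExclusionError(f"subject {label.subject_id!r} is excluded from training")
    return LossBreakdown(
        ce_right=_ce_from_probs(pred.right_probs, int(label.right)),
        ce_left=_ce_from_probs(pred.left_probs, int(label.left)),
        ce_symmetry=_ce_from_probs(pred.symmetry_probs, int(label.grade)),
    )


def single_side_loss(probs, cat: int) -> float:
    """Categorical cross-entropy of one ear's prediction."""
    if int(cat) == 3:
        raise ExclusionError("postoperative ears are excluded from training")
    return _ce_from_probs(probs, cat)


def stratified_split(
    labels: list[BilateralLabel],
    ratio: tuple[int, int] = (5, 1),
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Split subjects into training and validation sets, stratified by
    bilateral symmetry grade.

    Within each grade stratum the validation fraction is
    ``ratio[1] / sum(ratio)`` rounded to the nearest subject.  Excluded
    (postoperative) subjects do not participate.  Deterministic given
    ``seed``; disjoint and exhaustive over included subjects.
    """
    included = [l for l in labels if not l.excluded]
    if not included:
        raise ValueError("no included subjects to split")
    frac = ratio[1] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for grade in (0, 1, 2):
        stratum = [l.subject_id for l in included if int(l.grade) == grade]
        if not stratum:
            continue
        if len(stratum) < sum(ratio):
            warnings.warn(
                f"symmetry-grade {grade} stratum has only {len(stratum)} subjects; "
                "the split is degenerate",
                stacklevel=2,
            )
        n_val = int(np.floor(len(stratum) * frac + 0.5))
        order = rng.permutation(len(stratum))
        val_ids += [stratum[i] for i in order[:n_val]]
        train_ids += [stratum[i] for i in order[n_val:]]
    return train_ids, val_ids


# ---------------------------------------------------------------------------
# in-memory datasets


@dataclass
class BilateralDataset:
    """Paired ear images and labels for the bilateral model.

    ``right`` / ``left`` are (n, H, W) arrays in [0, 1]; the label arrays
    hold per-side categories (0-2) and the derived symmetry grade.
    """

    right: np.ndarray
    left: np.ndarray
    y_right: np.ndarray
    y_left: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.right = np.asarray(self.right, dtype=np.float32)
        self.left = np.asarray(self.left, dtype=np.float32)
        self.y_right = np.asarray(self.y_right, dtype=int)
        self.y_left = np.asarray(self.y_left, dtype=int)
        n = len(self.y_right)
        if not (len(self.left) == len(self.right) == len(self.y_left) == n):
            raise ValueError("misaligned bilateral dataset arrays")
        if np.any((self.y_right < 0) | (self.y_right > 2) | (self.y_left < 0) | (self.y_left > 2)):
            raise ExclusionError("bilateral datasets accept categories 0-2 only")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:05d}" for i in range(n)]

    @property
    def y_grade(self) -> np.ndarray:
        return np.abs(self.y_right - self.y_left)

    def __len__(self) -> int:
        return len(self.y_right)

    def subset(self, idx) -> "BilateralDataset":
        idx = np.asarray(idx)
        return BilateralDataset(
            self.right[idx],
            self.left[idx],
            self.y_right[idx],
            self.y_left[idx],
            [self.subject_ids[i] for i in idx],
        )

    def as_single_side(self) -> "SingleSideDataset":
        """Each ear becomes one independent sample (right images as-is;
        left images are already in right-ear orientation after
        preprocessing)."""
        return SingleSideDataset(
            np.concatenate([self.right, self.left]),
            np.concatenate([self.y_right, self.y_left]),
        )


@dataclass
class SingleSideDataset:
    images: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=int)
        if len(self.images) != len(self.y):
            raise ValueError("misaligned single-side dataset arrays")

    def __len__(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# training loops


def _ce_and_grad(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over a batch and d(mean CE)/d(logits)."""
    probs = softmax(logits, axis=1)
    n = len(targets)
    picked = probs[np.arange(n), targets]
    loss = float(-np.log(np.maximum(picked, _LOG_FLOOR)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


def _snapshot(net):
    return [layer.params[name].copy() for layer, name in iter_parameters(net)]


def _restore(net, snap):
    for (layer, name), arr in zip(iter_parameters(net), snap):
        layer.params[name][...] = arr


def _ear_auc(pos_scores: np.ndarray, truth: np.ndarray) -> float | None:
    """Mann-Whitney AUC of per-ear positive scores; None if one class."""
    from scipy.stats import rankdata

    truth = truth.astype(bool)
    m, n = int(truth.sum()), int((~truth).sum())
    if m == 0 or n == 0:
        return None
    ranks = rankdata(pos_scores)
    return float((ranks[truth].sum() - m * (m + 1) / 2) / (m * n))


def _bilateral_val_metrics(net, ds: BilateralDataset, batch: int):
    """Validation loss breakdown and per-ear AUC in one pass."""
    tot = np.zeros(3)
    n = len(ds)
    scores, truth = [], []
    for s in range(0, n, batch):
        sl = slice(s, min(s + batch, n))
        outs = net.predict_batch(ds.right[sl], ds.left[sl])
        lr, _ = _ce_and_grad(outs.right_logits, ds.y_right[sl])
        ll, _ = _ce_and_grad(outs.left_logits, ds.y_left[sl])
        ls, _ = _ce_and_grad(outs.sym_logits, ds.y_grade[sl])
        tot += np.array([lr, ll, ls]) * (sl.stop - sl.start)
        scores.append(np.r_[1.0 - outs.right_probs[:, 0], 1.0 - outs.left_probs[:, 0]])
        truth.append(np.r_[ds.y_right[sl] > 0, ds.y_left[sl] > 0])
    tot /= n
    auc = _ear_auc(np.concatenate(scores), np.concatenate(truth))
    return LossBreakdown(tot[0], tot[1], tot[2]), auc


def train_model(
    net,
    train_data,
    cfg: TrainConfig | None = None,
    val_data=None,
) -> pd.DataFrame:
    """Train a bilateral or single-side model in place.

    Returns the history as a DataFrame (per-epoch mean loss breakdown and
    validation totals).  With validation data the best-epoch weights (by
    validation total loss) are restored at the end.  Fully reproducible
    given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    if isinstance(net, BilateralSymmetryNet):
        return _train_bilateral(net, train_data, cfg, val_data)
    if isinstance(net, SingleSideNet):
        return _train_single(net, train_data, cfg, val_data)
    raise TypeError(f"unsupported model type {type(net).__name__}")


def _train_bilateral(net, ds: BilateralDataset, cfg: TrainConfig, val: BilateralDataset | None):
    if len(ds) == 0:
        raise ValueError("empty training set")
    opt = RMSprop(net, cfg.learning_rate, cfg.rmsprop_rho, cfg.rmsprop_eps)
    rng = np.random.default_rng(cfg.seed)
    w = cfg.symmetry_weight
    rows = []
    best_val = np.inf
    best_snap = None
    stall = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ds))
        sums = np.zeros(3)
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            zero_grads(net)
            outs = net.predict_batch(ds.right[idx], ds.left[idx])
            lr_, d_r = _ce_and_grad(outs.right_logits, ds.y_right[idx])
            ll_, d_l = _ce_and_grad(outs.left_logits, ds.y_left[idx])
            ls_, d_s = _ce_and_grad(outs.sym_logits, ds.y_grade[idx])
            total = lr_ + ll_ + 2.0 * w * ls_
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: non-finite loss "
                    f"(ce_right={lr_}, ce_left={ll_}, ce_symmetry={ls_})"
                )
            net.backward_outputs(outs, d_r, d_l, 2.0 * w * d_s)
            opt.step()
            sums += np.array([lr_, ll_, ls_]) * len(idx)
        mean = sums / len(ds)
        train_lb = LossBreakdown(mean[0], mean[1], mean[2])
        row = {
            "epoch": epoch,
            "ce_right": train_lb.ce_right,
            "ce_left": train_lb.ce_left,
            "ce_symmetry": train_lb.ce_symmetry,
            "total": train_lb.total,
        }
        if val is not None and len(val):
            vlb, vauc = _bilateral_val_metrics(net, val, max(cfg.batch_size, 16))
            row["val_total"] = vlb.total
            if vauc is not None:
                row["val_auc"] = vauc
            # minimize loss, or maximize AUC (negated), per the monitor
            crit = vlb.total if (cfg.monitor == "val_loss" or vauc is None) else -vauc
            if crit < best_val - 1e-9:
                best_val, best_snap, stall = crit, _snapshot(net), 0
            else:
                stall += 1
        rows.append(row)
        if val is not None and stall > cfg.patience:
            break
    if best_snap is not None:
        _restore(net, best_snap)
    return pd.DataFrame(rows)


def _train_single(net, ds: SingleSideDataset, cfg: TrainConfig, val: SingleSideDataset | None):
    if len(ds) == 0:
        raise ValueError("empty training set")
    opt = RMSprop(net, cfg.learning_rate, cfg.rmsprop_rho, cfg.rmsprop_eps)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    best_val = np.inf
    best_snap = None
    stall = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ds))
        loss_sum = 0.0
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            zero_grads(net)
            logits, cache = net.forward(ds.images[idx])
            loss, dlogits = _ce_and_grad(logits, ds.y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            net.backward(dlogits, cache)
            opt.step()
            loss_sum += loss * len(idx)
        row = {"epoch": epoch, "ce": loss_sum / len(ds)}
        if val is not None and len(val):
            vloss = 0.0
            scores, truth = [], []
            for s in range(0, len(val), 64):
                sl = slice(s, min(s + 64, len(val)))
                logits, _ = net.forward(val.images[sl])
                l, _ = _ce_and_grad(logits, val.y[sl])
                vloss += l * (sl.stop - sl.start)
                probs = softmax(logits, axis=1)
                scores.append(1.0 - probs[:, 0])
                truth.append(val.y[sl] > 0)
            vloss /= len(val)
            vauc = _ear_auc(np.concatenate(scores), np.concatenate(truth))
            row["val_total"] = vloss
            if vauc is not None:
                row["val_auc"] = vauc
            crit = vloss if (cfg.monitor == "val_loss" or vauc is None) else -vauc
            if crit < best_val - 1e-9:
                best_val, best_snap, stall = crit, _snapshot(net), 0
            else:
                stall += 1
        rows.append(row)
        if val is not None and stall > cfg.patience:
            break
    if best_snap is not None:
        _restore(net, best_snap)
    return pd.DataFrame(rows)
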