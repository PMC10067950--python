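"""Model / Results interface over the training machinery.

Follows the fit-then-inspect convention of statistical modelling packages:
a model object is built from data, ``fit()`` trains the network and returns
a results object carrying the trained weights, the loss history,
``predict`` methods and a ``summary()`` table; diagnostic evaluation hangs
off the results object and returns a :class:`~mastsym.stats_eval.DiagnosticReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import BilateralLabel, EarCategory
from .network import (
    BilateralPrediction,
    BilateralSymmetryNet,
    SingleSideNet,
    StreamConfig,
    architecture_summary,
)
from .stats_eval import DiagnosticReport, evaluate
from .training import BilateralDataset, TrainConfig, stratified_split, train_model

__all__ = ["SymmetryModel", "SingleSideModel", "SymmetryResults", "SingleSideResults",
           "dataset_labels"]

_UNIFORM = np.full(3, 1.0 / 3.0)


def dataset_labels(ds: BilateralDataset) -> list[BilateralLabel]:
    return [
        BilateralLabel(sid, EarCategory(int(r)), EarCategory(int(l)))
        for sid, r, l in zip(ds.subject_ids, ds.y_right, ds.y_left)
    ]


def _split_dataset(ds: BilateralDataset, ratio, seed):
    labels = dataset_labels(ds)
    train_ids, val_ids = stratified_split(labels, ratio, seed)
    index = {sid: i for i, sid in enumerate(ds.subject_ids)}
    return ds.subset([index[s] for s in train_ids]), ds.subset([index[s] for s in val_ids])


class SymmetryModel:
    """Bilateral symmetry-aware classifier specified on a paired-ear
    dataset.

    Parameters
    ----------
    data : BilateralDataset
        Preprocessed right/left ear images with per-side categories.
    stream_config : StreamConfig, optional
        Architecture of the shared CNN stream; defaults to the full-scale
        stream, which must match the image shape of ``data``.
    """

    def __init__(self, data: BilateralDataset, stream_config: StreamConfig | None = None):
        self.data = data
        self.stream_config = stream_config or StreamConfig()
        if data.right.shape[1:] != self.stream_config.input_shape:
            raise ValueError(
                f"dataset images {data.right.shape[1:]} do not match the stream "
                f"input shape {self.stream_config.input_shape}"
            )

    def fit(
        self,
        train_config: TrainConfig | None = None,
        validation: BilateralDataset | None = None,
    ) -> "SymmetryResults":
        """Train from He-initialized weights; when no validation set is
        given, one is carved out of the data by a stratified split on the
        symmetry grade at ``train_config.split_ratio``."""
        cfg = train_config or TrainConfig()
        if validation is None:
            train_ds, validation = _split_dataset(self.data, cfg.split_ratio, cfg.seed)
        else:
            train_ds = self.data
        net = BilateralSymmetryNet(self.stream_config, seed=cfg.seed)
        history = train_model(net, train_ds, cfg, validation)
        return SymmetryResults(self, net, history, cfg)


@dataclass
class SymmetryResults:
    model: SymmetryModel
    net: BilateralSymmetryNet
    history: pd.DataFrame
    train_config: TrainConfig
    _batch: int = field(default=32, repr=False)

    def predict(self, data: BilateralDataset) -> list[BilateralPrediction]:
        preds = []
        for s in range(0, len(data), self._batch):
            sl = slice(s, min(s + self._batch, len(data)))
            outs = self.net.predict_batch(data.right[sl], data.left[sl])
            pr, pl, ps = outs.right_probs, outs.left_probs, outs.symmetry_probs
            preds += [BilateralPrediction(pr[i], pl[i], ps[i]) for i in range(len(pr))]
        return preds

    def evaluate(self, data: BilateralDataset, comparators=None) -> DiagnosticReport:
        return evaluate(self.predict(data), dataset_labels(data), comparators)

    def summary(self) -> str:
        arch = architecture_summary(self.net)
        last = self.history.iloc[-1]
        lines = [
            "Bilateral symmetry model",
            f"  stream: {arch['config']['n_blocks']} SE-residual blocks, "
            f"widths {tuple(arch['config']['block_widths'])}",
            f"  parameters: {arch['n_parameters']} "
            f"(stream {arch['stream_parameters']}, shared across sides)",
            f"  epochs trained: {len(self.history)}",
            f"  final train loss: total {last['total']:.4f} "
            f"(right {last['ce_right']:.4f}, left {last['ce_left']:.4f}, "
            f"symmetry {last['ce_symmetry']:.4f})",
        ]
        if "val_total" in self.history:
            lines.append(f"  best validation total: {self.history['val_total'].min():.4f}")
        return "\n".join(lines)


class SingleSideModel:
    """Baseline classifier trained on individual ears (no symmetry path).

    Built from the same paired dataset as :class:`SymmetryModel`; each ear
    becomes an independent training sample.
    """

    def __init__(self, data: BilateralDataset, stream_config: StreamConfig | None = None):
        self.data = data
        self.stream_config = stream_config or StreamConfig()
        if data.right.shape[1:] != self.stream_config.input_shape:
            raise ValueError("dataset images do not match the stream input shape")

    def fit(
        self,
        train_config: TrainConfig | None = None,
        validation: BilateralDataset | None = None,
    ) -> "SingleSideResults":
        cfg = train_config or TrainConfig()
        if validation is None:
            train_ds, validation = _split_dataset(self.data, cfg.split_ratio, cfg.seed)
        else:
            train_ds = self.data
        net = SingleSideNet(self.stream_config, seed=cfg.seed)
        history = train_model(net, train_ds.as_single_side(), cfg,
                              validation.as_single_side())
        return SingleSideResults(self, net, history, cfg)


@dataclass
class SingleSideResults:
    model: SingleSideModel
    net: SingleSideNet
    history: pd.DataFrame
    train_config: TrainConfig
    _batch: int = field(default=64, repr=False)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        out = []
        for s in range(0, len(images), self._batch):
            out.append(self.net.predict_proba(images[s : s + self._batch]))
        return np.concatenate(out)

    def predict(self, data: BilateralDataset) -> list[BilateralPrediction]:
        """Per-subject predictions with each side classified independently.

        The baseline has no symmetry head; its symmetry probabilities are
        reported as uniform placeholders and carry no information.
        """
        pr = self.predict_proba(data.right)
        pl = self.predict_proba(data.left)
        return [BilateralPrediction(pr[i], pl[i], _UNIFORM) for i in range(len(data))]

    def evaluate(self, data: BilateralDataset, comparators=None) -> DiagnosticReport:
        return evaluate(self.predict(data), dataset_labels(data), comparators)

    def summary(self) -> str:
        arch = architecture_summary(self.net)
        last = self.history.iloc[-1]
        lines = [
            "Single-side baseline model",
            f"  parameters: {arch['n_parameters']}",
            f"  epochs trained: {len(self.history)}",
            f"  final train cross-entropy: {last['ce']:.4f}",
        ]
        if "val_total" in self.history:
            lines.append(f"  best validation loss: {self.history['val_total'].min():.4f}")
        return "\n".join(lines)
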