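"""Bidirectional-LSTM decoding of cognitive state from FHV sequences.

A two-layer bidirectional LSTM reads the sequence of Functional Health
Vectors X in R^{T x 2} (spectral balance FB_t, health index FHI_t) in
both temporal directions; forward and backward hidden states are
concatenated, h_t = [h_t-> || h_t<-], and a dense softmax head maps each
window to a probability triple over (Relaxed, Stress, Fatigue).  The
decoded state is the argmax, with ties broken in that fixed class order.

Training minimises categorical cross-entropy with Adam; early stopping
monitors validation macro-F1.  Evaluation reports the row-normalised
confusion matrix, per-class precision/recall/F1 and the macro-F1 (the
unweighted mean of class F1 scores) through the package's own metric
arithmetic, which the test-suite cross-checks against scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat
from . import nn

__all__ = [
    "STATE_ORDER", "StateSequence", "BiLSTMConfig", "BiLSTMStateClassifier",
    "predict_state", "classification_metrics",
]

#: fixed class order; argmax ties resolve to the earliest entry
STATE_ORDER = ("Relaxed", "Stress", "Fatigue")
_STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}


class DegenerateTrainingError(ValueError):
    """Fewer than two classes present in the training labels."""


@dataclass
class StateSequence:
    """A T x 2 FHV sequence with optional per-window state labels."""

    inputs: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        if self.inputs.ndim != 2 or self.inputs.shape[1] != 2:
            raise ValueError(
                f"inputs must be (T, 2), got {self.inputs.shape}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.inputs):
                raise ValueError("labels length mismatch")

    def label_indices(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("sequence has no labels")
        if self.labels.dtype.kind in "iu":
            return self.labels.astype(int)
        return np.array([_STATE_INDEX[s] for s in self.labels])


@dataclass
class BiLSTMConfig:
    hidden_units: int = 64
    layers: int = 2
    learning_rate: float = 1e-3
    max_epochs: int = 150
    patience: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1 or self.layers < 1:
            raise ValueError("hidden_units and layers must be >= 1")


def predict_state(probs: np.ndarray) -> np.ndarray:
    """Argmax state labels; ties resolve Relaxed < Stress < Fatigue."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    idx = probs.argmax(axis=1)  # argmax returns the first maximum
    return np.array([STATE_ORDER[i] for i in idx])


class BiLSTMStateClassifier(nn.Module):
    """Stacked bidirectional LSTM with a per-window softmax head."""

    def __init__(self, config: BiLSTMConfig | None = None):
        self.config = config or BiLSTMConfig()
        rng = np.random.default_rng(self.config.seed)
        H = self.config.hidden_units
        self.forward_layers: list[nn.LSTM] = []
        self.backward_layers: list[nn.LSTM] = []
        n_in = 2
        for _ in range(self.config.layers):
            self.forward_layers.append(nn.LSTM(n_in, H, rng))
            self.backward_layers.append(nn.LSTM(n_in, H, rng))
            n_in = 2 * H
        self.head = nn.Linear(2 * H, len(STATE_ORDER), rng)
        self.fitted = False

    # -------------------------------------------------------- forward --
    def _forward_graph(self, batch: np.ndarray) -> Tensor:
        """(B, T, 2) -> probability Tensor (B, T, 3)."""
        batch = np.asarray(batch, dtype=float)
        if batch.ndim != 3 or batch.shape[2] != 2:
            raise ValueError(f"expected (B, T, 2) input, got {batch.shape}")
        T = batch.shape[1]
        xs: list[Tensor] = [Tensor(batch[:, t, :]) for t in range(T)]
        for fwd, bwd in zip(self.forward_layers, self.backward_layers):
            hf = fwd(xs)
            hb = bwd(xs, reverse=True)
            xs = [concat([hf[t], hb[t]], axis=1) for t in range(T)]
        logits = [self.head(h) for h in xs]                 # T x (B, 3)
        stacked = concat([lg.reshape(lg.shape[0], 1, lg.shape[1])
                          for lg in logits], axis=1)        # (B, T, 3)
        return stacked.softmax(axis=-1)

    def forward(self, sequence: StateSequence | np.ndarray) -> np.ndarray:
        """Per-window state probabilities for one sequence, shape (T, 3)."""
        x = (sequence.inputs if isinstance(sequence, StateSequence)
             else np.asarray(sequence, dtype=float))
        return self._forward_graph(x[None]).data[0]

    def predict(self, sequence: StateSequence | np.ndarray) -> np.ndarray:
        return predict_state(self.forward(sequence))

    # ------------------------------------------------------- training --
    @staticmethod
    def _stack(dataset: list[StateSequence]):
        X = np.stack([s.inputs for s in dataset])
        y = np.stack([s.label_indices() for s in dataset])
        return X, y

    def fit(self, train: list[StateSequence],
            val: list[StateSequence] | None = None) -> dict:
        """Full-batch Adam training with early stopping on val macro-F1.

        Returns a history dict with per-epoch loss (and val macro-F1 when
        a validation split is supplied).  Deterministic under the config
        seed.
        """
        X, y = self._stack(train)
        if len(np.unique(y)) < 2:
            raise DegenerateTrainingError(
                "training labels contain a single class")
        opt = nn.Adam(self.parameters(), lr=self.config.learning_rate)
        history = {"loss": [], "val_macro_f1": []}
        best = {"f1": -1.0, "params": None, "since": 0}
        for _epoch in range(self.config.max_epochs):
            opt.zero_grad()
            probs = self._forward_graph(X)
            loss = nn.cross_entropy(probs, y)
            loss.backward()
            opt.step()
            history["loss"].append(loss.item())
            if val:
                metrics = self.evaluate(val)
                f1 = metrics["macro_f1"]
                history["val_macro_f1"].append(f1)
                if f1 > best["f1"]:
                    best = {"f1": f1,
                            "params": [p.data.copy() for p in self.parameters()],
                            "since": 0}
                else:
                    best["since"] += 1
                    if best["since"] >= self.config.patience:
                        break
        if val and best["params"] is not None:
            for p, saved in zip(self.parameters(), best["params"]):
                p.data = saved
        self.fitted = True
        history["train_metrics"] = self.evaluate(train)
        return history

    # ------------------------------------------------------ evaluation --
    def evaluate(self, dataset: list[StateSequence]) -> dict:
        """Confusion matrix and per-class precision/recall/F1 on a set."""
        X, y = self._stack(dataset)
        probs = self._forward_graph(X).data
        pred = probs.reshape(-1, len(STATE_ORDER)).argmax(axis=1)
        return classification_metrics(y.reshape(-1), pred)


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           n_classes: int = len(STATE_ORDER)) -> dict:
    """Confusion counts, row-normalised matrix, P/R/F1 and macro-F1.

    A class absent from ``y_true`` has undefined recall; it is excluded
    from the macro average (reported as NaN per class).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, counts / row_sums, 0.0)
    precision = np.full(n_classes, np.nan)
    recall = np.full(n_classes, np.nan)
    f1 = np.full(n_classes, np.nan)
    for c in range(n_classes):
        tp = counts[c, c]
        pred_c = counts[:, c].sum()
        true_c = counts[c, :].sum()
        if true_c == 0:
            continue  # class absent: undefined, excluded from macro
        p = tp / pred_c if pred_c > 0 else 0.0
        r = tp / true_c
        precision[c], recall[c] = p, r
        f1[c] = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
    macro = float(np.nanmean(f1))
    return {
        "confusion_counts": counts,
        "confusion_normalized": normalized,
        "precision": precision, "recall": recall, "f1": f1,
        "macro_f1": macro,
        "accuracy": float((y_true == y_pred).mean()),
    }
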