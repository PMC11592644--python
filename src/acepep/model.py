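"""Recurrent peptide-activity classifier.

The architecture is a stack of three LSTM layers (tanh gate activations,
hidden width 128, dropouts 0.4 / 0.4 / 0.25) followed by a two-unit sigmoid
output head read at the final time step; the positive-class probability is
the positive unit's sigmoid output renormalised so the two units sum to one,
which makes the usual 0.5 decision threshold well defined.  The input width
equals the descriptor combination's total feature count, so the same network
definition serves any single or combined encoding.

The network is implemented directly in NumPy — forward pass, truncated-free
backpropagation through time, inverted dropout and Adam — which keeps the
package dependency-light and makes training bit-reproducible for a fixed
seed under single-threaded BLAS.  Peptides are short (2–19 residues), so the
time loop is cheap.  Variable lengths inside a batch are handled by a masked
state carry: once a sequence ends, its hidden and cell states pass through
unchanged, so batched outputs equal single-peptide outputs exactly.

A :class:`MeanPoolLogistic` fast proxy (logistic regression on mean-pooled
encodings) implements the same prediction interface and backs the quick
modes of the feature-selection search and smoke tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .datasets import LabeledDataset
from .descriptors import (
    DescriptorCombination,
    DescriptorRegistry,
    EncodedPeptide,
    EncodingError,
    encode,
)

__all__ = [
    "ModelConfig",
    "TrainingDivergedError",
    "LSTMClassifier",
    "TrainedClassifier",
    "MeanPoolLogistic",
    "build_model",
    "train_classifier",
    "predict",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ModelConfig:
    """Network and optimisation settings.

    The architectural defaults (three LSTM layers of width 128, dropouts
    0.4/0.4/0.25, two-unit sigmoid head) are the reference configuration;
    ``input_features`` must equal the encoding combination's width.
    Optimisation settings are ordinary small-network defaults and are fully
    exposed here.
    """

    input_features: int
    hidden_size: int = 128
    n_lstm_layers: int = 3
    dropout: tuple[float, ...] = (0.4, 0.4, 0.25)
    output_size: int = 2
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 30
    validation_fraction: float = 0.1
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_features < 1:
            raise ValueError("input_features must be >= 1")
        if self.hidden_size < 1 or self.n_lstm_layers < 1:
            raise ValueError("hidden_size and n_lstm_layers must be >= 1")
        self.dropout = tuple(self.dropout)
        if len(self.dropout) != self.n_lstm_layers:
            raise ValueError(
                f"need one dropout rate per LSTM layer "
                f"({self.n_lstm_layers}), got {len(self.dropout)}"
            )
        if self.output_size != 2:
            raise ValueError("the classifier uses a two-unit output head")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _pad_batch(encs: Sequence[EncodedPeptide]) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad a list of encodings to (B, T, F) plus a (B, T) float mask."""
    B = len(encs)
    T = max(e.matrix.shape[0] for e in encs)
    F = encs[0].matrix.shape[1]
    X = np.zeros((B, T, F))
    M = np.zeros((B, T))
    for i, e in enumerate(encs):
        t = e.matrix.shape[0]
        X[i, :t] = e.matrix
        M[i, :t] = 1.0
    return X, M


class LSTMClassifier:
    """The stacked-LSTM network itself (parameters + forward/backward)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        H = config.hidden_size
        self.params: dict[str, np.ndarray] = {}
        fin = config.input_features
        for l in range(config.n_lstm_layers):
            self.params[f"W{l}"] = rng.standard_normal((fin, 4 * H)) / np.sqrt(fin)
            self.params[f"U{l}"] = rng.standard_normal((H, 4 * H)) / np.sqrt(H)
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias: remember by default
            self.params[f"b{l}"] = b
            fin = H
        self.params["Wo"] = rng.standard_normal((H, 2)) / np.sqrt(H)
        self.params["bo"] = np.zeros(2)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.fitted = False

    # -- forward -----------------------------------------------------------

    def _forward(
        self,
        X: np.ndarray,
        M: np.ndarray,
        train_rng: np.random.Generator | None = None,
    ):
        """Run the stack; return (probs, logits-sigmoids, caches).

        ``train_rng`` enables inverted dropout and cache collection for the
        backward pass; inference passes ``None`` and is fully deterministic.
        """
        cfg = self.config
        B, T, _ = X.shape
        H = cfg.hidden_size
        caches = []
        layer_in = X
        for l in range(cfg.n_lstm_layers):
            W, U, b = self.params[f"W{l}"], self.params[f"U{l}"], self.params[f"b{l}"]
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            Hseq = np.empty((B, T, H))
            steps = [] if train_rng is not None else None
            for t in range(T):
                x = layer_in[:, t, :]
                m = M[:, t][:, None]
                z = x @ W + h @ U + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H : 2 * H])
                g = np.tanh(z[:, 2 * H : 3 * H])
                o = _sigmoid(z[:, 3 * H :])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                if steps is not None:
                    steps.append((x, h, c, i, f, g, o, tc, m))
                h = m * h_new + (1.0 - m) * h
                c = m * c_new + (1.0 - m) * c
                Hseq[:, t, :] = h
            drop_mask = None
            p_drop = cfg.dropout[l]
            if train_rng is not None and p_drop > 0:
                drop_mask = (train_rng.random(Hseq.shape) >= p_drop) / (1.0 - p_drop)
                Hseq = Hseq * drop_mask
            if steps is not None:
                caches.append({"steps": steps, "drop": drop_mask, "in": layer_in})
            layer_in = Hseq
        h_final = layer_in[:, -1, :]
        logits = h_final @ self.params["Wo"] + self.params["bo"]
        s = np.clip(_sigmoid(logits), 1e-9, 1.0 - 1e-9)
        probs = s / s.sum(axis=1, keepdims=True)
        return probs, s, h_final, layer_in, caches

    def predict_proba_batch(self, X: np.ndarray, M: np.ndarray) -> np.ndarray:
        probs, _, _, _, _ = self._forward(X, M, None)
        return probs[:, 1]

    def predict_proba(
        self, encs: Sequence[EncodedPeptide], chunk: int = 512
    ) -> np.ndarray:
        out = np.empty(len(encs))
        for start in range(0, len(encs), chunk):
            part = encs[start : start + chunk]
            X, M = _pad_batch(part)
            out[start : start + len(part)] = self.predict_proba_batch(X, M)
        return out

    # -- backward ----------------------------------------------------------

    def _backward(
        self,
        X: np.ndarray,
        M: np.ndarray,
        y: np.ndarray,
        probs: np.ndarray,
        s: np.ndarray,
        h_final: np.ndarray,
        top_seq: np.ndarray,
        caches: list,
    ) -> dict[str, np.ndarray]:
        cfg = self.config
        B, T, _ = X.shape
        H = cfg.hidden_size
        Y = np.zeros_like(probs)
        Y[np.arange(B), y] = 1.0
        # loss = -log p_true with p = s / sum(s):  dL/dlogit = (p - y) (1 - s)
        dlogits = (probs - Y) * (1.0 - s) / B
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wo"] = h_final.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh_final = dlogits @ self.params["Wo"].T

        # gradient w.r.t. each layer's (dropped) output sequence
        dHseq = np.zeros((B, T, H))
        dHseq[:, -1, :] = dh_final
        for l in reversed(range(cfg.n_lstm_layers)):
            cache = caches[l]
            if cache["drop"] is not None:
                dHseq = dHseq * cache["drop"]
            W, U = self.params[f"W{l}"], self.params[f"U{l}"]
            dW = grads[f"W{l}"]
            dU = grads[f"U{l}"]
            db = grads[f"b{l}"]
            layer_in = cache["in"]
            dX = np.zeros_like(layer_in)
            dh = np.zeros((B, H))
            dc = np.zeros((B, H))
            for t in reversed(range(T)):
                x, h_prev, c_prev, i, f, g, o, tc, m = cache["steps"][t]
                dh_t = dh + dHseq[:, t, :]
                dc_t = dc
                dh_new = m * dh_t
                do = dh_new * tc
                dc_new = m * dc_t + dh_new * o * (1.0 - tc**2)
                df = dc_new * c_prev
                di = dc_new * g
                dg = dc_new * i
                dz = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g**2),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                dW += x.T @ dz
                dU += h_prev.T @ dz
                db += dz.sum(axis=0)
                dX[:, t, :] = dz @ W.T
                dh = dz @ U.T + (1.0 - m) * dh_t
                dc = dc_new * f + (1.0 - m) * dc_t
            dHseq = dX  # becomes the output-gradient of the layer below
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        if cfg.grad_clip and norm > cfg.grad_clip:
            scale = cfg.grad_clip / norm
            grads = {k: g * scale for k, g in grads.items()}
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g**2
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    # -- training ----------------------------------------------------------

    def fit(
        self,
        encs: Sequence[EncodedPeptide],
        y: np.ndarray,
        rng_seed: int | None = None,
    ) -> list[dict]:
        """Train with Adam + early stopping on held-out accuracy.

        Returns the per-epoch training log.  Deterministic for a fixed seed
        (all shuffling, dropout and the validation split come from one
        seeded generator).
        """
        cfg = self.config
        y = np.asarray(y, dtype=int)
        if len(encs) != len(y):
            raise ValueError("one label per encoded peptide required")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(cfg.seed if rng_seed is None else rng_seed)

        # stratified validation holdout for early stopping; with
        # validation_fraction <= 0 the monitor is training accuracy itself
        # (useful for capacity/overfit checks)
        val_idx: list[int] = []
        train_idx: list[int] = []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            idx = idx[rng.permutation(len(idx))]
            if cfg.validation_fraction > 0:
                n_val = int(round(cfg.validation_fraction * len(idx)))
                n_val = min(max(n_val, 1), len(idx) - 1)
            else:
                n_val = 0
            val_idx.extend(idx[:n_val])
            train_idx.extend(idx[n_val:])
        train_idx = np.array(train_idx)
        val_idx = np.array(val_idx) if val_idx else train_idx
        val_encs = [encs[i] for i in val_idx]
        val_y = y[val_idx]

        log: list[dict] = []
        best_acc = -1.0
        best_params = None
        best_epoch = -1
        stale = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(train_idx))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = train_idx[order[start : start + cfg.batch_size]]
                X, M = _pad_batch([encs[i] for i in batch])
                yb = y[batch]
                probs, s, h_final, top_seq, caches = self._forward(X, M, rng)
                loss = float(-np.log(probs[np.arange(len(yb)), yb]).mean())
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}; lower the learning "
                        f"rate or check the encoding scale"
                    )
                losses.append(loss)
                grads = self._backward(X, M, yb, probs, s, h_final, top_seq, caches)
                self._adam_step(grads)
            val_p = self.predict_proba(val_encs)
            val_acc = float(((val_p > 0.5).astype(int) == val_y).mean())
            log.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc}
            )
            if val_acc > best_acc:
                best_acc = val_acc
                best_params = {k: v.copy() for k, v in self.params.items()}
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        if best_params is not None:
            self.params = best_params
        log.append({"best_epoch": best_epoch, "best_val_acc": best_acc})
        self.fitted = True
        return log


@dataclass
class TrainedClassifier:
    """A fitted model bound to the descriptor combination it was trained on."""

    model: LSTMClassifier
    config: ModelConfig
    combination: DescriptorCombination
    training_log: list[dict] = field(default_factory=list)

    @property
    def combination_label(self) -> str:
        return self.combination.label

    def predict_encoded(self, encs: Sequence[EncodedPeptide]) -> np.ndarray:
        """Positive-class probability for already-encoded peptides."""
        return self.model.predict_proba(encs)

    def save(self, path: str | Path) -> None:
        """Versioned checkpoint: weights as .npz next to a .json config."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.model.params)
        meta = {
            "format_version": 1,
            "config": asdict(self.config),
            "combination": {
                "member_sets": list(self.combination.member_sets),
                "member_features": list(self.combination.member_features),
                "label": self.combination.label,
            },
            "training_log": self.training_log,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported checkpoint version in {path}")
        cfg_d = meta["config"]
        cfg_d["dropout"] = tuple(cfg_d["dropout"])
        config = ModelConfig(**cfg_d)
        model = LSTMClassifier(config)
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in data.files}
        model.fitted = True
        cmb = meta["combination"]
        combination = DescriptorCombination(
            tuple(cmb["member_sets"]), tuple(cmb["member_features"]), cmb["label"]
        )
        return cls(model, config, combination, meta.get("training_log", []))


class MeanPoolLogistic:
    """Fast proxy classifier: logistic regression on mean-pooled encodings.

    Pools each encoded peptide to the per-column mean over its residues and
    fits a plain logistic regression.  Implements the same
    ``predict_encoded`` interface as :class:`TrainedClassifier`, so it can
    stand in wherever speed matters more than sequence order (selection fast
    mode, smoke tests).
    """

    def __init__(self, combination: DescriptorCombination, seed: int = 0):
        self.combination = combination
        self._clf = LogisticRegression(max_iter=1000, random_state=seed)
        self.fitted = False

    @property
    def combination_label(self) -> str:
        return self.combination.label

    @staticmethod
    def _pool(encs: Sequence[EncodedPeptide]) -> np.ndarray:
        return np.stack([e.matrix.mean(axis=0) for e in encs])

    def fit(self, encs: Sequence[EncodedPeptide], y: np.ndarray) -> "MeanPoolLogistic":
        self._clf.fit(self._pool(encs), np.asarray(y, dtype=int))
        self.fitted = True
        return self

    def predict_encoded(self, encs: Sequence[EncodedPeptide]) -> np.ndarray:
        return self._clf.predict_proba(self._pool(encs))[:, 1]


# ---------------------------------------------------------------------------
# operations

def build_model(config: ModelConfig) -> LSTMClassifier:
    """Construct an untrained network for the given configuration."""
    return LSTMClassifier(config)


def train_classifier(
    ds: LabeledDataset,
    combination: DescriptorCombination,
    registry: DescriptorRegistry,
    config: ModelConfig | None = None,
    rng_seed: int | None = None,
) -> TrainedClassifier:
    """Encode the dataset's training records under a combination and fit.

    Uses every record whose ``split`` is ``"train"`` (or all records when no
    split is assigned).
    """
    records = [r for r in ds.records if r.split in (None, "train")]
    if not records:
        raise ValueError("dataset has no training records")
    if config is None:
        config = ModelConfig(input_features=combination.total_features)
    if config.input_features != combination.total_features:
        raise ValueError(
            f"config expects {config.input_features} input features but the "
            f"combination {combination.label!r} has {combination.total_features}"
        )
    encs = [encode(r.sequence, combination, registry) for r in records]
    y = np.array([1 if r.label == "positive" else 0 for r in records])
    model = build_model(config)
    log = model.fit(encs, y, rng_seed)
    return TrainedClassifier(model, config, combination, log)


def predict(
    model: TrainedClassifier | MeanPoolLogistic,
    sequences: Sequence[str],
    registry: DescriptorRegistry,
) -> tuple[np.ndarray, dict[int, str]]:
    """Positive-class probabilities for raw sequences, preserving order.

    Unencodable sequences are reported in the returned ``errors`` map
    (index → message) and carry ``nan`` probabilities; the batch continues.
    """
    encs: list[EncodedPeptide] = []
    ok_idx: list[int] = []
    errors: dict[int, str] = {}
    for i, s in enumerate(sequences):
        try:
            encs.append(encode(s, model.combination, registry))
            ok_idx.append(i)
        except EncodingError as err:
            errors[i] = str(err)
    probs = np.full(len(sequences), np.nan)
    if encs:
        probs[ok_idx] = model.predict_encoded(encs)
    return probs, errors
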