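"""1-D convolutional binary classifier for SRE/NF-Y composite windows.

The network maps a (200, 5) one-hot matrix (forward window + reverse
complement) to the probability that the window contains an SRE site with a
nearby NF-Y site.  Architecture:

    conv1d(n_filters, kernel, ReLU) -> max-pool(2)
    -> conv1d(n_filters, kernel, ReLU) -> global max-pool
    -> dense(64, ReLU) -> dropout(0.3) -> dense(1, sigmoid)

trained with binary cross-entropy and Adam (lr 1e-3).  Convolutions are
"valid" (no padding); the global max-pool gives position invariance, which is
what lets one trained model slide across promoters of arbitrary layout.

Everything — forward, backward, the optimizer and the staged early-stopping
loop — is implemented here on NumPy so training is deterministic for a fixed
seed on a given machine.  Batches of raw 100-base strings are one-hot encoded
on the fly (streaming), never materialized corpus-wide.

The tuning grid used when exploring hyperparameters is n_filters in
{32, 64, 128} and kernel_size in {3, 6, 12}; training runs up to three blocks
of 40/30/10 epochs with per-block early-stopping patiences 15/10/5 on
validation accuracy, restoring the best weights after each block.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .couples import LabeledSequence
from .encode import ENCODED_LENGTH, N_SYMBOLS, encode_batch

FILTER_GRID = (32, 64, 128)
KERNEL_GRID = (3, 6, 12)

CHECKPOINT_FORMAT = "srescan-cnn-v1"


@dataclass(frozen=True)
class ModelConfig:
    n_filters: int = 64
    kernel_size: int = 6
    batch_size: int = 512
    epoch_blocks: tuple[int, ...] = (40, 30, 10)
    patience_per_block: tuple[int, ...] = (15, 10, 5)
    learning_rate: float = 1e-3
    dense_units: int = 64
    dropout: float = 0.3
    rng_seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if len(self.epoch_blocks) != len(self.patience_per_block):
            raise ValueError("epoch_blocks and patience_per_block must align")
        if self.n_filters not in FILTER_GRID:
            warnings.warn(f"n_filters={self.n_filters} is off the usual grid {FILTER_GRID}")
        if self.kernel_size not in KERNEL_GRID:
            warnings.warn(f"kernel_size={self.kernel_size} is off the usual grid {KERNEL_GRID}")


@dataclass
class TrainingHistory:
    losses: list[float] = field(default_factory=list)
    val_accuracies: list[float] = field(default_factory=list)
    block_ends: list[int] = field(default_factory=list)   # epoch count after each block
    best_epoch: int = -1

    @property
    def best_val_accuracy(self) -> float:
        return max(self.val_accuracies) if self.val_accuracies else float("nan")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\tloss\tval_accuracy\n")
            for i, (l, a) in enumerate(zip(self.losses, self.val_accuracies)):
                fh.write(f"{i}\t{l:.6f}\t{a:.6f}\n")


@dataclass(frozen=True)
class ClassifierMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _conv_cols(x: np.ndarray, k: int) -> np.ndarray:
    """im2col: (B, L, C) -> (B, L-k+1, k*C)."""
    v = sliding_window_view(x, k, axis=1)          # (B, L-k+1, C, k)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - k + 1, k * x.shape[2]
    )


class SREClassifier:
    """The trainable network; see the module docstring for the layer stack."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        self.config = config
        self.rng = np.random.default_rng(config.rng_seed)
        k, f, d = config.kernel_size, config.n_filters, config.dense_units
        he = lambda fan_in, shape: (
            self.rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.params = {
            "W1": he(k * N_SYMBOLS, (k * N_SYMBOLS, f)),
            "b1": np.zeros(f, dtype=np.float32),
            "W2": he(k * f, (k * f, f)),
            "b2": np.zeros(f, dtype=np.float32),
            "W3": he(f, (f, d)),
            "b3": np.zeros(d, dtype=np.float32),
            "W4": (self.rng.standard_normal((d, 1)) * np.sqrt(1.0 / d)).astype(np.float32),
            "b4": np.zeros(1, dtype=np.float32),
        }
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- forward

    def _forward(self, x: np.ndarray, train: bool = False):
        p, cfg = self.params, self.config
        k = cfg.kernel_size
        cols1 = _conv_cols(x, k)
        z1 = cols1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        L1 = a1.shape[1]
        L1p = L1 // 2
        pairs = a1[:, : 2 * L1p].reshape(a1.shape[0], L1p, 2, -1)
        pool_arg = pairs.argmax(axis=2)
        a1p = pairs.max(axis=2)
        cols2 = _conv_cols(a1p, k)
        z2 = cols2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        g_arg = a2.argmax(axis=1)
        g = a2.max(axis=1)
        h_pre = g @ p["W3"] + p["b3"]
        h = np.maximum(h_pre, 0.0)
        if train and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            mask = (self.rng.random(h.shape) < keep).astype(np.float32) / keep
        else:
            mask = None
        h_out = h * mask if mask is not None else h
        z = h_out @ p["W4"] + p["b4"]
        prob = _sigmoid(z)
        cache = (x, cols1, z1, pool_arg, a1p, cols2, z2, g_arg, g, h_pre, h_out, mask, L1)
        return prob, cache

    def predict_proba(self, matrices: np.ndarray) -> np.ndarray:
        """Probabilities for a (n, 200, 5) batch of encoded windows."""
        matrices = np.asarray(matrices, dtype=np.float32)
        if matrices.ndim == 2:
            matrices = matrices[None]
        if matrices.shape[1:] != (ENCODED_LENGTH, N_SYMBOLS):
            raise ValueError(
                f"expected (*, {ENCODED_LENGTH}, {N_SYMBOLS}) matrices, got {matrices.shape}"
            )
        out = []
        bs = self.config.batch_size
        for i in range(0, len(matrices), bs):
            prob, _ = self._forward(matrices[i : i + bs], train=False)
            out.append(prob[:, 0])
        return np.concatenate(out) if out else np.zeros(0)

    def predict_proba_sequences(self, seqs: list[str]) -> np.ndarray:
        """Probabilities for raw 100-base windows (encoded in batches)."""
        out = []
        bs = self.config.batch_size
        for i in range(0, len(seqs), bs):
            out.append(self.predict_proba(encode_batch(seqs[i : i + bs])))
        return np.concatenate(out) if out else np.zeros(0)

    # --------------------------------------------------------------- backward

    def _backward(self, prob: np.ndarray, y: np.ndarray, cache) -> dict[str, np.ndarray]:
        p, cfg = self.params, self.config
        k = cfg.kernel_size
        (x, cols1, z1, pool_arg, a1p, cols2, z2, g_arg, g, h_pre, h_out, mask, L1) = cache
        B = x.shape[0]
        dz = (prob - y[:, None]).astype(np.float32) / B  # d(mean BCE)/d(logit)
        grads = {}
        grads["W4"] = h_out.T @ dz
        grads["b4"] = dz.sum(axis=0)
        dh = dz @ p["W4"].T
        if mask is not None:
            dh = dh * mask
        dh_pre = dh * (h_pre > 0)
        grads["W3"] = g.T @ dh_pre
        grads["b3"] = dh_pre.sum(axis=0)
        dg = dh_pre @ p["W3"].T
        F = dg.shape[1]
        da2 = np.zeros_like(z2)
        da2[np.arange(B)[:, None], g_arg, np.arange(F)[None, :]] = dg
        dz2 = da2 * (z2 > 0)
        L2 = z2.shape[1]
        grads["W2"] = cols2.reshape(B * L2, -1).T @ dz2.reshape(B * L2, F)
        grads["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = (dz2 @ p["W2"].T).reshape(B, L2, k, F)
        da1p = np.zeros_like(a1p)
        for j in range(k):
            da1p[:, j : j + L2] += dcols2[:, :, j, :]
        da1 = np.zeros_like(z1)
        L1p = a1p.shape[1]
        pos = 2 * np.arange(L1p)[None, :, None] + pool_arg
        np.put_along_axis(da1, pos, da1p, axis=1)
        dz1 = da1 * (z1 > 0)
        grads["W1"] = cols1.reshape(B * L1, -1).T @ dz1.reshape(B * L1, F)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for name, g in grads.items():
            m = self._adam_m[name] = b1 * self._adam_m[name] + (1 - b1) * g
            v = self._adam_v[name] = b2 * self._adam_v[name] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[name] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    def train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        prob, cache = self._forward(np.asarray(x, dtype=np.float32), train=True)
        p = np.clip(prob[:, 0], 1e-7, 1 - 1e-7)
        loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        self._adam_step(self._backward(prob, np.asarray(y, dtype=np.float32), cache))
        return loss

    # ------------------------------------------------------------ persistence

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k_: v.copy() for k_, v in self.params.items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for k_, v in snap.items():
            self.params[k_] = v.copy()

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def save(self, path) -> None:
        """Single-file checkpoint with a versioned header."""
        meta = dict(self.config.__dict__)
        meta["epoch_blocks"] = list(meta["epoch_blocks"])
        meta["patience_per_block"] = list(meta["patience_per_block"])
        np.savez(
            path,
            __format__=CHECKPOINT_FORMAT,
            __config__=json.dumps(meta),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "SREClassifier":
        with np.load(path, allow_pickle=False) as data:
            if str(data["__format__"]) != CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognized checkpoint format in {path}")
            meta = json.loads(str(data["__config__"]))
            meta["epoch_blocks"] = tuple(meta["epoch_blocks"])
            meta["patience_per_block"] = tuple(meta["patience_per_block"])
            model = cls(ModelConfig(**meta))
            for name in model.params:
                model.params[name] = data[name].astype(np.float32)
        return model


def build_model(config: ModelConfig = ModelConfig()) -> SREClassifier:
    return SREClassifier(config)


def _check_sets(train_set, val_set) -> None:
    if not train_set or not val_set:
        raise ValueError("training and validation sets must both be non-empty")
    labels = {s.label for s in train_set}
    if len(labels) < 2:
        raise ValueError("training set contains a single class; cannot fit a classifier")


def train(
    model: SREClassifier,
    train_set: list[LabeledSequence],
    val_set: list[LabeledSequence],
    config: ModelConfig | None = None,
) -> TrainingHistory:
    """Fit with streaming batches and staged early stopping.

    Runs up to ``len(epoch_blocks)`` blocks; within each block an epoch that
    fails to improve validation accuracy increments a patience counter and
    the block ends when the counter reaches that block's patience.  The best
    weights seen so far are restored at every block boundary and at the end,
    so the returned model is always the best-validation-accuracy one.
    """
    config = config or model.config
    _check_sets(train_set, val_set)
    rng = np.random.default_rng(config.rng_seed + 1)
    seqs = [s.sequence for s in train_set]
    y = np.array([s.label for s in train_set], dtype=np.float32)
    val_seqs = [s.sequence for s in val_set]
    val_y = np.array([s.label for s in val_set], dtype=np.float32)

    history = TrainingHistory()
    best_acc = -np.inf
    best_snap = model.snapshot()
    epoch = 0
    for block_epochs, patience in zip(config.epoch_blocks, config.patience_per_block):
        stale = 0
        for _ in range(block_epochs):
            order = rng.permutation(len(seqs))
            losses = []
            for i in range(0, len(order), config.batch_size):
                idx = order[i : i + config.batch_size]
                xb = encode_batch([seqs[j] for j in idx])
                losses.append(model.train_batch(xb, y[idx]))
            probs = model.predict_proba_sequences(val_seqs)
            acc = float(np.mean((probs >= config.decision_threshold) == (val_y == 1)))
            history.losses.append(float(np.mean(losses)))
            history.val_accuracies.append(acc)
            if acc > best_acc:
                best_acc = acc
                best_snap = model.snapshot()
                history.best_epoch = epoch
                stale = 0
            else:
                stale += 1
            epoch += 1
            if stale >= patience:
                break
        model.restore(best_snap)
        history.block_ends.append(epoch)
    model.restore(best_snap)
    return history


def predict_proba(model: SREClassifier, matrices: np.ndarray) -> np.ndarray:
    return model.predict_proba(matrices)


def evaluate(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ClassifierMetrics:
    """Confusion counts and accuracy/precision/recall/F1 at a threshold."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels).astype(int)
    if probabilities.size == 0:
        raise ValueError("cannot evaluate on an empty prediction vector")
    if probabilities.shape != labels.shape:
        raise ValueError("probabilities and labels must have equal length")
    pred = probabilities >= threshold
    truth = labels == 1
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    total = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ClassifierMetrics(
        accuracy=(tp + tn) / total,
        precision=precision,
        recall=recall,
        f1=f1,
        tp=tp, fp=fp, fn=fn, tn=tn,
    )
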