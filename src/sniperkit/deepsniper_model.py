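"""Convolutional sequence-to-activity regression networks.

Two architectures predict editing activity (%) of a high-fidelity Cas9
variant:

* **On-target**: a one-hot 30-nt target context (4-nt upstream, 20-nt
  protospacer, PAM, 3-nt downstream) passes a 256-filter, 5-nt
  convolution with length-preserving zero padding, ReLU, average
  pooling, then dense layers 1500-1500-100; the sgRNA expression system
  ((G/g)N19 vs tRNA-N20, a binary flag) is embedded as a learned
  100-dim vector and multiplied elementwise with the 100-unit layer
  output; a final linear map yields the score.

* **Off-target**: the 20-nt spacer and the mismatched 20-nt target are
  one-hot encoded and stacked as 8 channels x 20 positions into a
  128-filter convolution (width 3 or 5 depending on the variant
  profile); per-position numeric mismatch codes are concatenated after
  flattening; dense layers 1500-1500-1500-100 and a linear output head
  follow. No expression-system input.

Both train with mean-absolute-error loss and Adam at learning rate
1e-4, dropout 0.3 on the dense stack, under five-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import nn
from .library_model import AlphabetError, ShapeError, annotate_mismatches

__all__ = [
    "OnTargetConfig",
    "OffTargetConfig",
    "TrainingRun",
    "encode_on_target",
    "encode_off_target",
    "OnTargetModel",
    "OffTargetModel",
    "build_model",
    "train",
    "crossvalidate",
    "predict",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# 12 ordered substitutions (spacer base -> target base), 1-based codes;
# 0 means match
_SUBSTITUTION_CODE = {
    (s, t): i + 1
    for i, (s, t) in enumerate(
        (s, t) for s in "ACGT" for t in "ACGT" if s != t
    )
}


def _one_hot(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    mat = np.zeros((4, len(seq)))
    for i, base in enumerate(seq):
        if base not in _BASE_INDEX:
            raise AlphabetError(f"ambiguous base {base!r} in {seq!r}")
        mat[_BASE_INDEX[base], i] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    bases = "ACGT"
    return "".join(bases[int(i)] for i in mat.argmax(axis=0))


def encode_on_target(context: str, expression_system: str) -> tuple[np.ndarray, int]:
    """One-hot encode a 30-nt target context plus a binary
    expression-system flag (0 = (G/g)N19, 1 = tRNA-N20)."""
    if len(context) != 30:
        raise ShapeError(f"context must be 30 nt, got {len(context)}")
    flag = 1 if expression_system == "tRNA_N20" else 0
    return _one_hot(context), flag


def encode_off_target(spacer: str, target: str) -> tuple[np.ndarray, np.ndarray]:
    """Encode a spacer / mismatched-target pair.

    Returns an 8 x 20 one-hot stack (channels 1-4 spacer, 5-8 target)
    and a 20-long numeric feature vector: index p-1 holds the
    substitution code of the mismatch at PAM-anchored position p
    (0 when matched).
    """
    if len(spacer) != 20 or len(target) != 20:
        raise ShapeError("spacer and target must both be 20 nt")
    stack = np.vstack([_one_hot(spacer), _one_hot(target)])
    features = np.zeros(20)
    for m in annotate_mismatches(spacer, target):
        s = m.spacer_base.replace("U", "T")
        features[m.position_pam - 1] = _SUBSTITUTION_CODE[(s, m.protospacer_base)]
    return stack, features


@dataclass
class OnTargetConfig:
    input_length: int = 30
    conv_filters: int = 256
    conv_width: int = 5
    pool_width: int = 2
    pool_stride: int = 2
    fc_sizes: tuple[int, ...] = (1500, 1500, 100)
    system_embedding_dim: int = 100
    dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.fc_sizes[-1] != self.system_embedding_dim:
            raise ValueError(
                "final dense width must equal the embedding dimension for "
                "the elementwise product"
            )


@dataclass
class OffTargetConfig:
    input_length: int = 20
    conv_filters: int = 128
    conv_width: int = 5  # 3 for the Sniper1 profile, 5 for Sniper2L
    pool_width: int = 2
    pool_stride: int = 2
    fc_sizes: tuple[int, ...] = (1500, 1500, 1500, 100)
    n_mismatch_features: int = 20
    dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.conv_width not in (3, 5):
            raise ValueError("conv_width must be 3 or 5")


@dataclass
class TrainingRun:
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    folds: int = 5
    seed: int = 0
    patience: int = 10  # early stopping on validation MAE; 0 disables
    history: list[dict] = field(default_factory=list)


class OnTargetModel:
    """Sequence + expression-system activity regressor."""

    def __init__(self, config: OnTargetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.conv = nn.Conv1D(4, c.conv_filters, c.conv_width, rng)
        self.relu_c = nn.ReLU()
        self.pool = nn.AvgPool1D(c.pool_width, c.pool_stride)
        flat = c.conv_filters * (c.input_length // c.pool_stride)
        self.dense = []
        self.relu_d = []
        self.drop = []
        prev = flat
        for width in c.fc_sizes:
            self.dense.append(nn.Dense(prev, width, rng))
            self.relu_d.append(nn.ReLU())
            self.drop.append(nn.Dropout(c.dropout, rng))
            prev = width
        self.embed = nn.Embedding(2, c.system_embedding_dim, rng)
        self.head = nn.Dense(c.system_embedding_dim, 1, rng)
        self._layers = [self.conv, *self.dense, self.embed, self.head]

    def parameter_count(self) -> int:
        return sum(p.size for layer in self._layers for p in layer.params())

    def forward(self, x: np.ndarray, flags: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.pool.forward(self.relu_c.forward(self.conv.forward(x, train)))
        h = h.reshape(h.shape[0], -1)
        for dense, relu, drop in zip(self.dense, self.relu_d, self.drop):
            h = drop.forward(relu.forward(dense.forward(h, train)), train)
        e = self.embed.forward(flags)
        self._h, self._e = h, e
        return self.head.forward(h * e, train)[:, 0]

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g[:, None])
        self.embed.backward(g * self._h)
        g = g * self._e
        for dense, relu, drop in zip(
            reversed(self.dense), reversed(self.relu_d), reversed(self.drop)
        ):
            g = dense.backward(relu.backward(drop.backward(g)))
        b = g.shape[0]
        c = self.config
        g = g.reshape(b, c.conv_filters, c.input_length // c.pool_stride)
        self.conv.backward(self.relu_c.backward(self.pool.backward(g)))

    def params_grads(self):
        params, grads = [], []
        for layer in self._layers:
            params.extend(layer.params())
            grads.extend(layer.grads())
        return params, grads

    def predict(self, x: np.ndarray, flags: np.ndarray) -> np.ndarray:
        return self.forward(x, flags, train=False)


class OffTargetModel:
    """Spacer/mismatched-target activity regressor."""

    def __init__(self, config: OffTargetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.conv = nn.Conv1D(8, c.conv_filters, c.conv_width, rng)
        self.relu_c = nn.ReLU()
        self.pool = nn.AvgPool1D(c.pool_width, c.pool_stride)
        flat = c.conv_filters * (c.input_length // c.pool_stride)
        self.dense = []
        self.relu_d = []
        self.drop = []
        prev = flat + c.n_mismatch_features
        for width in c.fc_sizes:
            self.dense.append(nn.Dense(prev, width, rng))
            self.relu_d.append(nn.ReLU())
            self.drop.append(nn.Dropout(c.dropout, rng))
            prev = width
        self.head = nn.Dense(c.fc_sizes[-1], 1, rng)
        self._layers = [self.conv, *self.dense, self.head]

    def parameter_count(self) -> int:
        return sum(p.size for layer in self._layers for p in layer.params())

    def forward(
        self, x: np.ndarray, features: np.ndarray, train: bool = False
    ) -> np.ndarray:
        h = self.pool.forward(self.relu_c.forward(self.conv.forward(x, train)))
        h = h.reshape(h.shape[0], -1)
        self._n_flat = h.shape[1]
        h = np.concatenate([h, features], axis=1)
        for dense, relu, drop in zip(self.dense, self.relu_d, self.drop):
            h = drop.forward(relu.forward(dense.forward(h, train)), train)
        return self.head.forward(h, train)[:, 0]

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g[:, None])
        for dense, relu, drop in zip(
            reversed(self.dense), reversed(self.relu_d), reversed(self.drop)
        ):
            g = dense.backward(relu.backward(drop.backward(g)))
        g = g[:, : self._n_flat]  # drop the mismatch-feature columns
        b = g.shape[0]
        c = self.config
        g = g.reshape(b, c.conv_filters, c.input_length // c.pool_stride)
        self.conv.backward(self.relu_c.backward(self.pool.backward(g)))

    def params_grads(self):
        params, grads = [], []
        for layer in self._layers:
            params.extend(layer.params())
            grads.extend(layer.grads())
        return params, grads

    def predict(self, x: np.ndarray, features: np.ndarray) -> np.ndarray:
        return self.forward(x, features, train=False)


def build_model(config, seed: int = 0):
    """Instantiate the network matching the config type."""
    if isinstance(config, OnTargetConfig):
        return OnTargetModel(config, seed)
    if isinstance(config, OffTargetConfig):
        return OffTargetModel(config, seed)
    raise TypeError(f"unknown config type {type(config).__name__}")


def train(
    model,
    x: np.ndarray,
    aux: np.ndarray,
    y: np.ndarray,
    run: TrainingRun,
    x_val: np.ndarray | None = None,
    aux_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
):
    """Fit a model with MAE loss and Adam.

    ``aux`` is the expression-system flag vector (on-target) or the
    mismatch-feature matrix (off-target). History records per-epoch
    train (and, when a validation set is given, validation) MAE; early
    stopping restores nothing — it simply halts when the validation MAE
    has not improved for ``run.patience`` epochs.
    """
    n = len(y)
    if n == 0:
        raise ValueError("training dataset is empty")
    x = np.ascontiguousarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if aux.dtype.kind == "f":
        aux = np.asarray(aux, dtype=np.float32)
    if x_val is not None:
        x_val = np.ascontiguousarray(x_val, dtype=np.float32)
        if aux_val is not None and aux_val.dtype.kind == "f":
            aux_val = np.asarray(aux_val, dtype=np.float32)
    params, grads = model.params_grads()
    opt = nn.Adam(params, grads, lr=run.lr)
    rng = np.random.default_rng(run.seed)
    best_val = np.inf
    stale = 0
    for epoch in range(run.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, run.batch_size):
            idx = order[start : start + run.batch_size]
            pred = model.forward(x[idx], aux[idx], train=True)
            loss, g = nn.mae_loss(pred, y[idx])
            model.backward(g)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch + 1, "train_mae": float(np.mean(losses))}
        if y_val is not None:
            val_pred = predict(model, x_val, aux_val)
            entry["val_mae"] = float(np.abs(val_pred - y_val).mean())
            if entry["val_mae"] < best_val - 1e-9:
                best_val = entry["val_mae"]
                stale = 0
            else:
                stale += 1
        run.history.append(entry)
        if run.patience and y_val is not None and stale >= run.patience:
            break
    return model


def predict(model, x: np.ndarray, aux: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Deterministic eval-mode predictions (dropout off)."""
    x = np.ascontiguousarray(x, dtype=np.float32)
    if aux.dtype.kind == "f":
        aux = np.asarray(aux, dtype=np.float32)
    outputs = []
    for start in range(0, len(x), batch_size):
        outputs.append(model.forward(x[start : start + batch_size], aux[start : start + batch_size], train=False))
    return np.concatenate(outputs) if outputs else np.empty(0)


def crossvalidate(
    config,
    x: np.ndarray,
    aux: np.ndarray,
    y: np.ndarray,
    run: TrainingRun,
    k: int = 5,
) -> dict:
    """K-fold cross-validation: disjoint, exhaustive folds; fresh model
    per fold; per-fold and pooled MAE / Pearson / Spearman."""
    n = len(y)
    if k > n:
        raise ValueError(f"k = {k} exceeds dataset size {n}")
    rng = np.random.default_rng(run.seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    fold_metrics = []
    pooled_pred = np.empty(n)
    for i, val_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        fold_run = TrainingRun(
            lr=run.lr,
            epochs=run.epochs,
            batch_size=run.batch_size,
            seed=run.seed + i,
            patience=run.patience,
        )
        model = build_model(config, seed=run.seed + i)
        train(model, x[train_idx], aux[train_idx], y[train_idx], fold_run)
        pred = predict(model, x[val_idx], aux[val_idx])
        pooled_pred[val_idx] = pred
        fold_metrics.append(_metrics(pred, y[val_idx]))
    return {
        "folds": [f.tolist() for f in folds],
        "fold_metrics": fold_metrics,
        "pooled": _metrics(pooled_pred, y),
    }


def _metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    out = {"mae": float(np.abs(pred - truth).mean())}
    if len(pred) > 2 and np.std(pred) > 0 and np.std(truth) > 0:
        out["pearson"] = float(stats.pearsonr(pred, truth)[0])
        out["spearman"] = float(stats.spearmanr(pred, truth)[0])
    else:
        out["pearson"] = float("nan")
        out["spearman"] = float("nan")
    return out
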