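"""The next-base predictor: a character-level DNA model over gap flanks.

Architecture (fixed): one-hot input -> 1-D convolution (ReLU) -> batch
normalization -> max pooling -> dropout -> two stacked BiLSTM layers ->
elementwise residual sum with a width-1 convolutional projection of the
CNN features -> max pool over time -> affine map to 4 logits -> softmax.
The residual path gives the recurrent stack a direct shortcut to the
local convolutional features, easing gradient flow through the depth.

Training minimizes 4-class cross-entropy on (context -> next base)
pairs harvested by a sliding window over N-free genome stretches, with
Adam, a held-out validation split and early stopping. Everything is
seeded and single-threaded NumPy, so a fixed seed plus fixed data gives
bit-identical parameters and predictions.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .encode import CHANNEL_ORDER, one_hot_encode
from .io import ScaffoldRecord


class ModelIOError(ValueError):
    """Model file missing, corrupt, or inconsistent with this build."""


@dataclass(frozen=True)
class ModelConfig:
    window_len: int = 64
    conv_channels: int = 64
    kernel_size: int = 3
    stride: int = 1
    padding: int = 1
    pool_size: int = 2
    dropout_rate: float = 0.1
    bn_epsilon: float = 1e-5
    lstm_hidden: int = 128
    n_bilstm_layers: int = 2  # fixed by the architecture
    channel_order: str = CHANNEL_ORDER

    def __post_init__(self) -> None:
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.bn_epsilon <= 0:
            raise ValueError("bn_epsilon must be positive")
        if self.n_bilstm_layers != 2:
            raise ValueError("the architecture fixes n_bilstm_layers at 2")
        conv_len = (self.window_len + 2 * self.padding - self.kernel_size) // self.stride + 1
        if conv_len // self.pool_size < 1:
            raise ValueError("pool_size larger than the convolved sequence")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 50
    early_stop_patience: int = 5
    validation_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.early_stop_patience) <= 0:
            raise ValueError("learning_rate, batch_size, early_stop_patience must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass(frozen=True)
class TrainingExample:
    context: str
    target: str

    def __post_init__(self) -> None:
        if "N" in self.context or self.target not in "ACGT":
            raise ValueError("training examples must be N-free with a definite target")


class NextBaseModel:
    """Parameter bundle + config; produces P(next base | context)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.training_fingerprint: str | None = None
        rng = np.random.default_rng(seed)
        c, H = config.conv_channels, config.lstm_hidden
        self.conv = nn.Conv1d(4, c, config.kernel_size, config.stride, config.padding, rng=rng)
        self.relu = nn.ReLU()
        self.bn = nn.BatchNorm1d(c, eps=config.bn_epsilon)
        self.pool = nn.MaxPool1d(config.pool_size)
        self.drop = nn.Dropout(config.dropout_rate)
        self.bilstm1 = nn.BiLSTM(c, H, rng=rng)
        self.bilstm2 = nn.BiLSTM(2 * H, H, rng=rng)
        self.proj = nn.Conv1d(c, 2 * H, kernel=1, pad=0, rng=rng)
        self.gpool = nn.GlobalMaxPool()
        self.head = nn.Dense(2 * H, 4, rng=rng)
        self._layers = {
            "conv": self.conv, "bn": self.bn, "bilstm1": self.bilstm1,
            "bilstm2": self.bilstm2, "proj": self.proj, "head": self.head,
        }

    # ---- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": p for ln, l in self._layers.items() for pn, p in l.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": g for ln, l in self._layers.items() for pn, g in l.grads.items()}

    def zero_grads(self) -> None:
        for l in self._layers.values():
            l.zero_grads()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters().values())

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(batch, window_len, 4) one-hot -> (batch, 4) logits."""
        h = self.conv.forward(x, train)
        h = self.relu.forward(h, train)
        h = self.bn.forward(h, train)
        h = self.pool.forward(h, train)
        r = self.drop.forward(h, train)  # CNN-block features; residual source
        h = self.bilstm1.forward(r, train)
        h = self.bilstm2.forward(h, train)
        y = h + self.proj.forward(r, train)
        y = self.gpool.forward(y, train)
        return self.head.forward(y, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.gpool.backward(self.head.backward(dlogits))
        dr = self.proj.backward(dy)
        dr = dr + self.bilstm1.backward(self.bilstm2.backward(dy))
        dh = self.drop.backward(dr)
        dh = self.pool.backward(dh)
        dh = self.bn.backward(dh)
        self.conv.backward(self.relu.backward(dh))

    # ---- inference ----------------------------------------------------------
    def _encode_context(self, context: str) -> np.ndarray:
        if not context:
            raise ValueError("empty context")
        w = self.config.window_len
        ctx = context[-w:]
        if len(ctx) < w:
            ctx = "N" * (w - len(ctx)) + ctx  # zero rows under the default policy
        return one_hot_encode(ctx)

    def predict_batch(self, contexts: Sequence[str]) -> np.ndarray:
        """Probability simplex rows, one per context; dropout off, BN running stats."""
        x = np.stack([self._encode_context(c) for c in contexts])
        return nn.softmax(self.forward(x, train=False))

    def predict_next_probs(self, context: str) -> np.ndarray:
        return self.predict_batch([context])[0]

    def as_oracle(self):
        """Batched oracle callable for the beam search: list[str] -> (n, 4)."""
        return self.predict_batch


def build_model(config: ModelConfig, seed: int = 0) -> NextBaseModel:
    """Initialize an untrained model; weight init is deterministic in ``seed``."""
    return NextBaseModel(config, seed=seed)


def make_training_set(
    genomes: Sequence[ScaffoldRecord], window_len: int, step: int = 1, rng_seed: int = 0
) -> list[TrainingExample]:
    """Sliding-window (context -> next base) pairs over N-free stretches.

    Windows advance by ``step``; the target is the base immediately after
    the window. The output order is a seeded shuffle of the scan order.
    """
    import logging

    if step < 1:
        raise ValueError("step must be >= 1")
    examples: list[TrainingExample] = []
    for rec in genomes:
        for stretch in rec.sequence.split("N"):
            if len(stretch) < window_len + 1:
                continue
            for i in range(0, len(stretch) - window_len, step):
                examples.append(
                    TrainingExample(stretch[i : i + window_len], stretch[i + window_len])
                )
    if not examples:
        logging.getLogger(__name__).warning(
            "no N-free stretch of length %d+1; empty training set", window_len
        )
        return examples
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(examples))
    return [examples[i] for i in order]


def _encode_examples(examples: Sequence[TrainingExample]) -> tuple[np.ndarray, np.ndarray]:
    base_idx = {b: i for i, b in enumerate(CHANNEL_ORDER)}
    X = np.stack([one_hot_encode(e.context) for e in examples])
    y = np.array([base_idx[e.target] for e in examples], dtype=np.int64)
    return X, y


def _data_digest(examples: Sequence[TrainingExample]) -> str:
    h = hashlib.sha256()
    for e in examples:
        h.update(e.context.encode())
        h.update(e.target.encode())
    return h.hexdigest()[:16]


def train_model(
    model: NextBaseModel,
    examples: Sequence[TrainingExample],
    tc: TrainingConfig,
    verbose: bool = False,
) -> NextBaseModel:
    """Fit in place and return the model; early-stops on validation loss.

    The best-validation parameters are restored at the end. Raises on a
    non-finite loss (divergence) with the epoch in the message.
    """
    if not examples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tc.rng_seed)
    model.drop.rng = rng
    X, y = _encode_examples(examples)
    n_val = max(1, int(round(len(examples) * tc.validation_fraction)))
    if n_val >= len(examples):
        raise ValueError("validation split leaves no training data")
    X_tr, y_tr = X[:-n_val], y[:-n_val]
    X_val, y_val = X[-n_val:], y[-n_val:]

    opt = nn.Adam(model.parameters(), lr=tc.learning_rate)
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    strikes = 0
    model.val_loss_trace: list[float] = []
    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(y_tr))
        for lo in range(0, len(y_tr), tc.batch_size):
            sel = order[lo : lo + tc.batch_size]
            model.zero_grads()
            logits = model.forward(X_tr[sel], train=True)
            loss, dlogits = nn.softmax_xent(logits, y_tr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (loss={loss}) at epoch {epoch}")
            model.backward(dlogits)
            opt.step(model.gradients())
        val_logits = model.forward(X_val, train=False)
        val_loss, _ = nn.softmax_xent(val_logits, y_val)
        model.val_loss_trace.append(val_loss)
        if verbose:
            acc = float((np.argmax(val_logits, axis=1) == y_val).mean())
            print(f"epoch {epoch}: val_loss={val_loss:.4f} val_acc={acc:.4f}")
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.parameters().items()}
            best_bn = (model.bn.running_mean.copy(), model.bn.running_var.copy())
            strikes = 0
        else:
            strikes += 1
            if strikes >= tc.early_stop_patience:
                break
    if best_state is not None:
        for k, v in model.parameters().items():
            v[...] = best_state[k]
        model.bn.running_mean, model.bn.running_var = best_bn
    model.training_fingerprint = f"seed={tc.rng_seed}:data={_data_digest(examples)}"
    return model


def held_out_accuracy(model: NextBaseModel, examples: Sequence[TrainingExample]) -> float:
    """Fraction of examples whose argmax prediction equals the true next base."""
    X, y = _encode_examples(examples)
    preds = []
    for lo in range(0, len(y), 512):
        preds.append(np.argmax(model.forward(X[lo : lo + 512], train=False), axis=1))
    return float((np.concatenate(preds) == y).mean())


_FORMAT = "gapfill-nextbase-v1"


def save_model(model: NextBaseModel, path: str | Path) -> None:
    """Single self-describing archive: config + weights + BN stats + fingerprint."""
    meta = {
        "format": _FORMAT,
        "config": asdict(model.config),
        "fingerprint": model.training_fingerprint,
    }
    arrays = {f"param:{k}": v for k, v in model.parameters().items()}
    arrays["buffer:bn.running_mean"] = model.bn.running_mean
    arrays["buffer:bn.running_var"] = model.bn.running_var
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> NextBaseModel:
    """Inverse of :func:`save_model`; bit-identical predictions afterwards.

    Refuses files whose channel order differs from the running encoder's,
    and names any missing config field.
    """
    try:
        with np.load(path) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as exc:  # corrupt / foreign file
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if "__meta__" not in data:
        raise ModelIOError(f"{path}: not a model file (missing metadata)")
    meta = json.loads(bytes(data["__meta__"]).decode())
    if meta.get("format") != _FORMAT:
        raise ModelIOError(f"{path}: unrecognized model format {meta.get('format')!r}")
    cfg_dict = meta.get("config", {})
    import dataclasses

    for f in dataclasses.fields(ModelConfig):
        if f.name not in cfg_dict:
            raise ModelIOError(f"{path}: config field {f.name!r} missing")
    if cfg_dict["channel_order"] != CHANNEL_ORDER:
        raise ModelIOError(
            f"{path}: channel order {cfg_dict['channel_order']!r} does not match "
            f"the running encoder's {CHANNEL_ORDER!r}; refusing to load"
        )
    model = NextBaseModel(ModelConfig(**cfg_dict))
    params = model.parameters()
    for k, v in params.items():
        key = f"param:{k}"
        if key not in data:
            raise ModelIOError(f"{path}: parameter {k!r} missing")
        if data[key].shape != v.shape:
            raise ModelIOError(f"{path}: parameter {k!r} has shape {data[key].shape}, "
                               f"expected {v.shape}")
        v[...] = data[key]
    model.bn.running_mean = data["buffer:bn.running_mean"]
    model.bn.running_var = data["buffer:bn.running_var"]
    model.training_fingerprint = meta.get("fingerprint")
    return model
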