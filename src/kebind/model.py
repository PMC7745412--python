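"""The binding-site classifier network and its ablation variants.

Architecture (``full`` variant): the embedded sequence and embedded shape
string each pass through their own convolution module (kernel widths 8 and
16, ReLU, max-pool 2); the two feature maps are concatenated channel-wise at
matched positions and pass through a joint convolution module (kernel width
32, ReLU, max-pool 2); a bidirectional LSTM (32 units per direction, so 64
output features) scans the joint feature map; two fully connected layers and
a sigmoid produce the binding probability.

Ablation variants:

- ``no_structure``: the structure branch is dropped; the joint convolution
  consumes the sequence branch alone.
- ``one_hot``: additionally replaces the k-mer embedding with a 4-channel
  one-hot encoding of the nucleotides.
- ``cnn_only``: replaces the BiLSTM with a global max-pool over positions.

Variable-length input is handled by right-padding each batch with zeros and
masking: convolution outputs beyond an example's true length are zeroed
before every pooling step, pooled valid lengths shrink as floor(len/pool),
and the recurrence only consumes valid steps — so a prediction is invariant
to how much padding a batch happens to carry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DatasetError
from .nn import (
    Adam,
    BiLSTM,
    Conv1dSame,
    Dense,
    Dropout,
    GlobalMaxPool,
    LSTMDirection,
    MaskedReLU,
    MaxPool1d,
    sigmoid,
)

VARIANTS = ("full", "no_structure", "one_hot", "cnn_only")

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "LSTMWeights",
    "LSTMState",
    "lstm_step",
    "Network",
    "build_model",
    "pad_and_mask",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``kernel_widths`` assigns one width per convolution module in order
    (sequence branch, structure branch, joint module); the defaults are
    (8, 16, 32) with max-pool 2 and 32 LSTM units per direction.  Filter
    count, fully connected width and dropout rate are configurable; the
    defaults (16 filters, 32 fully connected units) are sized for training
    sets of a few hundred to a few thousand examples — wider nets memorise
    such datasets instead of generalising.
    """

    variant: str = "full"
    kernel_widths: tuple[int, int, int] = (8, 16, 32)
    filters: int = 16
    pool_width: int = 2
    lstm_units: int = 32
    fc_units: int = 32
    dropout: float = 0.25
    conv_dropout: float = 0.05
    input_dim_seq: int = 30
    input_dim_struct: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.pool_width < 1 or self.lstm_units < 1 or self.filters < 1:
            raise ConfigError("pool_width, lstm_units and filters must be >= 1")
        if not 0.0 <= self.dropout < 1.0 or not 0.0 <= self.conv_dropout < 1.0:
            raise ConfigError("dropout rates must be in [0, 1)")
        if self.variant == "one_hot" and self.input_dim_seq != 4:
            raise ConfigError("one_hot variant requires input_dim_seq = 4")

    @property
    def uses_structure(self) -> bool:
        return self.variant == "full"

    @property
    def uses_lstm(self) -> bool:
        return self.variant != "cnn_only"


# ---------------------------------------------------------------------------
# Didactic single-step LSTM with explicit per-gate weights.


@dataclass
class LSTMWeights:
    """Explicit per-gate LSTM weights: ``W_*`` act on the input x_t,
    ``U_*`` on the previous hidden state, ``b_*`` are biases."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    U_f: np.ndarray
    U_i: np.ndarray
    U_c: np.ndarray
    U_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @classmethod
    def zeros(cls, input_dim: int, units: int) -> "LSTMWeights":
        W = lambda: np.zeros((units, input_dim))
        U = lambda: np.zeros((units, units))
        b = lambda: np.zeros(units)
        return cls(W(), W(), W(), W(), U(), U(), U(), U(), b(), b(), b(), b())


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls, units: int) -> "LSTMState":
        return cls(h=np.zeros(units), c=np.zeros(units))


def lstm_step(
    x_t: np.ndarray, prev: LSTMState, w: LSTMWeights
) -> tuple[LSTMState, dict[str, np.ndarray]]:
    """One LSTM recurrence step::

        f_t = sigma(W_f x_t + U_f h_{t-1} + b_f)
        i_t = sigma(W_i x_t + U_i h_{t-1} + b_i)
        c_t = f_t * c_{t-1} + i_t * tanh(W_c x_t + U_c h_{t-1} + b_c)
        o_t = sigma(W_o x_t + U_o h_{t-1} + b_o)
        h_t = o_t * tanh(c_t)

    Returns the new state and the gate activations ``{'f','i','o','c_tilde'}``.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    f = sigmoid(w.W_f @ x_t + w.U_f @ prev.h + w.b_f)
    i = sigmoid(w.W_i @ x_t + w.U_i @ prev.h + w.b_i)
    c_tilde = np.tanh(w.W_c @ x_t + w.U_c @ prev.h + w.b_c)
    o = sigmoid(w.W_o @ x_t + w.U_o @ prev.h + w.b_o)
    c = f * prev.c + i * c_tilde
    h = o * np.tanh(c)
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(c))):
        raise FloatingPointError("non-finite LSTM state")
    return LSTMState(h=h, c=c), {"f": f, "i": i, "o": o, "c_tilde": c_tilde}


# ---------------------------------------------------------------------------
# Batch assembly.


def pad_and_mask(
    examples: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad variable-length (T_i, d) matrices with zeros to the batch
    maximum length.  Returns (batch tensor (B, T_max, d), lengths (B,))."""
    if len(examples) == 0:
        raise DatasetError("empty batch")
    lengths = np.array([len(x) for x in examples], dtype=np.int64)
    d = examples[0].shape[1]
    T = int(lengths.max())
    batch = np.zeros((len(examples), T, d), dtype=examples[0].dtype)
    for i, x in enumerate(examples):
        if x.shape[1] != d:
            raise DatasetError("inconsistent feature dimensions within batch")
        batch[i, : len(x)] = x
    return batch, lengths


def unpad(batch: np.ndarray, lengths: np.ndarray) -> list[np.ndarray]:
    """Inverse of :func:`pad_and_mask`: recover the original matrices."""
    return [batch[i, : int(n)].copy() for i, n in enumerate(lengths)]


# ---------------------------------------------------------------------------
# The network.


class Network:
    """CNN (+ optional structure branch) + BiLSTM (or global max-pool) +
    two fully connected layers + sigmoid, with hand-written backprop."""

    def __init__(self, config: ModelConfig, dtype=np.float32) -> None:
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        k_seq, k_struct, k_joint = config.kernel_widths
        F = config.filters

        self.conv_seq = Conv1dSame(k_seq, config.input_dim_seq, F, rng, dtype)
        self.relu_seq = MaskedReLU()
        self.pool_seq = MaxPool1d(config.pool_width)
        self.drop_seq = Dropout(config.conv_dropout)

        if config.uses_structure:
            self.conv_struct = Conv1dSame(
                k_struct, config.input_dim_struct, F, rng, dtype)
            self.relu_struct = MaskedReLU()
            self.pool_struct = MaxPool1d(config.pool_width)
            self.drop_struct = Dropout(config.conv_dropout)
            joint_in = 2 * F
        else:
            self.conv_struct = None
            joint_in = F

        self.conv_joint = Conv1dSame(k_joint, joint_in, F, rng, dtype)
        self.relu_joint = MaskedReLU()
        self.pool_joint = MaxPool1d(config.pool_width)
        self.drop_joint = Dropout(config.conv_dropout)

        if config.uses_lstm:
            self.lstm = BiLSTM(F, config.lstm_units, rng, dtype)
            feat = 2 * config.lstm_units
            self.global_pool = None
        else:
            self.lstm = None
            self.global_pool = GlobalMaxPool()
            feat = F
        self.feature_size = feat

        self.drop = Dropout(config.dropout)
        self.fc1 = Dense(feat, config.fc_units, rng, dtype)
        self.fc2 = Dense(config.fc_units, 1, rng, dtype)
        self._cache = None

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        params = {}
        params.update(self.conv_seq.params("conv_seq"))
        if self.conv_struct is not None:
            params.update(self.conv_struct.params("conv_struct"))
        params.update(self.conv_joint.params("conv_joint"))
        if self.lstm is not None:
            params.update(self.lstm.params("lstm"))
        params.update(self.fc1.params("fc1"))
        params.update(self.fc2.params("fc2"))
        return params

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        if set(own) != set(params):
            raise ConfigError("parameter name mismatch when loading weights")
        for name, arr in params.items():
            if own[name].shape != arr.shape:
                raise ConfigError(f"shape mismatch for parameter {name}")
            own[name][...] = arr

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        X_seq: np.ndarray,
        lengths: np.ndarray,
        X_struct: Optional[np.ndarray] = None,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Binding probabilities for a padded batch.

        ``X_seq``: (B, T, d_seq) embedded (or one-hot) sequences; ``lengths``
        true token counts; ``X_struct`` required for the ``full`` variant and
        must share the token grid of ``X_seq``.
        """
        cfg = self.config
        if X_seq.shape[2] != cfg.input_dim_seq:
            raise ConfigError(
                f"sequence feature dim {X_seq.shape[2]} != configured "
                f"{cfg.input_dim_seq}")
        pw = cfg.pool_width
        if int(lengths.min()) < pw * pw:
            raise DatasetError(
                f"example too short: every example needs >= {pw * pw} tokens")

        a = self.relu_seq.forward(self.conv_seq.forward(X_seq), lengths)
        a, l1 = self.pool_seq.forward(a, lengths)
        a = self.drop_seq.forward(a, train=train, rng=rng)

        if cfg.uses_structure:
            if X_struct is None:
                raise DatasetError("full variant requires structure input")
            if X_struct.shape[:2] != X_seq.shape[:2]:
                raise ConfigError("sequence/structure token grids differ")
            if X_struct.shape[2] != cfg.input_dim_struct:
                raise ConfigError(
                    f"structure feature dim {X_struct.shape[2]} != configured "
                    f"{cfg.input_dim_struct}")
            b = self.relu_struct.forward(
                self.conv_struct.forward(X_struct), lengths)
            b, _ = self.pool_struct.forward(b, lengths)
            b = self.drop_struct.forward(b, train=train, rng=rng)
            joint_in = np.concatenate([a, b], axis=2)
        else:
            joint_in = a

        d = self.relu_joint.forward(self.conv_joint.forward(joint_in), l1)
        d, l2 = self.pool_joint.forward(d, l1)
        d = self.drop_joint.forward(d, train=train, rng=rng)

        if cfg.uses_lstm:
            feat = self.lstm.forward(d, l2)
        else:
            feat = self.global_pool.forward(d, l2)

        feat_d = self.drop.forward(feat, train=train, rng=rng)
        z1 = self.fc1.forward(feat_d)
        a1 = np.maximum(z1, 0.0)
        z2 = self.fc2.forward(a1)
        # final probability in float64 so saturation never rounds to 0 or 1
        p = sigmoid(z2[:, 0].astype(np.float64))
        self._cache = {"z1": z1, "split": cfg.uses_structure and a.shape[2]}
        return p

    def backward(
        self, dlogit: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray, Optional[np.ndarray]]:
        """Backpropagate d(loss)/d(pre-sigmoid logit) of shape (B,).

        Returns (gradients keyed like :meth:`parameters`, d_X_seq,
        d_X_struct or None)."""
        cfg = self.config
        cache = self._cache
        grads: dict[str, np.ndarray] = {}

        da1, g = self.fc2.backward(dlogit[:, None].astype(self.dtype))
        grads.update({f"fc2.{k}": v for k, v in g.items()})
        dz1 = da1 * (cache["z1"] > 0)
        dfeat_d, g = self.fc1.backward(dz1)
        grads.update({f"fc1.{k}": v for k, v in g.items()})
        dfeat = self.drop.backward(dfeat_d)

        if cfg.uses_lstm:
            dd, g = self.lstm.backward(dfeat)
            grads.update({f"lstm.{k}": v for k, v in g.items()})
        else:
            dd = self.global_pool.backward(dfeat)

        dd = self.drop_joint.backward(dd)
        dd = self.pool_joint.backward(dd)
        dd = self.relu_joint.backward(dd)
        djoint_in, g = self.conv_joint.backward(dd)
        grads.update({f"conv_joint.{k}": v for k, v in g.items()})

        if cfg.uses_structure:
            F = cache["split"]
            da, db = djoint_in[:, :, :F], djoint_in[:, :, F:]
            db = self.drop_struct.backward(db)
            db = self.pool_struct.backward(db)
            db = self.relu_struct.backward(db)
            dXt, g = self.conv_struct.backward(db)
            grads.update({f"conv_struct.{k}": v for k, v in g.items()})
        else:
            da, dXt = djoint_in, None

        da = self.drop_seq.backward(da)
        da = self.pool_seq.backward(da)
        da = self.relu_seq.backward(da)
        dXs, g = self.conv_seq.backward(da)
        grads.update({f"conv_seq.{k}": v for k, v in g.items()})
        return grads, dXs, dXt


def build_model(cfg: ModelConfig, dtype=np.float32) -> Network:
    """Instantiate an untrained network with seeded weight initialisation."""
    return Network(cfg, dtype=dtype)


def save_model(net: Network, path: str | Path) -> None:
    """Checkpoint: weights plus embedded configuration, reloadable."""
    cfg_json = json.dumps(asdict(net.config))
    arrays = {name.replace(".", "__"): arr for name, arr in net.parameters().items()}
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path, dtype=np.float32) -> Network:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"].tobytes()).decode())
        cfg_dict["kernel_widths"] = tuple(cfg_dict["kernel_widths"])
        cfg = ModelConfig(**cfg_dict)
        net = Network(cfg, dtype=dtype)
        params = {
            name.replace("__", "."): data[name]
            for name in data.files
            if name != "__config__"
        }
        net.set_parameters(params)
    return net
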