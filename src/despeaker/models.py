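"""Dual-head sequence models for speaker-disentangled depression detection.

Every model is a shared encoder producing a per-segment embedding, feeding
two prediction heads:

* the MDD head — one sigmoid unit giving the probability that the segment
  comes from a depressed speaker, and
* the SID head — M raw logits over the M training speakers (the activation
  applied to these logits depends on the disentanglement loss, so the head
  itself stays linear).

Three encoder families are provided. CNN-LSTM stacks Conv1d → ReLU →
max-pool(3) → dropout blocks in front of unidirectional LSTM layers; the
embedding is the last hidden state. The reduced ECAPA variant is a
channel-128 TDNN with three SE-Res2 blocks (dilations 2, 3, 4), attentive
statistics pooling (attention dim 64) and a 128-dim embedding layer; the
heads read the embedding. LSTM-only stacks an input LSTM plus five hidden
LSTM layers (H=256) for high-dimensional SSL-style features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np

from .autodiff import Tensor, concatenate
from .layers import (
    Module, Linear, Conv1d, MaxPool1d, Dropout, LSTM,
    SERes2Block, AttentiveStatsPool,
)

__all__ = [
    "ModelFamily", "ModelSpec", "BatchOutputs", "DualHeadModel",
    "build_model", "cnn_lstm_spec", "ecapa_lite_spec", "lstm_only_spec",
]


class ModelFamily(str, Enum):
    CNN_LSTM = "cnn_lstm"
    ECAPA_LITE = "ecapa_lite"
    LSTM_ONLY = "lstm_only"


@dataclass
class ModelSpec:
    """Architecture description; serializable next to checkpoints."""

    family: ModelFamily
    n_speakers: int
    input_dim: int
    conv_layers: list = field(default_factory=list)   # [(C, K, S), ...]
    lstm_hidden: int = 128
    n_lstm_layers: int = 2
    attention_dim: int = 64
    embedding_dim: int = 128
    dropout: float = 0.05
    se_res2_dilations: list = field(default_factory=lambda: [2, 3, 4])
    se_res2_kernel: int = 5
    res2_scale: int = 4

    def __post_init__(self):
        self.family = ModelFamily(self.family)
        if self.n_speakers < 2:
            raise ValueError("SID head needs at least 2 speakers")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["family"] = self.family.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["conv_layers"] = [tuple(c) for c in d.get("conv_layers", [])]
        return cls(**d)


@dataclass
class BatchOutputs:
    """Per-segment model outputs (graph tensors while training)."""

    p: Tensor            # (N,) depression probability, in (0,1)
    sid_logits: Tensor   # (N, M) raw speaker logits
    embedding: Tensor    # (N, E)

    def detached(self) -> "BatchOutputs":
        return BatchOutputs(self.p.detach(), self.sid_logits.detach(),
                            self.embedding.detach())


# --------------------------------------------------------------------------
# printed presets
# --------------------------------------------------------------------------

def cnn_lstm_spec(feature_kind: str, n_speakers: int, input_dim: int | None = None,
                  dropout: float = 0.05) -> ModelSpec:
    """CNN-LSTM presets for low-level features.

    mel-40: one Conv1d (C=128, K=3, S=1), two LSTM layers H=128.
    raw audio: Conv1d (C=128, K=1024, S=512) then (C=128, K=3, S=1), H=128.
    prosodic-130: one Conv1d (C=256, K=3, S=1), two LSTM layers H=256.
    """
    kind = feature_kind.upper()
    if kind == "MEL":
        return ModelSpec(ModelFamily.CNN_LSTM, n_speakers, input_dim or 40,
                         conv_layers=[(128, 3, 1)], lstm_hidden=128,
                         n_lstm_layers=2, dropout=dropout)
    if kind == "RAW":
        return ModelSpec(ModelFamily.CNN_LSTM, n_speakers, 1,
                         conv_layers=[(128, 1024, 512), (128, 3, 1)],
                         lstm_hidden=128, n_lstm_layers=2, dropout=dropout)
    if kind == "PROSODIC130":
        return ModelSpec(ModelFamily.CNN_LSTM, n_speakers, input_dim or 130,
                         conv_layers=[(256, 3, 1)], lstm_hidden=256,
                         n_lstm_layers=2, dropout=dropout)
    raise ValueError(f"no CNN-LSTM preset for feature kind {feature_kind!r}")


def ecapa_lite_spec(feature_kind: str, n_speakers: int,
                    input_dim: int | None = None,
                    dropout: float = 0.5) -> ModelSpec:
    """Reduced ECAPA presets: C=128 throughout, attention 64, embedding 128."""
    kind = feature_kind.upper()
    if kind == "MEL":
        conv = [(128, 5, 1)]
        dim = input_dim or 80
    elif kind == "RAW":
        conv = [(128, 1024, 512)]
        dim = 1
    else:
        raise ValueError(f"no ECAPA preset for feature kind {feature_kind!r}")
    return ModelSpec(ModelFamily.ECAPA_LITE, n_speakers, dim,
                     conv_layers=conv, attention_dim=64, embedding_dim=128,
                     dropout=dropout)


def lstm_only_spec(n_speakers: int, input_dim: int,
                   dropout: float = 0.6) -> ModelSpec:
    """LSTM-only preset: input LSTM (H=256) plus five hidden LSTM layers."""
    return ModelSpec(ModelFamily.LSTM_ONLY, n_speakers, input_dim,
                     lstm_hidden=256, n_lstm_layers=6, dropout=dropout)


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

class DualHeadModel(Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        fam = spec.family
        dim = spec.input_dim
        if fam in (ModelFamily.CNN_LSTM, ModelFamily.ECAPA_LITE):
            if not spec.conv_layers:
                raise ValueError(f"{fam.value} requires conv_layers")
            self.convs = []
            c_in = dim
            for (c, k, s) in spec.conv_layers:
                self.convs.append(Conv1d(c_in, c, k, rng, stride=s))
                c_in = c
            self._channels = c_in
        if fam == ModelFamily.CNN_LSTM:
            self.pool = MaxPool1d(3)
            self.drop = Dropout(spec.dropout)
            self.lstms = []
            d = self._channels
            for _ in range(spec.n_lstm_layers):
                self.lstms.append(LSTM(d, spec.lstm_hidden, rng))
                d = spec.lstm_hidden
            emb_dim = spec.lstm_hidden
        elif fam == ModelFamily.ECAPA_LITE:
            c = self._channels
            self.blocks = [
                SERes2Block(c, spec.se_res2_kernel, dil, rng,
                            scale=spec.res2_scale)
                for dil in spec.se_res2_dilations
            ]
            self.mfa = Conv1d(c * len(self.blocks), c, 1, rng)
            self.asp = AttentiveStatsPool(c, spec.attention_dim, rng)
            self.emb_layer = Linear(2 * c, spec.embedding_dim, rng)
            self.drop = Dropout(spec.dropout)
            emb_dim = spec.embedding_dim
        elif fam == ModelFamily.LSTM_ONLY:
            self.drop = Dropout(spec.dropout)
            self.lstms = []
            d = dim
            for _ in range(spec.n_lstm_layers):
                self.lstms.append(LSTM(d, spec.lstm_hidden, rng))
                d = spec.lstm_hidden
            emb_dim = spec.lstm_hidden
        else:  # pragma: no cover
            raise ValueError(fam)
        self.embedding_dim = emb_dim
        self.mdd_head = Linear(emb_dim, 1, rng)
        self.sid_head = Linear(emb_dim, spec.n_speakers, rng)

    # -------------------------------------------------------------- encoder
    def encode(self, x: Tensor, training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Map a batch (N, T, D) to embeddings (N, E)."""
        n, t, d = x.shape
        if d != self.spec.input_dim:
            raise ValueError(
                f"expected input dim {self.spec.input_dim}, got {d}")
        fam = self.spec.family
        if fam == ModelFamily.CNN_LSTM:
            h = x.transpose(0, 2, 1)
            for conv in self.convs:
                h = self.drop(self.pool(conv(h).relu()),
                              training=training, rng=rng)
            h = h.transpose(0, 2, 1)
            for lstm in self.lstms:
                h = lstm(h)
            return h[:, -1, :]
        if fam == ModelFamily.ECAPA_LITE:
            h = x.transpose(0, 2, 1)
            for conv in self.convs:
                h = conv(h).relu()
            outs = []
            for blk in self.blocks:
                h = blk(h)
                outs.append(h)
            h = self.mfa(concatenate(outs, axis=1)).relu()
            h = self.drop(h, training=training, rng=rng)
            return self.emb_layer(self.asp(h))
        # LSTM_ONLY
        h = self.drop(x, training=training, rng=rng)
        for lstm in self.lstms:
            h = lstm(h)
        return h[:, -1, :]

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None) -> BatchOutputs:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        emb = self.encode(x, training=training, rng=rng)
        p = self.mdd_head(emb).sigmoid().reshape(x.shape[0])
        logits = self.sid_head(emb)
        if not (np.all(np.isfinite(p.data))
                and np.all(np.isfinite(logits.data))):
            raise FloatingPointError(
                "non-finite activations in forward pass "
                f"(family={self.spec.family.value}, batch={x.shape})")
        return BatchOutputs(p=p, sid_logits=logits, embedding=emb)

    __call__ = forward

    def extract_embedding(self, segment) -> np.ndarray:
        """Embedding vector for a single (T, D) segment, eval mode."""
        arr = np.asarray(segment, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        return self.encode(Tensor(arr)).data[0]


def build_model(spec: ModelSpec, seed: int = 0) -> DualHeadModel:
    """Construct a model with reproducible fan-in initialisation."""
    return DualHeadModel(spec, np.random.default_rng(seed))
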