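"""Optimisation loop, learning-rate schedule and ensemble training.

Training is deterministic given a seed: model initialisation, batch
shuffling, dropout masks and the LEV target noise all draw from generators
derived from it. The learning rate is multiplied by 0.9 whenever the
validation loss has failed to improve for two successive epochs; the
checkpoint with the best validation depression loss is retained, so
baseline (λ=0) and disentangled runs are selected on the same quantity
and λ remains the only differing hyperparameter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .features import FeatureSegment
from .losses import LossSpec, DisentMethod, mdd_loss, sid_term, total_loss
from .models import ModelSpec, DualHeadModel, build_model

__all__ = [
    "TrainConfig", "TrainedModel", "Adam", "lr_step", "train_model",
    "train_ensemble", "save_checkpoint", "load_checkpoint",
]

log = logging.getLogger(__name__)

FAMILY_DROPOUT = {"lstm_only": 0.6, "ecapa_lite": 0.5, "cnn_lstm": 0.05}


@dataclass
class TrainConfig:
    lr: float = 1e-3
    lr_decay: float = 0.9
    patience: int = 2              # epochs without improvement before decay
    max_epochs: int = 100
    early_stop: int = 10           # epochs without improvement before stop
    batch_size: int = 64
    weight_decay: float = 0.0
    seeds: list = field(default_factory=lambda: [11, 22, 33, 44, 55])

    def __post_init__(self):
        if not 0.0 < self.lr_decay < 1.0:
            raise ValueError("lr_decay must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class TrainedModel:
    model: DualHeadModel
    model_spec: ModelSpec
    loss_spec: LossSpec
    history: list            # per-epoch dicts
    seed: int
    best_val_loss: float


class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                p.data *= (1.0 - self.lr * self.weight_decay)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


def lr_step(current_lr: float, val_loss_history: list[float],
            cfg: TrainConfig) -> float:
    """Decay the learning rate after every `patience` consecutive epochs
    without a new best validation loss (the stall counter restarts after
    each decay, so four stalled epochs at patience 2 give two decays)."""
    hist = np.asarray(val_loss_history, dtype=float)
    if len(hist) < cfg.patience + 1:
        return current_lr
    streak = len(hist) - 1 - int(np.argmin(hist))
    if streak > 0 and streak % cfg.patience == 0:
        return current_lr * cfg.lr_decay
    return current_lr


def _stack(segments: list[FeatureSegment]):
    x = np.stack([s.data for s in segments])
    y = np.array([s.mdd_label for s in segments], dtype=np.float64)
    spk = np.array([s.speaker_index for s in segments], dtype=np.int64)
    return x, y, spk


def _val_loss(model: DualHeadModel, x_va, y_va, loss_spec: LossSpec) -> float:
    """Validation value of the training objective (deterministic mode).

    The equalization SID terms (LEV/LECE/LEKLD) are speaker-free, so they
    are evaluated on validation segments with the noise target disabled;
    the adversarial CE needs SID-head classes that validation speakers do
    not have (speaker-disjoint splits), so ADV and the baseline fall back
    to the depression loss alone.
    """
    out = model.forward(x_va)
    l_mdd = mdd_loss(out.p, y_va)
    if loss_spec.method in (DisentMethod.NONE, DisentMethod.ADV) \
            or loss_spec.lam == 0.0:
        return l_mdd.item()
    det_spec = LossSpec(loss_spec.method, loss_spec.lam, lev_noise=False,
                        lev_squared=loss_spec.lev_squared)
    dummy_spk = np.zeros(len(y_va), dtype=np.int64)
    l_sid = sid_term(det_spec, out.sid_logits, dummy_spk)
    return total_loss(det_spec, l_mdd, l_sid).item()


def _check_disjoint(train, val):
    spk_t = {s.speaker_index for s in train}
    spk_v = {s.speaker_index for s in val}
    if spk_t & spk_v:
        raise ValueError(f"train/val share speakers: {sorted(spk_t & spk_v)}")


def train_model(train_segments: list[FeatureSegment],
                val_segments: list[FeatureSegment],
                model_spec: ModelSpec, loss_spec: LossSpec,
                cfg: TrainConfig, seed: int,
                speaker_map: dict | None = None) -> TrainedModel:
    """Train one dual-head model.

    ``speaker_map`` maps corpus speaker indices to contiguous SID-head
    classes [0, M); by default it is built from the training speakers.
    Divergence (non-finite loss) aborts the run and returns the last good
    checkpoint.
    """
    if not train_segments or not val_segments:
        raise ValueError("empty train or validation set")
    _check_disjoint(train_segments, val_segments)
    x_tr, y_tr, spk_tr = _stack(train_segments)
    if len(set(y_tr)) < 2:
        raise ValueError("training set must contain both classes")
    x_va, y_va, _ = _stack(val_segments)
    if speaker_map is None:
        speaker_map = {s: i for i, s in enumerate(sorted(set(spk_tr)))}
    sid_classes = np.array([speaker_map[s] for s in spk_tr], dtype=np.int64)

    model = build_model(model_spec, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.lr,
               weight_decay=cfg.weight_decay)
    batch_rng = np.random.default_rng(seed + 101)
    drop_rng = np.random.default_rng(seed + 202)
    noise_rng = np.random.default_rng(seed + 303)

    n = len(x_tr)
    history: list[dict] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_state = [p.copy() for p in model.state_arrays()]
    best_epoch = -1
    lr = cfg.lr

    for epoch in range(cfg.max_epochs):
        opt.lr = lr
        order = batch_rng.permutation(n)
        ep_mdd, ep_sid, n_batches = 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            out = model.forward(x_tr[idx], training=True, rng=drop_rng)
            l_mdd = mdd_loss(out.p, y_tr[idx])
            l_sid = sid_term(loss_spec, out.sid_logits, sid_classes[idx],
                             noise_rng=noise_rng)
            loss = total_loss(loss_spec, l_mdd, l_sid)
            if not np.isfinite(loss.item()):
                log.error("loss diverged at epoch %d; restoring last good "
                          "checkpoint", epoch)
                model.load_state_arrays(best_state)
                return TrainedModel(model, model_spec, loss_spec, history,
                                    seed, best_val)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_mdd += l_mdd.item()
            ep_sid += l_sid.item() if l_sid is not None else 0.0
            n_batches += 1
        # validation: objective value in deterministic eval mode
        val_loss = _val_loss(model, x_va, y_va, loss_spec)
        val_losses.append(val_loss)
        history.append({"epoch": epoch, "lr": lr,
                        "train_mdd": ep_mdd / n_batches,
                        "train_sid": ep_sid / n_batches,
                        "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = [p.copy() for p in model.state_arrays()]
            best_epoch = epoch
        lr = lr_step(lr, val_losses, cfg)
        if epoch - best_epoch >= cfg.early_stop:
            break
    model.load_state_arrays(best_state)
    return TrainedModel(model, model_spec, loss_spec, history, seed, best_val)


def train_ensemble(subsets: list[list[FeatureSegment]],
                   val_segments: list[FeatureSegment],
                   model_spec: ModelSpec, loss_spec: LossSpec,
                   cfg: TrainConfig,
                   speaker_map: dict | None = None) -> list[TrainedModel]:
    """Train one model per training subset with the configured seeds.

    A single subset gives the single-model regime; five subsets give the
    5-model ensemble. Any member failure aborts the ensemble.
    """
    if len(subsets) > len(cfg.seeds):
        raise ValueError(f"{len(subsets)} subsets but only "
                         f"{len(cfg.seeds)} seeds configured")
    members = []
    for i, subset in enumerate(subsets):
        try:
            members.append(train_model(subset, val_segments, model_spec,
                                       loss_spec, cfg, cfg.seeds[i],
                                       speaker_map=speaker_map))
        except Exception as exc:
            raise RuntimeError(
                f"ensemble member {i} (seed {cfg.seeds[i]}) failed: {exc}"
            ) from exc
    return members


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(tm: TrainedModel, path: str | Path) -> Path:
    """Self-describing checkpoint: weights (.npz) + specs/history (.json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": a for i, a in enumerate(tm.model.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"model_spec": tm.model_spec.to_dict(),
            "loss_spec": tm.loss_spec.to_dict(),
            "history": tm.history, "seed": tm.seed,
            "best_val_loss": tm.best_val_loss}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec.from_dict(meta["model_spec"])
    loss_spec = LossSpec.from_dict(meta["loss_spec"])
    model = build_model(spec, seed=meta["seed"])
    with np.load(path.with_suffix(".npz")) as z:
        arrays = [z[f"p{i}"] for i in range(len(z.files))]
    model.load_state_arrays(arrays)
    return TrainedModel(model, spec, loss_spec, meta["history"],
                        meta["seed"], meta["best_val_loss"])
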