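"""Objective functions: depression loss and the four SID-loss manipulations.

The total training objective combines a binary cross-entropy depression
loss L_MDD with a speaker-identification term weighted by λ:

* ADV   — adversarial maximisation: total = L_MDD − λ·L_adv, where L_adv is
  the categorical cross-entropy of the SID softmax at the true speaker.
  Implemented as loss negation (exactly equivalent to gradient reversal for
  a single λ).
* LEV   — L2 equalisation: mean squared distance between the SID softmax
  and the uniform vector e = (1/M, …, 1/M). To block the trivial solution
  where the SID head memorises e without the encoder forgetting speakers,
  U(0,1) noise (scaled) is added to e and redrawn every batch.
* LECE  — cross-entropy equalisation against an all-ones target, which
  reduces to −Σ_m log softmax(x)_m; minimised exactly at the uniform
  distribution with value M·ln M.
* LEKLD — KL(e ‖ softmax(x)); zero iff the softmax is uniform.

All functions accept autodiff Tensors (for training) or plain arrays (for
evaluation) and return a scalar Tensor.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .autodiff import Tensor, astensor, maximum, minimum

__all__ = [
    "DisentMethod", "LossSpec", "uniform_target",
    "mdd_loss", "adv_sid_loss", "lev_loss", "lece_loss", "lece_loss_literal",
    "lekld_loss", "sid_term", "total_loss",
]

_EPS = 1e-12


class DisentMethod(str, Enum):
    NONE = "none"
    ADV = "adv"
    LEV = "lev"
    LECE = "lece"
    LEKLD = "lekld"


@dataclass
class LossSpec:
    """Disentanglement method and its weight λ."""

    method: DisentMethod = DisentMethod.NONE
    lam: float = 0.0
    lev_noise: bool = True
    lev_noise_scale: float = 0.1
    lev_squared: bool = True

    def __post_init__(self):
        self.method = DisentMethod(self.method)
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.method is DisentMethod.NONE:
            self.lam = 0.0

    def to_dict(self) -> dict:
        return {"method": self.method.value, "lam": self.lam,
                "lev_noise": self.lev_noise,
                "lev_noise_scale": self.lev_noise_scale,
                "lev_squared": self.lev_squared}

    @classmethod
    def from_dict(cls, d: dict) -> "LossSpec":
        return cls(**d)


def uniform_target(m: int) -> np.ndarray:
    """The equal-probability speaker vector e = (1/M, …, 1/M)."""
    if m < 2:
        raise ValueError("need at least 2 speakers")
    return np.full(m, 1.0 / m)


def _clip_prob(p: Tensor) -> Tensor:
    return minimum(maximum(p, _EPS), 1.0 - _EPS)


def mdd_loss(p, y) -> Tensor:
    """Mean binary cross-entropy of depression probabilities."""
    p = astensor(p)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    p = _clip_prob(p)
    yt = Tensor(y)
    ll = yt * p.log() + (1.0 - yt) * (1.0 - p).log()
    return -ll.mean()


def adv_sid_loss(x, spk) -> Tensor:
    """Categorical cross-entropy of the SID softmax at the true speaker."""
    x = astensor(x)
    spk = np.asarray(spk, dtype=np.int64)
    n, m = x.shape
    if spk.shape != (n,):
        raise ValueError("speaker index vector must have length N")
    if spk.min() < 0 or spk.max() >= m:
        raise ValueError(f"speaker index out of range [0, {m})")
    logp = x.log_softmax(axis=1)
    return -logp[np.arange(n), spk].mean()


def lev_loss(x, noise_rng: np.random.Generator | None = None,
             noise_scale: float = 0.1, squared: bool = True) -> Tensor:
    """Mean (squared) L2 distance between the SID softmax and the uniform
    target, optionally perturbed by fresh elementwise U(0,1)·scale noise."""
    x = astensor(x)
    n, m = x.shape
    e = uniform_target(m)
    if noise_rng is not None:
        e = e + noise_scale * noise_rng.random(m)
    diff = x.softmax(axis=1) - Tensor(e)
    sq = (diff * diff).sum(axis=1)
    return sq.mean() if squared else sq.sqrt().mean()


def lece_loss(x) -> Tensor:
    """Cross-entropy equalisation: −(1/N) Σ_n Σ_m log softmax(x)_{n,m}."""
    x = astensor(x)
    n, m = x.shape
    if m < 2:
        raise ValueError("need at least 2 speakers")
    logp = maximum(x.softmax(axis=1), _EPS).log()
    return -logp.sum(axis=1).mean()


def lece_loss_literal(x) -> Tensor:
    """The all-ones-target binary-style cross-entropy written out in full;
    with every target entry equal to one the (1−y) term vanishes, so this
    equals :func:`lece_loss`. Kept as an independent check."""
    x = astensor(x)
    s = maximum(x.softmax(axis=1), _EPS)
    y = np.ones(x.shape)
    yt = Tensor(y)
    terms = yt * s.log() + (1.0 - yt) * maximum(1.0 - s, _EPS).log()
    return -terms.sum(axis=1).mean()


def lekld_loss(x) -> Tensor:
    """Mean KL(e ‖ softmax(x)) over the batch; ≥ 0, zero iff uniform."""
    x = astensor(x)
    n, m = x.shape
    e = uniform_target(m)
    logp = maximum(x.softmax(axis=1), _EPS).log()
    et = Tensor(e)
    kl = (et * (Tensor(np.log(e)) - logp)).sum(axis=1)
    return kl.mean()


def sid_term(spec: LossSpec, sid_logits, spk,
             noise_rng: np.random.Generator | None = None) -> Tensor | None:
    """The method's SID loss for a batch; None when method is NONE."""
    m = spec.method
    if m is DisentMethod.NONE:
        return None
    if m is DisentMethod.ADV:
        return adv_sid_loss(sid_logits, spk)
    if m is DisentMethod.LEV:
        rng = noise_rng if spec.lev_noise else None
        return lev_loss(sid_logits, noise_rng=rng,
                        noise_scale=spec.lev_noise_scale,
                        squared=spec.lev_squared)
    if m is DisentMethod.LECE:
        return lece_loss(sid_logits)
    if m is DisentMethod.LEKLD:
        return lekld_loss(sid_logits)
    raise ValueError(m)  # pragma: no cover


def total_loss(spec: LossSpec, l_mdd, l_sid=None) -> Tensor:
    """Combine depression and SID losses.

    ADV subtracts (the SID loss is maximised); the equalisation methods add.
    With method NONE or λ=0 the result is exactly the depression loss.
    """
    l_mdd = astensor(l_mdd)
    if spec.method is DisentMethod.NONE or spec.lam == 0.0:
        return l_mdd
    if l_sid is None:
        raise ValueError(f"method {spec.method.value} needs an SID loss term")
    l_sid = astensor(l_sid)
    if spec.method is DisentMethod.ADV:
        return l_mdd - spec.lam * l_sid
    return l_mdd + spec.lam * l_sid
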