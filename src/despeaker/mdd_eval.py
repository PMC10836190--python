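"""Segment→speaker depression scoring, ensemble aggregation and macro-F1.

Evaluation is at speaker level: each model rounds its per-segment
probabilities at 0.5 and averages them into a speaker score; an ensemble
is then collapsed to a single binary decision by score averaging (AVG),
majority vote (MV), or a summed log-likelihood ratio over the raw segment
probabilities (LLR, ε = 1e−8). All rounding uses threshold 0.5; a score
exactly at the threshold rounds to 1 (depressed) so screening errs on the
sensitive side, and an LLR sum of exactly 0 likewise resolves to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Aggregation", "SpeakerScore", "ConfusionMatrix",
    "speaker_score", "segment_llr_sum", "aggregate", "confusion",
    "macro_f1", "evaluate_speakers",
]

_LLR_EPS = 1e-8


class Aggregation(str, Enum):
    AVG = "avg"
    MV = "mv"
    LLR = "llr"


@dataclass
class SpeakerScore:
    speaker_id: int
    scores: list          # one speaker-level score per ensemble member
    truth: int
    llr_sums: list | None = None   # per-model summed segment LLRs


@dataclass
class ConfusionMatrix:
    tn: int = 0
    fp: int = 0
    fn: int = 0
    tp: int = 0

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


def _round05(x: float) -> int:
    """Threshold at 0.5; exactly 0.5 rounds up to the depressed class."""
    return 1 if x >= 0.5 else 0


def speaker_score(segment_probs) -> float:
    """Mean of rounded (0.5-threshold) segment predictions for one speaker."""
    probs = np.asarray(segment_probs, dtype=np.float64)
    if probs.size == 0:
        raise ValueError("speaker has no segments")
    return float(np.mean(probs >= 0.5))


def segment_llr_sum(segment_probs) -> float:
    """Sum of log(p/(1−p)) over segment probabilities, clipped at ε=1e−8."""
    p = np.clip(np.asarray(segment_probs, dtype=np.float64),
                _LLR_EPS, 1.0 - _LLR_EPS)
    return float(np.sum(np.log(p) - np.log(1.0 - p)))


def aggregate(score: SpeakerScore, method: Aggregation | str) -> int:
    """Collapse per-model speaker scores into one binary prediction."""
    method = Aggregation(method)
    scores = np.asarray(score.scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("no ensemble scores")
    if method is Aggregation.AVG:
        return _round05(float(scores.mean()))
    if method is Aggregation.MV:
        if scores.size % 2 == 0 and scores.size > 1:
            # majority vote is defined for odd ensembles; fall back to AVG
            return _round05(float(scores.mean()))
        votes = (scores >= 0.5).sum()
        return 1 if votes > scores.size / 2 else 0
    # LLR over raw segment probabilities, summed across models
    if score.llr_sums is None:
        raise ValueError("LLR aggregation needs per-model segment LLR sums")
    total = float(np.sum(score.llr_sums))
    return 1 if total >= 0.0 else 0


def confusion(truth, predictions) -> ConfusionMatrix:
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truth and predictions differ in length")
    if not (set(np.unique(t)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise ValueError("labels must be binary")
    return ConfusionMatrix(
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        tp=int(np.sum((t == 1) & (p == 1))))


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the depressed and non-depressed F1 scores.

    A class with zero support and zero predicted positives contributes 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    denom_d = 2 * cm.tp + cm.fp + cm.fn
    denom_nd = 2 * cm.tn + cm.fn + cm.fp
    f1_d = 2 * cm.tp / denom_d if denom_d else 0.0
    f1_nd = 2 * cm.tn / denom_nd if denom_nd else 0.0
    return 0.5 * (f1_d + f1_nd)


def evaluate_speakers(per_model_segment_probs: list[dict],
                      truth: dict[int, int],
                      method: Aggregation | str = Aggregation.AVG
                      ) -> tuple[ConfusionMatrix, float, list[SpeakerScore]]:
    """Full speaker-level evaluation for an ensemble.

    ``per_model_segment_probs`` is one dict per ensemble member mapping
    speaker_id -> array of segment probabilities. Returns the confusion
    matrix, macro-F1, and the per-speaker score records.
    """
    speakers = sorted(truth)
    scores = []
    for sid in speakers:
        per_model = [speaker_score(m[sid]) for m in per_model_segment_probs]
        llrs = [segment_llr_sum(m[sid]) for m in per_model_segment_probs]
        scores.append(SpeakerScore(speaker_id=sid, scores=per_model,
                                   truth=truth[sid], llr_sums=llrs))
    preds = [aggregate(s, method) for s in scores]
    cm = confusion([s.truth for s in scores], preds)
    return cm, macro_f1(cm), scores
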