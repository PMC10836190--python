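"""Voice-privacy evaluation of embedding spaces.

Quantifies how much speaker identity survives in model embeddings before
(ORIGINAL) versus after (PROTECTED) disentanglement:

* PLDA similarity matrices — entry (i, j) is the sigmoid of the mean
  pairwise PLDA log-likelihood ratio between speaker i's segments under
  one condition and speaker j's under another;
* diagonal dominance — |mean diagonal − mean off-diagonal| of such a
  matrix: how much more similar a speaker is to themself than to others;
* GVD (gain of voice distinctiveness, dB) = 10·log10(D_pp / D_oo):
  negative means speakers became less distinguishable after protection;
* DeID (de-identification, %) = 100·(1 − D_op / D_oo): 100% means
  protected embeddings are unlinkable to the original ones;
* a linear SVC speaker-identification probe with its chance floor.

The protocol mirrors speaker-verification practice: PLDA models are
trained on one speaker set (default 25) and the matrices are built from a
disjoint evaluation set (default 10 speakers, 50 segments each), repeated
over random splits and averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from sklearn.svm import LinearSVC

from .plda import PLDA

__all__ = [
    "Condition", "EmbeddingSet", "SimilarityMatrix", "PrivacyReport",
    "fit_plda", "plda_llr", "similarity_matrix", "diag_dominance",
    "gvd", "deid", "privacy_protocol", "sid_probe",
]

log = logging.getLogger(__name__)


class Condition(str, Enum):
    ORIGINAL = "original"
    PROTECTED = "protected"


@dataclass
class EmbeddingSet:
    embeddings: np.ndarray     # (n, d)
    speaker_ids: np.ndarray    # (n,)
    condition: Condition = Condition.ORIGINAL

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.speaker_ids = np.asarray(self.speaker_ids)
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be n×d")
        if len(self.speaker_ids) != len(self.embeddings):
            raise ValueError("speaker_ids length mismatch")
        self.condition = Condition(self.condition)

    @property
    def speakers(self) -> np.ndarray:
        return np.unique(self.speaker_ids)

    def subset(self, speakers) -> "EmbeddingSet":
        mask = np.isin(self.speaker_ids, speakers)
        return EmbeddingSet(self.embeddings[mask], self.speaker_ids[mask],
                            self.condition)


@dataclass
class SimilarityMatrix:
    values: np.ndarray         # (K, K), entries in (0, 1)
    speakers: np.ndarray
    pair: str = "oo"           # oo | pp | op

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or \
                self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")


@dataclass
class PrivacyReport:
    gvd_db: float
    deid_pct: float
    n_repeats: int
    per_repeat_gvd: list = field(default_factory=list)
    per_repeat_deid: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"gvd_db": self.gvd_db, "deid_pct": self.deid_pct,
                "n_repeats": self.n_repeats,
                "per_repeat_gvd": self.per_repeat_gvd,
                "per_repeat_deid": self.per_repeat_deid}


# --------------------------------------------------------------------------
# PLDA wrappers
# --------------------------------------------------------------------------

def fit_plda(train: EmbeddingSet, latent_dim: int | None = None,
             n_iter: int = 25) -> PLDA:
    """Fit a two-covariance PLDA on a training embedding set.

    ``latent_dim`` defaults to min(d, K−1) with K training speakers.
    """
    k = len(train.speakers)
    d = train.embeddings.shape[1]
    if latent_dim is None:
        latent_dim = min(d, k - 1)
    return PLDA(latent_dim=latent_dim, n_iter=n_iter).fit(
        train.embeddings, train.speaker_ids)


def plda_llr(model: PLDA, a, b) -> float:
    return model.llr(a, b)


# --------------------------------------------------------------------------
# similarity matrices and metrics
# --------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def similarity_matrix(model: PLDA, a: EmbeddingSet, b: EmbeddingSet,
                      segs_per_spk: int = 50, seed: int = 0,
                      pair: str = "oo") -> SimilarityMatrix:
    """Speaker-by-speaker similarity: sigmoid of mean pairwise LLR."""
    spk_a, spk_b = a.speakers, b.speakers
    if not np.array_equal(spk_a, spk_b):
        raise ValueError("both sets must cover the same speaker roster")
    rng = np.random.default_rng(seed)
    picks = {}
    for cond, es in (("a", a), ("b", b)):
        picks[cond] = {}
        for s in spk_a:
            idx = np.nonzero(es.speaker_ids == s)[0]
            if len(idx) > segs_per_spk:
                idx = rng.choice(idx, size=segs_per_spk, replace=False)
            elif len(idx) < segs_per_spk:
                log.warning("speaker %s has only %d segments (< %d); "
                            "using all", s, len(idx), segs_per_spk)
            picks[cond][s] = es.embeddings[idx]
    k = len(spk_a)
    values = np.zeros((k, k))
    for i, si in enumerate(spk_a):
        for j, sj in enumerate(spk_b):
            llrs = model.llr_matrix(picks["a"][si], picks["b"][sj])
            values[i, j] = _sigmoid(np.mean(llrs))
    return SimilarityMatrix(values=values, speakers=spk_a, pair=pair)


def diag_dominance(m: SimilarityMatrix | np.ndarray) -> float:
    """|mean diagonal − mean off-diagonal| of a square similarity matrix."""
    values = m.values if isinstance(m, SimilarityMatrix) else np.asarray(m)
    k = values.shape[0]
    if k < 2:
        raise ValueError("need at least 2 speakers")
    diag = np.trace(values) / k
    off = (values.sum() - np.trace(values)) / (k * (k - 1))
    return float(abs(diag - off))


def gvd(m_oo: SimilarityMatrix | np.ndarray,
        m_pp: SimilarityMatrix | np.ndarray) -> float:
    """Gain of voice distinctiveness in dB: 10·log10(D_pp / D_oo)."""
    d_oo = diag_dominance(m_oo)
    if d_oo <= 1e-12:
        raise ValueError("original dominance is zero; GVD undefined")
    d_pp = max(diag_dominance(m_pp), 1e-12)
    return float(10.0 * np.log10(d_pp / d_oo))


def deid(m_oo: SimilarityMatrix | np.ndarray,
         m_op: SimilarityMatrix | np.ndarray) -> float:
    """De-identification percentage: 100·(1 − D_op / D_oo)."""
    d_oo = diag_dominance(m_oo)
    if d_oo <= 1e-12:
        raise ValueError("original dominance is zero; DeID undefined")
    return float(100.0 * (1.0 - diag_dominance(m_op) / d_oo))


# --------------------------------------------------------------------------
# protocol
# --------------------------------------------------------------------------

def privacy_protocol(original: EmbeddingSet, protected: EmbeddingSet,
                     n_train_spk: int = 25, n_eval_spk: int = 10,
                     segs_per_spk: int = 50, repeats: int = 3,
                     seed: int = 0, plda_iter: int = 15) -> PrivacyReport:
    """Full GVD/DeID protocol over random speaker splits.

    Per repeat: split speakers into a PLDA-training and an evaluation set;
    fit separate PLDAs on original and protected embeddings (for GVD) and
    one pooled PLDA (for DeID); build the oo, pp and op similarity
    matrices on the evaluation speakers; compute both metrics. Reports
    means over repeats.
    """
    speakers = original.speakers
    if not np.array_equal(speakers, protected.speakers):
        raise ValueError("original and protected must share speakers")
    total = len(speakers)
    if total < 4:
        raise ValueError("need at least 4 speakers")
    if n_train_spk + n_eval_spk > total:
        old = (n_train_spk, n_eval_spk)
        n_train_spk = max(2, int(round(total * n_train_spk
                                       / (n_train_spk + n_eval_spk))))
        n_eval_spk = max(2, total - n_train_spk)
        n_train_spk = total - n_eval_spk
        log.warning("only %d speakers; scaling PLDA split %s -> (%d, %d)",
                    total, old, n_train_spk, n_eval_spk)
    gvds, deids = [], []
    for r in range(repeats):
        rng = np.random.default_rng(seed + 1000 * r)
        perm = speakers[rng.permutation(total)]
        train_spk = perm[:n_train_spk]
        eval_spk = np.sort(perm[n_train_spk:n_train_spk + n_eval_spk])
        o_train, p_train = original.subset(train_spk), \
            protected.subset(train_spk)
        o_eval, p_eval = original.subset(eval_spk), protected.subset(eval_spk)
        plda_o = fit_plda(o_train, n_iter=plda_iter)
        plda_p = fit_plda(p_train, n_iter=plda_iter)
        pooled = EmbeddingSet(
            np.vstack([o_train.embeddings, p_train.embeddings]),
            np.concatenate([o_train.speaker_ids, p_train.speaker_ids]))
        plda_pool = fit_plda(pooled, n_iter=plda_iter)
        m_oo = similarity_matrix(plda_o, o_eval, o_eval, segs_per_spk,
                                 seed=seed + r, pair="oo")
        m_pp = similarity_matrix(plda_p, p_eval, p_eval, segs_per_spk,
                                 seed=seed + r, pair="pp")
        m_oo_pool = similarity_matrix(plda_pool, o_eval, o_eval,
                                      segs_per_spk, seed=seed + r, pair="oo")
        m_op = similarity_matrix(plda_pool, o_eval, p_eval, segs_per_spk,
                                 seed=seed + r, pair="op")
        gvds.append(gvd(m_oo, m_pp))
        deids.append(deid(m_oo_pool, m_op))
    return PrivacyReport(gvd_db=float(np.mean(gvds)),
                         deid_pct=float(np.mean(deids)),
                         n_repeats=repeats,
                         per_repeat_gvd=[float(g) for g in gvds],
                         per_repeat_deid=[float(x) for x in deids])


# --------------------------------------------------------------------------
# SID probe
# --------------------------------------------------------------------------

def sid_probe(embeddings: np.ndarray, speaker_ids, split_seed: int = 0,
              test_frac: float = 0.5) -> tuple[float, float]:
    """Linear SVC speaker-identification probe.

    Splits each speaker's segments into probe-train and probe-test halves,
    fits a linear SVC, and returns (held-out accuracy, chance = 1/M).
    Speakers with a single segment are excluded.
    """
    x = np.asarray(embeddings, dtype=np.float64)
    ids = np.asarray(speaker_ids)
    rng = np.random.default_rng(split_seed)
    train_idx, test_idx = [], []
    kept = 0
    for s in np.unique(ids):
        idx = np.nonzero(ids == s)[0]
        if len(idx) < 2:
            log.warning("speaker %s has one segment; excluded from probe", s)
            continue
        kept += 1
        idx = idx[rng.permutation(len(idx))]
        n_test = max(1, int(round(test_frac * len(idx))))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    if kept < 2:
        raise ValueError("probe needs at least 2 speakers with >= 2 segments")
    clf = LinearSVC(dual="auto", max_iter=5000, random_state=split_seed)
    clf.fit(x[train_idx], ids[train_idx])
    acc = float(np.mean(clf.predict(x[test_idx]) == ids[test_idx]))
    return acc, 1.0 / kept
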