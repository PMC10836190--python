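"""Two-covariance PLDA for speaker verification scoring.

Generative model: a speaker's latent voice y ~ N(μ, B) (between-speaker
covariance) and each embedding of that speaker x ~ N(y, W) (within-speaker
covariance). Fitted by EM on centered, length-normalized embeddings,
optionally after a PCA projection to ``latent_dim``. The verification
score for a pair (a, b) is the log-likelihood ratio

    LLR(a, b) = log p(a, b | same speaker) − log p(a) p(b),

which has a closed Gaussian form in μ, B, W and is symmetric in (a, b).
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["PLDA"]

log = logging.getLogger(__name__)


def _ensure_pd(cov: np.ndarray, reg: float) -> np.ndarray:
    """Add a ridge only when the covariance is near-singular, so exact EM
    monotonicity is preserved in the well-conditioned case."""
    if np.linalg.eigvalsh(cov).min() < reg:
        return cov + reg * np.eye(cov.shape[0])
    return cov


def _logdet(a: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(a)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-positive-definite covariance")
    return val


class PLDA:
    """Two-covariance PLDA with EM fitting and pairwise LLR scoring."""

    def __init__(self, latent_dim: int | None = None, n_iter: int = 25,
                 reg: float = 1e-6):
        self.latent_dim = latent_dim
        self.n_iter = n_iter
        self.reg = reg
        self.loglik_history: list[float] = []
        self._fitted = False

    # ---------------------------------------------------------- preprocess
    def _preprocess_fit(self, x: np.ndarray) -> np.ndarray:
        self.center_ = x.mean(axis=0)
        x = x - self.center_
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        x = x / np.maximum(norms, 1e-12)
        d = x.shape[1]
        k = self.latent_dim if self.latent_dim is not None else d
        k = min(k, d)
        if k < d:
            # PCA projection for a compact speaker subspace
            _, _, vt = np.linalg.svd(x, full_matrices=False)
            self.proj_ = vt[:k].T
        else:
            self.proj_ = np.eye(d)
        return x @ self.proj_

    def _preprocess(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64)) - self.center_
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        return (x / np.maximum(norms, 1e-12)) @ self.proj_

    # ----------------------------------------------------------------- fit
    def fit(self, embeddings: np.ndarray, speaker_ids) -> "PLDA":
        x = np.asarray(embeddings, dtype=np.float64)
        ids = np.asarray(speaker_ids)
        if x.ndim != 2 or len(ids) != len(x):
            raise ValueError("embeddings must be n×d with matching ids")
        uniq, inv = np.unique(ids, return_inverse=True)
        if len(uniq) < 2:
            raise ValueError("PLDA needs at least 2 speakers")
        counts = np.bincount(inv)
        if counts.min() < 2:
            raise ValueError("every speaker needs at least 2 embeddings")
        z = self._preprocess_fit(x)
        n, d = z.shape
        k_spk = len(uniq)
        sums = np.zeros((k_spk, d))
        np.add.at(sums, inv, z)
        means = sums / counts[:, None]

        # init: μ from grand mean, B/W from between/within scatter
        mu = z.mean(axis=0)
        b_cov = _ensure_pd(np.atleast_2d(np.cov(means.T)), self.reg)
        w_cov = np.zeros((d, d))
        for k in range(k_spk):
            dev = z[inv == k] - means[k]
            w_cov += dev.T @ dev
        w_cov = _ensure_pd(w_cov / n, self.reg)

        self.loglik_history = []
        for _ in range(self.n_iter):
            try:
                b_inv = np.linalg.inv(b_cov)
                w_inv = np.linalg.inv(w_cov)
            except np.linalg.LinAlgError:
                log.warning("singular covariance during EM; regularizing")
                b_cov += 10 * self.reg * np.eye(d)
                w_cov += 10 * self.reg * np.eye(d)
                b_inv = np.linalg.inv(b_cov)
                w_inv = np.linalg.inv(w_cov)
            # E-step: posterior over each speaker's latent mean
            post_means = np.zeros((k_spk, d))
            post_covs = {}
            for nk in np.unique(counts):
                post_covs[nk] = np.linalg.inv(b_inv + nk * w_inv)
            for k in range(k_spk):
                c = post_covs[counts[k]]
                post_means[k] = c @ (b_inv @ mu + w_inv @ sums[k])
            # M-step
            mu = post_means.mean(axis=0)
            dev_b = post_means - mu
            b_cov = dev_b.T @ dev_b / k_spk
            b_cov += np.mean([post_covs[c] for c in counts], axis=0)
            b_cov = _ensure_pd(b_cov, self.reg)
            w_new = np.zeros((d, d))
            for k in range(k_spk):
                dev = z[inv == k] - post_means[k]
                w_new += dev.T @ dev + counts[k] * post_covs[counts[k]]
            w_cov = _ensure_pd(w_new / n, self.reg)
            self.loglik_history.append(
                self._marginal_loglik(z, inv, counts, mu, b_cov, w_cov))

        self.mu_, self.b_cov_, self.w_cov_ = mu, b_cov, w_cov
        self._precompute_scoring()
        self._fitted = True
        return self

    @staticmethod
    def _marginal_loglik(z, inv, counts, mu, b_cov, w_cov) -> float:
        """Exact marginal log-likelihood via the mean/deviation split.

        For a speaker with n observations, an orthonormal rotation maps the
        data to n−1 deviation vectors ~ N(0, W) and the scaled mean
        √n·x̄ ~ N(√n·μ, W + n·B); the Jacobian is 1.
        """
        d = z.shape[1]
        w_inv = np.linalg.inv(w_cov)
        ld_w = _logdet(w_cov)
        total = 0.0
        for k in range(len(counts)):
            xk = z[inv == k]
            nk = counts[k]
            xbar = xk.mean(axis=0)
            scatter = (xk - xbar).T @ (xk - xbar)
            total += -0.5 * (nk - 1) * (d * np.log(2 * np.pi) + ld_w)
            total += -0.5 * np.trace(w_inv @ scatter)
            cov_m = w_cov + nk * b_cov
            diff = np.sqrt(nk) * (xbar - mu)
            total += -0.5 * (d * np.log(2 * np.pi) + _logdet(cov_m)
                             + diff @ np.linalg.solve(cov_m, diff))
        return float(total)

    # -------------------------------------------------------------- scoring
    def _precompute_scoring(self):
        t = self.b_cov_ + self.w_cov_
        t_inv = np.linalg.inv(t)
        schur = t - self.b_cov_ @ t_inv @ self.b_cov_
        f = np.linalg.inv(schur)
        self._q = t_inv - f                       # quadratic self term
        cross = t_inv @ self.b_cov_ @ f           # cross term (−G)
        self._cross = 0.5 * (cross + cross.T)     # symmetrize numerically
        self._const = -0.5 * (_logdet(schur) - _logdet(t))

    def llr(self, a, b) -> float:
        """LLR for a single pair of embeddings (symmetric)."""
        return float(self.llr_matrix(np.atleast_2d(a),
                                     np.atleast_2d(b))[0, 0])

    def llr_matrix(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Pairwise LLRs between two sets: (n, d) × (m, d) -> (n, m)."""
        if not self._fitted:
            raise RuntimeError("PLDA is not fitted")
        za = self._preprocess(a) - self.mu_
        zb = self._preprocess(b) - self.mu_
        qa = 0.5 * np.einsum("id,de,ie->i", za, self._q, za)
        qb = 0.5 * np.einsum("id,de,ie->i", zb, self._q, zb)
        return qa[:, None] + qb[None, :] + za @ self._cross @ zb.T \
            + self._const
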