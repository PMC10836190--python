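"""PLDA scoring, similarity matrices, GVD/DeID and the SID probe."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.metrics import roc_auc_score

from despeaker.plda import PLDA
from despeaker.privacy_eval import (EmbeddingSet, Condition, fit_plda,
                                    plda_llr, similarity_matrix,
                                    diag_dominance, gvd, deid,
                                    privacy_protocol, sid_probe,
                                    SimilarityMatrix)


def gaussian_speakers(rng, n_spk=12, n_per=15, d=8, between=2.0, within=0.3):
    means = rng.normal(scale=np.sqrt(between), size=(n_spk, d))
    x = np.concatenate([m + rng.normal(scale=np.sqrt(within),
                                       size=(n_per, d)) for m in means])
    ids = np.repeat(np.arange(n_spk), n_per)
    return x, ids


@pytest.fixture(scope="module")
def fitted_plda():
    rng = np.random.default_rng(0)
    x, ids = gaussian_speakers(rng)
    model = PLDA(n_iter=15).fit(x, ids)
    return model, x, ids


class TestPLDA:
    def test_em_loglik_nondecreasing(self, fitted_plda):
        model, _, _ = fitted_plda
        diffs = np.diff(model.loglik_history)
        assert np.all(diffs >= -1e-6)

    def test_llr_symmetry(self, fitted_plda):
        model, x, _ = fitted_plda
        assert plda_llr(model, x[0], x[1]) == \
            pytest.approx(plda_llr(model, x[1], x[0]), abs=1e-10)

    def test_llr_matches_direct_gaussian_computation(self, fitted_plda):
        model, x, _ = fitted_plda
        a = model._preprocess(x[3])[0]
        b = model._preprocess(x[40])[0]
        t = model.b_cov_ + model.w_cov_
        joint = np.block([[t, model.b_cov_], [model.b_cov_, t]])
        mu2 = np.concatenate([model.mu_, model.mu_])
        direct = multivariate_normal.logpdf(np.concatenate([a, b]),
                                            mu2, joint) \
            - multivariate_normal.logpdf(a, model.mu_, t) \
            - multivariate_normal.logpdf(b, model.mu_, t)
        assert model.llr(x[3], x[40]) == pytest.approx(direct, abs=1e-8)

    def test_same_speaker_scores_above_different(self, fitted_plda):
        model, x, ids = fitted_plda
        rng = np.random.default_rng(1)
        same, diff = [], []
        for _ in range(200):
            s = rng.integers(12)
            i, j = rng.choice(np.nonzero(ids == s)[0], 2, replace=False)
            same.append(model.llr(x[i], x[j]))
            other = (s + 1 + rng.integers(10)) % 12
            k = rng.choice(np.nonzero(ids == other)[0])
            diff.append(model.llr(x[i], x[k]))
        auc = roc_auc_score([1] * 200 + [0] * 200, same + diff)
        assert auc > 0.9

    def test_no_between_variance_means_no_separation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(120, 6))          # all speakers identical
        ids = np.repeat(np.arange(10), 12)
        model = PLDA(n_iter=10).fit(x, ids)
        same, diff = [], []
        for _ in range(150):
            s = rng.integers(10)
            i, j = rng.choice(np.nonzero(ids == s)[0], 2, replace=False)
            same.append(model.llr(x[i], x[j]))
            k = rng.choice(np.nonzero(ids != s)[0])
            diff.append(model.llr(x[i], x[k]))
        auc = roc_auc_score([1] * 150 + [0] * 150, same + diff)
        assert abs(auc - 0.5) < 0.1

    def test_min_speakers_and_counts_enforced(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            PLDA().fit(rng.normal(size=(10, 4)), np.zeros(10))
        with pytest.raises(ValueError):
            PLDA().fit(rng.normal(size=(3, 4)), [0, 0, 1])


class TestSimilarityMatrix:
    def test_entries_in_unit_interval_and_diag_dominant(self, fitted_plda):
        model, x, ids = fitted_plda
        es = EmbeddingSet(x, ids)
        m = similarity_matrix(model, es, es, segs_per_spk=10, seed=0)
        assert np.all((m.values > 0) & (m.values < 1))
        k = m.values.shape[0]
        diag = np.trace(m.values) / k
        off = (m.values.sum() - np.trace(m.values)) / (k * (k - 1))
        assert diag > off

    def test_pure_noise_embeddings_no_dominance(self):
        rng = np.random.default_rng(4)
        x, ids = gaussian_speakers(rng, between=2.0, within=0.3)
        model = PLDA(n_iter=10).fit(x, ids)
        noise = EmbeddingSet(rng.normal(size=x.shape), ids)
        m = similarity_matrix(model, noise, noise, segs_per_spk=10, seed=0)
        assert diag_dominance(m) < 0.05

    def test_deterministic_under_seed(self, fitted_plda):
        model, x, ids = fitted_plda
        es = EmbeddingSet(x, ids)
        m1 = similarity_matrix(model, es, es, segs_per_spk=5, seed=3)
        m2 = similarity_matrix(model, es, es, segs_per_spk=5, seed=3)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_mismatched_rosters_rejected(self, fitted_plda):
        model, x, ids = fitted_plda
        a = EmbeddingSet(x, ids)
        b = EmbeddingSet(x[ids < 5], ids[ids < 5])
        with pytest.raises(ValueError):
            similarity_matrix(model, a, b)


class TestDominanceAndMetrics:
    def test_identity_like_matrix(self):
        m = np.eye(10)
        assert diag_dominance(m) == pytest.approx(1.0)

    def test_constant_matrix_zero(self):
        assert diag_dominance(np.full((6, 6), 0.37)) == pytest.approx(0.0)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = rng.random((10, 10))
            diag_sum = sum(m[i, i] for i in range(10))
            off_sum = sum(m[i, j] for i in range(10) for j in range(10)
                          if i != j)
            oracle = abs(diag_sum / 10 - off_sum / 90)
            assert diag_dominance(m) == pytest.approx(oracle, abs=1e-12)

    def test_gvd_identical_matrices_zero_db(self):
        m = np.eye(5) * 0.9 + 0.05
        assert gvd(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_gvd_halved_dominance_minus_three_db(self):
        m_oo = np.eye(5) * 0.8 + 0.1
        m_pp = np.eye(5) * 0.4 + 0.1 + np.full((5, 5), 0.2) \
            - np.eye(5) * 0.2
        # construct matrices with dominance ratio exactly 0.5
        d_oo = diag_dominance(m_oo)
        m_half = np.full((5, 5), 0.3)
        np.fill_diagonal(m_half, 0.3 + d_oo / 2)
        assert gvd(m_oo, m_half) == pytest.approx(-10 * np.log10(2),
                                                  abs=1e-9)
        assert gvd(m_oo, m_half) == pytest.approx(-3.01, abs=0.01)

    def test_gvd_antisymmetric(self):
        rng = np.random.default_rng(6)
        a = rng.random((6, 6)) + np.eye(6)
        b = rng.random((6, 6)) + 2 * np.eye(6)
        assert gvd(a, b) == pytest.approx(-gvd(b, a), abs=1e-10)

    def test_deid_edge_cases(self):
        m = np.eye(5) * 0.8 + 0.1
        assert deid(m, m) == pytest.approx(0.0, abs=1e-12)
        flat = np.full((5, 5), 0.5)
        assert deid(m, flat) == pytest.approx(100.0)
        d = diag_dominance(m)
        half = np.full((5, 5), 0.2)
        np.fill_diagonal(half, 0.2 + d / 2)
        assert deid(m, half) == pytest.approx(50.0, abs=1e-9)

    def test_zero_original_dominance_raises(self):
        flat = np.full((4, 4), 0.2)
        with pytest.raises(ValueError):
            gvd(flat, np.eye(4))
        with pytest.raises(ValueError):
            deid(flat, np.eye(4))

    def test_dominance_needs_two_speakers(self):
        with pytest.raises(ValueError):
            diag_dominance(np.ones((1, 1)))


class TestProtocol:
    def test_identical_conditions_give_zero_metrics(self):
        rng = np.random.default_rng(7)
        x, ids = gaussian_speakers(rng, n_spk=14, n_per=10)
        es_o = EmbeddingSet(x, ids, Condition.ORIGINAL)
        es_p = EmbeddingSet(x.copy(), ids, Condition.PROTECTED)
        rep = privacy_protocol(es_o, es_p, n_train_spk=10, n_eval_spk=4,
                               segs_per_spk=8, repeats=2, seed=0,
                               plda_iter=8)
        assert rep.gvd_db == pytest.approx(0.0, abs=1e-6)
        assert rep.deid_pct == pytest.approx(0.0, abs=1e-6)
        assert len(rep.per_repeat_gvd) == 2

    def test_speaker_mean_removal_degrades_identity(self):
        rng = np.random.default_rng(8)
        x, ids = gaussian_speakers(rng, n_spk=14, n_per=12, between=3.0,
                                   within=0.3)
        removed = x.copy()
        for s in np.unique(ids):
            removed[ids == s] -= x[ids == s].mean(axis=0)
        removed += rng.normal(scale=0.05, size=removed.shape)
        rep = privacy_protocol(EmbeddingSet(x, ids),
                               EmbeddingSet(removed, ids,
                                            Condition.PROTECTED),
                               n_train_spk=10, n_eval_spk=4,
                               segs_per_spk=10, repeats=2, seed=1,
                               plda_iter=8)
        assert rep.gvd_db < 0
        assert rep.deid_pct > 0

    def test_report_carries_per_repeat_values(self):
        rng = np.random.default_rng(9)
        x, ids = gaussian_speakers(rng, n_spk=10, n_per=8)
        rep = privacy_protocol(EmbeddingSet(x, ids),
                               EmbeddingSet(x + 0.01, ids,
                                            Condition.PROTECTED),
                               n_train_spk=7, n_eval_spk=3,
                               segs_per_spk=6, repeats=3, seed=2,
                               plda_iter=5)
        assert rep.n_repeats == 3
        assert rep.gvd_db == pytest.approx(np.mean(rep.per_repeat_gvd))


class TestSidProbe:
    def test_structured_embeddings_beat_chance(self):
        rng = np.random.default_rng(10)
        x, ids = gaussian_speakers(rng, n_spk=8, n_per=12)
        acc, chance = sid_probe(x, ids, split_seed=0)
        assert chance == pytest.approx(1 / 8)
        assert acc > 5 * chance

    def test_permuted_labels_fall_to_chance(self):
        rng = np.random.default_rng(11)
        x, ids = gaussian_speakers(rng, n_spk=8, n_per=12)
        perm_ids = rng.permutation(ids)
        acc, chance = sid_probe(x, perm_ids, split_seed=0)
        assert acc < chance + 0.15

    def test_single_segment_speakers_excluded(self):
        rng = np.random.default_rng(12)
        x, ids = gaussian_speakers(rng, n_spk=4, n_per=10)
        x = np.vstack([x, rng.normal(size=(1, x.shape[1]))])
        ids = np.concatenate([ids, [99]])
        acc, chance = sid_probe(x, ids, split_seed=0)
        assert chance == pytest.approx(1 / 4)
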