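"""Training loop: LR schedule, determinism, baseline equivalence,
checkpointing and ensembles."""

import numpy as np
import pytest

from despeaker.losses import LossSpec, DisentMethod
from despeaker.training import (TrainConfig, train_model, train_ensemble,
                                lr_step, save_checkpoint, load_checkpoint)


class TestLrStep:
    CFG = TrainConfig(lr=1e-3)

    def test_two_stalled_epochs_decay_once(self):
        hist = [1.0, 1.1, 1.2]
        assert lr_step(1e-3, hist, self.CFG) == pytest.approx(9e-4)

    def test_improving_sequence_keeps_lr(self):
        assert lr_step(1e-3, [1.0, 0.9, 0.8], self.CFG) == 1e-3

    def test_four_stalls_decay_twice(self):
        lr = 1e-3
        hist = [1.0]
        for v in (1.1, 1.2, 1.3, 1.4):
            hist.append(v)
            lr = lr_step(lr, hist, self.CFG)
        assert lr == pytest.approx(8.1e-4)

    def test_short_history_untouched(self):
        assert lr_step(1e-3, [1.0], self.CFG) == 1e-3


class TestTrainModel:
    def test_lambda_zero_equals_none_bitwise(self, split_corpus,
                                             tiny_model_spec,
                                             quick_train_cfg):
        train, val, _ = split_corpus
        a = train_model(train, val, tiny_model_spec,
                        LossSpec(DisentMethod.NONE), quick_train_cfg, seed=5)
        b = train_model(train, val, tiny_model_spec,
                        LossSpec(DisentMethod.LECE, 0.0), quick_train_cfg,
                        seed=5)
        for pa, pb in zip(a.model.state_arrays(), b.model.state_arrays()):
            np.testing.assert_array_equal(pa, pb)

    def test_same_seed_identical_history(self, split_corpus,
                                         tiny_model_spec, quick_train_cfg):
        train, val, _ = split_corpus
        a = train_model(train, val, tiny_model_spec,
                        LossSpec(DisentMethod.LEKLD, 1.0), quick_train_cfg,
                        seed=6)
        b = train_model(train, val, tiny_model_spec,
                        LossSpec(DisentMethod.LEKLD, 1.0), quick_train_cfg,
                        seed=6)
        assert a.history == b.history

    def test_retained_checkpoint_has_min_val_loss(self, split_corpus,
                                                  tiny_model_spec,
                                                  quick_train_cfg):
        train, val, _ = split_corpus
        tm = train_model(train, val, tiny_model_spec,
                         LossSpec(DisentMethod.NONE), quick_train_cfg,
                         seed=7)
        losses = [h["val_loss"] for h in tm.history]
        assert tm.best_val_loss == pytest.approx(min(losses))

    def test_speaker_overlap_between_train_and_val_rejected(
            self, split_corpus, tiny_model_spec, quick_train_cfg):
        train, _, _ = split_corpus
        with pytest.raises(ValueError):
            train_model(train, train[:4], tiny_model_spec,
                        LossSpec(DisentMethod.NONE), quick_train_cfg, seed=0)

    def test_separable_data_reaches_high_training_accuracy(self):
        from despeaker.synthcorpus import SynthConfig, make_speakers, \
            synth_segments
        from despeaker.models import ModelSpec, ModelFamily
        cfg = SynthConfig(n_speakers=8, segments_per_speaker=10, frames=15,
                          dims=12, identity_strength=0.2, mdd_strength=4.0,
                          noise_sd=0.1, seed=12)
        segs = synth_segments(make_speakers(cfg), cfg)
        dep = sorted({s.speaker_index for s in segs if s.mdd_label})
        nd = sorted({s.speaker_index for s in segs if not s.mdd_label})
        tr_spk = set(dep[:1] + nd[:3])
        va_spk = set(dep[1:] + nd[3:])
        train = [s for s in segs if s.speaker_index in tr_spk]
        val = [s for s in segs if s.speaker_index in va_spk]
        spec = ModelSpec(ModelFamily.CNN_LSTM, n_speakers=len(tr_spk),
                         input_dim=12, conv_layers=[(8, 3, 1)],
                         lstm_hidden=8, n_lstm_layers=1, dropout=0.0)
        tm = train_model(train, val, spec, LossSpec(DisentMethod.NONE),
                         TrainConfig(lr=1e-2, batch_size=16, max_epochs=15,
                                     early_stop=15), seed=1)
        x = np.stack([s.data for s in train])
        y = np.array([s.mdd_label for s in train])
        pred = (tm.model.forward(x).p.data >= 0.5).astype(int)
        assert (pred == y).mean() > 0.9


class TestEnsemble:
    def test_members_have_distinct_weights(self, split_corpus,
                                           tiny_model_spec,
                                           quick_train_cfg):
        train, val, _ = split_corpus
        members = train_ensemble([train, train, train], val,
                                 tiny_model_spec,
                                 LossSpec(DisentMethod.NONE),
                                 quick_train_cfg)
        assert len(members) == 3
        w0 = np.concatenate([a.ravel()
                             for a in members[0].model.state_arrays()])
        w1 = np.concatenate([a.ravel()
                             for a in members[1].model.state_arrays()])
        assert np.linalg.norm(w0 - w1) > 0

    def test_single_model_mode(self, split_corpus, tiny_model_spec,
                               quick_train_cfg):
        train, val, _ = split_corpus
        members = train_ensemble([train], val, tiny_model_spec,
                                 LossSpec(DisentMethod.NONE),
                                 quick_train_cfg)
        assert len(members) == 1

    def test_more_subsets_than_seeds_rejected(self, split_corpus,
                                              tiny_model_spec,
                                              quick_train_cfg):
        train, val, _ = split_corpus
        with pytest.raises(ValueError):
            train_ensemble([train] * 4, val, tiny_model_spec,
                           LossSpec(DisentMethod.NONE), quick_train_cfg)


class TestCheckpoint:
    def test_round_trip_reproduces_outputs(self, split_corpus,
                                           tiny_model_spec,
                                           quick_train_cfg, tmp_path):
        train, val, ev = split_corpus
        tm = train_model(train, val, tiny_model_spec,
                         LossSpec(DisentMethod.LECE, 0.5), quick_train_cfg,
                         seed=9)
        save_checkpoint(tm, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        x = np.stack([s.data for s in ev[:6]])
        np.testing.assert_array_equal(tm.model.forward(x).p.data,
                                      back.model.forward(x).p.data)
        assert back.loss_spec.method is DisentMethod.LECE
        assert back.best_val_loss == tm.best_val_loss
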