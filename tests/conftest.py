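import numpy as np
import pytest

from despeaker.synthcorpus import SynthConfig, make_speakers, synth_segments
from despeaker.features import fit_norm_stats, apply_norm, balance_segments
from despeaker.models import ModelSpec, ModelFamily
from despeaker.training import TrainConfig


@pytest.fixture(scope="session")
def small_corpus():
    """A small but structured corpus: 12 speakers × 8 segments."""
    cfg = SynthConfig(n_speakers=12, segments_per_speaker=8, frames=20,
                      dims=16, identity_strength=1.0, mdd_strength=1.0,
                      noise_sd=0.5, seed=42)
    profiles = make_speakers(cfg)
    return cfg, profiles, synth_segments(profiles, cfg)


@pytest.fixture(scope="session")
def split_corpus(small_corpus):
    """Speaker-disjoint, normalized train/val/eval segment lists."""
    cfg, profiles, segments = small_corpus
    dep = sorted(p.speaker_index for p in profiles if p.mdd_label)
    nd = sorted(p.speaker_index for p in profiles if not p.mdd_label)
    tr = set(dep[:2] + nd[:4])
    va = set(dep[2:3] + nd[4:6])
    ev = set(dep[3:] + nd[6:])
    pick = lambda spk: [s for s in segments if s.speaker_index in spk]
    train, val, evl = pick(tr), pick(va), pick(ev)
    stats = fit_norm_stats(train)
    norm = lambda xs: [apply_norm(s, stats) for s in xs]
    train = balance_segments(norm(train), np.random.default_rng(0))
    return train, norm(val), norm(evl)


@pytest.fixture(scope="session")
def tiny_model_spec(split_corpus):
    train, _, _ = split_corpus
    m = len({s.speaker_index for s in train})
    return ModelSpec(ModelFamily.CNN_LSTM, n_speakers=m,
                     input_dim=train[0].dims, conv_layers=[(8, 3, 1)],
                     lstm_hidden=8, n_lstm_layers=1, dropout=0.0)


@pytest.fixture(scope="session")
def quick_train_cfg():
    return TrainConfig(lr=5e-3, batch_size=32, max_epochs=5, early_stop=5,
                       seeds=[7, 8, 9])
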