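"""Synthetic corpus: determinism, class counts, signal controllability,
waveforms and manifests."""

import numpy as np
import pandas as pd
import pytest
from scipy.io import wavfile
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from despeaker.features import FeatureConfig, melspec
from despeaker.synthcorpus import (SynthConfig, make_speakers, synth_segments,
                                   synth_waveforms, assign_splits,
                                   write_manifest, read_manifest)
from despeaker.privacy_eval import sid_probe


def _segment_means(segments):
    x = np.stack([s.data.mean(axis=0) for s in segments])
    spk = np.array([s.speaker_index for s in segments])
    y = np.array([s.mdd_label for s in segments])
    return x, spk, y


class TestMakeSpeakers:
    def test_rounded_prevalence(self):
        cfg = SynthConfig(n_speakers=10, prevalence=0.3, seed=7)
        profs = make_speakers(cfg)
        assert sum(p.mdd_label for p in profs) == 3
        assert len(profs) == 10

    def test_eatd_like_ratio(self):
        cfg = SynthConfig(n_speakers=100, prevalence=0.296, seed=0)
        assert sum(p.mdd_label for p in make_speakers(cfg)) == 30

    def test_determinism_bit_for_bit(self):
        cfg = SynthConfig(n_speakers=8, seed=11)
        a, b = make_speakers(cfg), make_speakers(cfg)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.identity_vector,
                                          pb.identity_vector)
            assert pa.mdd_label == pb.mdd_label

    def test_speaker_indices_unique(self):
        profs = make_speakers(SynthConfig(n_speakers=15, seed=1))
        assert len({p.speaker_index for p in profs}) == 15

    def test_single_speaker_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_speakers=1)


class TestSynthSegments:
    def test_segment_count_conserved(self):
        cfg = SynthConfig(n_speakers=6, segments_per_speaker=5, seed=2)
        segs = synth_segments(make_speakers(cfg), cfg)
        assert len(segs) == 30
        per_spk = {}
        for s in segs:
            per_spk[s.speaker_index] = per_spk.get(s.speaker_index, 0) + 1
        assert all(v == 5 for v in per_spk.values())

    def test_zero_identity_strength_probe_at_chance(self):
        cfg = SynthConfig(n_speakers=8, segments_per_speaker=12, frames=20,
                          dims=16, identity_strength=0.0, mdd_strength=0.0,
                          seed=3)
        segs = synth_segments(make_speakers(cfg), cfg)
        x, spk, _ = _segment_means(segs)
        acc, chance = sid_probe(x, spk, split_seed=0)
        # binomial CI around chance for 48 held-out segments
        assert acc < chance + 3 * np.sqrt(chance * (1 - chance) / 48)

    def test_zero_mdd_strength_auc_near_half(self):
        cfg = SynthConfig(n_speakers=10, segments_per_speaker=12, frames=20,
                          dims=16, identity_strength=0.0, mdd_strength=0.0,
                          seed=4)
        segs = synth_segments(make_speakers(cfg), cfg)
        x, _, y = _segment_means(segs)
        clf = LogisticRegression(max_iter=500).fit(x[::2], y[::2])
        auc = roc_auc_score(y[1::2], clf.predict_proba(x[1::2])[:, 1])
        assert abs(auc - 0.5) < 0.15

    def test_strong_mdd_low_noise_is_separable(self):
        cfg = SynthConfig(n_speakers=10, segments_per_speaker=10, frames=20,
                          dims=16, identity_strength=0.2, mdd_strength=5.0,
                          noise_sd=0.05, seed=5)
        segs = synth_segments(make_speakers(cfg), cfg)
        x, _, y = _segment_means(segs)
        clf = LogisticRegression(max_iter=500).fit(x[::2], y[::2])
        assert clf.score(x[1::2], y[1::2]) == pytest.approx(1.0)

    def test_probe_monotone_in_identity_strength(self):
        accs = []
        for strength in (0.0, 0.5, 2.0):
            cfg = SynthConfig(n_speakers=8, segments_per_speaker=10,
                              frames=20, dims=16, mdd_strength=0.0,
                              identity_strength=strength, seed=6)
            segs = synth_segments(make_speakers(cfg), cfg)
            x, spk, _ = _segment_means(segs)
            accs.append(sid_probe(x, spk, split_seed=0)[0])
        assert accs[0] <= accs[1] + 0.1 and accs[1] <= accs[2] + 0.1
        assert accs[2] > accs[0]

    def test_depressed_segments_have_flatter_contours(self):
        cfg = SynthConfig(n_speakers=20, segments_per_speaker=4, frames=30,
                          dims=16, identity_strength=0.0, mdd_strength=2.0,
                          noise_sd=0.1, seed=7)
        segs = synth_segments(make_speakers(cfg), cfg)
        var_dep = np.mean([s.data.var(axis=0).mean() for s in segs
                           if s.mdd_label])
        var_nd = np.mean([s.data.var(axis=0).mean() for s in segs
                          if not s.mdd_label])
        assert var_dep < var_nd

    def test_determinism(self):
        cfg = SynthConfig(n_speakers=4, segments_per_speaker=3, seed=8)
        profs = make_speakers(cfg)
        a = synth_segments(profs, cfg)
        b = synth_segments(profs, cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.data, sb.data)


@pytest.fixture(scope="module")
def wav_corpus(tmp_path_factory):
    cfg = SynthConfig(n_speakers=3, segments_per_speaker=2, seed=9)
    profs = make_speakers(cfg)
    out = tmp_path_factory.mktemp("wavs")
    manifest = synth_waveforms(profs, cfg, out)
    return cfg, manifest


class TestWaveforms:
    def test_sample_count_and_format(self, wav_corpus):
        _, manifest = wav_corpus
        sr, data = wavfile.read(manifest.iloc[0]["path"])
        assert sr == 16_000
        assert data.dtype == np.int16
        assert len(data) == 61_440        # 3.84 s at 16 kHz

    def test_same_seed_bit_identical_payloads(self, wav_corpus, tmp_path):
        cfg, manifest = wav_corpus
        profs = make_speakers(cfg)
        manifest2 = synth_waveforms(profs, cfg, tmp_path)
        for p1, p2 in zip(manifest["path"], manifest2["path"]):
            _, d1 = wavfile.read(p1)
            _, d2 = wavfile.read(p2)
            np.testing.assert_array_equal(d1, d2)

    def test_mel_front_end_yields_120_frames(self, wav_corpus):
        _, manifest = wav_corpus
        _, data = wavfile.read(manifest.iloc[0]["path"])
        mel = melspec(data / 32768.0, FeatureConfig(n_mels=40))
        assert mel.shape == (120, 40)


class TestManifest:
    def _records(self, n_spk=10, per=5):
        rows = []
        for s in range(n_spk):
            for k in range(per):
                rows.append({"id": f"s{s}u{k}", "path": f"s{s}u{k}.npy",
                             "speaker_id": s, "split": "train",
                             "label": int(s < 3)})
        return pd.DataFrame(rows)

    def test_row_count(self, tmp_path):
        df = self._records()
        write_manifest(df, tmp_path / "m.csv")
        assert len(read_manifest(tmp_path / "m.csv")) == 50

    def test_round_trip(self, tmp_path):
        df = assign_splits(self._records(), seed=1)
        path = write_manifest(df, tmp_path / "m.csv")
        back = read_manifest(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True),
            df[["id", "path", "speaker_id", "split", "label"]]
            .reset_index(drop=True))

    def test_duplicate_ids_rejected(self, tmp_path):
        df = self._records()
        df.loc[1, "id"] = df.loc[0, "id"]
        with pytest.raises(ValueError):
            write_manifest(df, tmp_path / "m.csv")

    def test_splits_are_speaker_disjoint(self):
        df = assign_splits(self._records(n_spk=20), train_frac=0.6,
                           val_frac=0.2, seed=2)
        per_spk = df.groupby("speaker_id")["split"].nunique()
        assert (per_spk == 1).all()
        assert set(df["split"]) == {"train", "val", "eval"}
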