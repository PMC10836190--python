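"""Synthetic multi-speaker corpora with controllable identity and
depression signals.

The generator emulates the statistical structure a depression-detection
front-end sees in a real clinical speech corpus, without any real audio:

* every speaker has a fixed identity signature — an additive offset and a
  mild diagonal scaling — confined to an *identity subspace* of the
  feature space;
* depressed speakers (binary label) carry a mean shift along a *depression
  subspace* and a flattened temporal contour (reduced frame-to-frame
  dynamic range, mimicking the monotonic prosody associated with
  depression);
* the depression subspace deliberately shares a configurable fraction of
  its directions with the identity subspace (default 0.25), so removing
  speaker information has a genuine cost for depression information —
  otherwise disentanglement would be trivially free;
* i.i.d. Gaussian noise on every frame.

A waveform mode renders per-speaker harmonic sources (speaker-specific
fundamental and resonance; depressed speakers get compressed pitch range
and energy dynamics) as 16 kHz 16-bit PCM WAV files for exercising the mel
front-end.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.io import wavfile

from .features import FeatureSegment

__all__ = [
    "SynthConfig", "SpeakerProfile", "make_speakers", "synth_segments",
    "synth_waveforms", "assign_splits", "write_manifest", "read_manifest",
]

SAMPLE_RATE = 16_000


@dataclass
class SynthConfig:
    n_speakers: int = 20
    segments_per_speaker: int = 20
    frames: int = 25
    dims: int = 24
    identity_strength: float = 1.0
    mdd_strength: float = 1.0
    noise_sd: float = 0.5
    prevalence: float = 0.3
    overlap: float = 0.25              # identity/depression subspace overlap
    identity_rank: int | None = None   # identity subspace dims (dims//3)
    mdd_rank: int | None = None        # depression subspace dims (dims//6)
    segment_seconds: float = 3.84
    seed: int = 0

    def __post_init__(self):
        if self.n_speakers < 2:
            raise ValueError("a corpus needs at least 2 speakers "
                             "(the SID branch needs >= 2 classes)")
        for name in ("segments_per_speaker", "frames", "dims"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.identity_strength < 0 or self.mdd_strength < 0:
            raise ValueError("signal strengths must be >= 0")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must be in [0, 1]")
        if self.identity_rank is None:
            self.identity_rank = max(1, self.dims // 3)
        if self.mdd_rank is None:
            self.mdd_rank = max(1, self.dims // 6)
        if self.identity_rank + self.mdd_rank > self.dims:
            raise ValueError("subspace ranks exceed feature dimension")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**d)


@dataclass
class SpeakerProfile:
    speaker_index: int
    identity_vector: np.ndarray     # (dims,) additive offset
    identity_scale: np.ndarray      # (dims,) diagonal scaling
    mdd_label: int
    f0_hz: float = 150.0            # waveform mode: fundamental
    formant_hz: float = 1000.0      # waveform mode: resonance centre


def _basis(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal identity / depression subspace bases (seeded).

    The depression basis reuses ``round(overlap·mdd_rank)`` identity
    directions and takes the rest from the orthogonal complement.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    q, _ = np.linalg.qr(rng.normal(size=(cfg.dims, cfg.dims)))
    ident = q[:, :cfg.identity_rank]
    n_shared = int(round(cfg.overlap * cfg.mdd_rank))
    shared = ident[:, :n_shared]
    fresh = q[:, cfg.identity_rank:cfg.identity_rank + cfg.mdd_rank - n_shared]
    return ident, np.hstack([shared, fresh])


def make_speakers(cfg: SynthConfig) -> list[SpeakerProfile]:
    """Create speaker profiles; depressed count = round(prevalence · M)."""
    rng = np.random.default_rng(cfg.seed)
    ident_basis, _ = _basis(cfg)
    n_dep = int(round(cfg.prevalence * cfg.n_speakers))
    n_dep = min(max(n_dep, 1), cfg.n_speakers - 1)
    labels = np.zeros(cfg.n_speakers, dtype=int)
    labels[rng.permutation(cfg.n_speakers)[:n_dep]] = 1
    profiles = []
    for i in range(cfg.n_speakers):
        coefs = rng.normal(size=cfg.identity_rank)
        offset = cfg.identity_strength * (ident_basis @ coefs)
        scale = 1.0 + cfg.identity_strength * 0.3 * \
            rng.uniform(-1.0, 1.0, size=cfg.dims)
        f0 = rng.uniform(90.0, 240.0)
        formant = rng.uniform(500.0, 2500.0)
        profiles.append(SpeakerProfile(
            speaker_index=i, identity_vector=offset, identity_scale=scale,
            mdd_label=int(labels[i]), f0_hz=f0, formant_hz=formant))
    return profiles


def synth_segments(profiles: list[SpeakerProfile],
                   cfg: SynthConfig) -> list[FeatureSegment]:
    """Generate frame×dim feature segments for every speaker.

    Each segment is: speaker offset (broadcast over frames), a depressed
    mean shift along the depression subspace, a smooth temporal contour
    whose amplitude is damped for depressed speakers (flattened prosody),
    and white Gaussian noise — all under the speaker's diagonal scaling.
    """
    if not profiles:
        raise ValueError("no speaker profiles")
    rng = np.random.default_rng(cfg.seed + 7)
    _, mdd_basis = _basis(cfg)
    # fixed depression pattern within its subspace
    pat_rng = np.random.default_rng(cfg.seed + 11)
    pattern = mdd_basis @ pat_rng.normal(size=mdd_basis.shape[1])
    pattern /= np.linalg.norm(pattern)
    t = np.arange(cfg.frames)
    segments = []
    for prof in profiles:
        flatten = 1.0 / (1.0 + cfg.mdd_strength) if prof.mdd_label else 1.0
        shift = cfg.mdd_strength * pattern if prof.mdd_label else 0.0
        for k in range(cfg.segments_per_speaker):
            # smooth contour: two random sinusoids per feature direction
            phases = rng.uniform(0, 2 * np.pi, size=(2, cfg.dims))
            freqs = rng.uniform(0.02, 0.15, size=(2, cfg.dims))
            contour = np.sin(2 * np.pi * freqs[None, 0] * t[:, None]
                             + phases[None, 0]) \
                + 0.5 * np.sin(2 * np.pi * freqs[None, 1] * t[:, None]
                               + phases[None, 1])
            data = (prof.identity_vector + shift
                    + flatten * contour
                    + rng.normal(scale=cfg.noise_sd,
                                 size=(cfg.frames, cfg.dims)))
            data = data * prof.identity_scale
            segments.append(FeatureSegment(
                data=data, speaker_index=prof.speaker_index,
                mdd_label=prof.mdd_label,
                source_utterance=f"spk{prof.speaker_index:04d}_seg{k:04d}"))
    return segments


# --------------------------------------------------------------------------
# waveform mode
# --------------------------------------------------------------------------

def _render_wave(prof: SpeakerProfile, cfg: SynthConfig,
                 rng: np.random.Generator) -> np.ndarray:
    n = int(round(cfg.segment_seconds * SAMPLE_RATE))
    t = np.arange(n) / SAMPLE_RATE
    depressed = bool(prof.mdd_label)
    # pitch contour: slow random modulation, compressed when depressed
    depth = 0.08 if not depressed else 0.08 / (1.0 + cfg.mdd_strength)
    lfo = np.sin(2 * np.pi * rng.uniform(0.5, 2.0) * t
                 + rng.uniform(0, 2 * np.pi))
    f0 = prof.f0_hz * (1.0 + depth * lfo)
    phase = 2 * np.pi * np.cumsum(f0) / SAMPLE_RATE
    wave = np.zeros(n)
    for k in range(1, 9):       # harmonics up to ~2 kHz for low f0
        if prof.f0_hz * k > 4000:
            break
        wave += np.sin(k * phase) / k
    # speaker resonance: 2nd-order IIR peak at the speaker formant
    w0 = prof.formant_hz / (SAMPLE_RATE / 2)
    b, a = sp_signal.iirpeak(w0, Q=4.0)
    wave = sp_signal.lfilter(b, a, wave)
    # energy dynamics: slow amplitude modulation, compressed when depressed
    mod_depth = 0.5 if not depressed else 0.5 / (1.0 + cfg.mdd_strength)
    env = 1.0 + mod_depth * np.sin(2 * np.pi * rng.uniform(1.0, 3.0) * t
                                   + rng.uniform(0, 2 * np.pi))
    wave = wave * env + cfg.noise_sd * 0.01 * rng.normal(size=n)
    wave = wave / (np.max(np.abs(wave)) + 1e-9) * 0.8
    return wave


def synth_waveforms(profiles: list[SpeakerProfile], cfg: SynthConfig,
                    out_dir: str | Path) -> pd.DataFrame:
    """Render per-segment WAV files (16 kHz, 16-bit PCM mono) + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 23)
    rows = []
    for prof in profiles:
        for k in range(cfg.segments_per_speaker):
            wave = _render_wave(prof, cfg, rng)
            pcm = np.clip(np.round(wave * 32767.0), -32768, 32767) \
                .astype(np.int16)
            uid = f"spk{prof.speaker_index:04d}_utt{k:04d}"
            path = out_dir / f"{uid}.wav"
            wavfile.write(path, SAMPLE_RATE, pcm)
            rows.append({"id": uid, "path": str(path),
                         "speaker_id": prof.speaker_index,
                         "split": "train", "label": prof.mdd_label})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# manifests and splits
# --------------------------------------------------------------------------

def assign_splits(records: pd.DataFrame, train_frac: float = 0.7,
                  val_frac: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Speaker-disjoint train/val/eval assignment, stratified by label.

    No speaker appears in more than one split; both classes are placed in
    train and eval whenever speaker counts permit.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    speakers = records[["speaker_id", "label"]].drop_duplicates("speaker_id")
    split_of: dict = {}
    for _, group in speakers.groupby("label"):
        ids = group["speaker_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        n_train = max(1, int(round(train_frac * len(ids))))
        n_val = int(round(val_frac * len(ids)))
        for i, sid in enumerate(ids):
            if i < n_train:
                split_of[sid] = "train"
            elif i < n_train + n_val:
                split_of[sid] = "val"
            else:
                split_of[sid] = "eval"
    out["split"] = out["speaker_id"].map(split_of)
    return out


_MANIFEST_COLS = ["id", "path", "speaker_id", "split", "label"]


def write_manifest(records: pd.DataFrame, path: str | Path) -> Path:
    """Write the corpus manifest CSV (id, path, speaker_id, split, label)."""
    if len(records) == 0:
        raise ValueError("empty manifest")
    missing = [c for c in _MANIFEST_COLS if c not in records.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    if records["id"].duplicated().any():
        dupes = records.loc[records["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate manifest ids: {dupes[:5]}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records[_MANIFEST_COLS].to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "path": str, "split": str})
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest at {path} missing columns {missing}")
    return df[_MANIFEST_COLS]
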