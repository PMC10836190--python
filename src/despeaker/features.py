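"""Feature extraction and segment preparation.

The mel front-end uses a Hann window of 1024 samples (64 ms at 16 kHz) and
a hop of 512 samples (32 ms); a 3.84 s clip therefore yields 120 frames
(the signal is right-padded so the frame count is floor(len/hop)).
Frame-level features are mean-variance normalized with statistics fitted
on the training pool only.

High-level feature kinds (prosodic 130-dim, SSL 512/768-dim) are consumed
as precomputed frame×dim arrays; this module only knows their segment
geometry and normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np

__all__ = [
    "FeatureKind", "FeatureConfig", "FeatureSegment", "NormStats",
    "hann_frames", "melspec", "mel_filterbank", "fit_norm_stats",
    "apply_norm", "segment_lengths", "crop_and_balance", "balance_segments",
]

log = logging.getLogger(__name__)

_SD_FLOOR = 1e-8
_LOG_FLOOR = 1e-10


class FeatureKind(str, Enum):
    MEL = "mel"
    RAW = "raw"
    PROSODIC130 = "prosodic130"
    SSL = "ssl"


@dataclass
class FeatureConfig:
    kind: FeatureKind = FeatureKind.MEL
    n_mels: int = 40
    win: int = 1024
    hop: int = 512
    segment_seconds: float = 3.84
    sample_rate: int = 16_000
    log_compress: bool = True       # power-scale selectable
    ssl_variant: str = "wavlm"      # wav2vec2 | contentvec | wavlm | whisper

    def __post_init__(self):
        self.kind = FeatureKind(self.kind)
        if not (self.win > self.hop > 0):
            raise ValueError("need win > hop > 0")
        if self.segment_seconds <= 0:
            raise ValueError("segment_seconds must be > 0")
        if self.n_mels not in (40, 80):
            raise ValueError("n_mels must be 40 or 80")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kind"] = self.kind.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**d)


@dataclass
class FeatureSegment:
    """A fixed-length frame×dim feature matrix with its labels."""

    data: np.ndarray
    speaker_index: int
    mdd_label: int
    source_utterance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("segment data must be 2-D (frames × dims)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment data contains non-finite entries")
        if self.mdd_label not in (0, 1):
            raise ValueError("mdd_label must be 0 or 1")

    @property
    def frames(self) -> int:
        return self.data.shape[0]

    @property
    def dims(self) -> int:
        return self.data.shape[1]


@dataclass
class NormStats:
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if np.any(self.sd <= 0):
            raise ValueError("sd must be positive (floored upstream)")


# --------------------------------------------------------------------------
# mel front-end
# --------------------------------------------------------------------------

def n_frames(n_samples: int, hop: int) -> int:
    return n_samples // hop


def hann_frames(wave: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Slice a waveform into Hann-windowed frames.

    The frame count is floor(len/hop); the waveform is right-padded with
    zeros so the final frames are defined. A 61 440-sample clip at
    win=1024, hop=512 gives exactly 120 frames.
    """
    wave = np.asarray(wave, dtype=np.float64)
    if wave.ndim != 1:
        raise ValueError("expected a mono sample vector")
    if len(wave) < win:
        raise ValueError(
            f"waveform ({len(wave)} samples) shorter than one window ({win})")
    frames = n_frames(len(wave), hop)
    needed = (frames - 1) * hop + win
    if needed > len(wave):
        wave = np.pad(wave, (0, needed - len(wave)))
    idx = np.arange(frames)[:, None] * hop + np.arange(win)
    window = np.hanning(win)
    return wave[idx] * window


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int,
                   fmin: float = 0.0, fmax: float | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank; returns (filters, centre frequencies)."""
    fmax = fmax or sample_rate / 2
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-9)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-9)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb, hz_pts[1:-1]


def melspec(wave: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Log-mel spectrogram, frames × n_mels."""
    framed = hann_frames(wave, cfg.win, cfg.hop)
    power = np.abs(np.fft.rfft(framed, axis=1)) ** 2
    fb, _ = mel_filterbank(cfg.n_mels, cfg.win, cfg.sample_rate)
    mel = power @ fb.T
    if cfg.log_compress:
        mel = np.log(np.maximum(mel, _LOG_FLOOR))
    return mel


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

def fit_norm_stats(segments: list[FeatureSegment]) -> NormStats:
    """Global per-dimension mean/sd over the (training) segment pool."""
    if not segments:
        raise ValueError("cannot fit normalization on an empty pool")
    stacked = np.concatenate([s.data for s in segments], axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    if np.any(sd < _SD_FLOOR):
        log.warning("constant feature dimension(s) %s: sd floored at %g",
                    np.nonzero(sd < _SD_FLOOR)[0].tolist(), _SD_FLOOR)
        sd = np.maximum(sd, _SD_FLOOR)
    return NormStats(mean=mean, sd=sd)


def apply_norm(segment: FeatureSegment, stats: NormStats) -> FeatureSegment:
    return FeatureSegment(
        data=(segment.data - stats.mean) / stats.sd,
        speaker_index=segment.speaker_index,
        mdd_label=segment.mdd_label,
        source_utterance=segment.source_utterance)


# --------------------------------------------------------------------------
# segment geometry
# --------------------------------------------------------------------------

# printed segment lengths for a 3.84 s clip
_SSL_FRAMES = {"wav2vec2": 200, "contentvec": 193, "wavlm": 193,
               "whisper": 193}


def segment_lengths(kind: FeatureKind | str,
                    ssl_variant: str = "wavlm") -> int:
    """Per-kind segment length (frames, or samples for raw audio)."""
    kind = FeatureKind(kind)
    if kind is FeatureKind.MEL:
        return 120
    if kind is FeatureKind.RAW:
        return 61_440
    if kind is FeatureKind.PROSODIC130:
        return 384          # 100 frames/s LLD rate
    if kind is FeatureKind.SSL:
        try:
            return _SSL_FRAMES[ssl_variant]
        except KeyError:
            raise ValueError(f"unknown SSL variant {ssl_variant!r}") from None
    raise ValueError(f"unknown feature kind {kind!r}")  # pragma: no cover


# --------------------------------------------------------------------------
# cropping and class balancing
# --------------------------------------------------------------------------

def balance_segments(segments: list[FeatureSegment],
                     rng: np.random.Generator) -> list[FeatureSegment]:
    """Equal depressed / non-depressed counts, sampled without replacement
    from the majority class (bounded by the minority class)."""
    pool = {0: [s for s in segments if s.mdd_label == 0],
            1: [s for s in segments if s.mdd_label == 1]}
    if not pool[0] or not pool[1]:
        raise ValueError("both classes must be present for balancing")
    n = min(len(pool[0]), len(pool[1]))
    out: list[FeatureSegment] = []
    for lab in (0, 1):
        picks = rng.permutation(len(pool[lab]))[:n]
        out.extend(pool[lab][i] for i in sorted(picks))
    return out


def _chop(data: np.ndarray, seg_len: int) -> list[np.ndarray]:
    return [data[i * seg_len:(i + 1) * seg_len]
            for i in range(data.shape[0] // seg_len)]


def crop_and_balance(utterances: list[FeatureSegment], seg_len: int,
                     n_subsets: int, seed: int,
                     crop: bool = True) -> list[list[FeatureSegment]]:
    """Build class-balanced training subsets of fixed-length segments.

    With ``crop=True`` every utterance is first randomly cropped to the
    length of the shortest utterance, then chopped into ``seg_len`` pieces;
    each subset draws, without replacement, an equal number of depressed
    and non-depressed segments (bounded by the minority class). With
    ``crop=False`` utterances are chopped from the start without cropping
    or sub-sampling and a single subset containing everything is returned
    per requested subset.
    """
    if not utterances:
        raise ValueError("no utterances")
    labels = {u.mdd_label for u in utterances}
    if labels != {0, 1}:
        raise ValueError("both classes must be present for balancing")
    rng = np.random.default_rng(seed)
    if crop:
        shortest = min(u.frames for u in utterances)
        if shortest < seg_len:
            raise ValueError("shortest utterance is below one segment length")
        subsets = []
        for _ in range(n_subsets):
            pool: dict[int, list[FeatureSegment]] = {0: [], 1: []}
            for u in utterances:
                start = rng.integers(0, u.frames - shortest + 1)
                for j, piece in enumerate(_chop(u.data[start:start + shortest],
                                                seg_len)):
                    pool[u.mdd_label].append(FeatureSegment(
                        data=piece, speaker_index=u.speaker_index,
                        mdd_label=u.mdd_label,
                        source_utterance=f"{u.source_utterance}#{j}"))
            n_take = min(len(pool[0]), len(pool[1]))
            subset = []
            for lab in (0, 1):
                picks = rng.permutation(len(pool[lab]))[:n_take]
                subset.extend(pool[lab][i] for i in sorted(picks))
            subsets.append(subset)
        return subsets
    # no-crop mode: deterministic chopping, no balancing subsampling
    segs = []
    for u in utterances:
        for j, piece in enumerate(_chop(u.data, seg_len)):
            segs.append(FeatureSegment(
                data=piece, speaker_index=u.speaker_index,
                mdd_label=u.mdd_label,
                source_utterance=f"{u.source_utterance}#{j}"))
    return [list(segs) for _ in range(n_subsets)]
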