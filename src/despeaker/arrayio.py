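"""Feature-array container: one ``.npy`` file per utterance plus a JSON
sidecar index.

Layout of a feature directory::

    features/
      index.json            # [{id, file, speaker_id, split, label}, ...]
      <utterance-id>.npy    # float64 frames × dims array

The index round-trips through :func:`save_feature_set` /
:func:`load_feature_set` losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .features import FeatureSegment

__all__ = ["save_feature_set", "load_feature_set"]

_INDEX = "index.json"


def save_feature_set(segments: list[FeatureSegment],
                     out_dir: str | Path,
                     splits: dict[int, str] | None = None) -> Path:
    """Write segments as one array file each plus the sidecar index."""
    if not segments:
        raise ValueError("nothing to save")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = []
    seen: set[str] = set()
    for seg in segments:
        uid = seg.source_utterance
        if not uid or uid in seen:
            raise ValueError(f"missing or duplicate utterance id {uid!r}")
        seen.add(uid)
        fname = f"{uid}.npy"
        np.save(out_dir / fname, seg.data)
        index.append({
            "id": uid, "file": fname,
            "speaker_id": int(seg.speaker_index),
            "split": (splits or {}).get(seg.speaker_index, "train"),
            "label": int(seg.mdd_label)})
    (out_dir / _INDEX).write_text(json.dumps(index, indent=1))
    return out_dir


def load_feature_set(in_dir: str | Path,
                     split: str | None = None) -> list[FeatureSegment]:
    """Read a feature directory back; optionally filter by split."""
    in_dir = Path(in_dir)
    index_path = in_dir / _INDEX
    if not index_path.exists():
        raise FileNotFoundError(f"no {_INDEX} in {in_dir}")
    index = json.loads(index_path.read_text())
    segments = []
    for row in index:
        if split is not None and row["split"] != split:
            continue
        segments.append(FeatureSegment(
            data=np.load(in_dir / row["file"]),
            speaker_index=row["speaker_id"],
            mdd_label=row["label"],
            source_utterance=row["id"]))
    return segments
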