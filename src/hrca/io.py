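"""Reading and writing segments (4-channel float WAV) and cohort manifests (CSV).

One WAV file per segment, named ``<participant>_<material>_<index>.wav``,
float32 samples with the sampling rate in the WAV header.  The manifest CSV
carries 0-based half-open sample indices.
"""

from __future__ import annotations

import os
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile

from hrca.core import CHANNELS, SwallowSegment

MANIFEST_COLUMNS = [
    "participant_id",
    "material",
    "file",
    "onset_sample",
    "offset_sample",
    "true_onset_sample",
    "true_offset_sample",
    "fs",
]


def segment_filename(segment: SwallowSegment) -> str:
    return f"{segment.participant_id}_{segment.material}_{segment.swallow_index}.wav"


def save_segment(segment: SwallowSegment, path: str) -> None:
    """Write a segment as 4-channel float32 WAV (channel order MIC, AP, SI, ML)."""
    data = np.column_stack([segment.channels[c] for c in CHANNELS]).astype(np.float32)
    wavfile.write(path, int(segment.fs), data)


def load_segment(path: str, row: pd.Series) -> SwallowSegment:
    """Load one segment WAV described by a manifest row."""
    fs, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != len(CHANNELS):
        raise ValueError(f"{path}: expected {len(CHANNELS)}-channel WAV, got shape {data.shape}")
    channels = {c: data[:, i].astype(np.float64) for i, c in enumerate(CHANNELS)}
    return SwallowSegment(
        participant_id=str(row["participant_id"]),
        material=str(row["material"]),
        channels=channels,
        fs=float(fs),
        onset_sample=int(row["onset_sample"]),
        offset_sample=int(row["offset_sample"]),
        true_onset_sample=_opt_int(row.get("true_onset_sample")),
        true_offset_sample=_opt_int(row.get("true_offset_sample")),
        swallow_index=int(str(os.path.basename(path)).rsplit("_", 1)[-1].split(".")[0]),
    )


def _opt_int(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return int(value)


def save_cohort(
    segments: List[SwallowSegment], manifest: pd.DataFrame, out_dir: str
) -> str:
    """Write all segment WAVs plus ``manifest.csv`` into ``out_dir``.

    Returns the manifest path.
    """
    os.makedirs(out_dir, exist_ok=True)
    for seg in segments:
        save_segment(seg, os.path.join(out_dir, segment_filename(seg)))
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_cohort(manifest_path: str) -> Tuple[List[SwallowSegment], pd.DataFrame]:
    """Load every segment referenced by a manifest CSV."""
    manifest = pd.read_csv(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    segments = [
        load_segment(os.path.join(base, row["file"]), row) for _, row in manifest.iterrows()
    ]
    return segments, manifest
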