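"""File formats: WAV waveforms, TIFF speckle videos, JSON/CSV artifacts.

Videos are stored as multi-page grayscale TIFF plus a JSON sidecar holding
the frame rate, bit depth, rendering configuration and (for synthetic
videos) the exact ground-truth shift sequence; a raw little-endian binary
stack is supported as a faster alternative. Waveforms go to standard WAV
(float32 or PCM-16); subject profiles and evaluation reports serialize to
JSON, feature matrices to CSV with path labels as the header.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.io import wavfile

from .heartsound import SubjectProfile
from .identify import EvaluationReport
from .signals import Waveform
from .speckle import SpeckleVideo, SpeckleVideoConfig


# -- waveforms --------------------------------------------------------------

def write_wav(path, wave: Waveform, pcm16: bool = False) -> None:
    """Write a waveform as float32 (default) or PCM-16 WAV."""
    path = Path(path)
    if pcm16:
        peak = np.max(np.abs(wave.samples)) or 1.0
        data = np.round(wave.samples / peak * 32767).astype(np.int16)
    else:
        data = wave.samples.astype(np.float32)
    wavfile.write(path, int(round(wave.fs)), data)


def read_wav(path) -> Waveform:
    """Read a WAV file; integer formats are rescaled to [-1, 1]."""
    fs, data = wavfile.read(Path(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return Waveform(samples=np.asarray(data, dtype=np.float64), fs=float(fs))


# -- speckle videos ---------------------------------------------------------

def _sidecar_path(video_path: Path) -> Path:
    return video_path.with_suffix(video_path.suffix + ".json")


def write_video(path, video: SpeckleVideo) -> None:
    """Write a video as multi-page TIFF (or .raw binary) + JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, video.frames, photometric="minisblack")
    elif path.suffix.lower() == ".raw":
        video.frames.tofile(path)
    else:
        raise ValueError(f"unsupported video container: {path.suffix}")
    meta = {
        "config": asdict(video.config),
        "shape": list(video.frames.shape),
        "dtype": str(video.frames.dtype),
        "truth_shifts": None if video.truth_shifts is None
        else np.asarray(video.truth_shifts).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_video(path) -> SpeckleVideo:
    """Read a video written by :func:`write_video`."""
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    config = SpeckleVideoConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in meta["config"].items()})
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    else:
        frames = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(
            meta["shape"])
    shifts = meta.get("truth_shifts")
    return SpeckleVideo(
        frames=frames, config=config,
        truth_shifts=None if shifts is None else np.asarray(shifts, float))


# -- profiles, features, reports -------------------------------------------

def write_profiles(path, profiles: Sequence[SubjectProfile]) -> None:
    Path(path).write_text(json.dumps(
        {"profiles": [p.to_dict() for p in profiles]}, indent=1))


def read_profiles(path) -> list[SubjectProfile]:
    data = json.loads(Path(path).read_text())
    return [SubjectProfile.from_dict(d) for d in data["profiles"]]


def write_features(path, features: np.ndarray, path_labels,
                   labels: Optional[Sequence] = None) -> None:
    """Feature matrix as CSV (header encodes each scattering path), or as
    a compact binary .npy matrix when the path ends in .npy."""
    if str(path).endswith(".npy"):
        np.save(path, np.asarray(features))
        return
    cols = ["|".join(f"{f:g}" for f in p) or "order0" for p in path_labels]
    df = pd.DataFrame(np.asarray(features), columns=cols)
    if labels is not None:
        df.insert(0, "label", list(labels))
    df.to_csv(path, index=False)


def read_features(path) -> tuple[np.ndarray, Optional[np.ndarray]]:
    df = pd.read_csv(path)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy()
    return df.to_numpy(dtype=np.float64), labels


def write_segments(directory, segments: Sequence[Waveform], subject_id: str,
                   session: str = "session1",
                   manifest_name: str = "manifest.csv") -> pd.DataFrame:
    """Write PCG segments as numbered WAV files plus a CSV manifest.

    The manifest (subject_id, session, segment_index, file) is appended to
    if it already exists, so several subjects/sessions can share one
    directory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seg in enumerate(segments):
        name = f"{subject_id}_{session}_{i:03d}.wav"
        write_wav(directory / name, seg)
        rows.append({"subject_id": subject_id, "session": session,
                     "segment_index": i, "file": name})
    manifest = pd.DataFrame(rows)
    target = directory / manifest_name
    if target.exists():
        manifest = pd.concat([pd.read_csv(target), manifest],
                             ignore_index=True)
    manifest.to_csv(target, index=False)
    return manifest


def write_report(path, report: EvaluationReport) -> None:
    """Evaluation report as JSON (plus the matrix as CSV next to it)."""
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1))
    pd.DataFrame(report.confusion_matrix,
                 index=list(report.labels),
                 columns=list(report.labels)).to_csv(
        path.with_suffix(".csv"))


def write_trace(path_wav, path_csv, trace) -> None:
    """Displacement trace: scalar as WAV, per-pair vectors as CSV."""
    write_wav(path_wav, trace.scalar)
    pd.DataFrame({"dx_px": trace.vectors[:, 0],
                  "dy_px": trace.vectors[:, 1],
                  "low_texture": trace.low_texture}).to_csv(
        path_csv, index=False)
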