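"""Plain-text I/O: recording CSV, run-length-encoded label sidecars, manifests.

Recording CSV has the header ``t,ax,ay,az`` with time in seconds (6
decimals) and accelerations in m/s^2. Label sidecars store per-sample
rest/tremor masks as run-length-encoded ``[value, count]`` pairs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import Recording

__all__ = [
    "rle_encode", "rle_decode", "write_recording_csv", "read_recording_csv",
    "write_labels_json", "read_labels_json", "write_manifest", "read_manifest",
    "load_cohort",
]


def rle_encode(track: np.ndarray) -> list:
    """[[value, run_length], ...] for an integer per-sample track."""
    track = np.asarray(track)
    if len(track) == 0:
        return []
    change = np.flatnonzero(np.diff(track)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(track)]))
    return [[int(track[s]), int(e - s)] for s, e in zip(starts, ends)]


def rle_decode(runs: list) -> np.ndarray:
    if not runs:
        return np.array([], dtype=np.int8)
    return np.concatenate([np.full(count, value, dtype=np.int8)
                           for value, count in runs])


def write_recording_csv(path: str | Path, recording: Recording) -> None:
    t = np.arange(recording.n_samples) / recording.sample_rate_hz
    df = pd.DataFrame({"t": t, "ax": recording.ax, "ay": recording.ay,
                       "az": recording.az})
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path: str | Path, subject_id: str | None = None,
                       visit_id: str | None = None,
                       labels_path: str | Path | None = None) -> Recording:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("t", "ax", "ay", "az"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(df) > 1:
        fs = 1.0 / float(np.median(np.diff(df["t"].to_numpy())))
    else:
        fs = 50.0
    rest = tremor = None
    if labels_path is not None:
        labels = read_labels_json(labels_path)
        rest, tremor = labels["rest"], labels["tremor"]
        fs = labels.get("sample_rate_hz", fs)
    if subject_id is None or visit_id is None:
        stem_parts = path.stem.split("_")
        subject_id = subject_id or "_".join(stem_parts[:2])
        visit_id = visit_id or "_".join(stem_parts[2:]) or "visit_01"
    return Recording(subject_id=subject_id, visit_id=visit_id,
                     ax=df["ax"].to_numpy(), ay=df["ay"].to_numpy(),
                     az=df["az"].to_numpy(), sample_rate_hz=round(fs, 6),
                     rest_labels=rest, tremor_labels=tremor)


def write_labels_json(path: str | Path, recording: Recording,
                      severity_class: int | None = None,
                      constancy_pct: float | None = None) -> None:
    obj = {
        "sample_rate_hz": recording.sample_rate_hz,
        "rest": rle_encode(recording.rest_labels) if recording.rest_labels is not None else None,
        "tremor": rle_encode(recording.tremor_labels) if recording.tremor_labels is not None else None,
        "severity_class": severity_class,
        "constancy_pct": constancy_pct,
    }
    Path(path).write_text(json.dumps(obj))


def read_labels_json(path: str | Path) -> dict:
    obj = json.loads(Path(path).read_text())
    return {
        "sample_rate_hz": obj.get("sample_rate_hz", 50.0),
        "rest": rle_decode(obj["rest"]) if obj.get("rest") is not None else None,
        "tremor": rle_decode(obj["tremor"]) if obj.get("tremor") is not None else None,
        "severity_class": obj.get("severity_class"),
        "constancy_pct": obj.get("constancy_pct"),
    }


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_cohort(dataset_dir: str | Path):
    """Read a simulated cohort directory back into Recording objects.

    Returns (manifest, list of (subject entry, visit entry, Recording)).
    """
    root = Path(dataset_dir)
    manifest = read_manifest(root / "manifest.json")
    out = []
    for subject in manifest["subjects"]:
        for visit in subject["visits"]:
            rec = read_recording_csv(
                root / visit["recording_csv"],
                subject_id=subject["subject_id"],
                visit_id=visit["visit_id"],
                labels_path=root / visit["labels_json"],
            )
            out.append((subject, visit, rec))
    return manifest, out
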