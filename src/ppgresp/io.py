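"""On-disk recording format: one CSV per channel plus a manifest JSON.

Each channel CSV has columns ``time_s,value``; the manifest lists the
subject id, the prescribed breathing rate, and every channel's file and
sampling rate.  Timestamps are seconds from recording start (sample 0
at t = 0).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import PhysioRecording, SignalChannel

__all__ = ["write_recording", "read_recording"]

_CHANNELS = ("ppg", "spo2", "pulse_rate", "rtv")


def write_recording(recording: PhysioRecording, directory: str | Path,
                    name: str | None = None) -> Path:
    """Write channel CSVs and a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if name is None:
        name = f"{recording.subject_id}_{recording.prescribed_rate_bpm:g}bpm"
    channels = []
    for ch_name in _CHANNELS:
        ch: SignalChannel = getattr(recording, ch_name)
        fname = f"{name}_{ch_name}.csv"
        pd.DataFrame({"time_s": ch.times, "value": ch.samples}).to_csv(
            directory / fname, index=False, float_format="%.12g")
        channels.append({"name": ch_name, "file": fname, "rate_hz": ch.rate_hz})
    manifest = {
        "subject_id": recording.subject_id,
        "prescribed_rate_bpm": recording.prescribed_rate_bpm,
        "channels": channels,
    }
    manifest_path = directory / f"{name}.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_recording(manifest_path: str | Path) -> PhysioRecording:
    """Load a recording written by :func:`write_recording`.

    Validates that every channel file exists, that its time column is
    strictly monotone, and that the declared rate matches the
    timestamps.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    loaded: dict[str, SignalChannel] = {}
    for entry in manifest["channels"]:
        path = manifest_path.parent / entry["file"]
        if not path.exists():
            raise FileNotFoundError(
                f"channel {entry['name']!r}: missing file {path}")
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError(
                    f"channel {entry['name']!r}: time column is not "
                    "strictly increasing")
            declared = float(entry["rate_hz"])
            if abs(np.median(dt) - 1.0 / declared) > 1e-4 / declared:
                raise ValueError(
                    f"channel {entry['name']!r}: timestamps disagree with "
                    f"declared rate {declared} Hz")
        loaded[entry["name"]] = SignalChannel(df["value"].to_numpy(float),
                                              float(entry["rate_hz"]))
    return PhysioRecording(
        ppg=loaded["ppg"], spo2=loaded["spo2"],
        pulse_rate=loaded["pulse_rate"], rtv=loaded["rtv"],
        subject_id=str(manifest["subject_id"]),
        prescribed_rate_bpm=float(manifest["prescribed_rate_bpm"]),
    )
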