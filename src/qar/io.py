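"""On-disk formats: the raw recording container, CSV tables, configs.

A recording is stored as a directory holding a JSON sidecar
(``recording.json``) plus one raw little-endian float32 matrix per sensor
(``<sensor_id>.f32``, row-major n_frames x n_bins).  The sidecar's shape
fields must match the byte counts exactly; any disagreement is treated as
corruption.  Raw-plus-sidecar keeps the container transparent and
readable with nothing but a text editor and ``numpy.fromfile``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, CorruptFileError, FormatError
from .synthetic import RadarRecording

FORMAT_VERSION = 1
SIDECAR_NAME = "recording.json"

__all__ = [
    "PipelineConfig",
    "write_recording",
    "read_recording",
    "write_curves_csv",
    "read_curves_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_totals_csv",
]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the processing + analysis stages.

    Round-trips losslessly through JSON (``to_file``/``from_file``).
    """

    alpha: float = 0.97
    threshold_multiplier: float = 3.0
    burn_in_frames: int = 100
    aggregation: str = "mean"
    n_resamples: int = 1000
    seed: int = 0
    dense_grid_size: int = 221

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError("alpha must lie in (0, 1]")
        if self.threshold_multiplier < 0:
            raise ConfigError("threshold_multiplier must be >= 0")
        if self.burn_in_frames < 0:
            raise ConfigError("burn_in_frames must be >= 0")
        if self.aggregation not in ("mean", "median"):
            raise ConfigError("aggregation must be 'mean' or 'median'")
        if self.n_resamples < 1:
            raise ConfigError("n_resamples must be >= 1")
        if self.dense_grid_size < 2:
            raise ConfigError("dense_grid_size must be >= 2")

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read pipeline config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def write_recording(recording: RadarRecording, path) -> Path:
    """Write a recording container; returns the directory written."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(recording.frames, dtype="<f4")
    meta = {
        "format_version": FORMAT_VERSION,
        "subject_id": recording.subject_id,
        "sensor_ids": list(recording.sensor_ids),
        "fps": recording.fps,
        "n_frames": int(frames.shape[1]),
        "n_bins": int(frames.shape[2]),
        "duration_minutes": recording.duration_minutes,
    }
    for i, sid in enumerate(recording.sensor_ids):
        frames[i].tofile(out / f"{sid}.f32")
    (out / SIDECAR_NAME).write_text(json.dumps(meta, indent=2) + "\n")
    return out


def read_recording(path) -> RadarRecording:
    """Read a recording container, validating shapes against byte counts."""
    root = Path(path)
    sidecar = root / SIDECAR_NAME
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {sidecar} is not valid JSON: {exc}") from exc
    required = ("format_version", "subject_id", "sensor_ids", "fps", "n_frames", "n_bins", "duration_minutes")
    for field in required:
        if field not in meta:
            raise FormatError(f"sidecar missing field {field!r}")
    n_frames, n_bins = int(meta["n_frames"]), int(meta["n_bins"])
    expected_bytes = n_frames * n_bins * 4
    mats = []
    for sid in meta["sensor_ids"]:
        f = root / f"{sid}.f32"
        if not f.exists():
            raise FormatError(f"missing sensor matrix {f}")
        actual = f.stat().st_size
        if actual != expected_bytes:
            raise CorruptFileError(
                f"{f}: expected {expected_bytes} bytes for n_frames={n_frames}"
                f" x n_bins={n_bins}, found {actual}"
            )
        mats.append(np.fromfile(f, dtype="<f4").reshape(n_frames, n_bins))
    return RadarRecording(
        frames=np.stack(mats),
        fps=float(meta["fps"]),
        sensor_ids=list(meta["sensor_ids"]),
        subject_id=str(meta["subject_id"]),
        duration_minutes=float(meta["duration_minutes"]),
    )


def write_curves_csv(minute_scores: dict, path) -> None:
    """Per-subject minute scores: columns subject_id, minute (1-based), qar_score."""
    rows = []
    for sid, scores in minute_scores.items():
        for m, s in enumerate(np.asarray(scores), start=1):
            rows.append({"subject_id": sid, "minute": m, "qar_score": float(s)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves_csv(path):
    """Read a curves CSV back into (matrix, subject_ids).

    Subjects are ordered by first appearance; every subject must have the
    same number of minutes.
    """
    df = pd.read_csv(path)
    for col in ("subject_id", "minute", "qar_score"):
        if col not in df.columns:
            raise FormatError(f"curves CSV missing column {col!r}")
    ids = list(dict.fromkeys(df["subject_id"]))
    lengths = df.groupby("subject_id", sort=False)["minute"].count()
    if lengths.nunique() != 1:
        raise FormatError("curves CSV has ragged subjects")
    mat = np.asarray(
        [df[df["subject_id"] == sid].sort_values("minute")["qar_score"].to_numpy() for sid in ids]
    )
    return mat, ids


def write_labels_csv(labels: dict, path) -> None:
    pd.DataFrame(
        [{"subject_id": k, "group": v} for k, v in labels.items()]
    ).to_csv(path, index=False)


def read_labels_csv(path) -> dict:
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise FormatError(f"labels CSV missing column {col!r}")
    return dict(zip(df["subject_id"].astype(str), df["group"].astype(str)))


def write_totals_csv(totals: dict, path) -> None:
    pd.DataFrame(
        [{"subject_id": k, "total_qar": float(v)} for k, v in totals.items()]
    ).to_csv(path, index=False)
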