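"""Per-frame and per-minute activity quantification (the QAR chain).

Given a raw frame stream x_i,n[k] per sensor i, the chain is:

1. Clutter removal (loop-back filter): the static background estimate is
   updated each frame, ``C_n = alpha*C_{n-1} + (1-alpha)*x_n``, and the
   residual is ``y_n = x_n - C_n``.  This acts as a high-pass filter in
   frame index, keeping only moving reflectors.
2. Envelope: the magnitude of the analytic signal
   ``A_n[k] = |y_n[k] + j*H[y_n][k]|`` (discrete Hilbert transform along
   range bins) demodulates the oscillatory pulse so that amplitude, not
   carrier phase, is compared between frames.
3. Movement detection: bin k moves at frame n iff
   ``|A_n[k] - A_{n-1}[k]| >= T_i``, where the threshold T_i is
   calibrated from an empty-room recording (mean + multiplier*SD of the
   pooled envelope differences).
4. Per-frame activity count Q_i[n] = number of moving bins; the first
   frame of a recording has no predecessor and is assigned Q_i[0] = 0.
5. Sensor fusion: QAR[n] = median over sensors of Q_i[n], robust to one
   sensor being masked by the subject's own body.
6. Minute aggregation: mean (optionally median) of QAR[n] over
   non-overlapping 60-second blocks; a 22-minute session yields exactly
   22 minute scores, and their sum is the subject's total activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert, lfilter

from .errors import CalibrationError, ConfigError, ContractError, ShapeError
from .synthetic import RadarRecording

__all__ = [
    "ClutterState",
    "ThresholdSet",
    "QARSeries",
    "subtract_background",
    "remove_clutter",
    "hilbert_envelope",
    "calibrate_threshold",
    "detect_movement",
    "frame_activity",
    "fuse_sensors",
    "aggregate_minutes",
    "total_activity",
    "process_recording",
]

DEFAULT_ALPHA = 0.97
DEFAULT_MULTIPLIER = 3.0
DEFAULT_BURN_IN = 100


@dataclass
class ClutterState:
    """Running clutter estimate for one sensor (one frame's worth of bins)."""

    alpha: float
    clutter: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must lie in [0, 1]")
        self.clutter = np.asarray(self.clutter, dtype=float)
        if not np.all(np.isfinite(self.clutter)):
            raise ConfigError("clutter state must be finite")


@dataclass
class ThresholdSet:
    """Calibrated per-sensor movement thresholds with provenance."""

    thresholds: np.ndarray
    n_frames_used: int
    multiplier: float
    burn_in: int
    rule: str = "mean_plus_multiplier_sd"

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(self.thresholds < 0):
            raise ConfigError("thresholds must be >= 0")

    @property
    def n_sensors(self) -> int:
        return self.thresholds.size


@dataclass
class QARSeries:
    """Per-frame and per-minute activity for one subject."""

    per_sensor_counts: np.ndarray  # (n_sensors, n_frames), counts[:, 0] == 0
    qar_per_frame: np.ndarray  # (n_frames,), across-sensor median
    minute_scores: np.ndarray
    total: float
    subject_id: str = ""
    fps: float = 0.0


def subtract_background(frame: np.ndarray, state: ClutterState):
    """One step of the clutter-removal recursion.

    The clutter estimate is updated first, then subtracted:
    ``C_n = alpha*C_{n-1} + (1-alpha)*x_n``; ``y_n = x_n - C_n``.
    Returns ``(residual, new_state)``; the input state is not mutated.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != state.clutter.shape:
        raise ShapeError(
            f"frame shape {frame.shape} != clutter shape {state.clutter.shape}"
        )
    clutter = state.alpha * state.clutter + (1.0 - state.alpha) * frame
    residual = frame - clutter
    return residual, ClutterState(alpha=state.alpha, clutter=clutter)


def remove_clutter(
    frames: np.ndarray, alpha: float, init: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized clutter removal over a whole (n_frames, n_bins) stream.

    Equivalent to iterating :func:`subtract_background` frame by frame
    (the recursion is a first-order IIR filter, evaluated with
    ``scipy.signal.lfilter``).  ``init`` is the clutter estimate before
    the first frame; by default the first frame itself, so the first
    residual reflects only the (1-alpha) leak.
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigError("pipeline alpha must lie in (0, 1]")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2:
        raise ShapeError("frames must be 2-D (n_frames, n_bins)")
    c0 = frames[0] if init is None else np.asarray(init, dtype=float)
    # C_n = alpha*C_{n-1} + (1-alpha)*x_n  <=>  IIR filter b=[1-a], a=[1,-a]
    zi = (alpha * c0)[None, :]
    clutter, _ = lfilter([1.0 - alpha], [1.0, -alpha], frames, axis=0, zi=zi)
    return frames - clutter


def hilbert_envelope(residual: np.ndarray) -> np.ndarray:
    """Envelope of the residual signal along range bins.

    ``A[k] = |y[k] + j*H[y][k]|`` with H the discrete Hilbert transform.
    Accepts one frame or a (n_frames, n_bins) stack (transform along the
    last axis).
    """
    y = np.asarray(residual, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("residual contains non-finite values")
    return np.abs(hilbert(y, axis=-1))


def calibrate_threshold(
    empty: RadarRecording,
    alpha: float = DEFAULT_ALPHA,
    multiplier: float = DEFAULT_MULTIPLIER,
    burn_in: int = DEFAULT_BURN_IN,
) -> ThresholdSet:
    """Per-sensor threshold from an empty-room recording.

    Runs clutter removal and the envelope over the empty recording and
    pools the absolute consecutive-frame envelope differences over all
    frames (after a burn-in that lets the clutter estimate converge) and
    all bins; ``T_i = mean + multiplier*SD`` of the pool.
    """
    if empty.n_frames < 2:
        raise CalibrationError("calibration needs at least 2 frames")
    if empty.n_frames - 1 <= burn_in:
        burn_in = max(0, empty.n_frames // 10)
    thresholds = np.empty(empty.n_sensors)
    for i in range(empty.n_sensors):
        env = hilbert_envelope(remove_clutter(empty.frames[i], alpha))
        diffs = np.abs(np.diff(env, axis=0))[burn_in:]
        pooled = diffs.ravel()
        thresholds[i] = pooled.mean() + multiplier * pooled.std(ddof=1)
    return ThresholdSet(
        thresholds=thresholds,
        n_frames_used=empty.n_frames,
        multiplier=multiplier,
        burn_in=burn_in,
    )


def detect_movement(a_n: np.ndarray, a_prev: np.ndarray, threshold: float) -> np.ndarray:
    """Binary movement mask: 1 where ``|A_n - A_prev| >= T`` (inclusive)."""
    a_n = np.asarray(a_n, dtype=float)
    a_prev = np.asarray(a_prev, dtype=float)
    if a_n.shape != a_prev.shape:
        raise ShapeError("envelope rows must have equal shape")
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    return (np.abs(a_n - a_prev) >= threshold).astype(np.uint8)


def frame_activity(mask: np.ndarray) -> int:
    """Number of moving bins in one frame's mask."""
    g = np.asarray(mask)
    if not np.isin(g, (0, 1)).all():
        raise ContractError("movement mask must be binary")
    return int(g.sum())


def fuse_sensors(counts: np.ndarray) -> np.ndarray:
    """Across-sensor median of per-frame counts.

    ``counts`` is (n_sensors, ...) ; even sensor counts give the midpoint
    of the middle pair, so fused values may be half-integers.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 0 or counts.shape[0] < 1:
        raise ShapeError("need at least one sensor")
    return np.median(counts, axis=0)


def aggregate_minutes(
    qar_per_frame: np.ndarray,
    fps: float,
    duration_minutes: float | None = None,
    mode: str = "mean",
) -> np.ndarray:
    """Per-minute scores from the per-frame QAR stream.

    Non-overlapping 60-second blocks of ``round(fps*60)`` frames; a
    trailing partial block is kept if it covers at least 30 seconds and
    dropped otherwise.  ``mode`` selects the within-block statistic:
    ``"mean"`` (default) or ``"median"``.
    """
    if mode not in ("mean", "median"):
        raise ConfigError(f"unknown aggregation mode {mode!r}")
    q = np.asarray(qar_per_frame, dtype=float)
    block = int(round(fps * 60.0))
    if q.size < block:
        raise ShapeError("recording shorter than one minute cannot be aggregated")
    stat = np.mean if mode == "mean" else np.median
    n_full = q.size // block
    scores = [stat(q[m * block : (m + 1) * block]) for m in range(n_full)]
    rem = q.size - n_full * block
    if rem >= block / 2:
        scores.append(stat(q[n_full * block :]))
    return np.asarray(scores)


def total_activity(minute_scores: np.ndarray) -> float:
    """Total activity: the sum of the per-minute scores."""
    s = np.asarray(minute_scores, dtype=float)
    if s.size == 0:
        raise ShapeError("minute_scores must be non-empty")
    return float(s.sum())


def process_recording(
    recording: RadarRecording,
    thresholds: ThresholdSet,
    alpha: float = DEFAULT_ALPHA,
    aggregation: str = "mean",
) -> QARSeries:
    """Run the full chain on one subject's recording.

    Pure function of its inputs: clutter removal, envelope, thresholded
    movement detection, per-frame counts (first frame = 0), median fusion
    across sensors, minute aggregation and the total.
    """
    if thresholds.n_sensors != recording.n_sensors:
        raise ConfigError(
            f"threshold set has {thresholds.n_sensors} sensors, "
            f"recording has {recording.n_sensors}"
        )
    n_frames = recording.n_frames
    counts = np.zeros((recording.n_sensors, n_frames), dtype=float)
    for i in range(recording.n_sensors):
        env = hilbert_envelope(remove_clutter(recording.frames[i], alpha))
        moving = np.abs(np.diff(env, axis=0)) >= thresholds.thresholds[i]
        counts[i, 1:] = moving.sum(axis=1)

    qar = fuse_sensors(counts)
    minute_scores = aggregate_minutes(
        qar, recording.fps, recording.duration_minutes, mode=aggregation
    )
    return QARSeries(
        per_sensor_counts=counts,
        qar_per_frame=qar,
        minute_scores=minute_scores,
        total=total_activity(minute_scores),
        subject_id=recording.subject_id,
        fps=recording.fps,
    )
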