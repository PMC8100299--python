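"""Synthetic multi-sensor impulse-radar recordings of moving subjects.

The generator emulates the measurement setting the pipeline is designed
for: four radially mounted impulse-radio ultra-wideband (IR-UWB) sensors
record a seated subject at 20 frames/s for 22 minutes.  Each received
frame is a vector over range (delay) bins,

    x_i,n[k] = sum_m a_m,i s[k - tau_m,i(n)] + N[k],

i.e. a pulse template ``s`` echoed along static clutter paths (walls,
furniture) and moving target paths, plus i.i.d. Gaussian receiver noise.
Subject movement is encoded as frame-to-frame jitter of the target path's
delay bin and amplitude, with jitter magnitude proportional to a latent
movement-intensity trajectory: more movement => larger consecutive-frame
signal changes, which is exactly what the downstream QAR score counts.

Two group profiles are built in.  Healthy controls (HC) keep a flat mean
intensity over the session; the ADHD profile keeps the same baseline up to
a changepoint (default minute 7) after which the mean rises linearly and
the between-/within-subject dispersion is inflated.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence.spawn``: the cohort seed spawns one child per
subject (in subject order, ADHD first) plus one for the empty-room
recording; each subject's child spawns one stream for the trajectory and
one per sensor.  Identical configs therefore give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, ShapeError

logger = logging.getLogger(__name__)

HC = "HC"
ADHD = "ADHD"

__all__ = [
    "HC",
    "ADHD",
    "RadarConfig",
    "SceneModel",
    "TrajectoryProfile",
    "CohortConfig",
    "RadarRecording",
    "Cohort",
    "make_pulse_template",
    "simulate_trajectory",
    "trajectory_mean",
    "simulate_recording",
    "simulate_empty_room",
    "simulate_cohort",
    "simulate_activity_curves",
    "default_scene",
    "hc_profile",
    "adhd_profile",
]


@dataclass(frozen=True)
class RadarConfig:
    """Geometry and front-end parameters of the simulated radar array.

    ``pulse_center_freq`` is the carrier of the impulse template in
    normalized cycles/bin; the real device's RF carrier is not modelled
    because the activity score only depends on frame-to-frame changes.
    """

    n_sensors: int = 4
    fps: float = 20.0
    n_bins: int = 128
    pulse_center_freq: float = 0.2
    pulse_width_bins: float = 3.0
    noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.n_sensors < 1:
            raise ConfigError("n_sensors must be >= 1")
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")
        if self.n_bins < 8:
            raise ConfigError("n_bins must be >= 8")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class SceneModel:
    """Static scene geometry per sensor.

    clutter_profiles : (n_sensors, n_bins) static background return.
    target_paths : per sensor, a list of (amplitude, base_delay_bin)
        moving-path terms; the delay jitters around base_delay_bin.
    delay_jitter_per_intensity : std-dev of per-frame delay jitter, in
        bins per unit movement intensity.
    amp_jitter_per_intensity : std-dev of per-frame relative amplitude
        jitter per unit movement intensity.
    """

    clutter_profiles: np.ndarray
    target_paths: tuple
    delay_jitter_per_intensity: float = 1.5
    amp_jitter_per_intensity: float = 0.2

    def __post_init__(self) -> None:
        c = np.asarray(self.clutter_profiles, dtype=float)
        if not np.all(np.isfinite(c)):
            raise ConfigError("clutter_profiles must be finite")
        n_bins = c.shape[1]
        for sensor_paths in self.target_paths:
            for amp, delay in sensor_paths:
                if not np.isfinite(amp):
                    raise ConfigError("path amplitudes must be finite")
                if not (0 <= delay < n_bins):
                    raise ConfigError(
                        f"path delay {delay} outside range bins [0, {n_bins})"
                    )


@dataclass(frozen=True)
class TrajectoryProfile:
    """Latent movement-intensity model for one group.

    The mean intensity is baseline_intensity before changepoint_minute and
    rises by trend_per_minute per minute afterwards.  Noise has two parts:
    a per-subject random offset (SD between_subject_sd) and a smooth
    within-session component built from independent per-minute Gaussian
    knots (SD within_noise_sd) interpolated linearly between minutes.
    After the changepoint both parts are multiplied by dispersion_scale.
    Intensities are clipped at zero (movement cannot be negative).
    """

    group: str = HC
    baseline_intensity: float = 1.0
    trend_per_minute: float = 0.0
    changepoint_minute: float = 7.0
    dispersion_scale: float = 1.0
    duration_minutes: float = 22.0
    between_subject_sd: float = 0.25
    within_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.duration_minutes <= 0:
            raise ConfigError("duration_minutes must be > 0")
        if not 0 <= self.changepoint_minute <= self.duration_minutes:
            raise ConfigError("changepoint_minute must lie in [0, duration]")
        if self.dispersion_scale < 0 or self.between_subject_sd < 0 or self.within_noise_sd < 0:
            raise ConfigError("noise scales must be >= 0")


def hc_profile(**overrides) -> TrajectoryProfile:
    """Flat healthy-control profile (stable movement over the session)."""
    return replace(TrajectoryProfile(group=HC), **overrides)


def adhd_profile(**overrides) -> TrajectoryProfile:
    """ADHD profile: mean rises slowly after minute 7 with doubled dispersion."""
    base = TrajectoryProfile(
        group=ADHD, trend_per_minute=0.06, dispersion_scale=2.0
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class CohortConfig:
    """Full generative configuration for a two-group study cohort.

    Defaults mirror the study design: 10 ADHD vs 15 HC subjects, 22-minute
    sessions, 4 sensors at 20 frames/s.
    """

    n_adhd: int = 10
    n_hc: int = 15
    adhd: TrajectoryProfile = field(default_factory=adhd_profile)
    hc: TrajectoryProfile = field(default_factory=hc_profile)
    radar: RadarConfig = field(default_factory=RadarConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adhd < 1 or self.n_hc < 1:
            raise ConfigError("group sizes must be >= 1")


@dataclass
class RadarRecording:
    """One subject's multi-sensor recording.

    frames : (n_sensors, n_frames, n_bins) float32 amplitudes.
    """

    frames: np.ndarray
    fps: float
    sensor_ids: list
    subject_id: str
    duration_minutes: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ShapeError("frames must be (n_sensors, n_frames, n_bins)")
        if len(self.sensor_ids) != self.frames.shape[0]:
            raise ShapeError("sensor_ids length must match frames")

    @property
    def n_sensors(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    @property
    def n_bins(self) -> int:
        return self.frames.shape[2]


@dataclass
class Cohort:
    """Simulated cohort bundle with retained ground truth."""

    recordings: list
    labels: list
    subject_ids: list
    truth_intensity: list  # per subject, per-frame latent intensity
    empty_room: RadarRecording
    config: CohortConfig


def n_frames_for(fps: float, duration_minutes: float) -> int:
    return int(round(fps * 60.0 * duration_minutes))


def make_pulse_template(radar: RadarConfig) -> np.ndarray:
    """Gaussian-modulated cosine impulse template in bin units.

    Zero-mean, odd length, peak magnitude normalized to 1.  The support is
    +/- 3 standard deviations of the Gaussian envelope.
    """
    w = float(radar.pulse_width_bins)
    if w < 1:
        raise ConfigError("pulse_width_bins must be >= 1")
    half = int(np.ceil(3.0 * w))
    k = np.arange(-half, half + 1, dtype=float)
    tpl = np.exp(-0.5 * (k / w) ** 2) * np.cos(2.0 * np.pi * radar.pulse_center_freq * k)
    tpl = tpl - tpl.mean()
    return tpl / np.max(np.abs(tpl))


def trajectory_mean(profile: TrajectoryProfile, t_minutes: np.ndarray) -> np.ndarray:
    """Piecewise-linear mean intensity at times ``t_minutes``."""
    t = np.asarray(t_minutes, dtype=float)
    return profile.baseline_intensity + profile.trend_per_minute * np.maximum(
        0.0, t - profile.changepoint_minute
    )


def _dispersion(profile: TrajectoryProfile, t_minutes: np.ndarray) -> np.ndarray:
    t = np.asarray(t_minutes, dtype=float)
    return np.where(t >= profile.changepoint_minute, profile.dispersion_scale, 1.0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trajectory(
    profile: TrajectoryProfile, fps: float, seed
) -> np.ndarray:
    """Per-frame latent movement-intensity series for one subject.

    The same seed always yields the identical series.  The noise knots are
    laid on integer minutes 0..duration and interpolated, so the series is
    smooth at the frame scale and its dispersion survives per-minute
    averaging downstream.
    """
    rng = _as_rng(seed)
    n = n_frames_for(fps, profile.duration_minutes)
    t = np.arange(n, dtype=float) / (fps * 60.0)  # minutes

    mean = trajectory_mean(profile, t)
    scale = _dispersion(profile, t)

    subject_offset = rng.normal(0.0, profile.between_subject_sd)
    knot_t = np.arange(0.0, np.ceil(profile.duration_minutes) + 1.0)
    knots = rng.normal(0.0, profile.within_noise_sd, size=knot_t.size)
    within = np.interp(t, knot_t, knots)

    intensity = mean + scale * (subject_offset + within)
    return np.maximum(intensity, 0.0)


def default_scene(radar: RadarConfig, seed) -> SceneModel:
    """Random but plausible static scene: smooth clutter plus one moving
    target path per sensor, placed at distinct delays mid-range."""
    rng = _as_rng(seed)
    # smooth clutter: low-pass filtered white noise, amplitude a few x pulse
    raw = rng.normal(0.0, 1.0, size=(radar.n_sensors, radar.n_bins + 16))
    kernel = np.hanning(17)
    kernel /= kernel.sum()
    clutter = np.empty((radar.n_sensors, radar.n_bins))
    for i in range(radar.n_sensors):
        clutter[i] = np.convolve(raw[i], kernel, mode="valid")[: radar.n_bins]
    clutter *= 3.0

    lo, hi = int(0.3 * radar.n_bins), int(0.7 * radar.n_bins)
    paths = []
    for _ in range(radar.n_sensors):
        amp = rng.uniform(0.8, 1.2)
        delay = int(rng.integers(lo, hi))
        paths.append(((amp, delay),))
    return SceneModel(clutter_profiles=clutter, target_paths=tuple(paths))


def _render_sensor_frames(
    template: np.ndarray,
    clutter: np.ndarray,
    paths,
    intensity: np.ndarray,
    scene: SceneModel,
    radar: RadarConfig,
    rng: np.random.Generator,
    subject_id: str,
) -> np.ndarray:
    """Render one sensor's (n_frames, n_bins) matrix."""
    n_frames = intensity.size
    n_bins = clutter.size
    frames = np.tile(clutter, (n_frames, 1))

    half = (template.size - 1) // 2
    offsets = np.arange(-half, half + 1)
    clipped = False
    for amp, base_delay in paths:
        jitter_sd = scene.delay_jitter_per_intensity * intensity
        delays = base_delay + np.rint(rng.normal(0.0, 1.0, n_frames) * jitter_sd)
        out_of_range = (delays < 0) | (delays >= n_bins)
        if np.any(out_of_range):
            clipped = True
            delays = np.clip(delays, 0, n_bins - 1)
        amp_jitter = scene.amp_jitter_per_intensity * intensity
        amps = amp * (1.0 + rng.normal(0.0, 1.0, n_frames) * amp_jitter)

        cols = delays[:, None].astype(int) + offsets[None, :]
        valid = (cols >= 0) & (cols < n_bins)
        rows = np.broadcast_to(np.arange(n_frames)[:, None], cols.shape)
        contrib = amps[:, None] * template[None, :]
        np.add.at(frames, (rows[valid], np.clip(cols, 0, n_bins - 1)[valid]), contrib[valid])
    if clipped:
        logger.warning("subject %s: target delay left the range window; clipped", subject_id)

    if radar.noise_sigma > 0:
        frames += rng.normal(0.0, radar.noise_sigma, frames.shape)
    return frames


def simulate_recording(
    scene: SceneModel,
    trajectory: np.ndarray,
    radar: RadarConfig,
    seed,
    subject_id: str = "S000",
) -> RadarRecording:
    """Render a full multi-sensor recording from a latent trajectory.

    Every sensor shares the trajectory but has its own clutter, path
    geometry and noise stream.
    """
    if scene.clutter_profiles.shape != (radar.n_sensors, radar.n_bins):
        raise ShapeError(
            "scene clutter shape "
            f"{scene.clutter_profiles.shape} != (n_sensors, n_bins) "
            f"({radar.n_sensors}, {radar.n_bins})"
        )
    trajectory = np.asarray(trajectory, dtype=float)
    template = make_pulse_template(radar)

    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seq.spawn(radar.n_sensors)
    mats = []
    for i in range(radar.n_sensors):
        rng = np.random.default_rng(children[i])
        mats.append(
            _render_sensor_frames(
                template,
                scene.clutter_profiles[i],
                scene.target_paths[i],
                trajectory,
                scene,
                radar,
                rng,
                subject_id,
            )
        )
    frames = np.stack(mats).astype(np.float32)
    duration = trajectory.size / (radar.fps * 60.0)
    return RadarRecording(
        frames=frames,
        fps=radar.fps,
        sensor_ids=[f"sensor_{i:02d}" for i in range(radar.n_sensors)],
        subject_id=subject_id,
        duration_minutes=duration,
    )


def simulate_empty_room(
    radar: RadarConfig, n_frames: int, seed, scene: SceneModel | None = None
) -> RadarRecording:
    """Recording of the room with nobody in it: clutter + noise only.

    Used to calibrate the movement-detection threshold.
    """
    if n_frames < 2:
        raise ConfigError("empty-room recording needs at least 2 frames")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    scene_seq, noise_seq = seq.spawn(2)
    if scene is None:
        scene = default_scene(radar, np.random.default_rng(scene_seq))
    rng = np.random.default_rng(noise_seq)
    frames = np.repeat(
        scene.clutter_profiles[:, None, :], n_frames, axis=1
    ).astype(float)
    if radar.noise_sigma > 0:
        frames += rng.normal(0.0, radar.noise_sigma, frames.shape)
    return RadarRecording(
        frames=frames.astype(np.float32),
        fps=radar.fps,
        sensor_ids=[f"sensor_{i:02d}" for i in range(radar.n_sensors)],
        subject_id="empty_room",
        duration_minutes=n_frames / (radar.fps * 60.0),
    )


def _cohort_seeds(config: CohortConfig):
    n = config.n_adhd + config.n_hc
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n + 1)
    return children[:n], children[n]


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Full radar-level cohort: ADHD subjects first, then HC.

    Retains each subject's latent intensity trajectory for
    parameter-recovery and end-to-end correlation tests, plus an
    empty-room recording (2 minutes) for threshold calibration.
    """
    subj_seeds, empty_seed = _cohort_seeds(config)
    profiles = [config.adhd] * config.n_adhd + [config.hc] * config.n_hc

    recordings, labels, subject_ids, truths = [], [], [], []
    for j, (profile, sseq) in enumerate(zip(profiles, subj_seeds)):
        traj_seq, scene_seq, render_seq = sseq.spawn(3)
        intensity = simulate_trajectory(
            profile, config.radar.fps, np.random.default_rng(traj_seq)
        )
        scene = default_scene(config.radar, np.random.default_rng(scene_seq))
        sid = f"S{j:03d}"
        rec = simulate_recording(
            scene, intensity, config.radar, render_seq, subject_id=sid
        )
        recordings.append(rec)
        labels.append(profile.group)
        subject_ids.append(sid)
        truths.append(intensity)

    empty = simulate_empty_room(
        config.radar, n_frames_for(config.radar.fps, 2.0), empty_seed
    )
    return Cohort(
        recordings=recordings,
        labels=labels,
        subject_ids=subject_ids,
        truth_intensity=truths,
        empty_room=empty,
        config=config,
    )


def simulate_activity_curves(config: CohortConfig):
    """Fast path: per-minute activity curves drawn directly from the
    trajectory model, skipping radar synthesis.

    Samples each subject's latent intensity at minutes t = 1..duration
    using the same noise model (and seed-splitting rule) as
    ``simulate_trajectory``.  Returns (curves, labels, subject_ids) with
    ``curves`` of shape (n_subjects, duration_minutes).  Intended for
    statistical-machinery experiments where the radar layer is irrelevant.
    """
    subj_seeds, _ = _cohort_seeds(config)
    profiles = [config.adhd] * config.n_adhd + [config.hc] * config.n_hc
    duration = int(round(profiles[0].duration_minutes))
    t = np.arange(1.0, duration + 1.0)

    curves, labels, ids = [], [], []
    for j, (profile, sseq) in enumerate(zip(profiles, subj_seeds)):
        traj_seq, _, _ = sseq.spawn(3)
        rng = np.random.default_rng(traj_seq)
        mean = trajectory_mean(profile, t)
        scale = _dispersion(profile, t)
        offset = rng.normal(0.0, profile.between_subject_sd)
        within = rng.normal(0.0, profile.within_noise_sd, size=t.size)
        curves.append(np.maximum(mean + scale * (offset + within), 0.0))
        labels.append(profile.group)
        ids.append(f"S{j:03d}")
    return np.asarray(curves), labels, ids
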