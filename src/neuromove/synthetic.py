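"""Synthetic multimodal sessions and cohorts with known ground truth.

Every generator emulates one acquisition stream of the study design --
paced reaching and circular steering blocks (20 s task / 20 s rest,
five 4 s-paced reaches per reaching block), 30 Hz skeleton tracking,
10 Hz dual-wavelength optical densities and 500 Hz 8-channel EEG -- and
records the injected parameters so that pipeline recovery can be tested
against ground truth.  Stroke-like subjects shift a configurable set of
metrics in the directions reported for chronic hemiparesis: more trunk
compensation and lower steering performance and hand velocity on the
paretic side, a larger task-evoked dHbO2 peak, and attenuated beta
desynchronization.  Effect magnitudes are configuration, not claims.

Recordings include a rest lead-in before the first task block (default
20 s) so that pre-onset baselines exist for every block; schedules start
at t = 0 with the first task interval and recordings start at negative
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from . import feeg
from .types import (
    BANDS,
    CONDITIONS,
    EEG_CHANNELS,
    EEG_HEMISPHERE,
    HANDS,
    TASKS,
    BlockSchedule,
    CircleGeometry,
    CursorTrace,
    EEGRecording,
    Interval,
    RawOptical,
    SkeletonTrace,
)
from .fnirs import extinction_matrix

__all__ = [
    "FNIRS_MONTAGE",
    "ReachProfile",
    "FnirsNoiseSpec",
    "SessionTruth",
    "Session",
    "Subject",
    "CohortConfig",
    "generate_block_schedule",
    "generate_reach_skeleton",
    "generate_steering_skeleton",
    "generate_steering_trace",
    "generate_fnirs",
    "fnirs_forward",
    "generate_eeg",
    "generate_cohort",
    "sample_metrics_cohort",
    "double_gamma_hrf",
]

#: default fNIRS montage: 4 channels per sensorimotor hemisphere
FNIRS_MONTAGE: dict[str, str] = {f"L{i}": "left" for i in range(1, 5)} | {
    f"R{i}": "right" for i in range(1, 5)
}


# ---------------------------------------------------------------------------
# block schedule
# ---------------------------------------------------------------------------

def generate_block_schedule(
    task: str,
    hand: str,
    condition: str | None,
    n_blocks: int,
    block_s: float = 20.0,
    rest_s: float = 20.0,
    cue_period_s: float = 4.0,
) -> BlockSchedule:
    """Alternating 20 s task / 20 s rest blocks starting at t = 0.

    Reaching blocks carry five movement cues at 4 s spacing ("go" 2 s,
    "stop" 2 s); steering blocks have no cues.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if hand not in HANDS:
        raise ValueError(f"unknown hand {hand!r}; expected one of {HANDS}")
    if task == "reach":
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    elif condition is not None:
        raise ValueError("steering task has no SAU/MAU condition")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    intervals: list[Interval] = []
    cues: list[float] = []
    t = 0.0
    for b in range(n_blocks):
        intervals.append(Interval(t, t + block_s, "task", b))
        if task == "reach":
            cues.extend(t + k * cue_period_s for k in range(int(block_s // cue_period_s)))
        t += block_s
        intervals.append(Interval(t, t + rest_s, "rest", b))
        t += rest_s
    return BlockSchedule(task, hand, condition, intervals, np.asarray(cues))


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

@dataclass
class ReachProfile:
    """Motion profile for a cued reach: injected amplitudes and geometry."""

    trunk_amp_deg: float = 10.0
    elbow_amp_deg: float = 55.0
    elbow_start_deg: float = 90.0
    shoulder_start_deg: float = 15.0
    shoulder_amp_deg: float = 65.0
    jitter_sd_mm: float = 3.0
    side: str = "right"
    trunk_mm: float = 500.0
    upper_arm_mm: float = 300.0
    forearm_mm: float = 260.0
    hand_mm: float = 80.0
    shoulder_halfwidth_mm: float = 180.0
    spine_base_y_mm: float = 900.0

    def validate(self) -> None:
        if not (0.0 <= self.trunk_amp_deg <= 90.0):
            raise ValueError("trunk amplitude must lie in [0, 90] degrees")
        if self.elbow_start_deg + self.elbow_amp_deg > 180.0 + 1e-9:
            raise ValueError("elbow extension beyond 180 degrees is non-physical")
        if min(self.trunk_mm, self.upper_arm_mm, self.forearm_mm) <= 0:
            raise ValueError("segment lengths must be positive")


def _sagittal(theta_rad: np.ndarray) -> np.ndarray:
    """Unit direction in the sagittal plane: 0 = straight down, pi/2 = anterior."""
    return np.stack(
        [np.zeros_like(theta_rad), -np.cos(theta_rad), np.sin(theta_rad)], axis=1
    )


def _reach_pose(profile: ReachProfile, w: np.ndarray) -> dict[str, np.ndarray]:
    """Forward kinematics for activation profile w(t) in [0, 1]."""
    p = profile
    alpha = np.radians(p.trunk_amp_deg * w)
    phi = np.radians(p.shoulder_start_deg + p.shoulder_amp_deg * w)
    elb = np.radians(p.elbow_start_deg + p.elbow_amp_deg * w)
    n = len(w)
    spine = np.tile([0.0, p.spine_base_y_mm, 0.0], (n, 1))
    trunk_dir = np.stack(
        [np.zeros(n), np.cos(alpha), np.sin(alpha)], axis=1
    )
    shoulder_center = spine + p.trunk_mm * trunk_dir
    off = np.array([p.shoulder_halfwidth_mm, 0.0, 0.0])
    acr_r = shoulder_center + off
    acr_l = shoulder_center - off
    acr = acr_r if p.side == "right" else acr_l
    upper_dir = _sagittal(phi)
    elbow = acr + p.upper_arm_mm * upper_dir
    fore_dir = _sagittal(phi + (np.pi - elb))
    wrist = elbow + p.forearm_mm * fore_dir
    hand = wrist + p.hand_mm * fore_dir
    return {
        "spine_base": spine,
        "shoulder_center": shoulder_center,
        "acromion_left": acr_l,
        "acromion_right": acr_r,
        "elbow": elbow,
        "wrist": wrist,
        "hand": hand,
    }


def _cue_activation(t: np.ndarray, cues: np.ndarray, cycle_s: float = 4.0) -> np.ndarray:
    """Smooth 0->1->0 activation over each 4 s cue cycle (peak at 2 s)."""
    w = np.zeros_like(t)
    for cue in cues:
        m = (t >= cue) & (t < cue + cycle_s)
        w[m] = np.sin(np.pi * (t[m] - cue) / cycle_s) ** 2
    return w


def generate_reach_skeleton(
    profile: ReachProfile,
    schedule: BlockSchedule,
    seed: int | np.random.Generator = 0,
    fs: float = 30.0,
) -> tuple[SkeletonTrace, dict[str, float]]:
    """Cued-reach joint positions at 30 Hz plus injected ground truth.

    Returns the trace and a dict with the injected angular ranges and the
    noise-free hand mean velocity over the outward (0-2 s) segments.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, schedule.duration, 1.0 / fs)
    w = _cue_activation(t, np.asarray(schedule.cues))
    joints = _reach_pose(profile, w)

    # noise-free mean outward-hand speed for ground truth
    speeds = []
    for cue in schedule.cues:
        m = (t >= cue) & (t <= cue + 2.0)
        if m.sum() >= 2:
            steps = np.linalg.norm(np.diff(joints["hand"][m], axis=0), axis=1)
            speeds.append(np.sum(steps) / (t[m][-1] - t[m][0]))
    truth = {
        "trunk_range_deg": profile.trunk_amp_deg,
        "elbow_range_deg": profile.elbow_amp_deg,
        "hand_velocity_mm_s": float(np.mean(speeds)) if speeds else np.nan,
    }
    if profile.jitter_sd_mm > 0:
        for name in joints:
            joints[name] = joints[name] + rng.normal(
                0.0, profile.jitter_sd_mm, joints[name].shape
            )
    return SkeletonTrace(t, joints, profile.side), truth


def generate_steering_skeleton(
    schedule: BlockSchedule,
    trunk_amp_deg: float,
    elbow_amp_deg: float,
    lap_rate: float,
    jitter_sd_mm: float = 3.0,
    side: str = "right",
    seed: int | np.random.Generator = 0,
    fs: float = 30.0,
) -> tuple[SkeletonTrace, dict[str, float]]:
    """Posture oscillations during steering: one trunk/elbow cycle per lap."""
    profile = ReachProfile(
        trunk_amp_deg=trunk_amp_deg,
        elbow_amp_deg=elbow_amp_deg,
        elbow_start_deg=100.0,
        shoulder_start_deg=30.0,
        shoulder_amp_deg=20.0,
        jitter_sd_mm=jitter_sd_mm,
        side=side,
    )
    profile.validate()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, schedule.duration, 1.0 / fs)
    w = np.zeros_like(t)
    for iv in schedule.task_intervals:
        m = (t >= iv.start) & (t < iv.stop)
        w[m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * lap_rate * (t[m] - iv.start)))
    joints = _reach_pose(profile, w)
    truth = {"trunk_range_deg": trunk_amp_deg, "elbow_range_deg": elbow_amp_deg}
    if jitter_sd_mm > 0:
        for name in joints:
            joints[name] = joints[name] + rng.normal(0.0, jitter_sd_mm, joints[name].shape)
    return SkeletonTrace(t, joints, side), truth


# ---------------------------------------------------------------------------
# steering cursor
# ---------------------------------------------------------------------------

def generate_steering_trace(
    lap_rate: float,
    radial_sd: float,
    geometry: CircleGeometry | None = None,
    duration: float = 20.0,
    seed: int | np.random.Generator = 0,
    fs: float = 60.0,
    t0: float = 0.0,
    start_angle_deg: float = 90.0,
) -> CursorTrace:
    """Clockwise cursor motion on the circle with Gaussian radial noise."""
    if lap_rate <= 0:
        raise ValueError("lap_rate must be positive")
    if radial_sd < 0:
        raise ValueError("radial_sd must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    geometry = geometry or CircleGeometry()
    rng = np.random.default_rng(seed)
    # endpoint included so the trace spans exactly `duration`
    t = np.linspace(0.0, duration, int(round(duration * fs)) + 1)
    theta = np.radians(start_angle_deg) - 2.0 * np.pi * lap_rate * t
    r = geometry.radius + (
        rng.normal(0.0, radial_sd, len(t)) if radial_sd > 0 else 0.0
    )
    return CursorTrace(
        time=t0 + t,
        x=geometry.cx + r * np.cos(theta),
        y=geometry.cy + r * np.sin(theta),
        geometry=geometry,
    )


def generate_session_cursor(
    schedule: BlockSchedule,
    lap_rate: float,
    radial_sd: float,
    geometry: CircleGeometry | None = None,
    seed: int | np.random.Generator = 0,
    fs: float = 60.0,
) -> CursorTrace:
    """Steering cursor covering each task block of a schedule."""
    rng = np.random.default_rng(seed)
    geometry = geometry or CircleGeometry()
    parts = [
        generate_steering_trace(
            lap_rate, radial_sd, geometry, iv.duration, rng, fs, t0=iv.start
        )
        for iv in schedule.task_intervals
    ]
    return CursorTrace(
        time=np.concatenate([p.time for p in parts]),
        x=np.concatenate([p.x for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# fNIRS
# ---------------------------------------------------------------------------

def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot 16 s)."""
    h = sp_stats.gamma.pdf(t, a=7.0) - sp_stats.gamma.pdf(t, a=17.0) / 6.0
    return h


@dataclass
class FnirsNoiseSpec:
    """Physiological + instrumental noise, amplitudes in micromolar.

    Cardiac (~1.1 Hz), respiration (~0.3 Hz) and Mayer waves (~0.095 Hz)
    are sinusoids with per-channel random phase; drift is linear with a
    random per-channel slope; white noise is i.i.d. per sample.
    """

    cardiac_um: float = 0.4
    cardiac_hz: float = 1.1
    resp_um: float = 0.3
    resp_hz: float = 0.3
    mayer_um: float = 0.1
    mayer_hz: float = 0.095
    drift_um: float = 0.5
    white_um: float = 0.15

    @classmethod
    def off(cls) -> "FnirsNoiseSpec":
        return cls(0.0, 1.1, 0.0, 0.3, 0.0, 0.095, 0.0, 0.0)


def _task_boxcar(t: np.ndarray, schedule: BlockSchedule) -> np.ndarray:
    box = np.zeros_like(t)
    for iv in schedule.task_intervals:
        box[(t >= iv.start) & (t < iv.stop)] = 1.0
    return box


def clean_hbo_response(
    t: np.ndarray, schedule: BlockSchedule, fs: float
) -> np.ndarray:
    """Unit-peak task-evoked dHbO2: boxcar convolved with the canonical HRF."""
    box = _task_boxcar(t, schedule)
    kernel = double_gamma_hrf(np.arange(0.0, 32.0, 1.0 / fs))
    resp = np.convolve(box, kernel)[: len(t)] / fs
    peak = np.max(np.abs(resp))
    return resp / peak if peak > 0 else resp


def fnirs_forward(
    hbo: np.ndarray,
    hbr: np.ndarray,
    distance_mm: float = 30.0,
    dpf: float = 6.0,
    wavelengths: tuple[float, float] = (760.0, 850.0),
) -> np.ndarray:
    """MBLL forward model: concentrations (uM) -> dOD, shape (..., 2)."""
    E = extinction_matrix(wavelengths)
    path_cm = (distance_mm / 10.0) * dpf
    conc = np.stack([hbo, hbr], axis=-1)
    return conc @ (E * path_cm).T


def generate_fnirs(
    schedule: BlockSchedule,
    hrf_amp: float | dict[str, float],
    noise: FnirsNoiseSpec | None = None,
    montage: dict[str, str] | None = None,
    seed: int | np.random.Generator = 0,
    fs: float = 10.0,
    lead_in_s: float = 20.0,
    hbr_ratio: float = -0.3,
    dpf: float = 6.0,
    distance_mm: float = 30.0,
) -> RawOptical:
    """Two-wavelength optical densities with an embedded evoked response.

    ``hrf_amp`` (uM) scales a unit-peak canonical response per channel;
    pass a dict for per-channel amplitudes.  ``noise=None`` disables all
    noise, making the forward model exactly invertible.
    """
    montage = dict(montage or FNIRS_MONTAGE)
    for ch, hemi in montage.items():
        if hemi not in ("left", "right"):
            raise ValueError(f"montage channel {ch!r} lacks a hemisphere label")
    channels = list(montage)
    if np.isscalar(hrf_amp):
        amps = {ch: float(hrf_amp) for ch in channels}
    else:
        amps = {ch: float(hrf_amp[ch]) for ch in channels}
    if any(a < 0 for a in amps.values()):
        raise ValueError("hrf_amp must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(-lead_in_s, schedule.duration, 1.0 / fs)
    base = clean_hbo_response(t, schedule, fs)
    n, nch = len(t), len(channels)
    hbo = np.empty((n, nch))
    hbr = np.empty((n, nch))
    for j, ch in enumerate(channels):
        hbo[:, j] = amps[ch] * base
        hbr[:, j] = hbr_ratio * amps[ch] * base
    if noise is not None:
        for j in range(nch):
            hbo[:, j] += _physio_noise(t, noise, rng, scale=1.0)
            hbr[:, j] += _physio_noise(t, noise, rng, scale=0.3)
    od = fnirs_forward(hbo, hbr, distance_mm, dpf)
    return RawOptical(
        time=t, od=od, channels=channels, hemispheres=montage,
        distance_mm=distance_mm,
    )


def _physio_noise(
    t: np.ndarray, spec: FnirsNoiseSpec, rng: np.random.Generator, scale: float
) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, freq in (
        (spec.cardiac_um, spec.cardiac_hz),
        (spec.resp_um, spec.resp_hz),
        (spec.mayer_um, spec.mayer_hz),
    ):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += amp * np.sin(2.0 * np.pi * freq * t + phase)
    span = t[-1] - t[0] if len(t) > 1 else 1.0
    out += rng.uniform(-spec.drift_um, spec.drift_um) * (t - t[0]) / span
    if spec.white_um > 0:
        out += rng.normal(0.0, spec.white_um, len(t))
    return scale * out


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def generate_eeg(
    schedule: BlockSchedule,
    erd_db: dict[str, float],
    ers_db: dict[str, float],
    montage: dict[str, str] | None = None,
    seed: int | np.random.Generator = 0,
    fs: float = 500.0,
    lead_in_s: float = 20.0,
    bands: dict[str, tuple[float, float]] | None = None,
    osc_uv: float = 10.0,
    background_uv: float = 3.0,
    hemi_scale: dict[str, float] | None = None,
) -> EEGRecording:
    """1/f background plus band-limited oscillators with ERD/ERS gains.

    Oscillator envelope power is multiplied by ``10**(erd/10)`` inside
    movement windows and ``10**(ers/10)`` inside post-movement windows,
    relative to rest.  ``hemi_scale`` optionally scales the dB deviations
    per hemisphere (e.g. weaker ipsilateral modulation).
    """
    bands = bands or BANDS
    for name, (lo, hi) in bands.items():
        if lo <= 0:
            raise ValueError(f"band {name!r} overlaps 0 Hz")
    for b in bands:
        if erd_db.get(b, 0.0) > 0:
            raise ValueError("ERD must be <= 0 dB")
        if ers_db.get(b, 0.0) < 0:
            raise ValueError("ERS must be >= 0 dB")
    montage = dict(montage or EEG_HEMISPHERE)
    channels = list(montage)
    hemi_scale = hemi_scale or {"left": 1.0, "right": 1.0}
    rng = np.random.default_rng(seed)
    t = np.arange(-lead_in_s, schedule.duration, 1.0 / fs)
    n = len(t)

    onsets = [iv.start for iv in schedule.task_intervals]
    mov_rel = feeg.movement_windows(schedule)
    post_rel = feeg.post_movement_windows(schedule)

    data = np.empty((n, len(channels)))
    for j, ch in enumerate(channels):
        x = background_uv * _pink_noise(n, fs, rng)
        scale = hemi_scale.get(montage[ch], 1.0)
        for b, (lo, hi) in bands.items():
            osc = _bandlimited_noise(n, fs, (lo, hi), rng)
            gain = _gain_profile(
                t, onsets, mov_rel, post_rel,
                erd_db.get(b, 0.0) * scale, ers_db.get(b, 0.0) * scale, fs,
            )
            x += osc_uv * osc * gain
        data[:, j] = x
    return EEGRecording(t, data, channels, montage)


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-power noise, flattened below 1 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / np.std(x)


def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    sos = sp_signal.butter(4, band, btype="band", fs=fs, output="sos")
    x = sp_signal.sosfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


def _gain_profile(
    t: np.ndarray,
    onsets: list[float],
    mov_rel: list[tuple[float, float]],
    post_rel: list[tuple[float, float]],
    erd_db: float,
    ers_db: float,
    fs: float,
    ramp_s: float = 0.1,
) -> np.ndarray:
    g = np.ones_like(t)
    for onset in onsets:
        for lo, hi in mov_rel:
            g[(t >= onset + lo) & (t < onset + hi)] = 10.0 ** (erd_db / 20.0)
        for lo, hi in post_rel:
            g[(t >= onset + lo) & (t < onset + hi)] = 10.0 ** (ers_db / 20.0)
    k = max(int(ramp_s * fs), 1)
    kernel = np.hanning(2 * k + 1)
    kernel /= kernel.sum()
    return np.convolve(g, kernel, mode="same")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SessionTruth:
    """Injected parameters for one session cell."""

    hrf_amp_um: dict[str, float] = field(default_factory=dict)  # hemisphere -> uM
    erd_db: dict[str, dict[str, float]] = field(default_factory=dict)  # band -> hemi -> dB
    ers_db: dict[str, dict[str, float]] = field(default_factory=dict)
    trunk_range_deg: float = np.nan
    elbow_range_deg: float = np.nan
    hand_velocity_mm_s: float = np.nan
    radial_sd_mm: float = np.nan
    lap_rate: float = np.nan


@dataclass
class Session:
    schedule: BlockSchedule
    skeleton: SkeletonTrace | None
    cursor: CursorTrace | None
    optical: RawOptical
    eeg: EEGRecording
    truth: SessionTruth


@dataclass
class Subject:
    subject_id: str
    group: str
    dominant_side: str  # all participants right-handed by design
    lesion_side: str | None
    clinical: dict[str, float]
    sessions: dict[tuple[str, str, str | None], Session] = field(default_factory=dict)

    def hand_side(self, hand: str) -> str:
        """Physical side of the moving hand for an analysis cell."""
        if self.group == "stroke":
            paretic = "left" if self.lesion_side == "right" else "right"
            return paretic if hand == "nondominant" else (
                "left" if paretic == "right" else "right"
            )
        return self.dominant_side if hand == "dominant" else (
            "left" if self.dominant_side == "right" else "right"
        )


def _default_group_effects() -> dict[str, tuple[float, float]]:
    """Stroke-like mean shifts (paretic-side unless noted) and between-subject SDs."""
    return {
        "trunk_flexion_deg": (8.0, 2.5),  # more trunk lean, paretic reaching/steering
        "elbow_extension_deg": (-10.0, 4.0),  # less spontaneous elbow use
        "lap_rate": (-0.10, 0.03),  # slower paretic steering
        "radial_sd_mm": (1.5, 0.5),  # noisier paretic path
        "hrf_amp_um": (0.4, 0.12),  # larger paretic-task dHbO2 peak
        "beta_erd_db": (1.5, 0.5),  # attenuated (less negative) beta ERD
        "alpha_ers_db": (1.0, 0.4),  # larger post-movement alpha rebound
    }


def _default_baselines() -> dict[str, float]:
    return {
        "trunk_amp_sau_deg": 10.0,
        "trunk_amp_mau_deg": 1.5,
        "elbow_amp_sau_deg": 55.0,
        "elbow_amp_mau_deg": 65.0,
        "steer_trunk_amp_deg": 3.0,
        "steer_elbow_amp_deg": 15.0,
        "lap_rate_dominant": 0.50,
        "lap_rate_nondominant": 0.45,
        "radial_sd_mm": 4.0,
        "hrf_amp_um": 0.8,
        "hemi_ipsi_factor": 0.65,  # ipsilateral / contralateral response ratio
        "alpha_erd_db": -2.5,
        "beta_erd_db": -4.0,
        "alpha_ers_db": 1.0,
        "beta_ers_db": 2.0,
        "eeg_hemi_ipsi_scale": 0.7,
        "between_sd_trunk_deg": 2.0,
        "between_sd_elbow_deg": 3.0,
        "between_sd_lap_rate": 0.04,
        "between_sd_radial_mm": 0.5,
        "between_sd_hrf_um": 0.12,
        "between_sd_erd_db": 0.5,
        "jitter_sd_mm": 3.0,
    }


@dataclass
class CohortConfig:
    """Study-design configuration for a synthetic cohort.

    Defaults mirror the acquisition design: 21 subjects per group, three
    blocks per task/hand/condition cell, 30/10/500 Hz sampling.
    ``group_effects`` holds the stroke-like (shift, between-subject SD)
    pairs; zeroing every shift makes the groups exchangeable.
    """

    n_per_group: int = 21
    seed: int = 0
    reach_blocks: int = 3
    steer_blocks: int = 3
    skeleton_fs: float = 30.0
    fnirs_fs: float = 10.0
    eeg_fs: float = 500.0
    group_effects: dict[str, tuple[float, float]] = field(
        default_factory=_default_group_effects
    )
    baselines: dict[str, float] = field(default_factory=_default_baselines)
    fnirs_noise: FnirsNoiseSpec = field(default_factory=FnirsNoiseSpec)
    lead_in_s: float = 20.0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for k, (shift, sd) in self.group_effects.items():
            if sd < 0:
                raise ValueError(f"group effect {k!r} has negative SD")
        for k in ("skeleton_fs", "fnirs_fs", "eeg_fs"):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be positive")
        if self.reach_blocks < 1 or self.steer_blocks < 1:
            raise ValueError("block counts must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _effect(cfg: CohortConfig, rng: np.random.Generator, key: str, scale: float) -> float:
    shift, sd = cfg.group_effects.get(key, (0.0, 0.0))
    if shift == 0.0 and sd == 0.0:
        return 0.0
    return shift * scale + rng.normal(0.0, sd)


def _draw_subject(
    cfg: CohortConfig, rng: np.random.Generator, group: str, idx: int
) -> tuple[Subject, dict]:
    b = cfg.baselines
    if group == "stroke":
        severity = rng.standard_normal()
        scale = max(0.2, 1.0 + 0.3 * severity)
        lesion = "right" if rng.random() < 0.5 else "left"
        clinical = {
            "FM_UE": float(np.clip(48.7 - 5.9 * severity, 15, 66)),
            "WMFT": float(np.clip(57.3 - 9.8 * severity, 0, 75)),
            "BBT_ratio": float(np.clip(54.0 - 20.0 * severity, 5, 120)),
            "BI": float(np.clip(88.0 - 8.0 * severity, 20, 100)),
        }
    else:
        severity, scale, lesion, clinical = 0.0, 0.0, None, {}
    subject = Subject(
        subject_id=f"{group[0].upper()}{idx + 1:02d}",
        group=group,
        dominant_side="right",
        lesion_side=lesion,
        clinical=clinical,
    )
    # subject-level latent parameters; paretic-hand shifts applied per cell
    sd = lambda key: b[key]
    params = {
        "trunk_sau": {
            h: max(0.5, b["trunk_amp_sau_deg"] + rng.normal(0, sd("between_sd_trunk_deg"))
                   + (_effect(cfg, rng, "trunk_flexion_deg", scale) if h == "nondominant" else 0.0))
            for h in HANDS
        },
        "trunk_mau": {h: max(0.3, b["trunk_amp_mau_deg"] + rng.normal(0, 0.5)) for h in HANDS},
        "elbow_sau": {
            h: float(np.clip(
                b["elbow_amp_sau_deg"] + rng.normal(0, sd("between_sd_elbow_deg"))
                + (_effect(cfg, rng, "elbow_extension_deg", scale) if h == "nondominant" else 0.0),
                10.0, 88.0))
            for h in HANDS
        },
        "elbow_mau": {
            h: float(np.clip(b["elbow_amp_mau_deg"] + rng.normal(0, sd("between_sd_elbow_deg")), 10.0, 88.0))
            for h in HANDS
        },
        "steer_trunk": {
            h: max(0.5, b["steer_trunk_amp_deg"] + rng.normal(0, 1.0)
                   + (0.6 * _effect(cfg, rng, "trunk_flexion_deg", scale) if h == "nondominant" else 0.0))
            for h in HANDS
        },
        "steer_elbow": {
            h: float(np.clip(b["steer_elbow_amp_deg"] + rng.normal(0, 2.0)
                     + (0.4 * _effect(cfg, rng, "elbow_extension_deg", scale) if h == "nondominant" else 0.0),
                     3.0, 60.0))
            for h in HANDS
        },
        "lap_rate": {
            h: max(0.10, b[f"lap_rate_{h}"] + rng.normal(0, sd("between_sd_lap_rate"))
                   + (_effect(cfg, rng, "lap_rate", scale) if h == "nondominant" else 0.0))
            for h in HANDS
        },
        "radial_sd": {
            h: max(1.0, b["radial_sd_mm"] + rng.normal(0, sd("between_sd_radial_mm"))
                   + (_effect(cfg, rng, "radial_sd_mm", scale) if h == "nondominant" else 0.0))
            for h in HANDS
        },
        "hrf_amp": {
            h: max(0.05, b["hrf_amp_um"] + rng.normal(0, sd("between_sd_hrf_um"))
                   + (_effect(cfg, rng, "hrf_amp_um", scale) if h == "nondominant" else 0.0))
            for h in HANDS
        },
        "beta_erd": {
            h: min(-0.2, b["beta_erd_db"] + rng.normal(0, sd("between_sd_erd_db"))
                   + _effect(cfg, rng, "beta_erd_db", scale))
            for h in HANDS
        },
        "alpha_erd": {
            h: min(-0.2, b["alpha_erd_db"] + rng.normal(0, sd("between_sd_erd_db")))
            for h in HANDS
        },
        "beta_ers": {
            h: max(0.2, b["beta_ers_db"] + rng.normal(0, sd("between_sd_erd_db")))
            for h in HANDS
        },
        "alpha_ers": {
            h: max(0.2, b["alpha_ers_db"] + rng.normal(0, sd("between_sd_erd_db"))
                   + _effect(cfg, rng, "alpha_ers_db", scale))
            for h in HANDS
        },
    }
    return subject, params


def _session_for_cell(
    cfg: CohortConfig,
    subject: Subject,
    params: dict,
    task: str,
    hand: str,
    condition: str | None,
    rng: np.random.Generator,
) -> Session:
    b = cfg.baselines
    side = subject.hand_side(hand)
    n_blocks = cfg.reach_blocks if task == "reach" else cfg.steer_blocks
    schedule = generate_block_schedule(task, hand, condition, n_blocks)
    truth = SessionTruth()
    skeleton = cursor = None
    if task == "reach":
        suffix = "sau" if condition == "SAU" else "mau"
        profile = ReachProfile(
            trunk_amp_deg=params[f"trunk_{suffix}"][hand],
            elbow_amp_deg=params[f"elbow_{suffix}"][hand],
            jitter_sd_mm=b["jitter_sd_mm"],
            side=side,
        )
        skeleton, ktruth = generate_reach_skeleton(profile, schedule, rng, cfg.skeleton_fs)
        truth.trunk_range_deg = ktruth["trunk_range_deg"]
        truth.elbow_range_deg = ktruth["elbow_range_deg"]
        truth.hand_velocity_mm_s = ktruth["hand_velocity_mm_s"]
    else:
        lap_rate = params["lap_rate"][hand]
        radial_sd = params["radial_sd"][hand]
        cursor = generate_session_cursor(schedule, lap_rate, radial_sd, seed=rng)
        skeleton, ktruth = generate_steering_skeleton(
            schedule,
            params["steer_trunk"][hand],
            params["steer_elbow"][hand],
            lap_rate,
            jitter_sd_mm=b["jitter_sd_mm"],
            side=side,
            seed=rng,
            fs=cfg.skeleton_fs,
        )
        truth.trunk_range_deg = ktruth["trunk_range_deg"]
        truth.elbow_range_deg = ktruth["elbow_range_deg"]
        truth.radial_sd_mm = radial_sd
        truth.lap_rate = lap_rate

    # hemisphere-resolved brain truth: contralateral to the moving hand is
    # stronger; ipsilateral responses are scaled down
    contra = "left" if side == "right" else "right"
    ipsi = side
    amp = params["hrf_amp"][hand]
    hemi_amp = {contra: amp, ipsi: b["hemi_ipsi_factor"] * amp}
    truth.hrf_amp_um = hemi_amp
    ch_amp = {ch: hemi_amp[h] for ch, h in FNIRS_MONTAGE.items()}
    optical = generate_fnirs(
        schedule, ch_amp, cfg.fnirs_noise, FNIRS_MONTAGE, rng,
        fs=cfg.fnirs_fs, lead_in_s=cfg.lead_in_s,
    )

    erd = {"alpha": params["alpha_erd"][hand], "beta": params["beta_erd"][hand]}
    ers = {"alpha": params["alpha_ers"][hand], "beta": params["beta_ers"][hand]}
    s_ipsi = b["eeg_hemi_ipsi_scale"]
    hemi_scale = {contra: 1.0, ipsi: s_ipsi}
    truth.erd_db = {bn: {contra: v, ipsi: s_ipsi * v} for bn, v in erd.items()}
    truth.ers_db = {bn: {contra: v, ipsi: s_ipsi * v} for bn, v in ers.items()}
    eeg = generate_eeg(
        schedule, erd, ers, EEG_HEMISPHERE, rng,
        fs=cfg.eeg_fs, lead_in_s=cfg.lead_in_s, hemi_scale=hemi_scale,
    )
    return Session(schedule, skeleton, cursor, optical, eeg, truth)


def session_cells() -> list[tuple[str, str, str | None]]:
    """All task/hand/condition analysis cells of one session."""
    cells: list[tuple[str, str, str | None]] = []
    for hand in HANDS:
        for condition in CONDITIONS:
            cells.append(("reach", hand, condition))
        cells.append(("steer", hand, None))
    return cells


def generate_cohort(config: CohortConfig) -> tuple[list[Subject], pd.DataFrame]:
    """Full synthetic cohort: all subjects x cells, plus a ground-truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects: list[Subject] = []
    rows = []
    for group in ("healthy", "stroke"):
        for i in range(config.n_per_group):
            subject, params = _draw_subject(config, rng, group, i)
            for task, hand, condition in session_cells():
                sess = _session_for_cell(config, subject, params, task, hand, condition, rng)
                subject.sessions[(task, hand, condition)] = sess
                tr = sess.truth
                rows.append({
                    "subject": subject.subject_id,
                    "group": group,
                    "task": task,
                    "hand": hand,
                    "condition": condition,
                    "trunk_range_deg": tr.trunk_range_deg,
                    "elbow_range_deg": tr.elbow_range_deg,
                    "hand_velocity_mm_s": tr.hand_velocity_mm_s,
                    "radial_sd_mm": tr.radial_sd_mm,
                    "lap_rate": tr.lap_rate,
                    "hrf_amp_contra_um": tr.hrf_amp_um[
                        "left" if subject.hand_side(hand) == "right" else "right"
                    ],
                    "beta_erd_contra_db": tr.erd_db["beta"][
                        "left" if subject.hand_side(hand) == "right" else "right"
                    ],
                })
            subjects.append(subject)
    return subjects, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metric-level cohorts for statistical simulation
# ---------------------------------------------------------------------------

def sample_metrics_cohort(
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Subject-level steering metrics drawn from the cohort's generative model.

    Samples the same per-subject parameter distributions as
    :func:`generate_cohort` and maps them through the steering-law
    formulas plus small measurement noise, without synthesizing raw
    signals.  Used for repeated-cohort statistical studies (type-I error
    calibration, power) where thousands of full signal pipelines would
    be redundant: the pipeline's metric extraction is validated
    separately against ground truth.
    """
    from .kinematics import WE_FACTOR

    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    R0 = CircleGeometry().radius
    rows = []
    for group in ("healthy", "stroke"):
        for i in range(config.n_per_group):
            _, params = _draw_subject(config, rng, group, i)
            for hand in HANDS:
                lap = params["lap_rate"][hand] + rng.normal(0.0, 0.01)
                sig = params["radial_sd"][hand] * (1.0 + rng.normal(0.0, 0.03))
                we = WE_FACTOR * sig
                ide = 2.0 * np.pi * R0 / we
                rows.append({
                    "subject": f"{group[0].upper()}{i + 1:02d}",
                    "group": group,
                    "task": "steer",
                    "hand": hand,
                    "trunk_flexion": params["steer_trunk"][hand] + rng.normal(0.0, 0.8),
                    "ipe": ide * lap,
                    "speed": lap,
                    "mt": 1.0 / lap,
                    "hbo_peak": params["hrf_amp"][hand] + rng.normal(0.0, 0.08),
                    "beta_erd": params["beta_erd"][hand] + rng.normal(0.0, 0.3),
                })
    return pd.DataFrame(rows)
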