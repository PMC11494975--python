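"""Movement metrics for the paced reaching and circular steering tasks.

Reaching metrics quantify trunk compensation and arm use: the range of
anterior trunk flexion, the range of elbow extension, the hand mean
velocity, and the proximal-arm non-use (PANU) obtained by contrasting
spontaneous (SAU) and maximal, trunk-restrained (MAU) reaching.

Steering metrics implement the effective (post-hoc) form of the steering
law for a circular tunnel: the effective path width ``We = sqrt(2*pi*e) * sigma``
with ``sigma`` the SD of the radial position, the effective index of
difficulty ``IDe = 2*pi*R / We`` and the effective index of performance
``IPe = IDe / MT`` with ``MT`` the movement time per lap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import BlockSchedule, CursorTrace, SkeletonTrace

__all__ = [
    "ReachMetrics",
    "SteeringMetrics",
    "trunk_flexion_angle",
    "elbow_angle",
    "segment_reaches",
    "smooth_trace",
    "reach_metrics",
    "panu",
    "steering_metrics",
    "steering_metrics_blocks",
]

#: low-pass cutoff (Hz) for skeleton smoothing; paced reaching has a 0.25 Hz
#: movement cycle so everything informative sits well below 2 Hz
SKELETON_LOWPASS_HZ = 2.0

#: Crossman/MacKenzie constant linking radial SD to effective width
WE_FACTOR = float(np.sqrt(2.0 * np.pi * np.e))


@dataclass
class ReachMetrics:
    """Per-cell reaching summaries (averaged over segments, then blocks)."""

    trunk_flexion_range: float  # degrees
    elbow_extension_range: float  # degrees
    hand_mean_velocity: float  # mm/s
    arm_use: float  # % of forward hand displacement not due to the trunk
    n_segments: int


@dataclass
class SteeringMetrics:
    """Per-trial circular steering summaries.

    ``ide``/``ipe``/``mt`` are NaN when degenerate (zero radial SD or zero
    laps) rather than infinite.
    """

    R: float  # mean radius, mm
    sigma: float  # SD of radius, mm
    we: float  # effective width, mm
    ide: float  # bits
    mt: float  # s per lap
    ipe: float  # bits/s
    speed: float  # laps/s
    bias: float  # We / tunnel width
    error_rate: float  # fraction of samples outside the tunnel
    laps: float
    duration: float


# ---------------------------------------------------------------------------
# joint-angle operators
# ---------------------------------------------------------------------------

def trunk_flexion_angle(trace: SkeletonTrace) -> np.ndarray:
    """Anterior trunk-flexion angle (degrees) per frame.

    Angle of the spine-base -> shoulder-centre vector from the vertical,
    projected into the sagittal (vertical-anterior) plane.  0 deg is
    upright; positive values lean toward the target.  Frames with a
    degenerate (zero-length) trunk projection are returned as NaN.
    """
    v = trace.joints["shoulder_center"] - trace.joints["spine_base"]
    y, z = v[:, 1], v[:, 2]
    norm = np.hypot(y, z)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(z, y))
    ang[norm < 1e-9] = np.nan
    return ang


def elbow_angle(trace: SkeletonTrace) -> np.ndarray:
    """Interior elbow angle (degrees) per frame; 180 deg = full extension."""
    elbow = trace.joints["elbow"]
    u = trace.acromion - elbow
    w = trace.joints["wrist"] - elbow
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, w) / (nu * nw)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[(nu < 1e-9) | (nw < 1e-9)] = np.nan
    return ang


# ---------------------------------------------------------------------------
# segmentation & preprocessing
# ---------------------------------------------------------------------------

def segment_reaches(
    trace: SkeletonTrace, schedule: BlockSchedule, move_s: float = 2.0
) -> list[tuple[float, float]]:
    """One outward-movement window per vocal cue: [cue, cue + 2 s].

    Windows are clipped to their task interval and to the recording span;
    cues falling outside the recording are dropped with a warning.
    """
    t0, t1 = float(trace.time[0]), float(trace.time[-1])
    segments: list[tuple[float, float]] = []
    for cue in np.asarray(schedule.cues, dtype=float):
        start, stop = cue, cue + move_s
        for iv in schedule.task_intervals:
            if iv.start <= cue < iv.stop:
                stop = min(stop, iv.stop)
                break
        if start < t0 or start >= t1:
            warnings.warn(f"cue at {cue:.2f}s outside recording span; dropped")
            continue
        if stop > t1:
            warnings.warn(f"segment at {cue:.2f}s clipped to recording end")
            stop = t1
        if stop - start > 0:
            segments.append((start, stop))
    return segments


def smooth_trace(trace: SkeletonTrace, cutoff_hz: float = SKELETON_LOWPASS_HZ) -> SkeletonTrace:
    """Zero-phase 4th-order Butterworth low-pass of every joint trajectory.

    Short runs (<=3 frames) of missing joints are linearly interpolated
    first; longer gaps stay NaN and invalidate the frames they cover.
    """
    out = trace.copy()
    fs = 1.0 / float(np.median(np.diff(trace.time)))
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    for name, pos in out.joints.items():
        pos = _interpolate_short_gaps(trace.time, pos, max_gap=3)
        if not np.any(np.isnan(pos)):
            pos = signal.sosfiltfilt(sos, pos, axis=0)
        out.joints[name] = pos
    return out


def _interpolate_short_gaps(t: np.ndarray, pos: np.ndarray, max_gap: int) -> np.ndarray:
    pos = pos.copy()
    bad = np.any(np.isnan(pos), axis=1)
    if not bad.any():
        return pos
    # find runs of consecutive bad frames
    idx = np.flatnonzero(bad)
    runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    good = ~bad
    for run in runs:
        if len(run) <= max_gap and good.any():
            for k in range(3):
                pos[run, k] = np.interp(t[run], t[good], pos[good, k])
    return pos


# ---------------------------------------------------------------------------
# reaching metrics
# ---------------------------------------------------------------------------

def reach_metrics(
    trace: SkeletonTrace,
    schedule: BlockSchedule,
    smooth: bool = True,
) -> ReachMetrics:
    """Segment-wise reaching metrics, averaged over segments.

    Per outward segment: trunk-flexion range and elbow-extension range are
    max - min of the respective angle series, hand mean velocity is the
    mean frame-to-frame speed of the hand joint, and arm use (AU, %) is

        AU = 100 * (hand forward displacement - acromion forward displacement)
                 / hand forward displacement,

    forward displacements being the max - min of the anterior (z)
    coordinate within the segment.  Segments with non-positive hand
    forward displacement are excluded from AU.
    """
    segments = segment_reaches(trace, schedule)
    if not segments:
        raise ValueError("no valid movement segments in schedule/recording overlap")
    work = smooth_trace(trace) if smooth else trace
    trunk = trunk_flexion_angle(work)
    elbow = elbow_angle(work)
    hand = work.joints["hand"]
    acromion = work.acromion
    t = work.time

    trunk_ranges, elbow_ranges, velocities, arm_uses = [], [], [], []
    for start, stop in segments:
        m = (t >= start) & (t <= stop)
        if m.sum() < 2:
            continue
        tr, el = trunk[m], elbow[m]
        if np.all(np.isnan(tr)) or np.all(np.isnan(el)):
            continue
        trunk_ranges.append(np.nanmax(tr) - np.nanmin(tr))
        elbow_ranges.append(np.nanmax(el) - np.nanmin(el))
        steps = np.linalg.norm(np.diff(hand[m], axis=0), axis=1)
        dt = np.diff(t[m])
        velocities.append(float(np.sum(steps) / np.sum(dt)))
        hand_fwd = float(np.nanmax(hand[m, 2]) - np.nanmin(hand[m, 2]))
        acr_fwd = float(np.nanmax(acromion[m, 2]) - np.nanmin(acromion[m, 2]))
        if hand_fwd > 0:
            arm_uses.append(100.0 * (hand_fwd - acr_fwd) / hand_fwd)
    if not trunk_ranges:
        raise ValueError("all movement segments invalid for this trial")
    return ReachMetrics(
        trunk_flexion_range=float(np.mean(trunk_ranges)),
        elbow_extension_range=float(np.mean(elbow_ranges)),
        hand_mean_velocity=float(np.mean(velocities)),
        arm_use=float(np.mean(arm_uses)) if arm_uses else np.nan,
        n_segments=len(trunk_ranges),
    )


def posture_ranges(
    trace: SkeletonTrace, schedule: BlockSchedule, smooth: bool = True
) -> tuple[float, float]:
    """Trunk-flexion and elbow-extension ranges during task blocks.

    Used for the steering task, where compensation is summarized per
    20 s block (max - min of each angle series) and averaged across
    blocks.
    """
    work = smooth_trace(trace) if smooth else trace
    trunk = trunk_flexion_angle(work)
    elbow = elbow_angle(work)
    t = work.time
    trunk_r, elbow_r = [], []
    for iv in schedule.task_intervals:
        m = (t >= iv.start) & (t < iv.stop)
        if m.sum() < 2:
            continue
        trunk_r.append(np.nanmax(trunk[m]) - np.nanmin(trunk[m]))
        elbow_r.append(np.nanmax(elbow[m]) - np.nanmin(elbow[m]))
    if not trunk_r:
        raise ValueError("no usable task blocks for posture ranges")
    return float(np.mean(trunk_r)), float(np.mean(elbow_r))


def panu(sau: ReachMetrics, mau: ReachMetrics) -> float:
    """Proximal-arm non-use (%): arm use gained when trunk use is restrained.

    PANU = AU(MAU) - AU(SAU).  Negative values (less arm use when forced)
    are allowed and meaningful; callers may flag them.
    """
    return float(mau.arm_use - sau.arm_use)


# ---------------------------------------------------------------------------
# steering metrics
# ---------------------------------------------------------------------------

def steering_metrics(trace: CursorTrace, clockwise_negative: bool = True) -> SteeringMetrics:
    """Effective steering-law metrics for one task interval.

    Laps are counted from the unwrapped polar angle about the circle
    centre (fractional laps allowed); clockwise screen motion maps to a
    decreasing mathematical angle.  With ``sigma == 0`` the effective
    width is 0 and IDe/IPe are undefined (NaN); with zero laps MT is
    undefined.
    """
    if len(trace.time) < 2:
        raise ValueError("steering trace needs at least 2 samples")
    g = trace.geometry
    dx, dy = trace.x - g.cx, trace.y - g.cy
    r = np.hypot(dx, dy)
    theta = np.unwrap(np.arctan2(dy, dx))
    duration = float(trace.time[-1] - trace.time[0])
    R = float(np.mean(r))
    sigma = float(np.std(r, ddof=1))
    if sigma < 1e-9:  # sub-nanometre radial spread is numerically zero
        sigma = 0.0
    we = WE_FACTOR * sigma
    laps = float(np.abs(theta[-1] - theta[0]) / (2.0 * np.pi))
    speed = laps / duration
    mt = duration / laps if laps > 0 else np.nan
    ide = 2.0 * np.pi * R / we if we > 0 else np.nan
    ipe = ide / mt if we > 0 and laps > 0 else np.nan
    bias = we / g.tunnel_width
    error_rate = float(np.mean(np.abs(r - g.radius) > g.tunnel_width / 2.0))
    return SteeringMetrics(
        R=R, sigma=sigma, we=we, ide=ide, mt=mt, ipe=ipe,
        speed=speed, bias=bias, error_rate=error_rate,
        laps=laps, duration=duration,
    )


def steering_metrics_blocks(trace: CursorTrace, schedule: BlockSchedule) -> SteeringMetrics:
    """Steering metrics per task block, averaged across blocks."""
    per_block = []
    for iv in schedule.task_intervals:
        m = (trace.time >= iv.start) & (trace.time < iv.stop)
        if m.sum() < 2:
            warnings.warn(f"task block at {iv.start:.1f}s has <2 cursor samples; skipped")
            continue
        sub = CursorTrace(trace.time[m], trace.x[m], trace.y[m], trace.geometry)
        per_block.append(steering_metrics(sub))
    if not per_block:
        raise ValueError("no usable task blocks in cursor trace")
    mean = lambda xs: float(np.nanmean(xs)) if np.any(np.isfinite(xs)) else np.nan
    return SteeringMetrics(
        R=mean([b.R for b in per_block]),
        sigma=mean([b.sigma for b in per_block]),
        we=mean([b.we for b in per_block]),
        ide=mean([b.ide for b in per_block]),
        mt=mean([b.mt for b in per_block]),
        ipe=mean([b.ipe for b in per_block]),
        speed=mean([b.speed for b in per_block]),
        bias=mean([b.bias for b in per_block]),
        error_rate=mean([b.error_rate for b in per_block]),
        laps=float(np.sum([b.laps for b in per_block])),
        duration=float(np.sum([b.duration for b in per_block])),
    )
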