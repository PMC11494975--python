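"""Functional EEG: event-related spectral perturbations and ERD/ERS summaries.

Power is estimated with a sliding Hann short-time Fourier transform.  For
each task block an epoch around the block onset is cut from the
time-frequency plane, epochs are averaged in the power domain, and the
map is expressed in dB relative to the mean rest-period power per
frequency and channel:

    ERSP(t, f) = 10 * log10( mean_epochs P(t, f) / Pbar_rest(f) )

Averaging power before taking the log keeps the map unbiased (the log of
a noisy power estimate is biased low); with 20 epochs the residual bias
is about -0.1 dB.  Event-related desynchronization (ERD) is the mean dB
change over the movement window in a band (negative for a power drop),
event-related synchronization (ERS) the mean over the post-movement
window (positive for a rebound).  Only STFT frames whose full window
lies inside the target interval contribute, so boundary frames never mix
movement and rest power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .types import BANDS, BlockSchedule, EEGRecording, ERSPMap, hemisphere_roles

__all__ = [
    "EEGPreprocessParams",
    "ErspSpec",
    "BandSummary",
    "preprocess_eeg",
    "ersp",
    "band_erd_ers",
    "hemisphere_summary_eeg",
    "movement_windows",
    "post_movement_windows",
]


@dataclass
class EEGPreprocessParams:
    band_hz: tuple[float, float] = (1.0, 40.0)
    order: int = 4
    reference: str = "car"  # "car" | "none"


@dataclass
class ErspSpec:
    """Spectral-estimation choices for the ERSP."""

    window_s: float = 1.0
    overlap: float = 0.9
    fmin: float = 1.0
    fmax: float = 40.0
    pre_s: float = 5.0  # epoch span before task onset
    post_s: float = 24.0  # epoch span after task onset
    baseline_guard_s: float = 5.0  # rest skipped after task offset (ERS rebound)
    reject_uv: float = 100.0  # per-epoch absolute-amplitude rejection

    @property
    def hop_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)


@dataclass
class BandSummary:
    """Band ERD/ERS (dB) per channel; sign is not clamped."""

    erd: dict[str, dict[str, float]]  # band -> channel -> dB
    ers: dict[str, dict[str, float]]
    meta: dict = field(default_factory=dict)


def preprocess_eeg(
    rec: EEGRecording, params: EEGPreprocessParams | None = None
) -> EEGRecording:
    """Zero-phase band-pass plus optional common-average re-reference."""
    params = params or EEGPreprocessParams()
    sos = signal.butter(
        params.order, params.band_hz, btype="band", fs=rec.fs, output="sos"
    )
    data = signal.sosfiltfilt(sos, rec.data, axis=0)
    if params.reference == "car":
        data = data - data.mean(axis=1, keepdims=True)
    elif params.reference != "none":
        raise ValueError(f"unknown reference scheme {params.reference!r}")
    return EEGRecording(rec.time.copy(), data, list(rec.channels), dict(rec.hemispheres))


def movement_windows(schedule: BlockSchedule) -> list[tuple[float, float]]:
    """Movement windows relative to task-block onset.

    Reaching: 0-2 s after each paced cue (the "go" phase); steering: the
    whole 20 s block.
    """
    if schedule.task == "steer":
        iv = schedule.task_intervals[0]
        return [(0.0, iv.duration)]
    iv = schedule.task_intervals[0]
    rel = [c - iv.start for c in schedule.cues if iv.start <= c < iv.stop]
    return [(c, c + 2.0) for c in rel]


def post_movement_windows(schedule: BlockSchedule) -> list[tuple[float, float]]:
    """Post-movement (ERS) windows relative to task-block onset.

    Reaching: 2-4 s after each cue (the "stop" phase); steering: 0-4 s
    after the block offset.
    """
    if schedule.task == "steer":
        iv = schedule.task_intervals[0]
        return [(iv.duration, iv.duration + 4.0)]
    iv = schedule.task_intervals[0]
    rel = [c - iv.start for c in schedule.cues if iv.start <= c < iv.stop]
    return [(c + 2.0, c + 4.0) for c in rel]


def _rest_windows(rec: EEGRecording, schedule: BlockSchedule, guard: float) -> list[tuple[float, float]]:
    wins = []
    t0 = float(rec.time[0])
    first = min(iv.start for iv in schedule.intervals)
    if first - t0 > 2.0:
        wins.append((t0 + 1.0, first - 1.0))
    for iv in schedule.rest_intervals:
        lo, hi = iv.start + guard, iv.stop - 1.0
        if hi > lo:
            wins.append((lo, hi))
    return wins


def ersp(
    rec: EEGRecording,
    schedule: BlockSchedule,
    spec: ErspSpec | None = None,
) -> ERSPMap:
    """Epoch-averaged time-frequency power change (dB) vs rest baseline."""
    spec = spec or ErspSpec()
    fs = rec.fs
    nperseg = int(round(spec.window_s * fs))
    noverlap = int(round(spec.overlap * nperseg))
    hop = (nperseg - noverlap) / fs
    onsets = [iv.start for iv in schedule.task_intervals]
    if not onsets:
        raise ValueError("schedule contains no task blocks")
    epoch_len = spec.pre_s + spec.post_s
    if epoch_len <= spec.window_s:
        raise ValueError("STFT window longer than the epoch span")

    freqs, times, Pxx = signal.spectrogram(
        rec.data, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        axis=0, mode="psd", detrend=False,
    )
    # Pxx: (n_samples_axis collapsed) -> (n_freq, n_channels, n_frames)
    centers = rec.time[0] + times
    fmask = (freqs >= spec.fmin) & (freqs <= spec.fmax)
    freqs = freqs[fmask]
    P = Pxx[fmask]  # (n_f, n_ch, n_frames)

    # rest baseline: frames fully inside clean rest windows
    half = spec.window_s / 2.0
    base_mask = np.zeros(len(centers), dtype=bool)
    for lo, hi in _rest_windows(rec, schedule, spec.baseline_guard_s):
        base_mask |= (centers - half >= lo) & (centers + half <= hi)
    if not base_mask.any():
        raise ValueError("no STFT frames fall inside the rest baseline")
    baseline = P[:, :, base_mask].mean(axis=2)  # (n_f, n_ch)

    n_frames = int(np.floor((epoch_len - spec.window_s) / hop)) + 1
    used, kept_onsets = [], []
    for onset in onsets:
        start = onset - spec.pre_s
        i0 = int(np.argmin(np.abs(centers - (start + half))))
        if i0 + n_frames > len(centers) or centers[i0] < rec.time[0]:
            continue
        # per-epoch amplitude rejection on the raw samples of the epoch
        smask = (rec.time >= start) & (rec.time <= onset + spec.post_s)
        if np.max(np.abs(rec.data[smask])) > spec.reject_uv:
            continue
        used.append(P[:, :, i0 : i0 + n_frames])
        kept_onsets.append(onset)
    if not used:
        raise ValueError("no usable epochs for ERSP")
    if len(used) < 0.5 * len(onsets):
        raise ValueError(
            f"{len(onsets) - len(used)}/{len(onsets)} epochs rejected (>50%)"
        )
    meanP = np.mean(used, axis=0)  # (n_f, n_ch, n_frames)
    data = 10.0 * np.log10(meanP / baseline[:, :, None])
    rel_times = (np.arange(n_frames) * hop) + (half - spec.pre_s)
    return ERSPMap(
        times=rel_times,
        freqs=freqs,
        data=np.moveaxis(data, 1, 0),  # (n_ch, n_f, n_t)
        channels=list(rec.channels),
        hemispheres=dict(rec.hemispheres),
        n_epochs=len(used),
        power=np.moveaxis(meanP, 1, 0),
        baseline=baseline.T,
        meta={
            "window_s": spec.window_s,
            "overlap": spec.overlap,
            "baseline": "rest",
            "baseline_guard_s": spec.baseline_guard_s,
            "onsets_used": kept_onsets,
        },
    )


def _window_mean(
    emap: ERSPMap, windows: list[tuple[float, float]], band: tuple[float, float]
) -> np.ndarray:
    """Band/window dB change per channel.

    Power ratios (per-frequency baseline-normalized) are averaged over
    the window frames and band rows before the log, so the summary is
    unbiased even at small epoch counts.  Frames must lie fully inside a
    window so boundary frames never mix regimes, and frequency rows must
    lie a main-lobe width inside the band so leakage from neighbouring
    rhythms (e.g. the alpha peak bleeding into the lowest beta bin)
    never dilutes the band mean.
    """
    half = emap.meta.get("window_s", 1.0) / 2.0
    guard = 1.0 / emap.meta.get("window_s", 1.0)  # Hann main-lobe half-width
    tmask = np.zeros(len(emap.times), dtype=bool)
    for lo, hi in windows:
        tmask |= (emap.times - half >= lo) & (emap.times + half <= hi)
    fmask = (emap.freqs >= band[0] + guard) & (emap.freqs <= band[1] - guard)
    if not tmask.any() or not fmask.any():
        raise ValueError("empty time-frequency window for band summary")
    if emap.power is not None and emap.baseline is not None:
        ratio = emap.power / emap.baseline[:, :, None]
        return 10.0 * np.log10(ratio[:, fmask][:, :, tmask].mean(axis=(1, 2)))
    return emap.data[:, fmask][:, :, tmask].mean(axis=(1, 2))


def band_erd_ers(
    emap: ERSPMap,
    schedule: BlockSchedule,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BandSummary:
    """ERD (movement-window) and ERS (post-movement-window) band means."""
    bands = bands or BANDS
    mov = movement_windows(schedule)
    post = post_movement_windows(schedule)
    erd = {
        b: dict(zip(emap.channels, map(float, _window_mean(emap, mov, rng))))
        for b, rng in bands.items()
    }
    ers = {
        b: dict(zip(emap.channels, map(float, _window_mean(emap, post, rng))))
        for b, rng in bands.items()
    }
    return BandSummary(
        erd=erd,
        ers=ers,
        meta={
            "movement_windows": mov,
            "post_movement_windows": post,
            "ers_window_origin": "post-movement latency (not between-block rest)",
            "n_epochs": emap.n_epochs,
        },
    )


def hemisphere_summary_eeg(
    summary: BandSummary,
    hemispheres: dict[str, str],
    hand_side: str,
    lesion_side: str | None = None,
) -> dict[str, dict[str, float]]:
    """Average band ERD/ERS within hemisphere with role labels.

    Returns measure name ("alpha_erd", "beta_ers", ...) -> role -> dB.
    """
    roles = hemisphere_roles(hand_side, lesion_side)
    out: dict[str, dict[str, float]] = {}
    for kind, table in (("erd", summary.erd), ("ers", summary.ers)):
        for band, chvals in table.items():
            key = f"{band}_{kind}"
            out[key] = {}
            for hemi, role in roles.items():
                vals = [v for ch, v in chvals.items() if hemispheres.get(ch) == hemi]
                out[key][role] = float(np.mean(vals)) if vals else np.nan
    return out
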