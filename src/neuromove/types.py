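"""Core data containers shared across the pipeline.

Conventions
-----------
* Skeleton coordinates are right-handed, millimetres: +x to the subject's
  right, +y vertical up, +z anterior (toward the reaching target).
* Times are seconds on a common session clock.  Block schedules start at
  t = 0 with the first task interval; recordings may begin earlier
  (negative times) to provide a pre-task baseline.
* Hands are labelled ``dominant`` / ``nondominant``; for stroke subjects
  the paretic hand occupies the ``nondominant`` slot, mirroring the
  non-paretic/dominant vs paretic/non-dominant analysis cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TASKS = ("reach", "steer")
HANDS = ("dominant", "nondominant")
CONDITIONS = ("SAU", "MAU")  # spontaneous vs maximal (trunk-restrained) arm use
GROUPS = ("healthy", "stroke")
HEMISPHERES = ("left", "right")

#: joints required in every skeleton trace
SKELETON_JOINTS = (
    "spine_base",
    "shoulder_center",
    "acromion_left",
    "acromion_right",
    "elbow",
    "wrist",
    "hand",
)

#: 10-10 labels of the 8-channel EEG montage over bilateral SM1
EEG_CHANNELS_RIGHT = ("C4", "FC2", "FC6", "CP2")
EEG_CHANNELS_LEFT = ("C3", "FC1", "FC3", "CP1")
EEG_CHANNELS = EEG_CHANNELS_LEFT + EEG_CHANNELS_RIGHT
EEG_HEMISPHERE = {ch: "left" for ch in EEG_CHANNELS_LEFT} | {
    ch: "right" for ch in EEG_CHANNELS_RIGHT
}

#: frequency bands (Hz) used for ERD/ERS summaries
BANDS = {"alpha": (8.0, 13.0), "beta": (14.0, 29.0)}


@dataclass(frozen=True)
class Interval:
    """One timed schedule interval."""

    start: float
    stop: float
    kind: str  # "task" | "rest"
    block: int  # 0-based block index

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class BlockSchedule:
    """Timed task/rest structure for one session cell.

    ``cues`` are the onsets of the paced "go" prompts (reaching only);
    each cue marks 2 s of outward movement followed by 2 s of return.
    """

    task: str
    hand: str
    condition: str | None
    intervals: list[Interval]
    cues: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def task_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.kind == "task"]

    @property
    def rest_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.kind == "rest"]

    @property
    def n_blocks(self) -> int:
        return len(self.task_intervals)

    @property
    def duration(self) -> float:
        return max(iv.stop for iv in self.intervals)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "hand": self.hand,
            "condition": self.condition,
            "intervals": [
                {"start": iv.start, "stop": iv.stop, "kind": iv.kind, "block": iv.block}
                for iv in self.intervals
            ],
            "cues": list(map(float, self.cues)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockSchedule":
        return cls(
            task=d["task"],
            hand=d["hand"],
            condition=d["condition"],
            intervals=[
                Interval(iv["start"], iv["stop"], iv["kind"], iv["block"])
                for iv in d["intervals"]
            ],
            cues=np.asarray(d["cues"], dtype=float),
        )


@dataclass
class SkeletonTrace:
    """Timestamped 3-D joint positions (mm) for one trial, nominal 30 Hz."""

    time: np.ndarray
    joints: dict[str, np.ndarray]  # joint -> (n, 3) mm
    side: str  # side of interest: "left" | "right"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("skeleton timestamps must be strictly increasing")
        missing = [j for j in SKELETON_JOINTS if j not in self.joints]
        if missing:
            raise ValueError(f"skeleton trace missing joints: {missing}")
        if self.side not in HEMISPHERES:
            raise ValueError(f"side must be one of {HEMISPHERES}, got {self.side!r}")

    @property
    def acromion(self) -> np.ndarray:
        """Acromion of the side of interest."""
        return self.joints[f"acromion_{self.side}"]

    def copy(self) -> "SkeletonTrace":
        return SkeletonTrace(
            self.time.copy(), {k: v.copy() for k, v in self.joints.items()}, self.side
        )


@dataclass(frozen=True)
class CircleGeometry:
    """Circular steering target: centre (mm), nominal radius and tunnel width."""

    cx: float = 0.0
    cy: float = 0.0
    #: radius of the 33-inch-circumference circle, 838.2 mm / 2pi
    radius: float = 838.2 / (2.0 * np.pi)
    tunnel_width: float = 20.0

    def __post_init__(self) -> None:
        if self.tunnel_width <= 0:
            raise ValueError("tunnel width must be positive")


@dataclass
class CursorTrace:
    """Timestamped 2-D stylus positions (mm) in the tablet plane."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    geometry: CircleGeometry = field(default_factory=CircleGeometry)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("cursor timestamps must be strictly increasing")


@dataclass
class RawOptical:
    """Dual-wavelength optical-density changes, nominal 10 Hz.

    ``od`` has shape (n_samples, n_channels, 2); the last axis follows
    ``wavelengths``.
    """

    time: np.ndarray
    od: np.ndarray
    channels: list[str]
    hemispheres: dict[str, str]  # channel -> "left" | "right"
    wavelengths: tuple[float, float] = (760.0, 850.0)
    distance_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.od.ndim != 3 or self.od.shape[2] != 2:
            raise ValueError("od must have shape (n_samples, n_channels, 2)")
        if self.distance_mm <= 0:
            raise ValueError("source-detector distance must be positive")
        for ch in self.channels:
            if self.hemispheres.get(ch) not in HEMISPHERES:
                raise ValueError(f"channel {ch!r} lacks a valid hemisphere label")


@dataclass
class HemoSeries:
    """Per-channel hemoglobin concentration changes (micromolar)."""

    time: np.ndarray
    hbo: np.ndarray  # (n_samples, n_channels)
    hbr: np.ndarray
    channels: list[str]
    hemispheres: dict[str, str]
    quality: dict[str, bool] = field(default_factory=dict)  # channel -> keep?

    def __post_init__(self) -> None:
        if not self.quality:
            self.quality = {ch: True for ch in self.channels}

    @property
    def good_channels(self) -> list[str]:
        return [ch for ch in self.channels if self.quality.get(ch, True)]


@dataclass
class EEGRecording:
    """8-channel EEG (microvolts) at a nominal 500 Hz."""

    time: np.ndarray
    data: np.ndarray  # (n_samples, n_channels)
    channels: list[str] = field(default_factory=lambda: list(EEG_CHANNELS))
    hemispheres: dict[str, str] = field(default_factory=lambda: dict(EEG_HEMISPHERE))

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("EEG channel labels must be unique")
        if self.data.shape != (len(self.time), len(self.channels)):
            raise ValueError("EEG data shape must be (n_samples, n_channels)")
        rate = 1.0 / np.median(np.diff(self.time))
        if abs(rate - 500.0) > 5.0:
            raise ValueError(f"EEG rate {rate:.1f} Hz deviates >1% from 500 Hz")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class ERSPMap:
    """Event-related spectral perturbation: dB power change vs rest baseline.

    ``data`` has shape (n_channels, n_freqs, n_times); times are relative
    to task-block onset.
    """

    times: np.ndarray
    freqs: np.ndarray
    data: np.ndarray
    channels: list[str]
    hemispheres: dict[str, str]
    n_epochs: int
    #: epoch-mean linear power and per-frequency rest baseline; band
    #: summaries average power ratios before taking the log, which keeps
    #: them unbiased at small epoch counts (the log of a noisy power
    #: estimate is biased low)
    power: np.ndarray | None = None  # (n_channels, n_freqs, n_times)
    baseline: np.ndarray | None = None  # (n_channels, n_freqs)
    meta: dict = field(default_factory=dict)  # window/baseline provenance


def hemisphere_roles(hand_side: str, lesion_side: str | None = None) -> dict[str, str]:
    """Map hemispheres to functional roles for a movement of ``hand_side``.

    The hemisphere opposite the moving hand is ``contralateral``, the other
    ``ipsilateral``.  For stroke subjects the lesioned hemisphere is
    additionally labelled ``ipsilesional`` and the intact one
    ``contralesional``.

    Returns a dict hemisphere -> "role" or "role/lesion-role".
    """
    if hand_side not in HEMISPHERES:
        raise ValueError(f"hand side must be one of {HEMISPHERES}")
    other = "left" if hand_side == "right" else "right"
    roles = {other: "contralateral", hand_side: "ipsilateral"}
    if lesion_side is not None:
        if lesion_side not in HEMISPHERES:
            raise ValueError(f"lesion side must be one of {HEMISPHERES}")
        lesion_roles = {
            lesion_side: "ipsilesional",
            ("left" if lesion_side == "right" else "right"): "contralesional",
        }
        roles = {h: f"{roles[h]}/{lesion_roles[h]}" for h in HEMISPHERES}
    return roles
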