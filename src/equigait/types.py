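"""Core containers for multi-IMU gait recordings and stride windows.

Axis conventions (fixed throughout the package):

* Accelerometer rows are expressed in the locomotion frame:
  ``long`` (longitudinal, direction of travel), ``med`` (mediolateral),
  ``vert`` (vertical).  Units: g.
* Gyroscope rows for trunk/poll sensors are ``roll``, ``pitch``, ``yaw``;
  for limb sensors they are ``introt`` (internal/external rotation, x),
  ``abdadd`` (abduction/adduction, y) and ``proret``
  (protraction/retraction, z).  Units: deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRUNK_LOCATIONS = ("sacrum", "withers", "poll")
LIMB_LOCATIONS = ("LF", "RF", "LH", "RH")
LOCATIONS = TRUNK_LOCATIONS + LIMB_LOCATIONS

GAITS = ("walk", "trot")
TRIALS = ("pre", "post")
GAIT_SUBSETS = ("walk", "trot", "walk_trot")
DATASETS = ("all", "high", "low")

ACC_AXES = ("long", "med", "vert")
GYR_AXES_TRUNK = ("roll", "pitch", "yaw")
GYR_AXES_LIMB = ("introt", "abdadd", "proret")

DEFAULT_RATE = 200.0

#: gravitational acceleration used for the g <-> m/s^2 conversion
GRAVITY = 9.81


def _build_feature_names() -> tuple[str, ...]:
    names = ["stride_duration", "stance_duration", "swing_duration", "speed"]
    names += [f"maxdiff_{loc}" for loc in TRUNK_LOCATIONS]
    names += [f"mindiff_{loc}" for loc in TRUNK_LOCATIONS]
    for kind in ("proret", "abdadd", "introt"):
        names += [f"{kind}_rom_{limb}" for limb in LIMB_LOCATIONS]
    for ax in GYR_AXES_TRUNK:
        names += [f"{ax}_rom_{loc}" for loc in TRUNK_LOCATIONS]
    for ax in ACC_AXES:
        names += [f"disp_{ax}_{loc}" for loc in LOCATIONS]
    return tuple(names)


#: canonical order of the 52 per-stride features
FEATURE_NAMES: tuple[str, ...] = _build_feature_names()
assert len(FEATURE_NAMES) == 52

#: features always computed and reported regardless of selection outcome
FORCED_FEATURES = ("speed", "stride_duration", "stance_duration", "swing_duration")


def gyr_axes_for(location: str) -> tuple[str, str, str]:
    """Gyroscope row labels for a sensor location."""
    return GYR_AXES_LIMB if location in LIMB_LOCATIONS else GYR_AXES_TRUNK


@dataclass
class SensorStream:
    """One IMU location's synchronized tri-axial acceleration and angular velocity.

    Parameters
    ----------
    location
        One of :data:`LOCATIONS`.
    rate
        Sampling rate in Hz.
    acc
        ``(3, T)`` array of acceleration in g, rows ordered per :data:`ACC_AXES`.
    gyr
        ``(3, T)`` array of angular velocity in deg/s, rows ordered per
        :func:`gyr_axes_for`.
    """

    location: str
    rate: float
    acc: np.ndarray
    gyr: np.ndarray

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown sensor location {self.location!r}")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        for name, arr in (("acc", self.acc), ("gyr", self.gyr)):
            if arr.ndim != 2 or arr.shape[0] != 3:
                raise ValueError(f"{name} must have shape (3, T)")
        if self.acc.shape[1] != self.gyr.shape[1]:
            raise ValueError("acc and gyr must share the sample count")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[1]

    def acc_channel(self, axis: str) -> np.ndarray:
        return self.acc[ACC_AXES.index(axis)]

    def gyr_channel(self, axis: str) -> np.ndarray:
        return self.gyr[gyr_axes_for(self.location).index(axis)]


@dataclass
class StrideWindow:
    """Half-open sample interval ``[start, end)`` covering one stride.

    A stride runs from one right-front hoof-on to the next; ``hoof_off_s``
    is the right-front hoof-off inside the stride.  All times are seconds
    on the recording clock.
    """

    horse_id: str
    trial: str
    gait: str
    start: int
    end: int
    hoof_on_s: float
    hoof_off_s: float
    next_hoof_on_s: float
    rate: float = DEFAULT_RATE
    valid: bool = True
    invalid_reason: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("stride window must satisfy start < end")
        if not (self.hoof_on_s <= self.hoof_off_s < self.next_hoof_on_s):
            self.valid = False
            self.invalid_reason = self.invalid_reason or "hoof-off outside stride"

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class HoofEvents:
    """Alternating right-front hoof-on / hoof-off times in seconds."""

    on_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    off_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.on_s = np.asarray(self.on_s, dtype=float)
        self.off_s = np.asarray(self.off_s, dtype=float)

    def __len__(self) -> int:
        return len(self.on_s)
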