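"""Per-stride biomechanical feature extraction (52 features per stride).

Feature families and their sources:

* gait-event durations (stride, stance, swing) from the hoof-event times;
* speed from the sacrum longitudinal cyclic displacement (a documented,
  pluggable stand-in for an external speed model);
* limb angular ROM (pro/ret, abd/add, int/ext) and trunk/poll angular ROM
  (roll, pitch, yaw) by per-stride integration of the angular velocity;
* displacement ROM per locomotion axis, and MaxDiff / MinDiff movement
  (a)symmetry indices of trunk/poll vertical displacement, by cyclic
  double integration of acceleration.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import integrate, signal

from .types import (
    ACC_AXES,
    FEATURE_NAMES,
    GRAVITY,
    GYR_AXES_TRUNK,
    LIMB_LOCATIONS,
    LOCATIONS,
    TRUNK_LOCATIONS,
    StrideWindow,
    gyr_axes_for,
)
from .synthetic import SPEED_ROM_FRACTION

logger = logging.getLogger(__name__)


def gait_event_durations(window: StrideWindow) -> tuple[float, float, float]:
    """(stride, stance, swing) durations in seconds from hoof-event times.

    stride = next hoof-on - hoof-on; stance = hoof-off - hoof-on; swing is
    constructed as their difference so the three always sum consistently.
    """
    stride = window.next_hoof_on_s - window.hoof_on_s
    stance = window.hoof_off_s - window.hoof_on_s
    if not (0.0 <= stance <= stride):
        window.valid = False
        window.invalid_reason = "hoof-off outside stride"
        return stride, np.nan, np.nan
    return stride, stance, stride - stance


def angular_rom(gyr_channel: np.ndarray, rate: float) -> float:
    """Range of motion (deg) of the angle obtained by integrating one
    stride's mean-free angular velocity (deg/s)."""
    x = np.asarray(gyr_channel, dtype=float)
    if x.size == 0:
        raise ValueError("empty angular-velocity series")
    angle = integrate.cumulative_trapezoid(x - x.mean(), dx=1.0 / rate, initial=0.0)
    return float(angle.max() - angle.min())


def _detrend_endpoints(x: np.ndarray) -> np.ndarray:
    """Remove the line through the first and last sample (closes the loop)."""
    n = len(x)
    if n < 2:
        return x - x[0]
    t = np.arange(n) / (n - 1)
    return x - (x[0] + (x[-1] - x[0]) * t)


def cyclic_displacement(acc_channel: np.ndarray, rate: float) -> np.ndarray:
    """Displacement (m) from one stride's acceleration (g) by cyclic double
    integration.

    Steps: convert g to m/s^2, remove the stride-mean acceleration,
    integrate to velocity, remove the velocity drift line (cyclic
    constraint), integrate to displacement and remove its drift line.  The
    stride is treated as one period of a cyclic signal: integration runs
    over the periodic extension (the first sample appended as the cycle
    closure), so the drift lines connect true period endpoints.  The
    returned series has ``n + 1`` samples and starts and ends at exactly
    equal values.
    """
    a = np.asarray(acc_channel, dtype=float)
    if a.size == 0:
        raise ValueError("empty acceleration series")
    a = a * GRAVITY
    a = a - a.mean()
    a = np.append(a, a[0])
    v = integrate.cumulative_trapezoid(a, dx=1.0 / rate, initial=0.0)
    v = _detrend_endpoints(v)
    d = integrate.cumulative_trapezoid(v, dx=1.0 / rate, initial=0.0)
    return _detrend_endpoints(d)


def displacement_rom(disp: np.ndarray) -> float:
    """max - min of a displacement series (m)."""
    d = np.asarray(disp, dtype=float)
    if d.size == 0:
        raise ValueError("empty displacement series")
    return float(d.max() - d.min())


def maxdiff_mindiff(vertical_disp: np.ndarray,
                    prominence_frac: float = 0.02) -> tuple[float, float]:
    """Movement (a)symmetry indices of a stride's vertical displacement.

    MaxDiff is the absolute difference between the two largest local
    maxima, MinDiff between the two smallest local minima, treating the
    stride as circular.  Returns ``(nan, nan)`` when the profile does not
    show two peaks or two troughs (logged by the caller).
    """
    x = np.asarray(vertical_disp, dtype=float)
    n = len(x)
    if n < 4:
        return np.nan, np.nan
    rom = x.max() - x.min()
    if rom == 0:
        return 0.0, 0.0   # flat profile: perfectly symmetric
    prom = prominence_frac * rom

    def two_extremes(y: np.ndarray) -> np.ndarray | None:
        half = n // 2
        ext = np.concatenate([y[-half:], y, y[:half]])
        peaks, _ = signal.find_peaks(ext, prominence=prom)
        peaks = peaks[(peaks >= half) & (peaks < half + n)] - half
        if len(peaks) < 2:
            return None
        return np.sort(y[peaks])[::-1]

    highs = two_extremes(x)
    lows = two_extremes(-x)
    maxdiff = float(highs[0] - highs[1]) if highs is not None else np.nan
    mindiff = float(lows[0] - lows[1]) if lows is not None else np.nan
    return maxdiff, mindiff


def estimate_speed(
    sacrum_long_disp: np.ndarray,
    stride_duration: float,
    rom_fraction: float = SPEED_ROM_FRACTION,
    stride_length_offset: float = 0.0,
) -> float:
    """Speed stand-in from the sacrum longitudinal displacement ROM.

    ``speed = (ROM / rom_fraction + offset) / stride_duration`` where
    ``rom_fraction`` is the assumed ratio of within-stride longitudinal
    oscillation to stride length.  With ``rom_fraction = 1`` this is the
    plain displacement-over-time definition.  The definition is pluggable;
    it replaces an external learned speed model.
    """
    if stride_duration <= 0:
        raise ValueError("stride duration must be positive")
    rom = displacement_rom(sacrum_long_disp)
    return (rom / rom_fraction + stride_length_offset) / stride_duration


def extract_stride_features(
    streams: dict,
    window: StrideWindow,
    rom_fraction: float = SPEED_ROM_FRACTION,
    stride_length_offset: float = 0.0,
) -> dict:
    """Compute the 52 named per-stride features for one stride window.

    ``streams`` maps every sensor location to its filtered
    :class:`~equigait.types.SensorStream`.  Returns a dict with the 52
    feature values (NaN for features whose extraction degenerates, e.g. a
    single-peaked vertical profile) plus the stride metadata.
    """
    missing = [loc for loc in LOCATIONS if loc not in streams]
    if missing:
        raise ValueError(f"missing sensor locations: {', '.join(missing)}")
    rate = streams["sacrum"].rate
    sl = slice(window.start, window.end)

    out: dict = {name: np.nan for name in FEATURE_NAMES}
    stride, stance, swing = gait_event_durations(window)
    out["stride_duration"] = stride
    out["stance_duration"] = stance
    out["swing_duration"] = swing

    disp_cache: dict = {}
    for loc in LOCATIONS:
        stream = streams[loc]
        for ax in ACC_AXES:
            d = cyclic_displacement(stream.acc_channel(ax)[sl], rate)
            disp_cache[(loc, ax)] = d
            out[f"disp_{ax}_{loc}"] = displacement_rom(d)
        for ax in gyr_axes_for(loc):
            rom = angular_rom(stream.gyr_channel(ax)[sl], rate)
            if loc in LIMB_LOCATIONS:
                out[f"{ax}_rom_{loc}"] = rom
            else:
                out[f"{ax}_rom_{loc}"] = rom

    for loc in TRUNK_LOCATIONS:
        md, mn = maxdiff_mindiff(disp_cache[(loc, "vert")])
        out[f"maxdiff_{loc}"] = md
        out[f"mindiff_{loc}"] = mn
        if not (np.isfinite(md) and np.isfinite(mn)):
            logger.info("maxdiff/mindiff undefined for %s stride at %.3f s (%s)",
                        loc, window.hoof_on_s, window.horse_id)

    out["speed"] = estimate_speed(
        disp_cache[("sacrum", "long")], stride,
        rom_fraction=rom_fraction, stride_length_offset=stride_length_offset)

    out["horse_id"] = window.horse_id
    out["trial"] = window.trial
    out["gait"] = window.gait
    out["hoof_on_s"] = window.hoof_on_s
    return out
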