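"""Filtering, rule-based hoof-event detection and stride segmentation.

The hoof-event detector replaces an external learned model with a signal
rule: during stance the limb barely rotates, so the smoothed magnitude of
the limb gyroscope falls well below its swing level.  Stance is the
contiguous region where that magnitude drops under ``theta`` times a
sliding robust maximum; detected edges are then refined to the midpoint
(50% level) of the stance/swing transition, which is where the synthetic
generator anchors its ground-truth hoof events.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import ndimage, signal

from .types import HoofEvents, SensorStream, StrideWindow

logger = logging.getLogger(__name__)


def lowpass(stream: SensorStream, order: int = 4, cutoff: float = 30.0) -> SensorStream:
    """Zero-phase Butterworth low-pass filter of all six channels.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    order but leaves event timing unshifted, which matters because the
    gait-event durations are features.
    """
    nyq = stream.rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist rate {nyq} Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = signal.butter(order, cutoff, btype="low", fs=stream.rate, output="sos")
    return replace(
        stream,
        acc=signal.sosfiltfilt(sos, stream.acc, axis=1),
        gyr=signal.sosfiltfilt(sos, stream.gyr, axis=1),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _estimate_period(x: np.ndarray, rate: float, min_period_s: float = 0.25) -> float | None:
    """Dominant cycle period from the autocorrelation of a zero-mean signal."""
    x = x - x.mean()
    if not np.any(x):
        return None
    n = len(x)
    ac = signal.fftconvolve(x, x[::-1], mode="full")[n - 1:]
    ac /= ac[0] if ac[0] > 0 else 1.0
    lag0 = int(min_period_s * rate)
    if lag0 >= n - 1:
        return None
    peaks, props = signal.find_peaks(ac[lag0:], height=0.2)
    if len(peaks) == 0:
        return None
    return (lag0 + peaks[0]) / rate


def _refine_edge(smag: np.ndarray, idx: int, level: float, direction: int,
                 max_search: int) -> float:
    """Refine a stance edge to the 50%-level crossing.

    ``direction`` = -1 walks backwards from a stance onset (falling edge),
    +1 walks forwards from a stance offset (rising edge).  Returns a
    fractional sample index.
    """
    half = 0.5 * level
    j = idx
    lo, hi = max(0, idx - max_search), min(len(smag) - 1, idx + max_search)
    while lo < j < hi and smag[j] < half:
        j += direction
    if smag[j] < half:     # never reached the 50% level: unrefinable edge
        return np.nan
    # crossing lies between j and j - direction
    a, b = (j - direction, j) if direction == -1 else (j - direction, j)
    a, b = min(a, b), max(a, b)
    ya, yb = smag[a], smag[b]
    if yb == ya:
        return float(j)
    frac = (half - ya) / (yb - ya)
    return a + frac * (b - a)


def detect_hoof_events(
    limb_stream: SensorStream,
    theta: float = 0.15,
    smooth_s: float = 0.05,
    robust_window_strides: float = 2.0,
    min_stance_frac: float = 0.15,
    merge_gap_frac: float = 0.10,
) -> HoofEvents:
    """Detect alternating hoof-on / hoof-off times on a limb gyro stream.

    Stance is where the smoothed gyroscope magnitude falls below ``theta``
    times a sliding 95th-percentile level (window ``robust_window_strides``
    stride periods); hoof-on is the refined stance onset, hoof-off the
    refined offset.  Runs shorter than ``min_stance_frac`` periods are
    discarded and sub-period gaps are merged, guarding against mid-swing
    dips and noise.  Returns an empty result when no cycles are detectable.
    """
    rate = limb_stream.rate
    mag = np.sqrt((limb_stream.gyr ** 2).sum(axis=0))
    if not np.any(mag > 0):
        return HoofEvents()
    k = max(3, int(round(smooth_s * rate)) | 1)
    smag = ndimage.uniform_filter1d(mag, size=k, mode="nearest")
    period_s = _estimate_period(smag, rate)
    if period_s is None or period_s * rate > len(smag):
        return HoofEvents()
    period = int(round(period_s * rate))
    win = max(3, int(round(robust_window_strides * period)))
    level = ndimage.percentile_filter(smag, 95, size=win, mode="nearest")
    mask = smag < theta * level

    runs = _runs(mask)
    # merge runs separated by short sub-threshold gaps
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap_frac * period:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = min_stance_frac * period
    ons, offs = [], []
    for s, e in merged:
        if e - s < min_len:
            continue
        # stances starting/ending near the array boundary have truncated
        # transitions and cannot be refined reliably
        if s < period // 4 or e > len(mask) - period // 4:
            continue
        on = _refine_edge(smag, s, level[s], -1, period)
        off = _refine_edge(smag, e - 1, level[e - 1], +1, period)
        if not (np.isfinite(on) and np.isfinite(off)):
            continue
        if offs and on <= offs[-1] * rate:
            continue
        ons.append(on / rate)
        offs.append(off / rate)
    return HoofEvents(on_s=np.asarray(ons), off_s=np.asarray(offs))


def segment_strides(
    streams: dict,
    events: HoofEvents,
    horse_id: str = "",
    trial: str = "pre",
    gait: str = "walk",
    mad_threshold: float = 3.0,
) -> list[StrideWindow]:
    """Window a recording into labeled strides between consecutive hoof-ons.

    Windows are half-open sample intervals and tile the event span without
    gaps.  Strides whose duration deviates more than ``mad_threshold``
    scaled median absolute deviations (floored at 2% of the median) from
    the recording's median stride duration are dropped as missed-event
    guards; drops are logged.
    """
    if len(events) < 2:
        return []
    rate = next(iter(streams.values())).rate
    ons = np.asarray(events.on_s, dtype=float)
    if np.any(np.diff(ons) <= 0):
        raise ValueError("hoof-on times must be strictly increasing")
    durations = np.diff(ons)
    med = float(np.median(durations))
    mad = 1.4826 * float(np.median(np.abs(durations - med)))
    tol = max(mad_threshold * mad, 0.02 * med)

    windows: list[StrideWindow] = []
    n_dropped = 0
    for i in range(len(ons) - 1):
        on, next_on = ons[i], ons[i + 1]
        start, end = int(round(on * rate)), int(round(next_on * rate))
        if end <= start:
            continue
        if abs((next_on - on) - med) > tol:
            n_dropped += 1
            continue
        offs_in = events.off_s[(events.off_s >= on) & (events.off_s < next_on)]
        off = float(offs_in[0]) if len(offs_in) else np.nan
        w = StrideWindow(
            horse_id=horse_id, trial=trial, gait=gait,
            start=start, end=end,
            hoof_on_s=float(on), hoof_off_s=off if np.isfinite(off) else float(on),
            next_hoof_on_s=float(next_on), rate=rate,
        )
        if not np.isfinite(off) or not len(offs_in) == 1:
            w.valid = False
            w.invalid_reason = "missing or ambiguous hoof-off"
        windows.append(w)
    if n_dropped:
        logger.info("segment_strides: dropped %d outlier strides (%s %s %s)",
                    n_dropped, horse_id, trial, gait)
    return windows
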