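"""Synthetic multi-IMU equine gait generator with known ground truth.

The generator emulates the signal content that the downstream feature
pipeline measures, not full equine kinematics:

* every channel is built from one or two stride-frequency harmonics, so
  accelerations and angular velocities are exact analytic derivatives of
  the prescribed displacement / angle trajectories;
* trunk and poll vertical displacement is a two-harmonic curve with exactly
  two peaks and two troughs per stride whose peak difference (the MaxDiff
  movement-asymmetry index) is prescribed;
* limb angles follow a warped oscillation whose rate of change is gated to
  ~0 during stance and ~1 during swing, giving the rule-based hoof-event
  detector a physically motivated signature (hoof-on = falling-edge
  midpoint of the gate);
* fatigue is injected as multiplicative pre -> post deltas on named gait
  parameters (e.g. longer walking stance, shorter trotting swing, reduced
  front-limb longitudinal displacement).

Emitted accelerations are gravity-compensated (linear acceleration only),
in g; angular velocities in deg/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .types import (
    ACC_AXES,
    DEFAULT_RATE,
    FEATURE_NAMES,
    GAITS,
    GRAVITY,
    GYR_AXES_LIMB,
    GYR_AXES_TRUNK,
    LIMB_LOCATIONS,
    LOCATIONS,
    TRIALS,
    TRUNK_LOCATIONS,
    SensorStream,
)

#: fraction of stride length (speed x stride duration) that appears as the
#: within-stride longitudinal oscillation of the sacrum; ties the simulated
#: sacrum longitudinal displacement ROM to the prescribed speed so that the
#: displacement-based speed stand-in is unbiased on synthetic data.
SPEED_ROM_FRACTION = 0.12

#: half-width of the stance/swing gate transition, as a fraction of stride
GATE_HALF_WIDTH = 0.05

FRONT_LIMBS = ("LF", "RF")
HIND_LIMBS = ("LH", "RH")

#: stance-onset phase of each limb relative to the right-front hoof-on
FOOTFALL_OFFSETS = {
    "walk": {"RF": 0.0, "LH": 0.25, "LF": 0.5, "RH": 0.75},
    "trot": {"RF": 0.0, "LH": 0.0, "LF": 0.5, "RH": 0.5},
}

#: phase constants of the three limb gyro channels (rad); pro/ret reaches its
#: extremes mid-swing while abd/add and int/ext are in quadrature, so the
#: combined gyro magnitude never vanishes inside swing.
LIMB_ANGLE_PHASE = {"proret": 0.0, "abdadd": math.pi / 2, "introt": -math.pi / 2}


def _golden_phases(keys: list) -> dict:
    golden = math.pi * (3.0 - math.sqrt(5.0))
    return {k: (i * golden) % (2 * math.pi) for i, k in enumerate(sorted(map(str, keys)))}


_TRUNK_ANGLE_PHASE = _golden_phases([f"{loc}:{ax}" for loc in TRUNK_LOCATIONS for ax in GYR_AXES_TRUNK])
_DISP_PHASE = _golden_phases([f"{loc}:{ax}" for loc in LOCATIONS for ax in ACC_AXES])


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GaitParams:
    """Prescribed per-gait kinematic parameters of one horse.

    Angles in degrees, displacements in metres, durations in seconds.
    ``disp_rom`` is keyed by ``(location, axis)`` with axes
    long/med/vert; ``trunk_angle_rom`` by ``(location, axis)`` with axes
    roll/pitch/yaw; the limb ROM dicts by limb id.
    """

    gait: str
    stride_duration: float
    duty_factor: float
    speed: float
    proret_rom: dict = field(default_factory=dict)
    abdadd_rom: dict = field(default_factory=dict)
    introt_rom: dict = field(default_factory=dict)
    trunk_angle_rom: dict = field(default_factory=dict)
    disp_rom: dict = field(default_factory=dict)
    vertical_peak_asymmetry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stride_duration <= 0:
            raise ConfigurationError("stride_duration must be positive")
        if not 0 < self.duty_factor < 1:
            raise ConfigurationError("duty_factor must lie in (0, 1)")
        for d in (self.proret_rom, self.abdadd_rom, self.introt_rom,
                  self.trunk_angle_rom, self.disp_rom, self.vertical_peak_asymmetry):
            if any(v < 0 for v in d.values()):
                raise ConfigurationError("ROM and asymmetry values must be >= 0")

    @classmethod
    def default(cls, gait: str) -> "GaitParams":
        """Typical walk / trot parameters of a sound sport horse."""
        if gait == "walk":
            p = cls(
                gait="walk", stride_duration=1.10, duty_factor=0.62, speed=1.5,
                proret_rom={"LF": 70.0, "RF": 70.0, "LH": 60.0, "RH": 60.0},
                abdadd_rom={l: 12.0 for l in LIMB_LOCATIONS},
                introt_rom={l: 9.0 for l in LIMB_LOCATIONS},
                trunk_angle_rom={
                    ("sacrum", "roll"): 8.0, ("sacrum", "pitch"): 6.0, ("sacrum", "yaw"): 7.0,
                    ("withers", "roll"): 6.0, ("withers", "pitch"): 7.0, ("withers", "yaw"): 5.0,
                    ("poll", "roll"): 10.0, ("poll", "pitch"): 12.0, ("poll", "yaw"): 9.0,
                },
                disp_rom={
                    ("sacrum", "med"): 0.035, ("sacrum", "vert"): 0.045,
                    ("withers", "long"): 0.16, ("withers", "med"): 0.030, ("withers", "vert"): 0.050,
                    ("poll", "long"): 0.14, ("poll", "med"): 0.040, ("poll", "vert"): 0.060,
                    **{(l, "long"): 0.85 for l in LIMB_LOCATIONS},
                    **{(l, "med"): 0.06 for l in LIMB_LOCATIONS},
                    **{(l, "vert"): 0.12 for l in LIMB_LOCATIONS},
                },
                vertical_peak_asymmetry={"sacrum": 0.006, "withers": 0.006, "poll": 0.008},
            )
        elif gait == "trot":
            p = cls(
                gait="trot", stride_duration=0.75, duty_factor=0.42, speed=3.5,
                proret_rom={"LF": 65.0, "RF": 65.0, "LH": 55.0, "RH": 55.0},
                abdadd_rom={l: 9.0 for l in LIMB_LOCATIONS},
                introt_rom={l: 7.0 for l in LIMB_LOCATIONS},
                trunk_angle_rom={
                    ("sacrum", "roll"): 7.0, ("sacrum", "pitch"): 6.0, ("sacrum", "yaw"): 5.0,
                    ("withers", "roll"): 5.0, ("withers", "pitch"): 6.0, ("withers", "yaw"): 4.0,
                    ("poll", "roll"): 8.0, ("poll", "pitch"): 9.0, ("poll", "yaw"): 7.0,
                },
                disp_rom={
                    ("sacrum", "med"): 0.030, ("sacrum", "vert"): 0.090,
                    ("withers", "long"): 0.28, ("withers", "med"): 0.025, ("withers", "vert"): 0.085,
                    ("poll", "long"): 0.24, ("poll", "med"): 0.035, ("poll", "vert"): 0.070,
                    **{(l, "long"): 1.00 for l in LIMB_LOCATIONS},
                    **{(l, "med"): 0.05 for l in LIMB_LOCATIONS},
                    **{(l, "vert"): 0.16 for l in LIMB_LOCATIONS},
                },
                vertical_peak_asymmetry={"sacrum": 0.008, "withers": 0.008, "poll": 0.010},
            )
        else:
            raise ConfigurationError(f"unknown gait {gait!r}")
        p.tie_speed_displacement()
        return p

    def tie_speed_displacement(self) -> None:
        """Couple the sacrum longitudinal oscillation to speed and cadence."""
        self.disp_rom[("sacrum", "long")] = SPEED_ROM_FRACTION * self.speed * self.stride_duration

    @property
    def stance_duration(self) -> float:
        return self.duty_factor * self.stride_duration

    @property
    def swing_duration(self) -> float:
        return (1.0 - self.duty_factor) * self.stride_duration


@dataclass
class FatigueEffectConfig:
    """Multiplicative pre -> post parameter deltas plus noise / variability.

    ``effects`` maps named parameters to fractional deltas (post = pre *
    (1 + delta)).  Recognised keys: ``stance_duration``, ``swing_duration``,
    ``stride_duration``, ``speed``, ``{front|hind}_limb_{longitudinal|
    mediolateral|vertical}_disp``, ``{front|hind}_limb_{proret|abdadd|
    introt}_rom``, dotted paths such as ``trunk_angle_rom.sacrum.roll``,
    ``disp_rom.withers.vert`` or ``vertical_peak_asymmetry.sacrum``; every
    key may carry a ``_walk`` / ``_trot`` suffix restricting it to one gait.
    """

    effects: dict = field(default_factory=dict)
    noise_sd_accel: float = 0.0   # g
    noise_sd_gyro: float = 0.0    # deg/s
    inter_horse_cv: float = 0.0
    stride_cv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("noise_sd_accel", "noise_sd_gyro", "inter_horse_cv", "stride_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @classmethod
    def study_default(cls) -> "FatigueEffectConfig":
        """Directional fatigue effects observed after a standardized exercise
        test: longer walking stance, shorter trotting swing, reduced
        front-limb longitudinal displacement and hind-limb pro/ret ROM."""
        return cls(
            effects={
                "stance_duration_walk": 0.10,
                "swing_duration_trot": -0.08,
                "front_limb_longitudinal_disp": -0.12,
                "hind_limb_proret_rom": -0.10,
            },
            noise_sd_accel=0.02,
            noise_sd_gyro=2.0,
            inter_horse_cv=0.08,
            stride_cv=0.04,
        )


_GROUP_LIMBS = {"front": FRONT_LIMBS, "hind": HIND_LIMBS}
_DISP_AXIS = {"longitudinal": "long", "mediolateral": "med", "vertical": "vert"}


def _split_gait_suffix(key: str) -> tuple[str, str | None]:
    for g in GAITS:
        if key.endswith("_" + g):
            return key[: -(len(g) + 1)], g
    return key, None


def apply_effects(params: GaitParams, effects: dict) -> GaitParams:
    """Return a copy of ``params`` with the configured deltas applied."""
    p = replace(
        params,
        proret_rom=dict(params.proret_rom),
        abdadd_rom=dict(params.abdadd_rom),
        introt_rom=dict(params.introt_rom),
        trunk_angle_rom=dict(params.trunk_angle_rom),
        disp_rom=dict(params.disp_rom),
        vertical_peak_asymmetry=dict(params.vertical_peak_asymmetry),
    )
    for key, delta in effects.items():
        base, gait = _split_gait_suffix(key)
        if gait is not None and gait != p.gait:
            continue
        factor = 1.0 + delta
        if base == "stance_duration":
            p.duty_factor *= factor
        elif base == "swing_duration":
            p.duty_factor = 1.0 - (1.0 - p.duty_factor) * factor
        elif base == "stride_duration":
            p.stride_duration *= factor
        elif base == "speed":
            p.speed *= factor
        elif base.startswith(("front_limb_", "hind_limb_")):
            group = base.split("_", 1)[0]
            rest = base[len(group) + 6:]  # strip '<group>_limb_'
            limbs = _GROUP_LIMBS[group]
            if rest.endswith("_disp"):
                axis = _DISP_AXIS[rest[: -len("_disp")]]
                for l in limbs:
                    p.disp_rom[(l, axis)] *= factor
            elif rest.endswith("_rom"):
                target = {"proret": p.proret_rom, "abdadd": p.abdadd_rom,
                          "introt": p.introt_rom}[rest[: -len("_rom")]]
                for l in limbs:
                    target[l] *= factor
            else:
                raise ConfigurationError(f"unknown effect key {key!r}")
        elif "." in base:
            parts = base.split(".")
            if parts[0] in ("trunk_angle_rom", "disp_rom") and len(parts) == 3:
                d = getattr(p, parts[0])
                d[(parts[1], parts[2])] *= factor
            elif parts[0] in ("proret_rom", "abdadd_rom", "introt_rom") and len(parts) == 2:
                getattr(p, parts[0])[parts[1]] *= factor
            elif parts[0] == "vertical_peak_asymmetry" and len(parts) == 2:
                p.vertical_peak_asymmetry[parts[1]] *= factor
            else:
                raise ConfigurationError(f"unknown effect key {key!r}")
        else:
            raise ConfigurationError(f"unknown effect key {key!r}")
    if not 0 < p.duty_factor < 1:
        raise ConfigurationError("effects pushed duty factor outside (0, 1)")
    return p


def effect_feature_names(effects: dict) -> list[str]:
    """Stride-feature names directly altered by the configured effects."""
    out: list[str] = []
    for key in effects:
        base, _ = _split_gait_suffix(key)
        if base in ("stance_duration", "swing_duration"):
            out += ["stance_duration", "swing_duration"]
        elif base == "stride_duration":
            out += ["stride_duration", "stance_duration", "swing_duration"]
        elif base == "speed":
            out += ["speed"]
        elif base.startswith(("front_limb_", "hind_limb_")):
            group = base.split("_", 1)[0]
            limbs = _GROUP_LIMBS[group]
            rest = base[len(group) + 6:]
            if rest.endswith("_disp"):
                axis = _DISP_AXIS[rest[: -len("_disp")]]
                out += [f"disp_{axis}_{l}" for l in limbs]
            elif rest.endswith("_rom"):
                kind = rest[: -len("_rom")]
                out += [f"{kind}_rom_{l}" for l in limbs]
        elif "." in base:
            parts = base.split(".")
            if parts[0] == "trunk_angle_rom":
                out.append(f"{parts[2]}_rom_{parts[1]}")
            elif parts[0] == "disp_rom":
                out.append(f"disp_{parts[2]}_{parts[1]}")
            elif parts[0] == "vertical_peak_asymmetry":
                out += [f"maxdiff_{parts[1]}", f"mindiff_{parts[1]}"]
            elif parts[0] in ("proret_rom", "abdadd_rom", "introt_rom"):
                out.append(f"{parts[0][:-4]}_rom_{parts[1]}")
    seen: dict[str, None] = {}
    for f in out:
        seen.setdefault(f)
    return list(seen)


# ---------------------------------------------------------------------------
# trajectory primitives
# ---------------------------------------------------------------------------

def _gate(x: np.ndarray, duty: float, w: float) -> np.ndarray:
    """Smooth stance/swing gate on the wrapped limb phase ``x`` in [0, 1).

    ~0 on the stance interval [0, duty], ~1 during swing, raised-cosine
    transitions of half-width ``w``; the falling-edge midpoint (value 0.5)
    sits exactly at x = 0, i.e. at hoof-on.
    """
    x = np.asarray(x, dtype=float) % 1.0
    g = np.empty_like(x)
    fall2 = x < w                             # second half of the falling edge
    stance = (x >= w) & (x < duty - w)
    rise = (x >= duty - w) & (x < duty + w)
    swing = (x >= duty + w) & (x < 1.0 - w)
    fall1 = x >= 1.0 - w                      # first half of the falling edge
    g[fall2] = 0.5 * (1.0 + np.cos(np.pi * (x[fall2] + w) / (2 * w)))
    g[stance] = 0.0
    g[rise] = 0.5 * (1.0 - np.cos(np.pi * (x[rise] - (duty - w)) / (2 * w)))
    g[swing] = 1.0
    g[fall1] = 0.5 * (1.0 + np.cos(np.pi * (x[fall1] - (1.0 - w)) / (2 * w)))
    return g


def _effective_half_width(duty: float, w: float) -> float:
    return min(w, 0.4 * duty, 0.4 * (1.0 - duty))


@lru_cache(maxsize=256)
def _warp_table(duty: float, w: float, offset: float, n_fine: int = 4096):
    """Cumulative swing-phase warp S(phi) on a fine grid, with S(1) = 1."""
    phi = np.linspace(0.0, 1.0, n_fine + 1)
    g = _gate(phi - offset, duty, w)
    raw = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) * 0.5 * np.diff(phi))])
    total = raw[-1]
    return phi, g, raw / total, total / 1.0  # S grid and mean gate value G


def limb_phase_warp(phase: np.ndarray, duty: float, w: float, offset: float):
    """Return (S, g, G): warped swing phase, gate value, mean gate."""
    w = _effective_half_width(duty, w)
    phi_f, _, S_f, G = _warp_table(round(duty, 9), round(w, 9), round(offset, 9))
    S = np.interp(np.asarray(phase, dtype=float) % 1.0, phi_f, S_f)
    g = _gate(np.asarray(phase, dtype=float) - offset, duty, w)
    return S, g, G


def _vertical_profile(phi: np.ndarray, a2: float, a1: float) -> np.ndarray:
    return a2 * np.sin(4 * np.pi * phi) + a1 * np.sin(2 * np.pi * phi)


def _measure_rom_peakdiff(a2: float, a1: float, n: int = 4096) -> tuple[float, float]:
    phi = np.arange(n) / n
    z = _vertical_profile(phi, a2, a1)
    left, right = np.roll(z, 1), np.roll(z, -1)
    peaks = np.sort(z[(z > left) & (z >= right)])[::-1]
    rom = float(z.max() - z.min())
    if len(peaks) < 2:
        return rom, 0.0
    return rom, float(peaks[0] - peaks[1])


@lru_cache(maxsize=1024)
def solve_vertical_amplitudes(rom: float, peak_asymmetry: float) -> tuple[float, float]:
    """Solve the two-harmonic amplitudes giving a prescribed vertical ROM and
    peak difference (MaxDiff).  Fixed-point iteration on fine-grid
    measurements; exact for ``peak_asymmetry = 0``."""
    if rom <= 0:
        return 0.0, 0.0
    if peak_asymmetry < 0:
        raise ConfigurationError("vertical peak asymmetry must be >= 0")
    if peak_asymmetry > 0.6 * rom:
        raise ConfigurationError("vertical peak asymmetry too large for a double-peaked profile")
    if peak_asymmetry == 0:
        return rom / 2.0, 0.0
    a2, a1 = rom / 2.0, peak_asymmetry / math.sqrt(2.0)
    for _ in range(80):
        m_rom, m_pd = _measure_rom_peakdiff(a2, a1)
        if m_pd <= 0:
            a1 *= 1.5
            continue
        a1 *= peak_asymmetry / m_pd
        a2 *= rom / m_rom
        if abs(m_rom - rom) < 1e-10 * rom and abs(m_pd - peak_asymmetry) < 1e-10 * peak_asymmetry:
            break
    return a2, a1


@dataclass
class StrideKinematics:
    """Analytic trajectories of one stride on a phase grid.

    ``disp`` / ``disp_d2`` map ``(location, axis)`` to displacement (m) and
    its second time derivative (m/s^2); ``angle`` / ``angle_d1`` map
    ``(location, axis)`` to angle (deg) and angular velocity (deg/s).
    """

    phase: np.ndarray
    stride_duration: float
    disp: dict = field(default_factory=dict)
    disp_d2: dict = field(default_factory=dict)
    angle: dict = field(default_factory=dict)
    angle_d1: dict = field(default_factory=dict)


def generate_stride_kinematics(
    params: GaitParams,
    phase: np.ndarray,
    amp_scale: float = 1.0,
    gate_half_width: float = GATE_HALF_WIDTH,
) -> StrideKinematics:
    """Evaluate every location's displacement and angle trajectory for one
    stride on ``phase`` (fraction of stride in [0, 1)).

    All trajectories are cyclic.  Trunk/poll vertical displacement has
    exactly two peaks and two troughs with the prescribed peak difference;
    limb angles oscillate only during swing.
    """
    if params.stride_duration <= 0:
        raise ConfigurationError("stride_duration must be positive")
    phase = np.asarray(phase, dtype=float)
    T = params.stride_duration
    kin = StrideKinematics(phase=phase, stride_duration=T)
    omega = 2 * np.pi / T

    def add_harmonic(store_v, store_d, key, amplitude, psi, order=1, deriv=2):
        k = order
        arg = 2 * np.pi * k * phase + psi
        store_v[key] = store_v.get(key, 0.0) + amplitude * np.sin(arg)
        if deriv == 2:
            store_d[key] = store_d.get(key, 0.0) - amplitude * (k * omega) ** 2 * np.sin(arg)
        else:
            store_d[key] = store_d.get(key, 0.0) + amplitude * k * omega * np.cos(arg)

    # displacements
    for loc in LOCATIONS:
        for ax in ACC_AXES:
            key = (loc, ax)
            rom = params.disp_rom.get(key, 0.0) * amp_scale
            if loc in TRUNK_LOCATIONS and ax == "vert":
                a2, a1 = solve_vertical_amplitudes(
                    round(params.disp_rom.get(key, 0.0), 12),
                    round(params.vertical_peak_asymmetry.get(loc, 0.0), 12),
                )
                add_harmonic(kin.disp, kin.disp_d2, key, a2 * amp_scale, 0.0, order=2)
                add_harmonic(kin.disp, kin.disp_d2, key, a1 * amp_scale, 0.0, order=1)
            else:
                psi = _DISP_PHASE[f"{loc}:{ax}"]
                add_harmonic(kin.disp, kin.disp_d2, key, rom / 2.0, psi, order=1)

    # trunk / poll angles: single harmonic per axis
    for loc in TRUNK_LOCATIONS:
        for ax in GYR_AXES_TRUNK:
            rom = params.trunk_angle_rom.get((loc, ax), 0.0) * amp_scale
            psi = _TRUNK_ANGLE_PHASE[f"{loc}:{ax}"]
            add_harmonic(kin.angle, kin.angle_d1, (loc, ax), rom / 2.0, psi, order=1, deriv=1)

    # limb angles: swing-gated oscillation
    for limb in LIMB_LOCATIONS:
        offset = FOOTFALL_OFFSETS[params.gait][limb]
        S, g, G = limb_phase_warp(phase, params.duty_factor, gate_half_width, offset)
        for ax, rom_map in (("proret", params.proret_rom),
                            ("abdadd", params.abdadd_rom),
                            ("introt", params.introt_rom)):
            rom = rom_map.get(limb, 0.0) * amp_scale
            c = LIMB_ANGLE_PHASE[ax]
            arg = 2 * np.pi * S + c
            kin.angle[(limb, ax)] = (rom / 2.0) * np.sin(arg)
            kin.angle_d1[(limb, ax)] = (rom / 2.0) * 2 * np.pi * np.cos(arg) * g / (G * T)
    return kin


def kinematics_to_imu(
    kin: StrideKinematics,
    rate: float,
    noise: FatigueEffectConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Convert analytic stride trajectories to per-location sensor streams.

    Acceleration channels are the analytic second derivative of displacement
    (gravity-free, in g) plus i.i.d. Gaussian noise; angular-velocity
    channels the analytic first derivative of angle (deg/s) plus noise.
    """
    n = len(kin.phase)
    sd_a = noise.noise_sd_accel if noise is not None else 0.0
    sd_g = noise.noise_sd_gyro if noise is not None else 0.0
    if (sd_a > 0 or sd_g > 0) and rng is None:
        rng = np.random.default_rng()
    streams = {}
    for loc in LOCATIONS:
        acc = np.zeros((3, n))
        for i, ax in enumerate(ACC_AXES):
            acc[i] = np.asarray(kin.disp_d2.get((loc, ax), np.zeros(n))) / GRAVITY
        axes = GYR_AXES_LIMB if loc in LIMB_LOCATIONS else GYR_AXES_TRUNK
        gyr = np.zeros((3, n))
        for i, ax in enumerate(axes):
            gyr[i] = np.asarray(kin.angle_d1.get((loc, ax), np.zeros(n)))
        if sd_a > 0:
            acc = acc + rng.normal(0.0, sd_a, size=acc.shape)
        if sd_g > 0:
            gyr = gyr + rng.normal(0.0, sd_g, size=gyr.shape)
        streams[loc] = SensorStream(location=loc, rate=rate, acc=acc, gyr=gyr)
    return streams


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Max plasma-lactate sampling distributions (mmol/L) of the two exercise
#: intensity groups, matching the reported group means/SDs of the study
#: population (high 4.04 +/- 1.80, low 1.62 +/- 0.57).
LACTATE_HIGH = (4.04, 1.80)
LACTATE_LOW = (1.62, 0.57)

#: fraction of horses exercised at high intensity (44 of 60 in the study)
HIGH_INTENSITY_FRACTION = 44.0 / 60.0


@dataclass
class SyntheticCohort:
    """A complete synthetic study: recordings, ground truth and metadata.

    ``recordings`` maps ``(horse_id, trial, gait)`` to a dict of the seven
    :class:`~equigait.types.SensorStream`; ``ground_truth`` has one row per
    generated stride with true hoof-event times and true feature values.
    """

    horses: list
    params: dict
    recordings: dict
    ground_truth: pd.DataFrame
    effect_features: list
    max_lactate: dict
    intensity_group: dict
    seed: int
    rate: float = DEFAULT_RATE
    gaits: tuple = GAITS


def _perturbed_baseline(base: GaitParams, cv: float, rng: np.random.Generator) -> GaitParams:
    def f(scale: float = 1.0) -> float:
        if cv == 0:
            return 1.0
        return float(np.clip(1.0 + scale * cv * rng.standard_normal(), 0.5, 1.5))

    p = replace(
        base,
        stride_duration=base.stride_duration * f(),
        duty_factor=float(np.clip(base.duty_factor * f(0.3), 0.15, 0.85)),
        speed=base.speed * f(),
        proret_rom={k: v * f() for k, v in base.proret_rom.items()},
        abdadd_rom={k: v * f() for k, v in base.abdadd_rom.items()},
        introt_rom={k: v * f() for k, v in base.introt_rom.items()},
        trunk_angle_rom={k: v * f() for k, v in base.trunk_angle_rom.items()},
        disp_rom={k: v * f() for k, v in base.disp_rom.items()},
        vertical_peak_asymmetry={k: v * f() for k, v in base.vertical_peak_asymmetry.items()},
    )
    p.tie_speed_displacement()
    return p


def _stride_truth_row(params: GaitParams, amp: float, duration: float) -> dict:
    row = dict.fromkeys(FEATURE_NAMES, 0.0)
    row["stride_duration"] = duration
    row["stance_duration"] = params.duty_factor * duration
    row["swing_duration"] = (1.0 - params.duty_factor) * duration
    row["speed"] = params.disp_rom[("sacrum", "long")] * amp / (SPEED_ROM_FRACTION * duration)
    for loc in TRUNK_LOCATIONS:
        asym = params.vertical_peak_asymmetry.get(loc, 0.0) * amp
        row[f"maxdiff_{loc}"] = asym
        row[f"mindiff_{loc}"] = asym
        for ax in GYR_AXES_TRUNK:
            row[f"{ax}_rom_{loc}"] = params.trunk_angle_rom.get((loc, ax), 0.0) * amp
    for limb in LIMB_LOCATIONS:
        row[f"proret_rom_{limb}"] = params.proret_rom.get(limb, 0.0) * amp
        row[f"abdadd_rom_{limb}"] = params.abdadd_rom.get(limb, 0.0) * amp
        row[f"introt_rom_{limb}"] = params.introt_rom.get(limb, 0.0) * amp
    for loc in LOCATIONS:
        for ax in ACC_AXES:
            row[f"disp_{ax}_{loc}"] = params.disp_rom.get((loc, ax), 0.0) * amp
    return row


def generate_recording(
    params: GaitParams,
    n_strides: int,
    rate: float,
    effects: FatigueEffectConfig,
    rng: np.random.Generator,
) -> tuple[dict, pd.DataFrame]:
    """Synthesize one continuous recording of ``n_strides`` strides.

    Returns the seven sensor streams and a per-stride ground-truth table
    (hoof-event times plus true feature values).
    """
    acc_parts = {loc: [] for loc in LOCATIONS}
    gyr_parts = {loc: [] for loc in LOCATIONS}
    rows = []
    t0 = 0.0
    sample0 = 0
    for k in range(n_strides):
        f_dur = 1.0 if effects.stride_cv == 0 else float(
            np.clip(1.0 + effects.stride_cv * rng.standard_normal(), 0.5, 1.5))
        amp = 1.0 if effects.stride_cv == 0 else float(
            np.clip(1.0 + effects.stride_cv * rng.standard_normal(), 0.5, 1.5))
        n_k = int(round(params.stride_duration * f_dur * rate))
        n_k = max(n_k, 8)
        T_k = n_k / rate
        phase = np.arange(n_k) / n_k
        kin = generate_stride_kinematics(
            replace(params, stride_duration=T_k), phase, amp_scale=amp)
        streams = kinematics_to_imu(kin, rate, effects, rng)
        for loc in LOCATIONS:
            acc_parts[loc].append(streams[loc].acc)
            gyr_parts[loc].append(streams[loc].gyr)
        row = _stride_truth_row(params, amp, T_k)
        row.update(stride_index=k, hoof_on_s=t0, hoof_off_s=t0 + params.duty_factor * T_k,
                   start_sample=sample0, end_sample=sample0 + n_k)
        rows.append(row)
        t0 += T_k
        sample0 += n_k
    streams = {
        loc: SensorStream(location=loc, rate=rate,
                          acc=np.concatenate(acc_parts[loc], axis=1),
                          gyr=np.concatenate(gyr_parts[loc], axis=1))
        for loc in LOCATIONS
    }
    return streams, pd.DataFrame(rows)


def generate_cohort(
    n_horses: int,
    strides_per_trial: int,
    effects: FatigueEffectConfig | None = None,
    seed: int = 0,
    gaits: tuple = GAITS,
    rate: float = DEFAULT_RATE,
    pad_strides: int = 2,
    high_intensity_fraction: float = HIGH_INTENSITY_FRACTION,
    base_params: dict | None = None,
) -> SyntheticCohort:
    """Generate a full pre/post cohort with ground truth.

    Each horse receives a per-gait baseline perturbed around the defaults
    with ``inter_horse_cv``; post-trial parameters are the pre-trial
    parameters with the fatigue effects applied.  ``pad_strides`` extra
    strides are synthesized per recording because the event detector cannot
    window the first and last stride of a recording.
    """
    if n_horses < 2:
        raise ConfigurationError("n_horses must be >= 2")
    if strides_per_trial < 2:
        raise ConfigurationError("strides_per_trial must be >= 2")
    effects = effects if effects is not None else FatigueEffectConfig()
    rng = np.random.default_rng(seed)
    horses = [f"H{i:03d}" for i in range(n_horses)]
    n_high = int(round(high_intensity_fraction * n_horses))
    groups = ["high"] * n_high + ["low"] * (n_horses - n_high)

    params: dict = {}
    recordings: dict = {}
    max_lactate: dict = {}
    intensity: dict = {}
    truth_frames = []
    for horse, group in zip(horses, groups):
        mu, sd = LACTATE_HIGH if group == "high" else LACTATE_LOW
        max_lactate[horse] = float(max(0.1, rng.normal(mu, sd)))
        intensity[horse] = group
        for gait in gaits:
            base = (base_params or {}).get(gait, GaitParams.default(gait))
            pre = _perturbed_baseline(base, effects.inter_horse_cv, rng)
            post = apply_effects(pre, effects.effects)
            params[(horse, "pre", gait)] = pre
            params[(horse, "post", gait)] = post
            for trial, p in (("pre", pre), ("post", post)):
                streams, truth = generate_recording(
                    p, strides_per_trial + pad_strides, rate, effects, rng)
                recordings[(horse, trial, gait)] = streams
                truth.insert(0, "horse_id", horse)
                truth.insert(1, "trial", trial)
                truth.insert(2, "gait", gait)
                truth_frames.append(truth)
    ground_truth = pd.concat(truth_frames, ignore_index=True)
    return SyntheticCohort(
        horses=horses,
        params=params,
        recordings=recordings,
        ground_truth=ground_truth,
        effect_features=effect_feature_names(effects.effects),
        max_lactate=max_lactate,
        intensity_group=intensity,
        seed=seed,
        rate=rate,
        gaits=tuple(gaits),
    )
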