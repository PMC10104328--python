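"""Per-stride feature extraction against closed forms and simulator truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from equigait.features import (
    angular_rom,
    cyclic_displacement,
    displacement_rom,
    estimate_speed,
    extract_stride_features,
    gait_event_durations,
    maxdiff_mindiff,
)
from equigait.types import FEATURE_NAMES, GRAVITY, LOCATIONS, SensorStream, StrideWindow


def _window(on=0.0, off=0.7, next_on=1.0, rate=200.0, start=0, end=200):
    return StrideWindow(horse_id="H0", trial="pre", gait="walk", start=start,
                        end=end, hoof_on_s=on, hoof_off_s=off,
                        next_hoof_on_s=next_on, rate=rate)


class TestGaitEventDurations:
    def test_definition(self):
        stride, stance, swing = gait_event_durations(_window(0.0, 0.7, 1.0))
        assert (stride, stance, swing) == pytest.approx((1.0, 0.7, 0.3))

    def test_degenerate_zero_stance(self):
        stride, stance, swing = gait_event_durations(_window(0.2, 0.2, 1.2))
        assert stance == 0.0 and swing == pytest.approx(stride)

    def test_invalid_off_flags_stride(self):
        w = _window(0.0, 1.5, 1.0)
        assert not w.valid
        _, stance, _ = gait_event_durations(w)
        assert np.isnan(stance)

    def test_stance_plus_swing_is_stride_exactly(self, rng):
        for _ in range(50):
            on = rng.uniform(0, 10)
            stride_d = rng.uniform(0.5, 1.5)
            off = on + rng.uniform(0, stride_d)
            stride, stance, swing = gait_event_durations(
                _window(on, off, on + stride_d))
            assert stance + swing == stride  # constructed identity


class TestAngularRom:
    def test_zero_velocity_zero_rom(self):
        assert angular_rom(np.zeros(100), 200.0) == 0.0

    def test_cosine_velocity_closed_form(self):
        """omega(t) = A (2 pi / T) cos(2 pi t / T) integrates to angle
        A sin(...), i.e. ROM = 2A."""
        A, T, rate = 35.0, 1.0, 200.0
        t = np.arange(int(T * rate)) / rate
        w = A * (2 * np.pi / T) * np.cos(2 * np.pi * t / T)
        assert angular_rom(w, rate) == pytest.approx(2 * A, rel=0.02)

    def test_matches_fine_grid_oracle(self, rng):
        """Random band-limited signal: trapezoidal ROM at 200 Hz matches the
        same integral on a 40x finer grid within 0.5%."""
        T, rate = 1.0, 200.0
        coef = rng.standard_normal(5) * [3.0, 2.0, 1.0, 0.5, 0.25]
        phase = rng.uniform(0, 2 * np.pi, 5)

        def omega(t):
            return sum(c * np.cos(2 * np.pi * (k + 1) * t / T + p)
                       for k, (c, p) in enumerate(zip(coef, phase)))

        coarse = angular_rom(omega(np.arange(int(T * rate)) / rate), rate)
        fine_rate = rate * 40
        tf = np.arange(int(T * fine_rate)) / fine_rate
        wf = omega(tf)
        angle = integrate.cumulative_trapezoid(wf - wf.mean(), dx=1 / fine_rate,
                                               initial=0.0)
        oracle = angle.max() - angle.min()
        assert coarse == pytest.approx(oracle, rel=0.005)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            angular_rom(np.empty(0), 200.0)


class TestCyclicDisplacement:
    def test_zero_acceleration_zero_displacement(self):
        d = cyclic_displacement(np.zeros(200), 200.0)
        assert not np.any(d)

    def test_sinusoid_closed_form(self):
        """a(t) = -A (2pi/T)^2 sin(2pi t/T)/g over one period recovers
        displacement of ROM 2A within 2%."""
        A, T, rate = 0.03, 1.0, 200.0
        t = np.arange(int(T * rate)) / rate
        acc = -A * (2 * np.pi / T) ** 2 * np.sin(2 * np.pi * t / T) / GRAVITY
        d = cyclic_displacement(acc, rate)
        assert displacement_rom(d) == pytest.approx(2 * A, rel=0.02)

    def test_cyclic_endpoint_constraint(self, rng):
        d = cyclic_displacement(rng.standard_normal(300) * 0.1, 200.0)
        assert abs(d[0] - d[-1]) <= 1e-9 * displacement_rom(d)

    def test_scale_equivariance(self, rng):
        a = rng.standard_normal(250) * 0.2
        d1 = displacement_rom(cyclic_displacement(a, 200.0))
        d2 = displacement_rom(cyclic_displacement(3.5 * a, 200.0))
        assert d2 == pytest.approx(3.5 * d1, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cyclic_displacement(np.empty(0), 200.0)


class TestDisplacementRomAndSymmetry:
    def test_constant_series_zero_rom(self):
        assert displacement_rom(np.full(50, 0.3)) == 0.0

    def test_sine_rom_is_twice_amplitude(self):
        t = np.linspace(0, 1, 400, endpoint=False)
        assert displacement_rom(0.04 * np.sin(2 * np.pi * t)) == pytest.approx(
            0.08, rel=1e-3)

    def test_symmetric_double_sinusoid(self):
        t = np.linspace(0, 1, 512, endpoint=False)
        md, mn = maxdiff_mindiff(0.02 * np.sin(4 * np.pi * t))
        assert md == pytest.approx(0.0, abs=1e-12)
        assert mn == pytest.approx(0.0, abs=1e-12)

    def test_constructed_peak_difference(self):
        """Peaks at 0.040 m and 0.030 m must give MaxDiff 0.010 m."""
        t = np.linspace(0, 1, 1024, endpoint=False)
        base = np.sin(4 * np.pi * t)
        bump = np.exp(-0.5 * ((t - 0.125) / 0.05) ** 2)   # raise first peak only
        x = 0.030 * base + 0.010 * bump
        md, _ = maxdiff_mindiff(x)
        assert md == pytest.approx(0.010, rel=0.05)

    def test_single_peak_gives_sentinel(self):
        t = np.linspace(0, 1, 256, endpoint=False)
        md, mn = maxdiff_mindiff(0.05 * np.sin(2 * np.pi * t))
        assert np.isnan(md) and np.isnan(mn)


class TestSpeed:
    def test_zero_motion_zero_speed(self):
        assert estimate_speed(np.zeros(100), 1.0, rom_fraction=1.0) == 0.0

    def test_definition_with_unit_fraction(self):
        t = np.linspace(0, 1, 200, endpoint=False)
        disp = 0.75 * np.sin(2 * np.pi * t)    # ROM 1.5 m
        assert estimate_speed(disp, 1.0, rom_fraction=1.0) == pytest.approx(1.5, rel=1e-3)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            estimate_speed(np.zeros(10), 0.0)

    def test_monotone_in_prescribed_speed(self):
        """Across a cohort with inter-horse speed variation, the estimated
        speed rank-correlates > 0.9 with the prescribed speed."""
        from equigait.pipeline import extract_cohort_features
        from equigait.synthetic import FatigueEffectConfig, generate_cohort
        effects = FatigueEffectConfig(inter_horse_cv=0.12, stride_cv=0.02)
        cohort = generate_cohort(8, 5, effects, seed=21, gaits=("walk",))
        feats = extract_cohort_features(cohort)
        gt = cohort.ground_truth
        est, true = [], []
        for (h, tr, g), block in feats.groupby(["horse_id", "trial", "gait"]):
            gtb = gt[(gt.horse_id == h) & (gt.trial == tr) & (gt.gait == g)]
            est.append(block["speed"].mean())
            true.append(gtb["speed"].mean())
        rho = pd.Series(est).corr(pd.Series(true), method="spearman")
        assert rho > 0.9


class TestExtractStrideFeatures:
    def test_vector_has_exactly_52_features(self, zero_noise_cohort):
        streams = zero_noise_cohort.recordings[
            (zero_noise_cohort.horses[0], "pre", "walk")]
        from equigait.preprocessing import lowpass
        filtered = {loc: lowpass(s) for loc, s in streams.items()}
        gt = zero_noise_cohort.ground_truth
        row = gt[(gt.horse_id == zero_noise_cohort.horses[0])
                 & (gt.trial == "pre") & (gt.gait == "walk")].iloc[1]
        w = StrideWindow("H000", "pre", "walk", int(row.start_sample),
                         int(row.end_sample), row.hoof_on_s, row.hoof_off_s,
                         row.hoof_on_s + row.stride_duration)
        out = extract_stride_features(filtered, w)
        assert sum(1 for k in FEATURE_NAMES if k in out) == 52
        assert all(np.isfinite(out[k]) for k in FEATURE_NAMES)

    def test_missing_location_is_named(self):
        streams = {loc: SensorStream(location=loc, rate=200.0,
                                     acc=np.zeros((3, 400)), gyr=np.zeros((3, 400)))
                   for loc in LOCATIONS if loc != "poll"}
        with pytest.raises(ValueError, match="poll"):
            extract_stride_features(streams, _window())

    def test_all_zero_streams_give_zero_motion_features(self):
        streams = {loc: SensorStream(location=loc, rate=200.0,
                                     acc=np.zeros((3, 400)), gyr=np.zeros((3, 400)))
                   for loc in LOCATIONS}
        out = extract_stride_features(streams, _window())
        for k in FEATURE_NAMES:
            if k in ("stride_duration", "stance_duration", "swing_duration"):
                continue
            assert out[k] == 0.0, k
        assert out["stride_duration"] == pytest.approx(1.0)

    def test_zero_noise_features_match_ground_truth(self, zero_noise_cohort,
                                                    zero_noise_features):
        """Every feature within 5% of its prescribed value at zero noise."""
        gt = zero_noise_cohort.ground_truth
        for (h, tr, g), block in zero_noise_features.groupby(
                ["horse_id", "trial", "gait"]):
            gtb = gt[(gt.horse_id == h) & (gt.trial == tr) & (gt.gait == g)]
            ons = gtb.hoof_on_s.to_numpy()
            row = block.iloc[0]
            i = int(np.argmin(np.abs(ons - row.hoof_on_s)))
            for k in FEATURE_NAMES:
                truth = gtb.iloc[i][k]
                if truth == 0:
                    continue
                assert row[k] == pytest.approx(truth, rel=0.05), (k, h, tr, g)
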