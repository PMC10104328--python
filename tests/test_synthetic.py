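"""Generator correctness: prescribed kinematics, effects, determinism."""

import numpy as np
import pytest

from equigait.features import cyclic_displacement, displacement_rom
from equigait.synthetic import (
    ConfigurationError,
    FatigueEffectConfig,
    GaitParams,
    apply_effects,
    effect_feature_names,
    generate_cohort,
    generate_recording,
    generate_stride_kinematics,
    kinematics_to_imu,
    solve_vertical_amplitudes,
)
from equigait.types import GRAVITY, LIMB_LOCATIONS, LOCATIONS, TRUNK_LOCATIONS


def _closed_phase(n=512):
    return np.linspace(0.0, 1.0, n + 1)


class TestStrideKinematics:
    def test_vertical_has_two_peaks_with_prescribed_difference(self):
        p = GaitParams.default("walk")
        kin = generate_stride_kinematics(p, np.arange(2048) / 2048)
        z = kin.disp[("sacrum", "vert")]
        left, right = np.roll(z, 1), np.roll(z, -1)
        peaks = np.sort(z[(z > left) & (z >= right)])[::-1]
        troughs = np.sort(z[(z < left) & (z <= right)])
        assert len(peaks) == 2 and len(troughs) == 2
        assert peaks[0] - peaks[1] == pytest.approx(
            p.vertical_peak_asymmetry["sacrum"], rel=1e-3)
        assert z.max() - z.min() == pytest.approx(p.disp_rom[("sacrum", "vert")], rel=1e-3)

    def test_zero_asymmetry_gives_equal_peaks(self):
        p = GaitParams.default("walk")
        p.vertical_peak_asymmetry = {loc: 0.0 for loc in TRUNK_LOCATIONS}
        kin = generate_stride_kinematics(p, np.arange(2048) / 2048)
        z = kin.disp[("withers", "vert")]
        left, right = np.roll(z, 1), np.roll(z, -1)
        peaks = z[(z > left) & (z >= right)]
        assert len(peaks) == 2
        assert abs(peaks[0] - peaks[1]) < 1e-12

    def test_limb_proret_range_is_prescribed(self):
        p = GaitParams.default("trot")
        p.proret_rom["LF"] = 10.0
        kin = generate_stride_kinematics(p, np.arange(4096) / 4096)
        a = kin.angle[("LF", "proret")]
        assert a.max() - a.min() == pytest.approx(10.0, rel=1e-4)

    def test_duty_factor_defines_stance_and_swing(self):
        p = GaitParams.default("walk")
        p.stride_duration, p.duty_factor = 1.0, 0.6
        assert p.stance_duration == pytest.approx(0.6)
        assert p.swing_duration == pytest.approx(0.4)

    def test_all_trajectories_are_cyclic(self):
        p = GaitParams.default("walk")
        kin = generate_stride_kinematics(p, _closed_phase())
        for store in (kin.disp, kin.angle):
            for key, traj in store.items():
                rng_ = np.ptp(traj)
                if rng_ == 0:
                    continue
                assert abs(traj[0] - traj[-1]) <= 1e-9 * rng_, key

    def test_nonpositive_stride_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            GaitParams.default("walk").__class__(
                gait="walk", stride_duration=0.0, duty_factor=0.5, speed=1.0)


class TestVerticalAmplitudeSolver:
    @pytest.mark.parametrize("rom,asym", [(0.05, 0.005), (0.09, 0.012), (0.03, 0.0)])
    def test_solver_hits_targets(self, rom, asym):
        a2, a1 = solve_vertical_amplitudes(rom, asym)
        from equigait.synthetic import _measure_rom_peakdiff
        m_rom, m_pd = _measure_rom_peakdiff(a2, a1)
        assert m_rom == pytest.approx(rom, rel=1e-6)
        assert m_pd == pytest.approx(asym, abs=1e-9 if asym == 0 else asym * 1e-6)

    def test_excessive_asymmetry_rejected(self):
        with pytest.raises(ConfigurationError):
            solve_vertical_amplitudes(0.04, 0.04)


class TestKinematicsToImu:
    def test_acceleration_is_analytic_second_derivative(self):
        """Displacement A sin(2 pi t / T) must emit -A (2 pi / T)^2 sin / g."""
        p = GaitParams.default("walk")
        T = p.stride_duration
        n = 256
        phase = np.arange(n) / n
        kin = generate_stride_kinematics(p, phase)
        A_rom = p.disp_rom[("withers", "long")]
        acc = kin.disp_d2[("withers", "long")]
        # reconstruct from the displacement trajectory itself
        expected = -((2 * np.pi / T) ** 2) * kin.disp[("withers", "long")]
        assert np.allclose(acc, expected, atol=1e-9 * A_rom)
        streams = kinematics_to_imu(kin, rate=n / T)
        assert np.allclose(streams["withers"].acc_channel("long"), acc / GRAVITY)

    def test_zero_trajectories_give_zero_mean_noise(self, rng):
        p = GaitParams(gait="walk", stride_duration=1.0, duty_factor=0.6, speed=0.0)
        kin = generate_stride_kinematics(p, np.arange(400) / 400)
        noise = FatigueEffectConfig(noise_sd_accel=0.05, noise_sd_gyro=3.0)
        streams = kinematics_to_imu(kin, 200.0, noise, rng)
        acc = streams["sacrum"].acc
        assert abs(acc.mean()) < 5 * 0.05 / np.sqrt(acc.size)
        assert acc.std() == pytest.approx(0.05, rel=0.1)

    def test_same_seed_same_noise(self):
        p = GaitParams.default("trot")
        kin = generate_stride_kinematics(p, np.arange(128) / 128)
        noise = FatigueEffectConfig(noise_sd_accel=0.05, noise_sd_gyro=3.0)
        s1 = kinematics_to_imu(kin, 200.0, noise, np.random.default_rng(7))
        s2 = kinematics_to_imu(kin, 200.0, noise, np.random.default_rng(7))
        for loc in LOCATIONS:
            assert np.array_equal(s1[loc].acc, s2[loc].acc)
            assert np.array_equal(s1[loc].gyr, s2[loc].gyr)


class TestEffects:
    def test_multiplicative_stance_effect(self):
        pre = GaitParams.default("walk")
        post = apply_effects(pre, {"stance_duration_walk": 0.10})
        assert post.stance_duration == pytest.approx(1.10 * pre.stance_duration)
        assert post.stride_duration == pre.stride_duration

    def test_swing_effect_trot_only(self):
        pre = GaitParams.default("walk")
        assert apply_effects(pre, {"swing_duration_trot": -0.2}).swing_duration == \
            pytest.approx(pre.swing_duration)
        pre_t = GaitParams.default("trot")
        post_t = apply_effects(pre_t, {"swing_duration_trot": -0.2})
        assert post_t.swing_duration == pytest.approx(0.8 * pre_t.swing_duration)

    def test_zero_effects_identity(self):
        pre = GaitParams.default("trot")
        post = apply_effects(pre, {})
        assert post == pre

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_effects(GaitParams.default("walk"), {"bogus_key": 0.1})

    def test_effect_feature_mapping(self):
        names = effect_feature_names({
            "front_limb_longitudinal_disp": -0.1,
            "hind_limb_proret_rom": -0.1,
            "vertical_peak_asymmetry.sacrum": 0.2,
        })
        assert set(names) == {"disp_long_LF", "disp_long_RF", "proret_rom_LH",
                              "proret_rom_RH", "maxdiff_sacrum", "mindiff_sacrum"}


class TestCohort:
    def test_determinism(self):
        eff = FatigueEffectConfig.study_default()
        c1 = generate_cohort(3, 4, eff, seed=9)
        c2 = generate_cohort(3, 4, eff, seed=9)
        assert c1.ground_truth.equals(c2.ground_truth)
        for key in c1.recordings:
            for loc in LOCATIONS:
                assert np.array_equal(c1.recordings[key][loc].acc,
                                      c2.recordings[key][loc].acc)

    def test_pre_and_post_exist_for_every_horse(self, zero_noise_cohort):
        for h in zero_noise_cohort.horses:
            for gait in zero_noise_cohort.gaits:
                assert (h, "pre", gait) in zero_noise_cohort.recordings
                assert (h, "post", gait) in zero_noise_cohort.recordings

    def test_effect_injection_exact_ratio(self, zero_noise_cohort):
        """Post/pre ground-truth stance ratio equals 1 + delta exactly at walk."""
        gt = zero_noise_cohort.ground_truth
        for h in zero_noise_cohort.horses:
            pre = gt[(gt.horse_id == h) & (gt.trial == "pre") & (gt.gait == "walk")]
            post = gt[(gt.horse_id == h) & (gt.trial == "post") & (gt.gait == "walk")]
            ratio = post.stance_duration.iloc[0] / pre.stance_duration.iloc[0]
            assert ratio == pytest.approx(1.10, abs=1e-9)

    def test_zero_effects_zero_noise_pre_equals_post(self):
        c = generate_cohort(2, 3, FatigueEffectConfig(), seed=1, gaits=("walk",))
        gt = c.ground_truth
        pre = gt[gt.trial == "pre"].drop(columns=["trial", "hoof_on_s", "hoof_off_s",
                                                  "start_sample", "end_sample"])
        post = gt[gt.trial == "post"].drop(columns=["trial", "hoof_on_s", "hoof_off_s",
                                                    "start_sample", "end_sample"])
        assert np.allclose(pre.select_dtypes(float).to_numpy(),
                           post.select_dtypes(float).to_numpy())

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(1, 10, FatigueEffectConfig(), seed=0)
        with pytest.raises(ConfigurationError):
            generate_cohort(5, 1, FatigueEffectConfig(), seed=0)

    def test_double_integration_consistency_oracle(self):
        """Zero noise: cyclically double-integrating the emitted acceleration
        recovers the prescribed displacement ROM within 2%."""
        p = GaitParams.default("trot")
        rate = 200.0
        streams, truth = generate_recording(p, 3, rate, FatigueEffectConfig(),
                                            np.random.default_rng(0))
        row = truth.iloc[1]
        sl = slice(int(row.start_sample), int(row.end_sample))
        for loc in ("sacrum", "LF"):
            for ax in ("long", "vert"):
                d = cyclic_displacement(streams[loc].acc_channel(ax)[sl], rate)
                assert displacement_rom(d) == pytest.approx(
                    p.disp_rom[(loc, ax)], rel=0.02)
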