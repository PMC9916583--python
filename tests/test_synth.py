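"""Synthetic trial generation: ground-truth consistency and determinism."""

import math

import numpy as np
import pytest

from exogait.dynamics import check_residuals, inverse_dynamics
from exogait.kinematics import forward_kinematics
from exogait.signals import compute_mvc, process_emg
from exogait.synth import (SynthConfig, SynthError, _stance_weight,
                           build_condition_models, generate_consistent_loads,
                           generate_emg, generate_encoder,
                           generate_gait_trajectory, generate_markers,
                           generate_trial)

DEG = math.pi / 180.0


@pytest.fixture(scope="module")
def assisted_models():
    return build_condition_models("assisted")


@pytest.fixture(scope="module")
def unassisted_models():
    return build_condition_models("unassisted")


@pytest.fixture(scope="module")
def assisted_bundle(assisted_models):
    cfg = SynthConfig.for_condition("assisted", seed=11)
    return generate_trial(cfg, assisted_models)


class TestTrajectories:
    def test_assisted_peak_knee_flexion_exact(self, assisted_models):
        cfg = SynthConfig.for_condition("assisted", seed=0)
        traj = generate_gait_trajectory(cfg, assisted_models.ik_model)
        peak = traj.column("knee_flexion_l").max() / DEG
        assert peak == pytest.approx(50.1, abs=1e-9)

    def test_unassisted_peak_knee_flexion_exact(self, unassisted_models):
        cfg = SynthConfig.for_condition("unassisted", seed=0)
        traj = generate_gait_trajectory(cfg, unassisted_models.ik_model)
        peak = traj.column("knee_flexion_l").max() / DEG
        assert peak == pytest.approx(68.6, abs=1e-9)

    def test_exo_pins_track_human_joints(self, assisted_models):
        cfg = SynthConfig.for_condition("assisted", seed=0)
        traj = generate_gait_trajectory(cfg, assisted_models.ik_model)
        np.testing.assert_allclose(traj.column("exo_knee_flexion_r"),
                                   traj.column("knee_flexion_r"))

    def test_static_config_is_stationary(self, unassisted_models):
        cfg = SynthConfig.standing(seed=0)
        traj = generate_gait_trajectory(cfg, unassisted_models.ik_model)
        assert np.all(traj.qdot == 0)
        assert np.all(traj.qddot == 0)
        assert np.ptp(traj.q, axis=0).max() == 0

    def test_left_right_half_cycle_offset(self, unassisted_models):
        cfg = SynthConfig.for_condition("unassisted", seed=0)
        traj = generate_gait_trajectory(cfg, unassisted_models.ik_model)
        T = cfg.cycle_duration
        half = int(round(0.5 * T * cfg.marker_rate))
        left = traj.column("knee_flexion_l")
        right = traj.column("knee_flexion_r")
        np.testing.assert_allclose(left[:-half], right[half:], atol=1e-9)

    def test_amplitude_out_of_range_rejected(self, unassisted_models):
        cfg = SynthConfig.for_condition(
            "unassisted", seed=0, amplitudes={"knee_peak": 200.0})
        with pytest.raises(SynthError, match="out of joint range"):
            generate_gait_trajectory(cfg, unassisted_models.ik_model)


class TestMarkers:
    def test_noiseless_markers_equal_fk(self, assisted_models):
        cfg = SynthConfig.for_condition("assisted", seed=0, n_cycles=1)
        traj = generate_gait_trajectory(cfg, assisted_models.ik_model)
        mset = generate_markers(assisted_models.ik_model, traj, noise_sd=0.0)
        fk = forward_kinematics(assisted_models.ik_model, traj.q[7])
        for m, name in enumerate(assisted_models.ik_model.marker_names):
            np.testing.assert_allclose(mset.markers[name][7], fk.markers[m],
                                       atol=1e-12)

    def test_noise_sd_recovered(self, unassisted_models):
        cfg = SynthConfig.standing(seed=3)
        traj = generate_gait_trajectory(cfg, unassisted_models.ik_model)
        mset0 = generate_markers(unassisted_models.ik_model, traj,
                                 noise_sd=0.0)
        mset = generate_markers(unassisted_models.ik_model, traj,
                                noise_sd=0.005, seed=5)
        diffs = np.concatenate(
            [(mset.markers[n] - mset0.markers[n]).ravel()
             for n in mset.markers])
        assert diffs.std() == pytest.approx(0.005, rel=0.05)
        assert diffs.size >= 10_000

    def test_same_seed_identical(self, unassisted_models):
        cfg = SynthConfig.standing(seed=0)
        traj = generate_gait_trajectory(cfg, unassisted_models.ik_model)
        a = generate_markers(unassisted_models.ik_model, traj,
                             noise_sd=0.003, occlusion_rate=0.05, seed=9)
        b = generate_markers(unassisted_models.ik_model, traj,
                             noise_sd=0.003, occlusion_rate=0.05, seed=9)
        for name in a.markers:
            np.testing.assert_array_equal(a.markers[name], b.markers[name])
            np.testing.assert_array_equal(a.occluded[name], b.occluded[name])


class TestConsistentLoads:
    def test_static_standing_even_split(self, unassisted_models):
        cfg = SynthConfig.standing(seed=0)
        model = unassisted_models.id_model
        traj = generate_gait_trajectory(cfg, model)
        loads = generate_consistent_loads(model, traj, cfg)
        weight = model.total_mass * 9.81
        for ld in loads:
            np.testing.assert_allclose(ld.force[:, 2], weight / 2,
                                       rtol=1e-9)

    def test_forces_sum_to_newton_resultant(self, assisted_bundle,
                                            assisted_models):
        from exogait.dynamics import body_kinematics
        model = assisted_models.id_model
        traj = assisted_bundle.id_traj
        masses = np.array([s.mass for s in model.segments.values()])
        total_f = sum(ld.force for ld in assisted_bundle.loads)
        for k in (0, 57, 201):
            bk = body_kinematics(model, traj.q[k], traj.qdot[k],
                                 traj.qddot[k])
            expected = masses @ bk.a_com - masses.sum() * np.array(
                [0, 0, -9.81])
            np.testing.assert_allclose(total_f[k], expected, atol=1e-9)

    def test_id_base_residuals_vanish(self, assisted_bundle, assisted_models):
        report = check_residuals(assisted_bundle.torques,
                                 assisted_models.id_model,
                                 assisted_bundle.id_traj,
                                 assisted_bundle.loads)
        weight = assisted_models.id_model.total_mass * 9.81
        assert report.max_force < 1e-6 * weight

    def test_missing_accelerations_rejected(self, unassisted_models):
        from exogait.kinematics import CoordinateTrajectory
        model = unassisted_models.id_model
        traj = CoordinateTrajectory(time=[0.0],
                                    q=np.zeros((1, model.n_coordinates)))
        with pytest.raises(SynthError, match="exact accelerations"):
            generate_consistent_loads(model, traj)

    def test_stance_weights_cover_cycle(self):
        phi = np.linspace(0, 1, 1001)
        wl = _stance_weight(phi, 0.6, 0.1)
        wr = _stance_weight(phi + 0.5, 0.6, 0.1)
        assert (wl + wr).min() > 1e-6  # no flight phase
        mid = (phi > 0.15) & (phi < 0.45)
        np.testing.assert_allclose(wl[mid] / (wl + wr)[mid], 1.0)


class TestEMG:
    def test_mvc_round_trip_peak_unity(self):
        cfg = SynthConfig.for_condition("assisted", seed=2, n_cycles=1)
        emg = generate_emg(cfg)
        fs = emg["fs"]
        rest = emg["resting_offset"]
        trials = emg["mvc_trials"]["soleus_l"]
        mvc = compute_mvc({"soleus_l": trials}, fs=fs, resting_mean=rest)
        peaks = [process_emg(tr, rest, mvc["soleus_l"], fs=fs).max()
                 for tr in trials]
        assert max(peaks) == pytest.approx(1.0, abs=1e-12)

    def test_plantarflexor_burst_in_propulsion(self):
        cfg = SynthConfig.for_condition("unassisted", seed=2)
        emg = generate_emg(cfg)
        fs = emg["fs"]
        env = process_emg(emg["channels"]["soleus_l"],
                          emg["resting_offset"], 1.0, fs=fs)
        t = emg["time"]
        phi = np.mod(t / cfg.cycle_duration, 1.0)
        prop = (phi > 0.3) & (phi < 0.6)
        swing = (phi > 0.7) & (phi < 0.95)
        assert env[prop].mean() > 3 * env[swing].mean()

    def test_static_trial_channels_near_rest(self):
        cfg = SynthConfig.standing(seed=2)
        emg = generate_emg(cfg)
        ch = emg["channels"]["rectus_femoris_l"]
        np.testing.assert_allclose(ch, emg["resting_offset"], atol=1e-12)

    def test_sixteen_channels(self):
        cfg = SynthConfig.for_condition("assisted", seed=0, n_cycles=1)
        assert len(generate_emg(cfg)["channels"]) == 16


class TestEncoder:
    def test_offset_only_recovers_zero_rms(self, assisted_models):
        cfg = SynthConfig.for_condition("assisted", seed=0,
                                        encoder_noise_sd_deg=0.0)
        traj = generate_gait_trajectory(cfg, assisted_models.ik_model)
        enc = generate_encoder(traj, cfg)
        from exogait.kinematics import compare_ik_encoder
        ik_deg = traj.column("exo_hip_flexion_l") / DEG
        rms = compare_ik_encoder(traj.time, ik_deg, enc["time"],
                                 enc["channels"]["exo_hip_flexion_l"])
        assert rms < 1e-9

    def test_default_noise_within_reported_bound(self, assisted_bundle):
        from exogait.kinematics import compare_ik_encoder
        b = assisted_bundle
        worst = 0.0
        for name, channel in b.encoder["channels"].items():
            ik_deg = b.traj.column(name) / DEG
            worst = max(worst, compare_ik_encoder(
                b.traj.time, ik_deg, b.encoder["time"], channel))
        assert worst <= 3.3

    def test_same_seed_identical_stream(self, assisted_models):
        cfg = SynthConfig.for_condition("assisted", seed=1, n_cycles=1)
        traj = generate_gait_trajectory(cfg, assisted_models.ik_model)
        a = generate_encoder(traj, cfg, seed=4)
        b = generate_encoder(traj, cfg, seed=4)
        for name in a["channels"]:
            np.testing.assert_array_equal(a["channels"][name],
                                          b["channels"][name])

    def test_no_exo_joints_rejected(self, unassisted_models):
        cfg = SynthConfig.for_condition("unassisted", seed=0, n_cycles=1)
        traj = generate_gait_trajectory(cfg, unassisted_models.ik_model)
        with pytest.raises(SynthError, match="no exoskeleton"):
            generate_encoder(traj, cfg)


class TestBundles:
    def test_truth_events_match_stance_fraction(self, assisted_bundle):
        cfg = assisted_bundle.config
        ev = assisted_bundle.events["left"]
        assert ev["strikes"][0] == pytest.approx(0.0)
        assert ev["toeoffs"][0] == pytest.approx(
            cfg.stance_fraction * cfg.cycle_duration)

    def test_bundle_determinism(self, assisted_models):
        cfg = SynthConfig.for_condition("assisted", seed=21, n_cycles=1)
        b1 = generate_trial(cfg, assisted_models)
        b2 = generate_trial(cfg, assisted_models)
        np.testing.assert_array_equal(b1.traj.q, b2.traj.q)
        for name in b1.markers.markers:
            np.testing.assert_array_equal(b1.markers.markers[name],
                                          b2.markers.markers[name])
        np.testing.assert_array_equal(b1.torques.tau, b2.torques.tau)
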