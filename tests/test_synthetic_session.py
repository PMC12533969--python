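import numpy as np
import pytest

from bcivmr import (TaskConfig, PerturbationSchedule, LearningModel,
                    NeuronSpec, make_targets, generate_session, simulate_trial,
                    save_session, load_session, midpoint_angle,
                    align_to_target_frame, apply_vmr)
from bcivmr.synthetic_session import (make_population, minimum_jerk_speed,
                                      population_label, _calibration_block)
from bcivmr.kf_decoder import calibrate


def _noiseless_specs(n=30, seed=0):
    rng = np.random.default_rng(seed)
    return make_population(n, "M1", True, rng, noise_sd=0.0, latent_rank=0)


def _decoder_for(specs, config, seed=0):
    rng = np.random.default_rng(seed)
    y, v = _calibration_block(specs, config, rng, n_trials=24, round_counts=False)
    return calibrate(y, v, unit_ids=[s.unit_id for s in specs])


class TestSpecs:
    def test_neuron_spec_validation(self):
        with pytest.raises(ValueError):
            NeuronSpec("u0", "V1", True, 1.0, np.zeros(3))
        with pytest.raises(ValueError):
            NeuronSpec("u0", "M1", True, -1.0, np.zeros(3))
        with pytest.raises(ValueError):
            NeuronSpec("u0", "M1", True, 1.0, np.zeros(3), planning_gain=2.0)

    def test_population_pds_cover_directions(self):
        rng = np.random.default_rng(0)
        specs = make_population(400, "PMd", False, rng)
        pds = np.array([s.b_vec / np.linalg.norm(s.b_vec) for s in specs])
        # approximately uniform on the sphere: small mean resultant vector
        assert np.linalg.norm(pds.mean(axis=0)) < 0.12

    def test_population_label_and_gain_lookup(self):
        spec = NeuronSpec("u0", "PRR", False, 1.0, np.ones(3))
        assert population_label(spec) == "PRR:noncontrolling"
        lm = LearningModel(adaptation_gain_by_population={
            "PRR:noncontrolling": 0.4, "noncontrolling": 0.8})
        assert lm.gain_for(spec) == 0.4
        spec2 = NeuronSpec("u1", "M1", False, 1.0, np.ones(3))
        assert lm.gain_for(spec2) == 0.8
        assert LearningModel().gain_for(spec) == 1.0


class TestMinimumJerk:
    def test_integrates_to_distance(self):
        speed = minimum_jerk_speed(14, 0.05, 60.6, 0.7)
        assert speed.sum() * 0.05 == pytest.approx(60.6)
        assert speed.min() >= 0
        # bell shape: peak in the middle
        assert np.argmax(speed) in (6, 7)


class TestSimulateTrial:
    def test_unadapted_rotation_error_equals_rotation(self):
        config = TaskConfig()
        specs = _noiseless_specs()
        dec = _decoder_for(specs, config)
        sched = PerturbationSchedule()
        target = make_targets(config)[3]
        _, cursor, _, ev = simulate_trial(
            0.0, target, specs, dec, sched, np.random.default_rng(0),
            config=config, phase="rotation", round_counts=False)
        path = cursor[ev["go_bin"]: ev["move_end_bin"] + 1]
        al = align_to_target_frame(path, target, rotation_sign=1)
        assert midpoint_angle(al).alpha_deg == pytest.approx(30.0, abs=1e-6)

    def test_full_compensation_goes_straight(self):
        config = TaskConfig()
        specs = _noiseless_specs()
        dec = _decoder_for(specs, config)
        sched = PerturbationSchedule()
        target = make_targets(config)[5]
        _, cursor, _, ev = simulate_trial(
            -30.0, target, specs, dec, sched, np.random.default_rng(0),
            config=config, phase="rotation", round_counts=False)
        path = cursor[ev["go_bin"]: ev["move_end_bin"] + 1]
        al = align_to_target_frame(path, target, rotation_sign=1)
        assert abs(midpoint_angle(al).alpha_deg) < 1e-6
        # and the endpoint lands on the target
        np.testing.assert_allclose(path[-1], target, atol=1e-3)

    def test_cursor_at_center_before_go_and_held_after(self):
        config = TaskConfig()
        specs = _noiseless_specs(10)
        dec = _decoder_for(specs, config)
        _, cursor, _, ev = simulate_trial(
            0.0, make_targets(config)[0], specs, dec, PerturbationSchedule(),
            np.random.default_rng(1), config=config, round_counts=False)
        np.testing.assert_array_equal(cursor[: ev["go_bin"] + 1], 0.0)
        end = cursor[ev["move_end_bin"]]
        assert (cursor[ev["move_end_bin"]:] == end[None, :]).all()

    def test_counts_nonnegative_integers_when_rounded(self):
        config = TaskConfig()
        rng = np.random.default_rng(2)
        specs = make_population(8, "M1", True, rng)
        dec = _decoder_for(specs, config)
        counts, _, hand, _ = simulate_trial(
            0.0, make_targets(config)[2], specs, dec, PerturbationSchedule(),
            rng, config=config, round_counts=True)
        assert counts.min() >= 0
        np.testing.assert_array_equal(counts, np.rint(counts))
        assert np.linalg.norm(hand, axis=1).max() <= config.hand_security_radius_mm + 1e-9

    def test_decoder_roster_mismatch_rejected(self):
        config = TaskConfig()
        specs = _noiseless_specs(6)
        dec = _decoder_for(specs, config)
        with pytest.raises(ValueError):
            simulate_trial(0.0, make_targets(config)[0], specs[:-1], dec,
                           PerturbationSchedule(), np.random.default_rng(0),
                           config=config)

    def test_workspace_rotation_equivariance(self):
        """Rotating all tuning vectors and the target together leaves the
        motor-frame counts unchanged (noiseless)."""
        config = TaskConfig()
        specs = _noiseless_specs(12, seed=4)
        dec = _decoder_for(specs, config)
        target = make_targets(config)[1]
        c1, _, _, _ = simulate_trial(0.0, target, specs, dec,
                                     PerturbationSchedule(),
                                     np.random.default_rng(0), config=config,
                                     delay_bins=4, round_counts=False)
        # rotate workspace 90 deg about Z: maps the target set onto itself
        target_rot = apply_vmr(target, 90, "CCW")
        specs_rot = []
        for s in specs:
            import dataclasses
            specs_rot.append(dataclasses.replace(s, b_vec=apply_vmr(s.b_vec, 90, "CCW")))
        dec_rot = _decoder_for(specs_rot, config)
        c2, _, _, _ = simulate_trial(0.0, target_rot, specs_rot, dec_rot,
                                     PerturbationSchedule(),
                                     np.random.default_rng(0), config=config,
                                     delay_bins=4, round_counts=False)
        np.testing.assert_allclose(c1, c2, atol=1e-8)


class TestGenerateSession:
    def test_no_learning_control(self, noiseless_session):
        s = noiseless_session
        np.testing.assert_array_equal(s.truth, 0.0)
        rot = s.trials_in_phase("rotation")
        alphas = s.trial_table["alpha_deg"].to_numpy()[rot]
        np.testing.assert_allclose(alphas, 30.0, atol=1e-6)

    def test_learning_rule_matches_scalar_iteration_oracle(self):
        """Noiseless closed loop: iterate the scalar rule as the oracle."""
        rng = np.random.default_rng(5)
        specs = _noiseless_specs(25, seed=5)
        lr, rho = 0.05, 1.0
        learning = LearningModel(learning_rate=lr, retention=rho, seed=5)
        sched = PerturbationSchedule(n_baseline=2, n_rotation=40, n_washout=0)
        s = generate_session(TaskConfig(), sched, specs, learning,
                            round_counts=False)
        aim, expected = 0.0, []
        for t in range(sched.n_trials):
            expected.append(aim)
            alpha = (30.0 + aim) if sched.phase_of(t) == "rotation" else aim
            aim = rho * aim - lr * alpha
        np.testing.assert_allclose(s.truth, expected, atol=1e-4)
        # decaying exponential toward the analytic fixed point (0 here)
        rot_alpha = s.trial_table["alpha_deg"].to_numpy()[2:]
        ratios = rot_alpha[1:] / rot_alpha[:-1]
        np.testing.assert_allclose(ratios, 1 - lr, atol=1e-3)

    def test_aim_monotone_with_full_retention(self):
        specs = _noiseless_specs(25, seed=6)
        learning = LearningModel(learning_rate=0.05, retention=1.0, seed=6)
        sched = PerturbationSchedule(n_baseline=4, n_rotation=60, n_washout=0)
        s = generate_session(TaskConfig(), sched, specs, learning,
                             round_counts=False)
        aim = s.truth[4:]
        # monotone toward the fixed point (full compensation, -30)
        assert (np.diff(aim) < 1e-9).all()
        assert aim[-1] < -25

    def test_negative_aftereffect_sign(self, adapted_session):
        s = adapted_session
        rot = s.trials_in_phase("rotation")
        wash = s.trials_in_phase("washout")[:15]
        alpha = s.trial_table["alpha_deg"].to_numpy()
        late_rot = alpha[rot[-30:]].mean()
        early_wash = alpha[wash].mean()
        assert late_rot > 0 and early_wash < 0

    def test_determinism_same_seed(self):
        rng_specs = lambda: make_population(6, "M1", True, np.random.default_rng(3))
        sched = PerturbationSchedule(n_baseline=4, n_rotation=4, n_washout=2)
        s1 = generate_session(TaskConfig(), sched, rng_specs(),
                              LearningModel(seed=9))
        s2 = generate_session(TaskConfig(), sched, rng_specs(),
                              LearningModel(seed=9))
        np.testing.assert_array_equal(s1.counts, s2.counts)
        np.testing.assert_array_equal(s1.cursor, s2.cursor)
        np.testing.assert_array_equal(s1.truth, s2.truth)
        assert s1.trial_table.equals(s2.trial_table)

    def test_noiseless_decoding_accuracy_invariant(self):
        """Noiseless well-spread population: decoded velocity reproduces the
        command to <1% per bin (oracle: the intended minimum-jerk profile)."""
        config = TaskConfig()
        specs = _noiseless_specs(40, seed=8)
        dec = _decoder_for(specs, config)
        target = make_targets(config)[6]
        _, cursor, _, ev = simulate_trial(
            0.0, target, specs, dec, PerturbationSchedule(),
            np.random.default_rng(0), config=config, round_counts=False)
        v_out = np.diff(cursor[ev["go_bin"]: ev["move_end_bin"] + 1], axis=0) / 0.05
        speed = minimum_jerk_speed(config.movement_bins, 0.05,
                                   np.linalg.norm(target), 0.7)
        v_true = np.outer(speed, target / np.linalg.norm(target))
        rel = (np.linalg.norm(v_out - v_true, axis=1)
               / np.maximum(np.linalg.norm(v_true, axis=1), 1.0))
        assert rel.max() < 0.01


class TestSerialization:
    def test_roundtrip_lossless(self, tiny_session, tmp_path):
        save_session(tiny_session, tmp_path / "sess")
        back = load_session(tmp_path / "sess")
        np.testing.assert_array_equal(back.counts, tiny_session.counts)
        np.testing.assert_array_equal(back.cursor, tiny_session.cursor)
        np.testing.assert_array_equal(back.truth, tiny_session.truth)
        assert len(back.units) == len(tiny_session.units)
        for a, b in zip(back.units, tiny_session.units):
            assert a.unit_id == b.unit_id and a.area == b.area
            np.testing.assert_allclose(a.b_vec, b.b_vec)
            assert a.reference_frame == b.reference_frame
        assert back.schedule == tiny_session.schedule
        assert back.config == tiny_session.config
        assert back.decoder is not None

    def test_canonical_serialization_byte_identical(self, tiny_session, tmp_path):
        save_session(tiny_session, tmp_path / "a")
        save_session(tiny_session, tmp_path / "b")
        for name in ("arrays.h5", "trial_table.csv", "units.csv", "config.json"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name

    def test_schema_version_checked(self, tiny_session, tmp_path):
        import json
        save_session(tiny_session, tmp_path / "s")
        cfg = json.loads((tmp_path / "s" / "config.json").read_text())
        cfg["schema_version"] = 99
        (tmp_path / "s" / "config.json").write_text(json.dumps(cfg))
        with pytest.raises(ValueError):
            load_session(tmp_path / "s")
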