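"""Generator contracts: counts, determinism, planted observables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from throwspeed import GeneratorConfig, generate_study
from throwspeed.errors import ConfigError, GenerationError
from throwspeed.synthdata import (
    THROW_TYPES,
    TYPE_SPEED_RANGES,
    features_from_truth,
    read_truth_table,
    synthesize_accel_stream,
    synthesize_throw_kinematics,
    write_truth_table,
)


class TestGenerateStudy:
    def test_default_protocol_yields_475_throws(self, study):
        assert len(study.truth) == 475
        assert len(study.participants) == 19
        assert sum(p.sex == "female" for p in study.participants) == 8
        # 25 throws per session, 5 of each type
        for session in study.sessions:
            assert len(session.truths) == 25
            types = pd.Series([t.throw_type for t in session.truths])
            assert types.value_counts().eq(5).all()

    def test_minimal_study_one_row_per_type(self):
        cfg = GeneratorConfig(n_participants=1, n_female=1, n_throws_per_type=1, seed=4)
        truth = generate_study(cfg).truth
        assert len(truth) == 5
        assert set(truth["throw_type"]) == set(THROW_TYPES)

    def test_row_count_scales_with_config(self):
        cfg = GeneratorConfig(n_participants=3, n_female=1, n_throws_per_type=2, seed=4)
        assert len(generate_study(cfg).truth) == 3 * 2 * 5

    def test_same_seed_bit_identical(self):
        a = generate_study(GeneratorConfig(seed=42)).truth
        b = generate_study(GeneratorConfig(seed=42)).truth
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_study(GeneratorConfig(seed=1)).truth
        b = generate_study(GeneratorConfig(seed=2)).truth
        assert not a["true_release_speed_mps"].equals(b["true_release_speed_mps"])

    def test_throw_order_randomised_within_session(self, study):
        orders = {tuple(t.throw_type for t in s.truths) for s in study.sessions}
        assert len(orders) > 1

    def test_full_clipping_keeps_speeds_in_type_ranges(self):
        cfg = GeneratorConfig(seed=9, clip_speeds="full")
        truth = generate_study(cfg).truth
        for ttype, (lo, hi) in TYPE_SPEED_RANGES.items():
            speeds = truth.loc[truth["throw_type"] == ttype, "true_release_speed_mps"]
            assert speeds.between(lo, hi).all()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="n_throws_per_type"):
            GeneratorConfig(n_throws_per_type=0)
        with pytest.raises(ConfigError, match="mocap_rate"):
            GeneratorConfig(mocap_rate=-1)
        with pytest.raises(ConfigError, match="residual_speed_sd"):
            GeneratorConfig(residual_speed_sd=-0.1)
        # within-type SD too small to accommodate the committed components
        with pytest.raises(ConfigError, match="within_type_speed_sd"):
            GeneratorConfig(within_type_speed_sd=1.0)

    def test_speed_distribution_matches_configured_spread(self, study):
        # overall SD is induced by the type means plus within-type SD 2.7
        assert study.truth["true_release_speed_mps"].std() == pytest.approx(4.36, abs=0.25)

    def test_truth_table_roundtrip(self, study, tmp_path):
        path = tmp_path / "truth.csv"
        write_truth_table(study.truth, path)
        back = read_truth_table(path)
        ours = study.truth.sort_values(
            ["participant_id", "release_time_s"]
        ).reset_index(drop=True)
        assert back["throw_id"].tolist() == ours["throw_id"].tolist()
        np.testing.assert_allclose(
            back["true_release_speed_mps"], ours["true_release_speed_mps"]
        )


class TestThrowKinematicsSynthesis:
    def test_markers_coincide_before_release(self, study):
        truth = study.sessions[0].truths[0]
        traj = study.trajectory(truth)
        release_frame = int(round(0.4 * traj.frame_rate))
        pre = np.linalg.norm(
            traj.ball[: release_frame - 1] - traj.hand[: release_frame - 1], axis=1
        )
        assert np.all(pre < 0.01)

    def test_distance_increase_first_exceeds_threshold_at_planted_frame(self, study):
        for truth in study.sessions[0].truths[:5]:
            traj = study.trajectory(truth)
            d = np.linalg.norm(traj.ball - traj.hand, axis=1)
            first = int(np.nonzero(np.diff(d) > 0.01)[0][0]) + 1
            assert first == int(round(0.4 * traj.frame_rate))

    def test_forward_difference_speed_at_release_is_planted(self, study):
        from throwspeed.kinematics import marker_speed

        truth = study.sessions[0].truths[0]
        traj = study.trajectory(truth)
        speeds = marker_speed(traj.ball, traj.frame_rate)
        r = int(round(0.4 * traj.frame_rate))
        assert speeds[r] == pytest.approx(truth.true_release_speed, rel=1e-9)

    def test_lowpass_changes_release_speed_below_two_percent(self, study):
        from throwspeed.kinematics import lowpass_filter, marker_speed

        truth = study.sessions[0].truths[0]
        traj = study.trajectory(truth)
        r = int(round(0.4 * traj.frame_rate))
        raw = marker_speed(traj.ball, traj.frame_rate)[r]
        filt = marker_speed(
            lowpass_filter(traj.ball, traj.frame_rate, 20.0), traj.frame_rate
        )[r]
        assert abs(filt - raw) / raw < 0.02

    def test_release_time_outside_span_raises(self, study):
        truth = dataclasses.replace(study.sessions[0].truths[0], release_time=0.1)
        with pytest.raises(GenerationError, match="span"):
            synthesize_throw_kinematics(truth, 240.0)


class TestAccelStreamSynthesis:
    def test_one_pulse_per_throw(self, study):
        from throwspeed.accel import segment_throws

        session = study.sessions[0]
        stream = study.accel_stream(session)
        assert len(segment_throws(stream)) == 25

    def test_pulse_peak_matches_planted_within_sample_error(self, study):
        from throwspeed.accel import segment_throws

        session = study.sessions[0]
        segments = segment_throws(study.accel_stream(session))
        for seg, truth in zip(segments, session.truths):
            assert seg.peak_total_accel == pytest.approx(truth.peak_total_accel, abs=1.0)

    def test_background_norm_below_tenth_of_smallest_peak(self, study):
        from throwspeed.accel import total_acceleration

        session = study.sessions[0]
        stream = study.accel_stream(session)
        norm = total_acceleration(stream.accel)
        release_times = np.array([t.release_time for t in session.truths])
        near_throw = np.zeros(len(stream), dtype=bool)
        for rt in release_times:
            near_throw |= np.abs(stream.times - rt) < 0.2
        smallest = min(t.peak_total_accel for t in session.truths)
        assert norm[~near_throw].max() < 0.1 * smallest

    def test_pulse_axis_decomposition_preserves_norm(self, study):
        # the planted peak is split across the three axes by a unit vector,
        # so the norm at the pulse centre equals the planted magnitude
        from throwspeed.accel import total_acceleration

        session = study.sessions[0]
        stream = study.accel_stream(session)
        norm = total_acceleration(stream.accel)
        truth = session.truths[0]
        idx = np.argmin(np.abs(stream.times - truth.release_time))
        assert norm[idx] == pytest.approx(truth.peak_total_accel, abs=0.2)

    def test_overlapping_pulses_raise(self, study):
        cfg = study.config
        t0 = study.sessions[0].truths[0]
        t1 = dataclasses.replace(
            t0, release_time=t0.release_time + 0.05, throw_id="x"
        )
        with pytest.raises(GenerationError, match="overlap"):
            synthesize_accel_stream(
                [t0, t1], dataclasses.replace(cfg, inter_throw_gap=3.0)
            )

    def test_stream_deterministic_for_session_seed(self, study):
        session = study.sessions[0]
        a = study.accel_stream(session)
        b = study.accel_stream(session)
        np.testing.assert_array_equal(a.accel, b.accel)


class TestNoiselessIdentifiability:
    def test_truth_features_recover_generator_coefficients_exactly(self):
        from throwspeed import fit_model

        cfg = GeneratorConfig(seed=5, residual_speed_sd=0.0, background_noise_sd=0.0)
        study = generate_study(cfg)
        fitted = fit_model(features_from_truth(study.truth), "Full")
        coef = cfg.accel_model_coefficients
        expected = {
            "intercept": coef.intercept,
            "log_peak_accel": coef.log_slope,
            "sex_male": coef.sex_male,
            "type_low_norun": coef.type_offsets["low_norun"],
            "type_med_norun": coef.type_offsets["med_norun"],
            "type_max_norun": coef.type_offsets["max_norun"],
            "type_max_run": coef.type_offsets["max_run"],
        }
        for term, value in expected.items():
            assert fitted.params[term] == pytest.approx(value, rel=1e-6, abs=1e-9)

    def test_signal_features_recover_coefficients_to_measurement_error(self):
        # the signal path adds ~0.2-0.3% speed measurement error, so the
        # noiseless recovery is exact only to that level, not 1e-6
        from throwspeed import fit_model
        from throwspeed.pipeline import RunConfig, extract_features

        cfg = RunConfig(
            seed=5,
            generator=GeneratorConfig(
                seed=5, residual_speed_sd=0.0, background_noise_sd=0.0
            ),
        )
        study = generate_study(cfg.generator)
        fitted = fit_model(extract_features(study, cfg), "Full")
        coef = cfg.generator.accel_model_coefficients
        assert fitted.params["log_peak_accel"] == pytest.approx(coef.log_slope, rel=5e-3)
        assert fitted.params["sex_male"] == pytest.approx(coef.sex_male, rel=5e-3)
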