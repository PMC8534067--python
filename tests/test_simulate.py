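"""Generator: geometry, trial kinematics, reading traces, cohorts."""

import math
from dataclasses import replace

import numpy as np
import pytest

import oculoml.simulate as sim
from conftest import noiseless


class TestVergenceAngle:
    @pytest.mark.parametrize("distance, rounded", [
        (0.40, 9), (0.20, 17), (1.50, 2),
    ])
    def test_printed_target_angles(self, distance, rounded):
        assert round(sim.vergence_angle(distance, 0.060)) == rounded

    def test_convergence_step_is_eight_degrees(self):
        step = sim.vergence_angle(0.20, 0.060) - sim.vergence_angle(0.40, 0.060)
        assert round(step) == 8

    def test_infinite_distance_gives_zero(self):
        assert sim.vergence_angle(math.inf, 0.060) == 0.0

    @pytest.mark.parametrize("d, ipd", [(0.0, 0.06), (-1.0, 0.06), (0.4, 0.0)])
    def test_non_positive_arguments_rejected(self, d, ipd):
        with pytest.raises(ValueError):
            sim.vergence_angle(d, ipd)


class TestProtocols:
    def test_vergence_protocol_composition(self, rng):
        p = sim.StimulusProtocol.vergence(rng)
        kinds = [t.kind for t in p.trials]
        assert kinds.count("convergence") == 20
        assert kinds.count("divergence") == 20
        assert all(1400 <= t.fixation_ms <= 2000 for t in p.trials)

    def test_saccade_protocol_composition(self, rng):
        p = sim.StimulusProtocol.saccade(rng)
        kinds = [t.kind for t in p.trials]
        assert kinds.count("saccade-left") == 20
        assert kinds.count("saccade-right") == 20


class TestVergenceTrial:
    def test_noiseless_convergence_ends_at_target(self, noiseless_vergence_params):
        rng = np.random.default_rng(0)
        proto = sim.StimulusProtocol.vergence(rng, n_each=1)
        trial = next(t for t in proto.trials if t.kind == "convergence")
        t, left, right, gt = sim.generate_vergence_trial(
            trial, proto, noiseless_vergence_params, rng)
        verg = left - right
        assert abs(verg[-1] - sim.vergence_angle(0.20)) < 0.01
        assert abs(verg[0] - sim.vergence_angle(0.40)) < 0.01

    def test_same_seed_gives_identical_trace(self, noiseless_vergence_params):
        proto = sim.StimulusProtocol.vergence(np.random.default_rng(3), n_each=2)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            tr, gts = sim.generate_test_trace(
                proto, sim.default_vergence_params(), rng)
            out.append((tr.left.copy(), tr.right.copy()))
        np.testing.assert_array_equal(out[0][0], out[1][0])
        np.testing.assert_array_equal(out[0][1], out[1][1])

    def test_latency_distribution_recovered(self):
        # 1000 drawn latencies: sample mean within 2 SE of configured mean
        rng = np.random.default_rng(4)
        params = sim.default_vergence_params()
        proto = sim.StimulusProtocol.vergence(rng, n_each=500)
        _, gts = sim.generate_test_trace(proto, params, rng)
        lat = np.array([g.drawn_latency_ms for g in gts])
        se = params.latency_sd_ms / math.sqrt(len(lat))
        assert abs(lat.mean() - params.latency_mean_ms) < 2 * se


class TestSaccadeTrial:
    def test_zero_disconjugacy_makes_eyes_parallel(self, noiseless_saccade_params):
        rng = np.random.default_rng(5)
        proto = sim.StimulusProtocol.saccade(rng, n_each=1)
        trial = proto.trials[0]
        t, left, right, gt = sim.generate_saccade_trial(
            trial, proto, noiseless_saccade_params, rng)
        # constant vergence offset apart, the eyes move identically
        np.testing.assert_allclose(np.diff(left), np.diff(right), atol=1e-12)

    def test_configured_disconjugacy_appears_in_trace(self):
        rng = np.random.default_rng(6)
        params = noiseless(sim.default_saccade_params, disconjugacy_deg=0.5,
                           disconjugacy_sd_deg=0.0)
        proto = sim.StimulusProtocol.saccade(rng, n_each=1)
        trial = proto.trials[0]
        t, left, right, gt = sim.generate_saccade_trial(trial, proto, params, rng)
        dl = left[-1] - left[0]
        dr = right[-1] - right[0]
        assert abs((dl - dr) - 0.5) < 0.01

    def test_blink_probability_one_flags_and_disturbs_every_trial(self):
        rng = np.random.default_rng(7)
        params = sim.default_saccade_params(blink_prob=1.0)
        proto = sim.StimulusProtocol.saccade(rng, n_each=3)
        tr, gts = sim.generate_test_trace(proto, params, rng)
        assert all(g.blink for g in gts)
        assert tr.left.min() < -20.0  # the dropout excursion is present


class TestReading:
    def test_zero_regression_probability(self):
        rng = np.random.default_rng(8)
        params = sim.ReadingParams(regression_prob=0.0)
        _, gt, _ = sim.generate_reading_trace(50, params, rng)
        assert gt.n_regressive == 0
        assert gt.n_progressive == 50

    def test_speed_is_words_over_minutes(self):
        rng = np.random.default_rng(9)
        trace, gt, speed = sim.generate_reading_trace(
            150, sim.ReadingParams(), rng)
        assert speed == pytest.approx(150 / (trace.duration_s / 60.0))

    def test_regression_rate_recovered(self):
        # 500 words at p = 0.2: empirical rate inside the binomial 95% CI
        rng = np.random.default_rng(10)
        params = sim.ReadingParams(regression_prob=0.2)
        _, gt, _ = sim.generate_reading_trace(500, params, rng)
        p_hat = gt.n_regressive / gt.n_words
        half = 1.96 * math.sqrt(0.2 * 0.8 / 500)
        assert abs(p_hat - 0.2) < half

    def test_rejects_empty_text(self):
        with pytest.raises(ValueError):
            sim.generate_reading_trace(0, sim.ReadingParams(),
                                       np.random.default_rng(0))


class TestCohort:
    def test_same_seed_gives_identical_cohort(self):
        spec = sim.CohortSpec(n_control=2, n_dyslexic=2,
                              trials_per_condition=3, n_words=30, seed=21)
        a = sim.generate_cohort(spec)
        b = sim.generate_cohort(spec)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.reading_speed == sb.reading_speed
            for test in ("vergence", "saccade", "reading"):
                np.testing.assert_array_equal(sa.traces[test].left,
                                              sb.traces[test].left)

    def test_null_effects_make_groups_exchangeable(self):
        # with zero offsets a subject's data depends on (seed, index) only
        spec = sim.CohortSpec(n_control=1, n_dyslexic=1,
                              trials_per_condition=2, n_words=20, seed=22,
                              effects=sim.GroupEffects.null())
        s_ctrl = sim.generate_subject(spec, 0, "control")
        s_dys = sim.generate_subject(spec, 0, "dyslexic")
        for test in ("vergence", "saccade", "reading"):
            np.testing.assert_array_equal(s_ctrl.traces[test].left,
                                          s_dys.traces[test].left)

    def test_zero_noise_speed_matches_linear_model(self):
        model = sim.SpeedModel(noise_sd=0.0)
        spec = sim.CohortSpec(n_control=1, n_dyslexic=1,
                              trials_per_condition=2, n_words=20, seed=23,
                              speed_model=model)
        subj = sim.generate_subject(spec, 0, "control")
        expected = model.intercept + sum(
            c * subj.true_values[k] for k, c in model.coefs.items())
        assert subj.reading_speed == pytest.approx(expected)

    def test_cohort_extensible_without_perturbing_existing_subjects(self):
        small = sim.CohortSpec(n_control=2, n_dyslexic=1,
                               trials_per_condition=2, n_words=20, seed=24)
        large = replace(small, n_control=3)
        a = sim.generate_cohort(small).subjects[0]
        b = sim.generate_cohort(large).subjects[0]
        np.testing.assert_array_equal(a.traces["saccade"].left,
                                      b.traces["saccade"].left)


class TestFeatureCohort:
    def test_deterministic(self):
        a = sim.generate_feature_cohort(5, n_features=4, seed=31)
        b = sim.generate_feature_cohort(5, n_features=4, seed=31)
        assert a.values.equals(b.values)
        assert a.speed.equals(b.speed)

    def test_planted_speed_exact_without_noise(self):
        fm = sim.generate_feature_cohort(4, n_features=3,
                                         planted_coefs={0: 2.0},
                                         speed_intercept=100.0,
                                         speed_noise_sd=0.0, seed=32)
        expected = 100.0 + 2.0 * fm.values.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(fm.speed.to_numpy(), expected)
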