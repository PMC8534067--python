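"""Event detection: channels, velocity, detectors, descriptors, reading."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oculoml.events as ev
import oculoml.simulate as sim
from conftest import noiseless

FS = 200.0


def make_trace(left, right, events=()):
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    return sim.BinocularTrace(time=np.arange(len(left)) / FS, left=left,
                              right=right, rate=FS, events=list(events))


class TestChannels:
    def test_identical_eyes(self):
        x = np.linspace(0, 5, 50)
        verg, conj = ev.derive_channels(make_trace(x, x))
        np.testing.assert_allclose(verg, 0.0)
        np.testing.assert_allclose(conj, x)

    def test_symmetric_eyes(self):
        verg, conj = ev.derive_channels(
            make_trace(np.full(10, 2.0), np.full(10, -2.0)))
        np.testing.assert_allclose(verg, 4.0)
        np.testing.assert_allclose(conj, 0.0)

    @given(st.lists(st.tuples(
        st.floats(-30, 30, allow_nan=False),
        st.floats(-30, 30, allow_nan=False)), min_size=3, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_reconstruction(self, pairs):
        left = np.array([p[0] for p in pairs])
        right = np.array([p[1] for p in pairs])
        verg, conj = ev.derive_channels(make_trace(left, right))
        np.testing.assert_allclose(conj + verg / 2.0, left, atol=1e-12)
        np.testing.assert_allclose(conj - verg / 2.0, right, atol=1e-12)


class TestVelocity:
    def test_constant_series_has_zero_velocity(self):
        v = ev.velocity(np.full(50, 3.2), FS)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_linear_ramp_exact_without_smoothing(self):
        cfg = ev.ExtractionConfig(smooth_samples=1)
        x = 10.0 * np.arange(100) / FS  # 10 deg/s
        v = ev.velocity(x, FS, cfg)
        np.testing.assert_allclose(v[1:-1], 10.0, atol=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            ev.velocity(np.array([1.0, 2.0]), FS)

    def test_saccade_peak_matches_analytic_profile(self,
                                                   noiseless_saccade_params):
        rng = np.random.default_rng(0)
        proto = sim.StimulusProtocol.saccade(rng, n_each=2)
        tr, gts = sim.generate_test_trace(proto, noiseless_saccade_params, rng)
        df = ev.extract_test_trials(tr)
        for (_, row), gt in zip(df.iterrows(), gts):
            rel = abs(row.peak_velocity_deg_s - gt.peak_velocity_deg_s) \
                / gt.peak_velocity_deg_s
            assert rel < 0.02


class TestVergenceDetector:
    def test_flat_trace_returns_none(self):
        verg = np.zeros(400)
        assert ev.detect_vergence_movement(verg, FS, (0, 400)) is None

    def test_onset_close_to_ground_truth(self, noiseless_vergence_params):
        rng = np.random.default_rng(1)
        proto = sim.StimulusProtocol.vergence(rng, n_each=2)
        tr, gts = sim.generate_test_trace(proto, noiseless_vergence_params, rng)
        verg, _ = ev.derive_channels(tr)
        for gt in gts:
            i0 = int(round(gt.target_onset_s * FS))
            seg = ev.detect_vergence_movement(verg, FS, (i0, i0 + 400))
            onset_ms = (seg.onset_s - gt.target_onset_s) * 1000.0
            assert abs(onset_ms - gt.latency_ms) < 5.0

    def test_first_of_two_movements_is_returned(self):
        # two 4-deg ramps; brute-force scan of the velocity array locates
        # the first 5 deg/s crossing independently
        t = np.arange(600) / FS
        pos = sim._ramp(t - 0.5, 4.0, 0.3) + sim._ramp(t - 1.8, 4.0, 0.3)
        cfg = ev.ExtractionConfig()
        seg = ev.detect_vergence_movement(pos, FS, (0, 600), cfg)
        speed = np.abs(ev.velocity(pos, FS, cfg))
        brute_onset = np.flatnonzero(speed >= 5.0)[0]
        assert abs(seg.onset_s * FS - brute_onset) <= 1.0
        assert seg.offset_s < 1.8  # bounded before the second movement

    def test_raising_threshold_never_gives_earlier_onset(self):
        rng = np.random.default_rng(2)
        proto = sim.StimulusProtocol.vergence(rng, n_each=3)
        tr, gts = sim.generate_test_trace(
            proto, sim.default_vergence_params(blink_prob=0.0), rng)
        verg, _ = ev.derive_channels(tr)
        for gt in gts:
            i0 = int(round(gt.target_onset_s * FS))
            onsets = []
            for thr in (5.0, 8.0, 12.0):
                cfg = ev.ExtractionConfig(vergence_velocity_threshold=thr)
                seg = ev.detect_vergence_movement(verg, FS, (i0, i0 + 400), cfg)
                if seg is not None:
                    onsets.append(seg.onset_s)
            assert onsets == sorted(onsets)


class TestSaccadeDetector:
    def test_flat_trace_returns_none(self):
        assert ev.detect_saccade(np.zeros(400), FS, (0, 400)) is None

    def test_amplitude_recovered(self, noiseless_saccade_params):
        rng = np.random.default_rng(3)
        proto = sim.StimulusProtocol.saccade(rng, n_each=2)
        tr, gts = sim.generate_test_trace(proto, noiseless_saccade_params, rng)
        _, conj = ev.derive_channels(tr)
        for gt in gts:
            i0 = int(round(gt.target_onset_s * FS))
            seg = ev.detect_saccade(conj, FS, (i0, i0 + 400))
            assert abs(seg.amplitude_deg - gt.phasic_amplitude_deg) < 0.1

    def test_forty_floor_equals_ten_percent_rule_at_peak_400(self):
        # a 20-deg profile with a 400 deg/s peak: 10% of peak = 40 deg/s,
        # so the floor rule and the fraction rule must coincide
        dur = np.pi * 20.0 / (2.0 * 400.0)
        t = np.arange(400) / FS
        pos = sim._ramp(t - 0.5, 20.0, dur)
        seg = ev.detect_saccade(pos, FS, (0, 400))
        raw = np.abs(np.gradient(pos, 1.0 / FS))
        above = np.flatnonzero(raw >= 40.0)
        assert abs(seg.onset_s * FS - above[0]) <= 1.0
        assert abs(seg.offset_s * FS - above[-1]) <= 1.0


class TestTrialDescriptors:
    def test_missing_segment_marks_trial_invalid(self):
        tr = make_trace(np.zeros(500), np.zeros(500))
        d = ev.compute_trial_descriptors(tr, None, 0.5, "convergence")
        assert not d.valid
        assert np.isnan(d.latency_ms)

    def test_identities_and_recovery(self, noiseless_vergence_params,
                                     noiseless_saccade_params):
        rng = np.random.default_rng(4)
        for kind, params, factory in (
                ("vergence", noiseless_vergence_params,
                 sim.StimulusProtocol.vergence),
                ("saccade", noiseless_saccade_params,
                 sim.StimulusProtocol.saccade)):
            proto = factory(rng, n_each=10)
            tr, gts = sim.generate_test_trace(proto, params, rng)
            df = ev.extract_test_trials(tr)
            assert df.valid.all()
            for (_, row), gt in zip(df.iterrows(), gts):
                # additivity holds exactly by construction
                assert row.total_amplitude_deg == \
                    row.phasic_amplitude_deg + row.amp160_deg
                assert row.total_duration_ms == \
                    pytest.approx(row.phasic_duration_ms + 160.0)
                assert row.avg_velocity_deg_s == pytest.approx(
                    abs(row.total_amplitude_deg)
                    / (row.total_duration_ms / 1000.0))
                assert abs(row.latency_ms - gt.latency_ms) < 5.0
                assert abs(row.phasic_amplitude_deg
                           - gt.phasic_amplitude_deg) < 0.1

    def test_zero_drift_gives_zero_drift_descriptors(self,
                                                     noiseless_saccade_params):
        rng = np.random.default_rng(5)
        proto = sim.StimulusProtocol.saccade(rng, n_each=3)
        tr, _ = sim.generate_test_trace(proto, noiseless_saccade_params, rng)
        df = ev.extract_test_trials(tr)
        assert np.all(np.abs(df.drift1_deg) < 0.02)
        assert np.all(np.abs(df.drift2_deg) < 0.02)

    def test_blink_trials_are_aberrant(self):
        rng = np.random.default_rng(6)
        params = sim.default_saccade_params(blink_prob=1.0)
        proto = sim.StimulusProtocol.saccade(rng, n_each=3)
        tr, gts = sim.generate_test_trace(proto, params, rng)
        df = ev.extract_test_trials(tr)
        assert not df.valid.any()


class TestReadingDescriptors:
    def test_counts_and_percentage(self):
        # 10 progressive + 2 regressive planted saccades -> 20%
        rng = np.random.default_rng(7)
        params = sim.ReadingParams(noise_sd_deg=0.0, regression_prob=0.0)
        trace, gt, _ = sim.generate_reading_trace(10, params, rng)
        rd = ev.compute_reading_descriptors(trace)
        assert rd.n_progressive == 10
        assert rd.n_regressive == 0

        # craft a trace with known composition via the regression draw
        params = sim.ReadingParams(noise_sd_deg=0.0, regression_prob=0.2)
        for seed in range(40):
            trace, gt, _ = sim.generate_reading_trace(
                10, params, np.random.default_rng(seed))
            if gt.n_regressive == 2:
                break
        assert gt.n_regressive == 2
        rd = ev.compute_reading_descriptors(trace)
        assert rd.n_progressive == 10
        assert rd.n_regressive == 2
        assert rd.pct_regressive == pytest.approx(20.0)

    def test_fixed_fixation_duration_recovered(self):
        # a huge gamma shape makes every fixation essentially 250 ms
        rng = np.random.default_rng(8)
        params = sim.ReadingParams(noise_sd_deg=0.0, fixation_shape=1e6,
                                   regression_prob=0.0)
        trace, _, _ = sim.generate_reading_trace(40, params, rng)
        rd = ev.compute_reading_descriptors(trace)
        assert abs(rd.fixation_durations_ms.mean() - 250.0) < 10.0

    def test_flat_trace_flagged_invalid(self):
        tr = make_trace(np.zeros(800), np.zeros(800))
        rd = ev.compute_reading_descriptors(tr)
        assert not rd.valid
        assert np.isnan(rd.pct_regressive)
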