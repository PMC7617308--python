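"""Generator tests: IBI model, waveform rendering, artifact bookkeeping."""

import numpy as np
import pytest

from biofeedbacklab import (
    BreathingPattern,
    GroundTruth,
    InjectedArtifact,
    VirtualParticipantProfile,
    generate_ibis,
    generate_study_cohort,
    render_ppg,
    render_respiration,
    respiration_summary,
)


def clean_profile(**kwargs):
    defaults = dict(rsa_gain=0.0, ibi_noise_sd=0.0, artifact_rate=0.0, seed=1)
    defaults.update(kwargs)
    return VirtualParticipantProfile(**defaults)


class TestBreathingPattern:
    def test_paced_cycle_count_and_range(self):
        pat = BreathingPattern.paced(300)
        assert pat.n_cycles == 20
        t = np.linspace(0, 299.99, 5000)
        v = pat.value(t)
        assert v.min() >= 0 and v.max() <= 1
        assert len(pat.breath_times(300)) == 20

    def test_rsa_waveform_is_centred_and_unit_amplitude(self):
        for pat in (BreathingPattern.paced(300), BreathingPattern.sinusoidal(13, 300)):
            t = np.linspace(0, pat.cycle_durations[0], 20001)[:-1]
            w = pat.rsa_waveform(t)
            assert abs(np.mean(w)) < 1e-3
            assert np.max(np.abs(w)) == pytest.approx(1.0, abs=1e-3)

    def test_attenuation_full_at_slow_pacing(self):
        assert BreathingPattern.paced(60).rsa_attenuation([1.0])[0] == 1.0
        fast = BreathingPattern.sinusoidal(15, 60).rsa_attenuation([1.0])[0]
        assert fast == pytest.approx(4.0 / 15.0, rel=1e-9)

    def test_mixture_adherence_extremes(self, rng):
        all_paced = BreathingPattern.mixture(300, 1.0, 13.0, rng)
        assert np.all(all_paced.cycle_durations == 15.0)
        none_paced = BreathingPattern.mixture(300, 0.0, 13.0, rng)
        assert not np.any(none_paced.cycle_durations == 15.0)


class TestGenerateIbis:
    def test_constant_rate_noise_free(self):
        truth = generate_ibis(clean_profile(baseline_hr=60.0), BreathingPattern.sinusoidal(13, 60), 60)
        assert len(truth.ibis_ms) == 60
        np.testing.assert_allclose(truth.ibis_ms, 1000.0)
        assert truth.true_mean_hr == pytest.approx(60.0)

    def test_mean_hr_matches_baseline(self):
        truth = generate_ibis(clean_profile(baseline_hr=78.49), BreathingPattern.sinusoidal(13, 300), 300)
        assert truth.true_mean_hr == pytest.approx(78.49, abs=1e-9)

    def test_sinusoid_rsa_sdnn_matches_closed_form(self):
        """At the 4/min reference rate a 50 ms gain gives IBIs sampled from a
        sinusoid of amplitude 50, whose SD is 50/sqrt(2)."""
        truth = generate_ibis(
            clean_profile(baseline_hr=60.0, rsa_gain=50.0), BreathingPattern.sinusoidal(4, 600), 600
        )
        brute = float(np.std(truth.ibis_ms, ddof=1))
        assert brute == pytest.approx(50.0 / np.sqrt(2), rel=0.02)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(duration=30),
            dict(duration=-5),
            dict(pattern=BreathingPattern.empty()),
        ],
    )
    def test_rejects_bad_inputs(self, bad):
        pattern = bad.get("pattern", BreathingPattern.sinusoidal(13, 300))
        with pytest.raises(ValueError):
            generate_ibis(clean_profile(), pattern, bad.get("duration", 300))

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            VirtualParticipantProfile(baseline_hr=-1)
        with pytest.raises(ValueError):
            VirtualParticipantProfile(adherence_ability=1.5)
        with pytest.raises(ValueError):
            VirtualParticipantProfile(artifact_rate=-0.1)

    def test_determinism(self):
        prof = VirtualParticipantProfile(seed=7)
        a = generate_ibis(prof, BreathingPattern.sinusoidal(13, 120), 120)
        b = generate_ibis(prof, BreathingPattern.sinusoidal(13, 120), 120)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)
        assert [(x.time, x.kind) for x in a.injected_artifacts] == [
            (x.time, x.kind) for x in b.injected_artifacts
        ]

    def test_sdnn_monotone_in_rsa_gain(self):
        sdnns = []
        for gain in (0.0, 25.0, 50.0):
            truth = generate_ibis(
                clean_profile(rsa_gain=gain), BreathingPattern.sinusoidal(4, 300), 300
            )
            sdnns.append(np.std(truth.ibis_ms, ddof=1))
        assert sdnns[0] <= sdnns[1] <= sdnns[2]
        assert sdnns[2] > sdnns[0]

    def test_slow_pacing_raises_sdnn(self):
        slow = generate_ibis(clean_profile(rsa_gain=100.0), BreathingPattern.sinusoidal(4, 300), 300)
        fast = generate_ibis(clean_profile(rsa_gain=100.0), BreathingPattern.sinusoidal(15, 300), 300)
        assert np.std(slow.ibis_ms, ddof=1) >= np.std(fast.ibis_ms, ddof=1)

    def test_beat_and_breath_times_strictly_increasing(self):
        truth = generate_ibis(VirtualParticipantProfile(seed=3), BreathingPattern.paced(300), 300)
        assert np.all(np.diff(truth.beat_times) > 0)
        assert np.all(np.diff(truth.breath_times) > 0)


class TestRenderPpg:
    def test_template_count_conservation(self):
        """Rendered templates = beats - missed + ectopic."""
        prof = VirtualParticipantProfile(seed=21, artifact_rate=2.0)
        truth = generate_ibis(prof, BreathingPattern.sinusoidal(13, 300), 300)
        trace = render_ppg(truth)
        n_missed = sum(1 for a in truth.injected_artifacts if a.kind == "missed")
        n_ectopic = sum(1 for a in truth.injected_artifacts if a.kind == "ectopic")
        assert trace.meta["n_templates"] == len(truth.beat_times) - n_missed + n_ectopic

    def test_missed_artifact_suppresses_template(self):
        beat_times = 0.5 + np.arange(60) * 1.0
        truth = GroundTruth(beat_times, [], 0.0, 60.0, [InjectedArtifact(10.5, "missed")], duration=61.0)
        trace = render_ppg(truth, noise_sd=0.0, wander_amplitude=0.0)
        t = trace.times()
        window = trace.samples[(t >= 10.0) & (t <= 11.0)]
        assert np.max(np.abs(window)) < 1e-9

    def test_empty_beats_give_flat_wander(self):
        truth = GroundTruth(np.empty(0), [], 0.0, 0.0, duration=40.0)
        trace = render_ppg(truth, noise_sd=0.0, wander_amplitude=0.1)
        assert np.max(np.abs(trace.samples)) <= 0.1 + 1e-9

    def test_rejects_overlapping_templates(self):
        truth = GroundTruth(np.array([1.0, 1.1, 2.0]), [], 0.0, 60.0, duration=10.0)
        with pytest.raises(ValueError, match="250 ms"):
            render_ppg(truth)


class TestRenderRespiration:
    def test_paced_trace_has_expected_cycle_maxima(self):
        trace = render_respiration(BreathingPattern.paced(300), 300, noise_sd=0.0)
        assert respiration_summary(trace).n_breaths == 20

    def test_spontaneous_rate_recovered(self, rng):
        pat = BreathingPattern.spontaneous(13.02, 60, rng=rng)
        trace = render_respiration(pat, 60, noise_sd=0.02, rng=rng)
        assert abs(respiration_summary(trace).n_breaths - 13) <= 1

    def test_silent_pattern_detects_no_breaths(self, rng):
        trace = render_respiration(BreathingPattern.silent(120), 120, noise_sd=0.2, rng=rng)
        summ = respiration_summary(trace)
        assert summ.n_breaths == 0 and not summ.usable

    def test_duration_must_cover_one_cycle(self):
        with pytest.raises(ValueError):
            render_respiration(BreathingPattern.paced(300), 10.0)


class TestCohort:
    def test_study2_shape(self):
        cohort = generate_study_cohort(3, "study2", seed=5, render_signals=False)
        assert len(cohort) == 6
        assert sum(r.group == "control" for r in cohort) == 3
        for rec in cohort:
            assert set(rec.sessions) == {"baseline", "intruder", "training", "stressor"}
            for session in rec.sessions.values():
                assert session.truth is not None

    def test_study1_shape(self):
        cohort = generate_study_cohort(4, "study1", seed=5, render_signals=False)
        assert len(cohort) == 4
        assert all(set(r.sessions) == {"baseline", "training", "stressor"} for r in cohort)

    def test_seed_determinism(self):
        a = generate_study_cohort(2, "study2", seed=9, render_signals=False)
        b = generate_study_cohort(2, "study2", seed=9, render_signals=False)
        for ra, rb in zip(a, b):
            assert ra.profile == rb.profile
            for cond in ra.sessions:
                np.testing.assert_array_equal(
                    ra.sessions[cond].truth.beat_times, rb.sessions[cond].truth.beat_times
                )

    def test_perfect_adherence_gives_paced_rate_exactly(self):
        cohort = generate_study_cohort(
            2, "study2", seed=3, render_signals=False,
            profile_overrides={"adherence_ability": 1.0, "stress_delta_hr": 0.0},
        )
        trained = [r for r in cohort if r.group == "trained"]
        for rec in trained:
            assert rec.sessions["stressor"].truth.true_resp_rate == pytest.approx(4.0)

    def test_matched_demographics_across_groups(self):
        cohort = generate_study_cohort(3, "study2", seed=1, render_signals=False)
        control = [r for r in cohort if r.group == "control"]
        trained = [r for r in cohort if r.group == "trained"]
        assert [r.demographics for r in control] == [r.demographics for r in trained]

    def test_rejects_tiny_group(self):
        with pytest.raises(ValueError):
            generate_study_cohort(1, "study2")
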