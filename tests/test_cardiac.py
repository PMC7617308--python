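"""Cardiac pipeline tests: detection, correction, excision, QC, HRV."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofeedbacklab import (
    BeatSeries,
    BreathingPattern,
    ExcludedRecordingError,
    InjectedArtifact,
    SignalTrace,
    VirtualParticipantProfile,
    apply_ibi_artifacts,
    correct_ibis,
    detect_ppg_peaks,
    excise_noise,
    find_noisy_spans,
    generate_ibis,
    render_ppg,
    summarize_hrv,
)

from conftest import constant_beats, interior_truth


class TestDetection:
    def test_recovers_interior_beats_exactly(self):
        truth = interior_truth(60)
        trace = render_ppg(truth, noise_sd=0.0)
        beats = detect_ppg_peaks(trace)
        assert beats.n_peaks == 60
        max_err_samples = np.max(np.abs(beats.peak_times - truth.beat_times)) * trace.sampling_rate
        assert max_err_samples <= 1.0 + 1e-9

    def test_flat_trace_excluded_not_raised(self):
        beats = detect_ppg_peaks(SignalTrace(np.zeros(75 * 60), channel="ppg"))
        assert beats.n_peaks == 0
        assert beats.qc.excluded and beats.qc.reason == "no beats"

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_ppg_peaks(SignalTrace(np.zeros(75 * 10), channel="ppg"))

    def test_noise_burst_leaves_other_beats_exact(self):
        prof = VirtualParticipantProfile(artifact_rate=0.0, seed=7)
        rng = np.random.default_rng(7)
        truth = generate_ibis(prof, BreathingPattern.spontaneous(13, 120, rng=rng), 120, rng=rng)
        truth.injected_artifacts.append(InjectedArtifact(60.0, "noise_burst"))
        trace = render_ppg(truth, noise_sd=0.0, rng=np.random.default_rng(8))
        beats = detect_ppg_peaks(trace)
        away = truth.beat_times[(np.abs(truth.beat_times - 60.0) > 2.0) & (truth.beat_times > 0.3)]
        for t0 in away:
            assert np.min(np.abs(beats.peak_times - t0)) <= 1.0 / trace.sampling_rate + 1e-9

    def test_mean_hr_matches_ground_truth(self):
        """End-to-end oracle equivalence on a clean rendered recording."""
        prof = VirtualParticipantProfile(artifact_rate=0.0, seed=11)
        rng = np.random.default_rng(11)
        truth = generate_ibis(prof, BreathingPattern.spontaneous(13, 300, rng=rng), 300, rng=rng)
        beats = detect_ppg_peaks(render_ppg(truth, noise_sd=0.0))
        hrv = summarize_hrv(correct_ibis(beats))
        assert abs(hrv.mean_hr - truth.true_mean_hr) < 0.5


class TestCorrection:
    def test_clean_series_untouched(self):
        beats = constant_beats(40)
        out = correct_ibis(beats)
        np.testing.assert_array_equal(out.ibis, beats.ibis)
        assert set(out.flags) == {"normal"}

    def test_requires_ten_ibis(self):
        with pytest.raises(ValueError):
            correct_ibis(constant_beats(5))

    def test_missed_beat_split_restores_count(self):
        ibis = np.full(40, 1000.0)
        ibis[20] = 2000.0
        beats = BeatSeries.from_peak_times(np.concatenate([[0.0], np.cumsum(ibis) / 1000]))
        out = correct_ibis(beats)
        assert len(out.ibis) == len(ibis) + 1
        assert np.max(np.abs(out.ibis - 1000.0)) < 50.0
        assert np.sum(out.flags == "corrected_missed") == 2

    def test_ectopic_pair_flagged_and_variance_reduced(self):
        ibis = np.full(40, 1000.0)
        ibis[20], ibis[21] = 700.0, 1300.0
        beats = BeatSeries.from_peak_times(np.concatenate([[0.0], np.cumsum(ibis) / 1000]))
        out = correct_ibis(beats)
        assert out.flags[20] == out.flags[21] == "corrected_ectopic"
        assert np.std(out.ibis, ddof=1) < np.std(ibis, ddof=1)
        assert len(out.ibis) == len(ibis)

    def test_long_beat_interpolated_count_preserved(self):
        ibis = np.full(40, 1000.0)
        ibis[20] = 1600.0
        out = correct_ibis(BeatSeries.from_peak_times(np.concatenate([[0.0], np.cumsum(ibis) / 1000])))
        assert len(out.ibis) == len(ibis)
        assert out.flags[20] == "corrected_long"
        assert abs(out.ibis[20] - 1000.0) < 50.0

    def test_correction_reduces_aggregate_beat_count_error(self):
        """Over 100 seeded single-artifact injections, correction strictly
        reduces the total absolute beat-count error versus ground truth
        (missed beats are restored far more often than long/ectopic beats
        are ever mistaken for them)."""
        err_before = err_after = 0
        kinds = ["missed", "long", "ectopic"]
        for i in range(100):
            rng = np.random.default_rng(4000 + i)
            prof = VirtualParticipantProfile(artifact_rate=0.0, seed=i)
            pat = BreathingPattern.spontaneous(13, 300, rng=rng)
            truth = generate_ibis(prof, pat, 300, rng=rng)
            n = len(truth.beat_times)
            pos = int(rng.integers(20, n - 20))
            art = InjectedArtifact(truth.beat_times[pos], kinds[i % 3])
            modified = apply_ibi_artifacts(truth.beat_times, [art])
            corrected = correct_ibis(BeatSeries.from_peak_times(modified))
            err_before += abs(len(modified) - n)
            err_after += abs(corrected.n_peaks - n)
        assert err_after < err_before
        assert err_after <= 5  # near-perfect recovery in aggregate


class TestExcision:
    def test_no_spans_is_identity(self):
        beats = constant_beats(40)
        out = excise_noise(beats, [])
        np.testing.assert_array_equal(out.ibis, beats.ibis)
        assert out.qc.n_noisy_regions == 0

    def test_five_beat_span_bookkeeping(self):
        beats = constant_beats(40)  # peaks at 0..40 s
        out = excise_noise(beats, [(9.5, 14.5)])  # covers peaks 10..14, i.e. 5 beats
        assert out.qc.n_noisy_regions == 1
        hrv = summarize_hrv(out)
        assert hrv.n_beats == beats.n_peaks - 5

    def test_small_span_warns_and_noops(self):
        beats = constant_beats(40)
        with pytest.warns(UserWarning):
            out = excise_noise(beats, [(10.2, 12.8)])  # 3 beats only
        assert out.qc.n_noisy_regions == 0
        assert not np.any(out.flags == "excised")

    def test_four_regions_exclude_record(self):
        beats = constant_beats(60)
        spans = [(5.5, 10.5), (15.5, 20.5), (25.5, 30.5), (35.5, 40.5)]
        out = excise_noise(beats, spans)
        assert out.qc.n_noisy_regions == 4
        assert out.qc.excluded
        with pytest.raises(ExcludedRecordingError):
            summarize_hrv(out)

    def test_bridging_ibis_dropped_not_concatenated(self):
        beats = constant_beats(40)
        out = excise_noise(beats, [(9.5, 14.5)])
        retained = out.retained_ibis()
        assert np.max(retained) <= 1000.0 + 1e-9  # no spurious long interval

    def test_noise_burst_span_found_by_sqi(self):
        truth = interior_truth(100, ibi_s=0.8)
        truth.injected_artifacts.append(InjectedArtifact(40.0, "noise_burst"))
        trace = render_ppg(truth, noise_sd=0.005, rng=np.random.default_rng(3))
        spans = find_noisy_spans(trace)
        assert any(s <= 40.0 <= e for s, e in spans)


class TestSummary:
    def test_constant_series(self):
        hrv = summarize_hrv(constant_beats(40))
        assert hrv.sdnn == 0.0 and hrv.cvsdnn == 0.0
        assert hrv.mean_hr == pytest.approx(60.0)

    def test_toy_series_arithmetic(self):
        beats = BeatSeries.from_peak_times(np.concatenate([[0.0], np.cumsum([800, 850, 900]) / 1000]))
        hrv = summarize_hrv(beats)
        assert hrv.mean_ibi == pytest.approx(850.0)
        assert hrv.sdnn == pytest.approx(50.0)
        assert hrv.cvsdnn == pytest.approx(100 * 50 / 850, abs=1e-10)
        assert hrv.cvsdnn == pytest.approx(5.8824, abs=1e-4)
        assert hrv.mean_hr == pytest.approx(60000 / 850)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=30, deadline=None)
    def test_cvsdnn_scale_invariance(self, k):
        base = np.array([800.0, 850.0, 900.0, 820.0, 880.0])
        a = BeatSeries.from_peak_times(np.concatenate([[0.0], np.cumsum(base) / 1000]))
        b = BeatSeries.from_peak_times(np.concatenate([[0.0], np.cumsum(base * k) / 1000]))
        assert summarize_hrv(a).cvsdnn == pytest.approx(summarize_hrv(b).cvsdnn, rel=1e-9)

    def test_needs_two_retained_ibis(self):
        with pytest.raises(ValueError):
            summarize_hrv(BeatSeries.from_peak_times([0.0, 1.0]))

    def test_refuses_excluded(self):
        beats = constant_beats(40)
        beats.qc.total_unreliable_s = 100.0
        beats.qc.update()
        with pytest.raises(ExcludedRecordingError):
            summarize_hrv(beats)
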