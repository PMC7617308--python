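import numpy as np
import pytest

from biofeedbacklab import BeatSeries, GroundTruth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def constant_beats(n_ibis: int = 40, ibi_ms: float = 1000.0) -> BeatSeries:
    """A clean constant-rate beat series."""
    ibis = np.full(n_ibis, ibi_ms)
    peaks = np.concatenate([[0.0], np.cumsum(ibis) / 1000.0])
    return BeatSeries.from_peak_times(peaks)


def interior_truth(n_beats: int, ibi_s: float = 0.8, start: float = 0.5) -> GroundTruth:
    """Ground truth with all beats away from the trace edges."""
    beat_times = start + np.arange(n_beats) * ibi_s
    return GroundTruth(
        beat_times=beat_times,
        breath_times=np.empty(0),
        true_resp_rate=0.0,
        true_mean_hr=60.0 / ibi_s,
        duration=float(beat_times[-1] + 1.0),
    )
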