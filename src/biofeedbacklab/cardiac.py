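"""PPG beat extraction, artifact correction, QC and time-domain HRV.

The HRV statistic of interest is SDNN (sample standard deviation of
interbeat intervals) together with its heart-rate-corrected form

    cvSDNN = 100 * SDNN / mean IBI,

a coefficient of variation that removes the mechanical dependence of SDNN
on heart rate.  Both are always computed from the same segment, so each
condition's SDNN is adjusted by that condition's own mean IBI.

Quality control follows two rules: a recording is excluded when more than
60 s of it shows unreliable peak detection, or when more than three
independent noisy regions had to be excised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signals import PPG, SignalTrace

FLAG_NORMAL = "normal"
FLAG_MISSED = "corrected_missed"
FLAG_LONG = "corrected_long"
FLAG_ECTOPIC = "corrected_ectopic"
FLAG_EXCISED = "excised"

#: QC thresholds: >60 s unreliable, or >3 excised regions, excludes a record
MAX_UNRELIABLE_S = 60.0
MAX_NOISY_REGIONS = 3

#: spans must cover more than this many beats to be excisable
MIN_EXCISABLE_BEATS = 3


class ExcludedRecordingError(RuntimeError):
    """Raised when metrics are requested from a QC-excluded recording."""


@dataclass
class QCReport:
    total_unreliable_s: float = 0.0
    n_noisy_regions: int = 0
    excised_spans: list = field(default_factory=list)
    excluded: bool = False
    reason: str = ""

    def update(self) -> None:
        """Apply the exclusion rule; preserves any earlier hard exclusion."""
        if self.total_unreliable_s > MAX_UNRELIABLE_S:
            self.excluded = True
            self.reason = f"unreliable peak detection for {self.total_unreliable_s:.1f} s (>60 s)"
        elif self.n_noisy_regions > MAX_NOISY_REGIONS:
            self.excluded = True
            self.reason = f"{self.n_noisy_regions} noisy regions excised (>3)"


def qc_excluded(total_unreliable_s: float, n_noisy_regions: int) -> bool:
    """The bare exclusion rule: >60 s unreliable or >3 excised regions."""
    return total_unreliable_s > MAX_UNRELIABLE_S or n_noisy_regions > MAX_NOISY_REGIONS


@dataclass
class BeatSeries:
    """Detected pulse peaks, their IBIs and per-IBI audit flags."""

    peak_times: np.ndarray
    ibis: np.ndarray  # ms
    flags: np.ndarray  # one flag per IBI
    source_condition: str | None = None
    qc: QCReport = field(default_factory=QCReport)

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        if len(self.peak_times) > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")
        if len(self.flags) != len(self.ibis):
            raise ValueError("need one flag per IBI")

    @classmethod
    def from_peak_times(cls, peak_times, condition: str | None = None) -> "BeatSeries":
        peak_times = np.asarray(peak_times, dtype=float)
        ibis = np.diff(peak_times) * 1000.0
        return cls(peak_times, ibis, np.full(len(ibis), FLAG_NORMAL, dtype=object), condition)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)

    def retained_ibis(self) -> np.ndarray:
        return self.ibis[self.flags != FLAG_EXCISED]

    def retained_peak_count(self) -> int:
        """Peaks outside all excised spans."""
        if not self.qc.excised_spans:
            return self.n_peaks
        keep = np.ones(self.n_peaks, dtype=bool)
        for start, end in self.qc.excised_spans:
            keep &= ~((self.peak_times >= start) & (self.peak_times <= end))
        return int(keep.sum())


@dataclass
class HRVSummary:
    mean_hr: float
    mean_ibi: float
    sdnn: float
    cvsdnn: float
    n_beats: int
    qc: QCReport = field(default_factory=QCReport)


# ---------------------------------------------------------------------- #
# peak detection
# ---------------------------------------------------------------------- #


def detect_ppg_peaks(trace: SignalTrace, min_separation_s: float = 0.25) -> BeatSeries:
    """Detect systolic peaks in a PPG trace.

    Band-pass (0.5-8 Hz, zero phase) then local-maximum search with a 250 ms
    minimum separation; each candidate is refined to the local maximum of
    the raw signal so peak times are sample-exact on clean traces.  A flat
    or degenerate trace yields zero peaks and a QC exclusion rather than an
    exception.  Seconds not bracketed by plausible beats (gaps longer than
    ``max(2 s, 2.5 x median IBI)``, including the leading and trailing ends)
    count toward the unreliable-signal total.
    """
    if trace.channel != PPG:
        raise ValueError("detect_ppg_peaks requires a PPG trace")
    if trace.duration < 30:
        raise ValueError("trace must be at least 30 s long")

    x = trace.samples
    fs = trace.sampling_rate
    qc = QCReport()
    if np.ptp(x) < 1e-12:
        qc.total_unreliable_s = trace.duration
        qc.excluded = True
        qc.reason = "no beats"
        return BeatSeries(np.empty(0), np.empty(0), np.empty(0, dtype=object), trace.condition, qc)

    sos = sps.butter(3, [0.5, min(8.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    xf = sps.sosfiltfilt(sos, x)
    lo, hi = np.percentile(xf, [2.5, 97.5])
    prominence = 0.3 * (hi - lo) / 2.0
    if prominence <= 0:
        qc.total_unreliable_s = trace.duration
        qc.excluded = True
        qc.reason = "no beats"
        return BeatSeries(np.empty(0), np.empty(0), np.empty(0, dtype=object), trace.condition, qc)

    peaks, _ = sps.find_peaks(xf, distance=max(1, int(min_separation_s * fs)), prominence=prominence)
    if len(peaks) >= 3:
        # reject filter edge transients: real systolic peaks have comparable
        # filtered amplitude, edge artifacts are much weaker
        amps = xf[peaks]
        peaks = peaks[amps >= 0.5 * np.median(amps)]
    # refine to the raw local maximum so clean traces are sample-exact
    refined = []
    r = max(1, int(round(0.05 * fs)))
    for p in peaks:
        lo_i, hi_i = max(0, p - r), min(len(x), p + r + 1)
        refined.append(lo_i + int(np.argmax(x[lo_i:hi_i])))
    refined = np.unique(np.asarray(refined, dtype=int))
    peak_times = refined / fs

    if len(peak_times) == 0:
        qc.total_unreliable_s = trace.duration
        qc.excluded = True
        qc.reason = "no beats"
        return BeatSeries(np.empty(0), np.empty(0), np.empty(0, dtype=object), trace.condition, qc)

    edges = np.concatenate([[0.0], peak_times, [trace.duration]])
    gaps = np.diff(edges)
    median_ibi = float(np.median(np.diff(peak_times))) if len(peak_times) > 1 else trace.duration
    gap_limit = max(2.0, 2.5 * median_ibi)
    qc.total_unreliable_s = float(gaps[gaps > gap_limit].sum())
    qc.update()

    series = BeatSeries.from_peak_times(peak_times, trace.condition)
    series.qc = qc
    return series


def find_noisy_spans(
    trace: SignalTrace,
    highpass_hz: float = 15.0,
    rms_window_s: float = 0.5,
    threshold_factor: float = 6.0,
    merge_gap_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Signal-quality index: spans where high-frequency power is anomalous.

    The rolling RMS of the >15 Hz residual is compared with its own median;
    windows exceeding ``threshold_factor`` times the median are flagged and
    merged into spans.  This is the automated analogue of visually marking
    noisy periods for excision.
    """
    fs = trace.sampling_rate
    if highpass_hz >= fs / 2:
        return []
    sos = sps.butter(3, highpass_hz, btype="highpass", fs=fs, output="sos")
    resid = sps.sosfiltfilt(sos, trace.samples)
    w = max(1, int(rms_window_s * fs))
    power = pd.Series(resid**2).rolling(w, center=True, min_periods=1).mean().to_numpy()
    rms = np.sqrt(power)
    floor = np.median(rms)
    if floor <= 0:
        return []
    noisy = rms > threshold_factor * floor
    spans: list[tuple[float, float]] = []
    idx = np.flatnonzero(noisy)
    if len(idx) == 0:
        return []
    start = idx[0]
    prev = idx[0]
    gap = int(merge_gap_s * fs)
    for i in idx[1:]:
        if i - prev > gap:
            spans.append((start / fs, prev / fs))
            start = i
        prev = i
    spans.append((start / fs, prev / fs))
    return spans


# ---------------------------------------------------------------------- #
# artifact correction
# ---------------------------------------------------------------------- #


def _rolling_median(values: np.ndarray, window: int = 21) -> np.ndarray:
    """Centred rolling median of the IBI series.

    The default window (21 beats, roughly three breathing cycles at rest)
    is deliberately wider than one respiratory cycle so the local baseline
    does not ride the respiratory sinus arrhythmia phase -- a narrow window
    under- or over-states the expected IBI near RSA peaks and troughs,
    which misclassifies artifact intervals sized against the typical beat.
    """
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def correct_ibis(
    beats: BeatSeries,
    missed_factor: float = 1.75,
    long_factor: float = 1.5,
    ectopic_short: float = 0.8,
    ectopic_long: float = 1.2,
) -> BeatSeries:
    """Detect and repair missed, long and ectopic beats in an IBI series.

    Against a centred rolling median ``m``: an alternating short-long (or
    long-short) pair whose sum is near ``2 m`` is an ectopic displacement
    and both intervals are replaced by their mean; an isolated interval
    above ``missed_factor * m`` is a missed beat and is split in two; an
    interval above ``long_factor * m`` is a long beat and is replaced by the
    local median.  All repairs are flagged for audit.  If more than half the
    intervals needed repair the series is marked excluded.
    """
    n = len(beats.ibis)
    if n < 10:
        raise ValueError("need at least 10 IBIs to correct")
    m = _rolling_median(beats.ibis)
    out_ibis: list[float] = []
    out_flags: list[str] = []
    ib = beats.ibis
    fl = beats.flags
    k = 0
    while k < n:
        ibi, mk = ib[k], m[k]
        if fl[k] == FLAG_EXCISED:
            out_ibis.append(ibi)
            out_flags.append(FLAG_EXCISED)
            k += 1
            continue
        pair_ok = False
        if k + 1 < n and fl[k + 1] != FLAG_EXCISED:
            nxt, mn = ib[k + 1], m[k + 1]
            alternating = (ibi < ectopic_short * mk and nxt > ectopic_long * mn) or (
                ibi > ectopic_long * mk and nxt < ectopic_short * mn
            )
            if alternating and abs((ibi + nxt) - (mk + mn)) < 0.3 * (mk + mn):
                mean_pair = (ibi + nxt) / 2.0
                out_ibis += [mean_pair, mean_pair]
                out_flags += [FLAG_ECTOPIC, FLAG_ECTOPIC]
                k += 2
                pair_ok = True
        if pair_ok:
            continue
        if ibi > missed_factor * mk:
            half = ibi / 2.0
            out_ibis += [half, half]
            out_flags += [FLAG_MISSED, FLAG_MISSED]
        elif ibi > long_factor * mk:
            out_ibis.append(mk)
            out_flags.append(FLAG_LONG)
        else:
            out_ibis.append(ibi)
            out_flags.append(fl[k])
        k += 1

    new_ibis = np.asarray(out_ibis)
    new_flags = np.asarray(out_flags, dtype=object)
    anchor = beats.peak_times[0] if beats.n_peaks else 0.0
    new_peaks = anchor + np.concatenate([[0.0], np.cumsum(new_ibis) / 1000.0])
    qc = QCReport(
        total_unreliable_s=beats.qc.total_unreliable_s,
        n_noisy_regions=beats.qc.n_noisy_regions,
        excised_spans=list(beats.qc.excised_spans),
        excluded=beats.qc.excluded,
        reason=beats.qc.reason,
    )
    n_flagged = int(np.sum((new_flags != FLAG_NORMAL) & (new_flags != FLAG_EXCISED)))
    if n_flagged > 0.5 * len(new_flags):
        qc.excluded = True
        qc.reason = f"{n_flagged}/{len(new_flags)} IBIs required correction (>50%)"
    qc.update()
    return BeatSeries(new_peaks, new_ibis, new_flags, beats.source_condition, qc)


def excise_noise(beats: BeatSeries, spans: list[tuple[float, float]]) -> BeatSeries:
    """Remove noisy spans from the series, mirroring manual excision.

    Only spans covering more than three beats are removable; smaller spans
    are ignored with a warning.  IBIs with either endpoint inside an applied
    span are flagged ``excised`` (so intervals bridging an excision are
    dropped rather than concatenated into spurious long intervals).  Each
    applied span counts as one noisy region toward the QC rule.
    """
    qc = QCReport(
        total_unreliable_s=beats.qc.total_unreliable_s,
        n_noisy_regions=beats.qc.n_noisy_regions,
        excised_spans=list(beats.qc.excised_spans),
        excluded=beats.qc.excluded,
        reason=beats.qc.reason,
    )
    flags = beats.flags.copy()
    for start, end in spans:
        if end <= start:
            raise ValueError("span end must exceed start")
        inside = (beats.peak_times >= start) & (beats.peak_times <= end)
        if int(inside.sum()) <= MIN_EXCISABLE_BEATS:
            warnings.warn(
                f"span ({start:.1f}, {end:.1f}) covers <= {MIN_EXCISABLE_BEATS} beats; not excised",
                stacklevel=2,
            )
            continue
        for k in range(len(beats.ibis)):
            t0, t1 = beats.peak_times[k], beats.peak_times[k + 1]
            if (start <= t0 <= end) or (start <= t1 <= end):
                flags[k] = FLAG_EXCISED
        qc.n_noisy_regions += 1
        qc.excised_spans.append((float(start), float(end)))
    qc.update()
    return BeatSeries(beats.peak_times.copy(), beats.ibis.copy(), flags, beats.source_condition, qc)


# ---------------------------------------------------------------------- #
# summary
# ---------------------------------------------------------------------- #


def summarize_hrv(beats: BeatSeries) -> HRVSummary:
    """Mean HR, mean IBI, SDNN and cvSDNN over the retained IBIs.

    SDNN uses the sample (n-1) standard deviation.  cvSDNN is computed from
    the same segment's mean IBI, which is what makes it a per-condition
    heart-rate adjustment.  Refuses QC-excluded series.
    """
    if beats.qc.excluded:
        raise ExcludedRecordingError(f"recording excluded by QC: {beats.qc.reason}")
    retained = beats.retained_ibis()
    if len(retained) < 2:
        raise ValueError("need at least 2 retained IBIs")
    mean_ibi = float(np.mean(retained))
    sdnn = float(np.std(retained, ddof=1))
    return HRVSummary(
        mean_hr=60000.0 / mean_ibi,
        mean_ibi=mean_ibi,
        sdnn=sdnn,
        cvsdnn=100.0 * sdnn / mean_ibi,
        n_beats=beats.retained_peak_count(),
        qc=beats.qc,
    )
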