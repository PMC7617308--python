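"""Virtual-participant cardiorespiratory signal generator.

The generator produces interbeat-interval (IBI) series whose variability is
driven by respiratory sinus arrhythmia (RSA), renders them into PPG-like
pulse trains and respiration-belt traces, and injects the artifact types the
cardiac correction pipeline is designed to repair (missed, long and ectopic
beats, and noise bursts).  Ground truth -- beat times, breath times and the
injected artifacts -- is retained alongside every rendered trace so that
every downstream measurement can be tested against what was actually
simulated.

The IBI model is

    IBI_i = 60000 / HR_base + g_eff(t_i) * w(phi_i) + eps_i        [ms]

where ``w`` is the mean-centred unit-amplitude breathing waveform at the
beat's breathing phase, ``eps_i`` is i.i.d. Gaussian noise with SD
``ibi_noise_sd``, and ``g_eff = rsa_gain * min(1, cycle_period / 15 s)`` is
the RSA gain attenuated for breathing faster than the 4/min paced reference
(see :mod:`biofeedbacklab.patterns`).  Beat times are cumulative sums of the
IBIs starting from a beat at t = 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .patterns import BreathingPattern
from .signals import PPG, RESPIRATION, SignalTrace

ARTIFACT_KINDS = ("missed", "long", "ectopic", "noise_burst")

#: resolution of the tabulated RSA waveform used inside the beat loop
_RSA_GRID_DT = 1.0 / 16.0

#: half-width of the pulse template suppression window for missed-beat
#: artifacts, seconds
_MISSED_WINDOW_S = 0.5


@dataclass(frozen=True)
class VirtualParticipantProfile:
    """Population and per-participant parameters of the virtual cohort.

    Defaults encode a healthy adult cohort at rest: baseline heart rate
    78.49 bpm with a between-subject SD of 11.00 bpm, spontaneous breathing
    at 13.02 breaths/min, a stressor-induced elevation of 6.57 bpm
    (85.06 - 78.49), an RSA gain of 150 ms (half the peak-to-trough IBI
    swing under deep slow pacing), 50 ms of beat-to-beat IBI noise, and 0.4
    recording artifacts per minute.
    """

    baseline_hr: float = 78.49
    hr_between_subject_sd: float = 11.00
    rsa_gain: float = 150.0
    stress_delta_hr: float = 6.57
    adherence_ability: float = 0.85
    baseline_resp_rate: float = 13.02
    ibi_noise_sd: float = 50.0
    artifact_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hr <= 0:
            raise ValueError("baseline_hr must be positive")
        if not 0.0 <= self.adherence_ability <= 1.0:
            raise ValueError("adherence_ability must lie in [0, 1]")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")
        if self.ibi_noise_sd < 0 or self.rsa_gain < 0:
            raise ValueError("rsa_gain and ibi_noise_sd must be non-negative")

    def replace(self, **kwargs) -> "VirtualParticipantProfile":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class InjectedArtifact:
    time: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")


@dataclass
class GroundTruth:
    """What was actually simulated for one session."""

    beat_times: np.ndarray
    breath_times: np.ndarray
    true_resp_rate: float
    true_mean_hr: float
    injected_artifacts: list[InjectedArtifact] = field(default_factory=list)
    duration: float = 0.0

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.breath_times = np.asarray(self.breath_times, dtype=float)
        for name, arr in (("beat_times", self.beat_times), ("breath_times", self.breath_times)):
            if len(arr) > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def ibis_ms(self) -> np.ndarray:
        return np.diff(self.beat_times) * 1000.0

    def to_dict(self) -> dict:
        return {
            "beat_times": self.beat_times.tolist(),
            "breath_times": self.breath_times.tolist(),
            "true_resp_rate": self.true_resp_rate,
            "true_mean_hr": self.true_mean_hr,
            "injected_artifacts": [[a.time, a.kind] for a in self.injected_artifacts],
            "duration": self.duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            beat_times=np.asarray(d["beat_times"]),
            breath_times=np.asarray(d["breath_times"]),
            true_resp_rate=d["true_resp_rate"],
            true_mean_hr=d["true_mean_hr"],
            injected_artifacts=[InjectedArtifact(t, k) for t, k in d.get("injected_artifacts", [])],
            duration=d.get("duration", 0.0),
        )


# ---------------------------------------------------------------------- #
# IBI generation
# ---------------------------------------------------------------------- #


def generate_ibis(
    profile: VirtualParticipantProfile,
    resp_pattern: BreathingPattern,
    duration: float,
    rng: np.random.Generator | None = None,
    base_hr: float | None = None,
) -> GroundTruth:
    """Simulate a beat sequence coupled to a breathing pattern.

    Parameters
    ----------
    profile : VirtualParticipantProfile
        RSA gain, IBI noise and artifact rate; ``profile.seed`` seeds the
        generator when ``rng`` is not supplied.
    resp_pattern : BreathingPattern
        The breathing pattern whose phase modulates the IBIs.
    duration : float
        Session length in seconds (at least 60 s).
    base_hr : float, optional
        Overrides ``profile.baseline_hr`` (used for stressor sessions).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < 60:
        raise ValueError("duration must be at least 60 s")
    if resp_pattern.n_cycles == 0:
        raise ValueError("breathing pattern is empty")
    rng = rng if rng is not None else np.random.default_rng(profile.seed)
    hr = base_hr if base_hr is not None else profile.baseline_hr
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    base_ibi = 60000.0 / hr

    # tabulate the RSA modulation (gain * attenuation * waveform) once;
    # the beat loop linearly interpolates it
    grid_t = np.arange(0.0, duration + 4 * _RSA_GRID_DT, _RSA_GRID_DT)
    if profile.rsa_gain > 0:
        mod = profile.rsa_gain * resp_pattern.rsa_attenuation(grid_t) * resp_pattern.rsa_waveform(grid_t)
    else:
        mod = np.zeros_like(grid_t)

    n_max = int(duration / (base_ibi / 1000.0) * 1.6) + 16
    if profile.ibi_noise_sd > 0:
        eps = rng.normal(0.0, profile.ibi_noise_sd, n_max)
    else:
        eps = np.zeros(n_max)

    mod_list = mod.tolist()
    eps_list = eps.tolist()
    inv_dt = 1.0 / _RSA_GRID_DT
    beats = [0.0]
    ibis = []
    t = 0.0
    k = 0
    while True:
        x = t * inv_dt
        i = int(x)
        fr = x - i
        w = mod_list[i] + fr * (mod_list[i + 1] - mod_list[i])
        ibi = base_ibi + w + eps_list[k]
        if ibi < 300.0:  # physiological floor (200 bpm)
            ibi = 300.0
        t_next = t + ibi / 1000.0
        if t_next > duration + 1e-9:
            break
        beats.append(t_next)
        ibis.append(ibi)
        t = t_next
        k += 1

    beat_times = np.asarray(beats)
    breath_times = resp_pattern.breath_times(duration)
    artifacts = _draw_artifacts(profile, beat_times, duration, rng)
    mean_ibi = float(np.mean(ibis)) if ibis else base_ibi
    return GroundTruth(
        beat_times=beat_times,
        breath_times=breath_times,
        true_resp_rate=60.0 * len(breath_times) / duration,
        true_mean_hr=60000.0 / mean_ibi,
        injected_artifacts=artifacts,
        duration=float(duration),
    )


def _draw_artifacts(
    profile: VirtualParticipantProfile,
    beat_times: np.ndarray,
    duration: float,
    rng: np.random.Generator,
) -> list[InjectedArtifact]:
    """Poisson artifact placement, snapped to beats where the kind needs it."""
    if profile.artifact_rate == 0 or len(beat_times) < 20:
        return []
    n = rng.poisson(profile.artifact_rate * duration / 60.0)
    artifacts: list[InjectedArtifact] = []
    used_times: list[float] = []
    median_ibi_s = float(np.median(np.diff(beat_times)))
    for _ in range(n):
        kind = ARTIFACT_KINDS[rng.integers(len(ARTIFACT_KINDS))]
        for _attempt in range(20):
            if kind == "noise_burst":
                t = float(rng.uniform(5.0, duration - 5.0))
            else:
                idx = int(rng.integers(5, len(beat_times) - 5))
                t = float(beat_times[idx])
                if kind == "ectopic":
                    t -= 0.35 * median_ibi_s
            if all(abs(t - u) > 5.0 for u in used_times):
                used_times.append(t)
                artifacts.append(InjectedArtifact(t, kind))
                break
    artifacts.sort(key=lambda a: a.time)
    return artifacts


def apply_ibi_artifacts(
    beat_times: np.ndarray, artifacts: list[InjectedArtifact], rng: np.random.Generator | None = None
) -> np.ndarray:
    """Realise beat-level artifacts directly on a beat-time series.

    ``missed`` deletes the nearest beat; ``long`` delays the nearest beat and
    all later beats by 0.6 of the typical (median) IBI, producing one
    prolonged interval; ``ectopic`` advances the nearest beat by 0.3 of the
    typical IBI (a short-long pair).  Magnitudes are defined against the
    median interval so the injected artifact always belongs to its own
    class -- a "long beat" sized from a single noisy interval can come out
    anywhere between a normal and a fully missed beat.  ``noise_burst`` has
    no beat-level effect.  Used by inject-and-recover tests of the
    correction pipeline.
    """
    times = np.asarray(beat_times, dtype=float).copy()
    typical = float(np.median(np.diff(times)))
    for art in artifacts:
        if art.kind == "noise_burst":
            continue
        idx = int(np.argmin(np.abs(times - art.time)))
        idx = min(max(idx, 2), len(times) - 3)
        if art.kind == "missed":
            times = np.delete(times, idx)
        elif art.kind == "long":
            times[idx:] += 0.6 * typical
        elif art.kind == "ectopic":
            times[idx] -= 0.3 * typical
    return times


# ---------------------------------------------------------------------- #
# waveform rendering
# ---------------------------------------------------------------------- #


def _pulse_template(sampling_rate: float) -> tuple[np.ndarray, int]:
    """Asymmetric unimodal pulse: 100 ms half-cosine rise, 200 ms decay.

    Returns the template and the index of its peak sample.
    """
    rise = max(2, int(round(0.1 * sampling_rate)))
    decay = max(3, int(round(0.2 * sampling_rate)))
    up = 0.5 - 0.5 * np.cos(np.pi * np.arange(rise + 1) / rise)
    down = 0.5 + 0.5 * np.cos(np.pi * np.arange(1, decay + 1) / decay)
    return np.concatenate([up, down]), rise


def render_ppg(
    truth: GroundTruth,
    sampling_rate: float = 75.0,
    noise_sd: float = 0.01,
    wander_amplitude: float = 0.1,
    rng: np.random.Generator | None = None,
    condition: str | None = None,
) -> SignalTrace:
    """Render a PPG-like trace: one pulse template per beat plus wander/noise.

    Injected artifacts are realised here: ``missed`` suppresses the template
    nearest the artifact time, ``ectopic`` adds an extra early template,
    ``long`` displaces the nearest template late by 0.6 of the median IBI,
    and ``noise_burst`` overlays 2 s of high-variance noise.  The realised
    template times are stored in ``trace.meta["template_times"]``.
    """
    if sampling_rate < 25:
        raise ValueError("sampling_rate must be at least 25 Hz")
    ibis = np.diff(truth.beat_times)
    if len(ibis) and np.min(ibis) < 0.25:
        raise ValueError("implausible IBI < 250 ms: pulse templates would overlap")
    rng = rng if rng is not None else np.random.default_rng(0)

    duration = truth.duration
    if duration <= 0:
        duration = (truth.beat_times[-1] + 1.0) if len(truth.beat_times) else 10.0
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate

    template_times = list(truth.beat_times)
    for art in truth.injected_artifacts:
        if art.kind == "missed" and template_times:
            idx = int(np.argmin(np.abs(np.asarray(template_times) - art.time)))
            if abs(template_times[idx] - art.time) <= _MISSED_WINDOW_S:
                template_times.pop(idx)
        elif art.kind == "ectopic":
            template_times.append(art.time)
        elif art.kind == "long" and template_times:
            idx = int(np.argmin(np.abs(np.asarray(template_times) - art.time)))
            shift = 0.6 * (float(np.median(ibis)) if len(ibis) else 0.8)
            template_times[idx] += shift
    template_times.sort()

    samples = np.zeros(n)
    tpl, peak_idx = _pulse_template(sampling_rate)
    for bt in template_times:
        center = int(round(bt * sampling_rate))
        lo = center - peak_idx
        hi = lo + len(tpl)
        src_lo = max(0, -lo)
        src_hi = len(tpl) - max(0, hi - n)
        if src_lo < src_hi:
            samples[lo + src_lo : lo + src_hi] += tpl[src_lo:src_hi]

    samples += wander_amplitude * np.sin(2 * np.pi * 0.05 * t)
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, n)
    for art in truth.injected_artifacts:
        if art.kind == "noise_burst":
            mask = (t >= art.time - 1.0) & (t <= art.time + 1.0)
            samples[mask] += rng.normal(0.0, 0.5, int(mask.sum()))

    return SignalTrace(
        samples,
        sampling_rate,
        channel=PPG,
        condition=condition,
        meta={"template_times": template_times, "n_templates": len(template_times)},
    )


def render_respiration(
    pattern: BreathingPattern,
    duration: float,
    sampling_rate: float = 75.0,
    noise_sd: float = 0.0,
    drift_amplitude: float = 0.02,
    rng: np.random.Generator | None = None,
    condition: str | None = None,
) -> SignalTrace:
    """Render a belt-like respiration trace with slow drift and noise."""
    if pattern.n_cycles == 0:
        raise ValueError("breathing pattern is empty")
    if duration < float(pattern.cycle_durations[0]):
        raise ValueError("duration must cover at least one breath cycle")
    rng = rng if rng is not None else np.random.default_rng(0)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    samples = pattern.value(t) + drift_amplitude * np.sin(2 * np.pi * 0.005 * t)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, n)
    return SignalTrace(samples, sampling_rate, channel=RESPIRATION, condition=condition)
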