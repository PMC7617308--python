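"""Virtual study cohorts.

Two designs are generated:

* ``study1`` -- a single group (baseline, training, stressor): everyone is
  trained and applies the paced technique under stress with their own
  adherence level.
* ``study2`` -- matched control and trained groups (baseline, intruder,
  training, stressor): the trained group breathes the paced 5-5-5 pattern
  during the stressor with per-cycle probability equal to their adherence,
  controls breathe spontaneously; both groups receive the stressor heart
  rate elevation.  The control group's "training" slot is a quiet rest of
  the same length, mirroring the dummy-baseline session of the design.

Between-subject draws use the population means and SDs of the default
profile (baseline HR 78.49 / SD 11.00 bpm; spontaneous respiration
13.02 / SD 4.92 breaths/min; stressor HR elevation 6.57 bpm).  Control and
trained participants with the same index are matched on demographics
(age, gender, trait anxiety), mirroring matched recruitment.
"""

from __future__ import annotations

import numpy as np

from .cardiac import BeatSeries
from .patterns import BreathingPattern
from .records import GROUP_CONTROL, GROUP_STUDY1, GROUP_TRAINED, ParticipantRecord, SessionData
from .respiration import TRAINED_RATE, RespSummary
from .synthetic import VirtualParticipantProfile, generate_ibis, render_ppg, render_respiration

DESIGNS = ("study1", "study2")

#: session lengths in seconds: 5 min baseline/intruder recordings, ~5 min
#: (study1) or ~3.5 min (study2) training games, 10 min stressor
SESSION_DURATIONS = {
    "study1": {"baseline": 300.0, "training": 300.0, "stressor": 600.0},
    "study2": {"baseline": 300.0, "intruder": 300.0, "training": 220.0, "stressor": 600.0},
}

#: heart-rate elevation during the passive intruder scene, bpm
INTRUDER_DELTA_HR = 4.0
#: relative speed-up of spontaneous breathing under the intruder stress
INTRUDER_RESP_FACTOR = 1.15
#: small spontaneous slowing controls show in the stressor, breaths/min
CONTROL_STRESSOR_RESP_DROP = 1.5

_POP = VirtualParticipantProfile()  # population defaults


def _draw_profile(rng: np.random.Generator, seed: int, overrides: dict) -> VirtualParticipantProfile:
    def pick(name, sampler):
        return overrides[name] if name in overrides else sampler()

    hr = pick("baseline_hr", lambda: float(np.clip(rng.normal(_POP.baseline_hr, _POP.hr_between_subject_sd), 50, 110)))
    resp = pick("baseline_resp_rate", lambda: float(np.clip(rng.normal(_POP.baseline_resp_rate, 4.92), 6, 24)))
    adherence = pick("adherence_ability", lambda: float(np.clip(rng.normal(_POP.adherence_ability, 0.10), 0.3, 1.0)))
    delta = pick("stress_delta_hr", lambda: float(np.clip(rng.normal(_POP.stress_delta_hr, 4.0), -2, 20)))
    return VirtualParticipantProfile(
        baseline_hr=hr,
        hr_between_subject_sd=_POP.hr_between_subject_sd,
        rsa_gain=overrides.get("rsa_gain", _POP.rsa_gain),
        stress_delta_hr=delta,
        adherence_ability=adherence,
        baseline_resp_rate=resp,
        ibi_noise_sd=overrides.get("ibi_noise_sd", _POP.ibi_noise_sd),
        artifact_rate=overrides.get("artifact_rate", _POP.artifact_rate),
        seed=seed,
    )


def _session_plan(design: str, group: str, profile: VirtualParticipantProfile, durations: dict):
    """(condition, pattern factory, heart rate) per session, in order."""
    paced = profile.adherence_ability
    resp = profile.baseline_resp_rate
    hr = profile.baseline_hr
    plan = []

    def spont(rate, dur):
        return lambda rng: BreathingPattern.spontaneous(rate, dur, rng=rng)

    def mix(dur):
        return lambda rng: BreathingPattern.mixture(dur, paced, resp, rng)

    plan.append(("baseline", spont(resp, durations["baseline"]), hr))
    if design == "study2":
        plan.append(("intruder", spont(resp * INTRUDER_RESP_FACTOR, durations["intruder"]), hr + INTRUDER_DELTA_HR))
    trains = mix(durations["training"]) if group != GROUP_CONTROL else spont(resp, durations["training"])
    plan.append(("training", trains, hr))
    if group == GROUP_CONTROL:
        stress_pattern = spont(max(resp - CONTROL_STRESSOR_RESP_DROP, 5.0), durations["stressor"])
    else:
        stress_pattern = mix(durations["stressor"])
    plan.append(("stressor", stress_pattern, hr + profile.stress_delta_hr))
    return plan


def _truth_metrics(session: SessionData) -> None:
    """Fill metrics straight from ground truth (no waveform round trip)."""
    truth = session.truth
    session.beats = BeatSeries.from_peak_times(truth.beat_times, session.condition)
    rate = truth.true_resp_rate
    session.resp_summary = RespSummary(rate, TRAINED_RATE - rate, len(truth.breath_times), True, truth.breath_times)


def generate_study_cohort(
    n_per_group: int,
    design: str = "study2",
    seed: int = 0,
    render_signals: bool = True,
    profile_overrides: dict | None = None,
    ppg_noise_sd: float = 0.01,
    resp_noise_sd: float = 0.03,
) -> list[ParticipantRecord]:
    """Generate a full virtual cohort with ground truth for every session.

    With ``render_signals=True`` each session carries PPG and belt traces to
    be pushed through the measurement pipelines; with ``False`` the sessions
    carry BeatSeries/breath counts taken directly from ground truth, which
    is the fast path used for many-replicate statistical checks.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    overrides = profile_overrides or {}
    durations = SESSION_DURATIONS[design]
    groups = [GROUP_STUDY1] if design == "study1" else [GROUP_CONTROL, GROUP_TRAINED]

    root = np.random.SeedSequence(seed)
    demo_seq, *group_seqs = root.spawn(1 + len(groups))
    demo_rng = np.random.default_rng(demo_seq)
    # one demographics draw per index: study2 pairs are matched across groups
    demographics = [
        {
            "age": int(np.clip(round(demo_rng.normal(25, 5)), 18, 40)),
            "gender": str(demo_rng.choice(["female", "male", "nonbinary"], p=[0.48, 0.48, 0.04])),
            "trait_anxiety": float(np.round(demo_rng.normal(38.0, 8.5), 1)),
        }
        for _ in range(n_per_group)
    ]

    records: list[ParticipantRecord] = []
    for group, gseq in zip(groups, group_seqs):
        for i, pseq in enumerate(gseq.spawn(n_per_group)):
            rng = np.random.default_rng(pseq)
            pseed = int(pseq.generate_state(1)[0] % (2**31))
            profile = _draw_profile(rng, pseed, overrides)
            record = ParticipantRecord(
                participant_id=f"{group}_{i:03d}", group=group, demographics=dict(demographics[i]), profile=profile
            )
            for condition, make_pattern, hr in _session_plan(design, group, profile, durations):
                dur = durations[condition]
                pattern = make_pattern(rng)
                truth = generate_ibis(profile, pattern, dur, rng=rng, base_hr=hr)
                session = SessionData(condition=condition, duration=dur, truth=truth)
                if render_signals:
                    session.ppg = render_ppg(truth, noise_sd=ppg_noise_sd, rng=rng, condition=condition)
                    session.resp = render_respiration(
                        pattern, dur, noise_sd=resp_noise_sd, rng=rng, condition=condition
                    )
                else:
                    _truth_metrics(session)
                record.sessions[condition] = session
            records.append(record)
    return records
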