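"""Deterministic re-implementation of the stressor game's real-time logic.

The game maps the rolling 30-beat mean heart rate onto a bounded stress
index via a logistic curve centred on the participant's training heart
rate::

    C           = 2 * ln(3) * (RefBPM - BPM) / RangeBPM
    StressScore = 1 / (exp(C) + 1)

so the score is 0.5 at RefBPM, 0.9 at RefBPM + RangeBPM and 0.1 at
RefBPM - RangeBPM.  The score drives a three-light display (green below
0.41, amber from 0.41, red from 0.778; "reaching" a threshold escalates,
so comparisons are >=).  Being in the red state at one of five prespecified
session times triggers an early "death" unless deaths are disabled.

The boat-speed mapping of the training game is also reproduced, including
the documented coding error: speed = mean HR + 50, so the boat sped up with
heart rate instead of slowing down.  The reconstructed intended mapping
(``as_intended``) mirrors HR around the reference before adding the
constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cardiac import BeatSeries

GREEN, AMBER, RED = "green", "amber", "red"

TWO_LN_3 = 2.0 * math.log(3.0)

#: RangeBPM values the experimenter UI allows
ALLOWED_RANGE_BPM = tuple(range(5, 101, 5))

DEFAULT_DEATH_TIMES = (100.0, 200.0, 300.0, 400.0, 500.0)


@dataclass(frozen=True)
class BiofeedbackParams:
    """Engine configuration.

    ``ref_bpm`` is the mean BPM of the participant's most recent training
    session; ``range_bpm`` scales the sigmoid (25 in the first study, 15 in
    the second).  ``death_times`` are the five prespecified session times at
    which a red light is fatal; they default to evenly spaced times over a
    10-minute session.
    """

    ref_bpm: float
    range_bpm: float = 25.0
    amber_threshold: float = 0.41
    red_threshold: float = 0.778
    window_beats: int = 30
    death_times: tuple = DEFAULT_DEATH_TIMES
    session_duration: float = 600.0
    death_enabled: bool = True
    boat_constant: float = 50.0
    boat_direction: str = "as_implemented"

    def __post_init__(self) -> None:
        if self.ref_bpm <= 0:
            raise ValueError("ref_bpm must be positive")
        if self.range_bpm not in ALLOWED_RANGE_BPM:
            raise ValueError(f"range_bpm must be one of {ALLOWED_RANGE_BPM}")
        if not 0 < self.amber_threshold < self.red_threshold < 1:
            raise ValueError("thresholds must satisfy 0 < amber < red < 1")
        if len(self.death_times) != 5:
            raise ValueError("exactly five death times are required")
        if self.boat_direction not in ("as_implemented", "as_intended"):
            raise ValueError("boat_direction must be 'as_implemented' or 'as_intended'")


@dataclass
class StressTimeline:
    """Per-beat engine output for one stressor session."""

    beat_times: np.ndarray
    rolling_bpm: np.ndarray
    c_values: np.ndarray
    stress_scores: np.ndarray
    lights: np.ndarray
    died: bool = False
    death_time: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_time_s": self.beat_times,
                "rolling_bpm": self.rolling_bpm,
                "c_value": self.c_values,
                "stress_score": self.stress_scores,
                "light": self.lights,
                "died": np.full(len(self.beat_times), self.died),
            }
        )


def rolling_bpm(beats: BeatSeries, window_beats: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Rolling mean BPM over the last ``window_beats`` IBIs, per beat.

    Before the window fills, all IBIs so far are used (expanding warm-up).
    Returns (beat_times, bpm), one value per beat from the second beat on.
    Empty input gives empty output.
    """
    ibis = np.asarray(beats.ibis, dtype=float)
    if len(ibis) == 0:
        return np.empty(0), np.empty(0)
    csum = np.concatenate([[0.0], np.cumsum(ibis)])
    k = np.arange(1, len(ibis) + 1)
    lo = np.maximum(0, k - window_beats)
    mean_ibi = (csum[k] - csum[lo]) / (k - lo)
    return beats.peak_times[1:], 60000.0 / mean_ibi


def stress_score(bpm, params: BiofeedbackParams):
    """The game's sigmoid stress index; returns ``(C, score)``.

    Vectorised over ``bpm``.  The score is strictly increasing in BPM and
    symmetric about ``ref_bpm`` (score(ref + d) + score(ref - d) = 1).
    """
    bpm = np.asarray(bpm, dtype=float)
    c = TWO_LN_3 * (params.ref_bpm - bpm) / params.range_bpm
    score = 1.0 / (np.exp(c) + 1.0)
    if bpm.ndim == 0:
        return float(c), float(score)
    return c, score


def light_state(score: float, params: BiofeedbackParams) -> str:
    """Green/amber/red classification; thresholds are inclusive (>=)."""
    if score >= params.red_threshold:
        return RED
    if score >= params.amber_threshold:
        return AMBER
    return GREEN


def light_states(scores: np.ndarray, params: BiofeedbackParams) -> np.ndarray:
    out = np.full(len(scores), GREEN, dtype=object)
    out[scores >= params.amber_threshold] = AMBER
    out[scores >= params.red_threshold] = RED
    return out


def run_session(beats: BeatSeries, params: BiofeedbackParams) -> StressTimeline:
    """Run the per-beat engine over a session's beats.

    With deaths enabled, a red light at the beat nearest one of the five
    prespecified death times truncates the timeline there; with deaths
    disabled the timeline always spans the full session.
    """
    times, bpm = rolling_bpm(beats, params.window_beats)
    c, scores = stress_score(bpm, params) if len(bpm) else (np.empty(0), np.empty(0))
    lights = light_states(scores, params)
    timeline = StressTimeline(times, bpm, c, scores, lights)
    if params.death_enabled and len(times):
        for dt in sorted(params.death_times):
            idx = int(np.argmin(np.abs(times - dt)))
            if lights[idx] == RED:
                end = idx + 1
                return StressTimeline(
                    times[:end], bpm[:end], c[:end], scores[:end], lights[:end],
                    died=True, death_time=float(times[idx]),
                )
    return timeline


def boat_speed(mean_hr: float, params: BiofeedbackParams) -> float:
    """Training-game boat speed for a session's mean HR.

    ``as_implemented`` reproduces the shipped (erroneous) positive mapping
    ``HR + 50``; ``as_intended`` is the documented reconstruction of the
    planned inverse mapping, ``max(0, 2*ref - HR) + 50``.
    """
    if mean_hr < 0:
        raise ValueError("mean_hr must be non-negative")
    if params.boat_direction == "as_implemented":
        return mean_hr + params.boat_constant
    return max(0.0, 2.0 * params.ref_bpm - mean_hr) + params.boat_constant


def find_light_boundary(
    params: BiofeedbackParams, boundary: str = "green_amber", tol: float = 1e-12
) -> tuple[float, float]:
    """Bisection on BPM through score-then-classify; returns (bpm, score).

    Locates the BPM at which the light classifier first leaves the lower
    state, then reports the stress score there.  Used to verify that the
    display thresholds sit exactly at the documented score values.
    """
    if boundary == "green_amber":
        above = lambda bpm: light_state(stress_score(bpm, params)[1], params) != GREEN
    elif boundary == "amber_red":
        above = lambda bpm: light_state(stress_score(bpm, params)[1], params) == RED
    else:
        raise ValueError("boundary must be 'green_amber' or 'amber_red'")
    lo = params.ref_bpm - 4.0 * params.range_bpm
    hi = params.ref_bpm + 4.0 * params.range_bpm
    if above(lo) or not above(hi):
        raise RuntimeError("bisection bracket does not straddle the boundary")
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if above(mid):
            hi = mid
        else:
            lo = mid
    return hi, stress_score(hi, params)[1]
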