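"""Per-participant session containers shared by the generator and pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

from .cardiac import BeatSeries, HRVSummary
from .respiration import RespSummary
from .signals import SignalTrace
from .synthetic import GroundTruth, VirtualParticipantProfile

GROUP_CONTROL = "control"
GROUP_TRAINED = "trained"
GROUP_STUDY1 = "study1"


@dataclass
class SessionData:
    """One condition's recordings and (once computed) metrics."""

    condition: str
    duration: float
    truth: GroundTruth | None = None
    ppg: SignalTrace | None = None
    resp: SignalTrace | None = None
    beats: BeatSeries | None = None
    hrv: HRVSummary | None = None
    resp_summary: RespSummary | None = None


@dataclass
class ParticipantRecord:
    """All sessions plus group assignment for one (virtual) participant."""

    participant_id: str
    group: str
    sessions: dict[str, SessionData] = field(default_factory=dict)
    demographics: dict = field(default_factory=dict)
    profile: VirtualParticipantProfile | None = None

    def __post_init__(self) -> None:
        if self.group not in (GROUP_CONTROL, GROUP_TRAINED, GROUP_STUDY1):
            raise ValueError(f"unknown group {self.group!r}")
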