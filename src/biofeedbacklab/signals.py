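"""Uniformly sampled physiological signal container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PPG = "ppg"
RESPIRATION = "respiration"

CONDITIONS = ("baseline", "training", "intruder", "stressor")


@dataclass
class SignalTrace:
    """One uniformly sampled channel (PPG or respiration belt).

    Amplitudes are in arbitrary units; the default sampling rate matches the
    75 Hz acquisition of the recording hardware the pipelines were designed
    around.
    """

    samples: np.ndarray
    sampling_rate: float = 75.0
    channel: str = PPG
    condition: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel not in (PPG, RESPIRATION):
            raise ValueError(f"unknown channel {self.channel!r}")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self.samples) / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds, starting at 0."""
        return np.arange(len(self.samples)) / self.sampling_rate
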