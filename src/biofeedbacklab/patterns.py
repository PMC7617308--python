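"""Breathing-cycle patterns: paced 5-5-5, sinusoidal, spontaneous, mixtures.

A :class:`BreathingPattern` is a sequence of breath cycles, each with a start
time, a duration and a waveform shape.  It provides three views used by the
rest of the package:

* ``value(t)`` -- belt-like amplitude in [0, 1], used to render the
  respiration channel;
* ``rsa_waveform(t)`` -- the same waveform mean-centred per shape and scaled
  to unit amplitude, used to modulate interbeat intervals (respiratory sinus
  arrhythmia);
* ``rsa_attenuation(t)`` -- a per-cycle vagal low-pass factor
  ``min(1, cycle_duration / 15 s)``: breathing at or below the 4/min paced
  rate receives the full RSA gain, faster breathing is attenuated in
  proportion to frequency.  This reproduces the physiological observation
  that slow paced breathing maximises heart-rate variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Cycle period of the 4 breaths/min slow-paced reference (5 s inhale,
#: 5 s hold, 5 s exhale).  RSA gain is not attenuated at or below this rate.
RSA_REFERENCE_PERIOD_S = 15.0

KIND_FLAT = 0
KIND_SIN = 1
KIND_PACED = 2


@dataclass
class BreathingPattern:
    """A piecewise sequence of breath cycles.

    Attributes
    ----------
    cycle_starts, cycle_durations : arrays, seconds
        Start time and length of each cycle; the first cycle starts at 0.
    cycle_kinds : int array
        Shape code per cycle (flat / sinusoidal / paced ramp-hold-ramp).
    paced_fractions : (float, float, float)
        Inhale/hold/exhale fractions of a paced cycle (default equal thirds,
        i.e. 5-5-5 for a 15 s cycle).
    """

    cycle_starts: np.ndarray
    cycle_durations: np.ndarray
    cycle_kinds: np.ndarray
    paced_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        self.cycle_starts = np.asarray(self.cycle_starts, dtype=float)
        self.cycle_durations = np.asarray(self.cycle_durations, dtype=float)
        self.cycle_kinds = np.asarray(self.cycle_kinds, dtype=int)
        if not (len(self.cycle_starts) == len(self.cycle_durations) == len(self.cycle_kinds)):
            raise ValueError("cycle arrays must have equal length")
        if np.any(self.cycle_durations <= 0):
            raise ValueError("cycle durations must be positive")

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #

    @classmethod
    def paced(
        cls,
        duration: float,
        inhale_s: float = 5.0,
        hold_s: float = 5.0,
        exhale_s: float = 5.0,
    ) -> "BreathingPattern":
        """Strictly periodic paced pattern (default 5-5-5, 4 breaths/min)."""
        cycle = inhale_s + hold_s + exhale_s
        n = max(1, int(np.ceil(duration / cycle - 1e-9)))
        starts = np.arange(n) * cycle
        fr = (inhale_s / cycle, hold_s / cycle, exhale_s / cycle)
        return cls(starts, np.full(n, cycle), np.full(n, KIND_PACED), fr)

    @classmethod
    def sinusoidal(cls, rate_per_min: float, duration: float) -> "BreathingPattern":
        """Periodic sinusoidal breathing at a fixed rate."""
        if rate_per_min <= 0:
            raise ValueError("rate_per_min must be positive")
        cycle = 60.0 / rate_per_min
        n = max(1, int(np.ceil(duration / cycle - 1e-9)))
        return cls(np.arange(n) * cycle, np.full(n, cycle), np.full(n, KIND_SIN))

    @classmethod
    def spontaneous(
        cls,
        rate_per_min: float,
        duration: float,
        cycle_cv: float = 0.08,
        rng: np.random.Generator | None = None,
    ) -> "BreathingPattern":
        """Quiet breathing with mildly jittered cycle lengths."""
        if rate_per_min <= 0:
            raise ValueError("rate_per_min must be positive")
        rng = rng if rng is not None else np.random.default_rng(0)
        mean_cycle = 60.0 / rate_per_min
        starts, durations = [], []
        t = 0.0
        while t < duration - 1e-9:
            d = mean_cycle * (1.0 + cycle_cv * rng.standard_normal())
            d = max(d, 0.5 * mean_cycle)
            starts.append(t)
            durations.append(d)
            t += d
        return cls(np.array(starts), np.array(durations), np.full(len(starts), KIND_SIN))

    @classmethod
    def mixture(
        cls,
        duration: float,
        adherence: float,
        spontaneous_rate: float,
        rng: np.random.Generator,
        paced_cycle: tuple[float, float, float] = (5.0, 5.0, 5.0),
        cycle_cv: float = 0.08,
    ) -> "BreathingPattern":
        """Per-cycle Bernoulli mixture of paced and spontaneous breathing.

        At the start of each cycle the virtual participant follows the paced
        pattern with probability ``adherence``, otherwise breathes one
        spontaneous cycle.  This is the generator's model of imperfect
        adherence to the trained technique.
        """
        if not 0.0 <= adherence <= 1.0:
            raise ValueError("adherence must lie in [0, 1]")
        paced_len = float(sum(paced_cycle))
        spont_len = 60.0 / spontaneous_rate
        fr = tuple(s / paced_len for s in paced_cycle)
        starts, durations, kinds = [], [], []
        t = 0.0
        while t < duration - 1e-9:
            if rng.random() < adherence:
                d, k = paced_len, KIND_PACED
            else:
                d = max(0.5 * spont_len, spont_len * (1.0 + cycle_cv * rng.standard_normal()))
                k = KIND_SIN
            starts.append(t)
            durations.append(d)
            kinds.append(k)
            t += d
        return cls(np.array(starts), np.array(durations), np.array(kinds), fr)

    @classmethod
    def silent(cls, duration: float) -> "BreathingPattern":
        """Zero-amplitude pattern (belt signal is pure noise/drift)."""
        return cls(np.array([0.0]), np.array([max(duration, 1.0)]), np.array([KIND_FLAT]))

    @classmethod
    def empty(cls) -> "BreathingPattern":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=int))

    # ------------------------------------------------------------------ #
    # geometry
    # ------------------------------------------------------------------ #

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_starts)

    @property
    def duration(self) -> float:
        if self.n_cycles == 0:
            return 0.0
        return float(self.cycle_starts[-1] + self.cycle_durations[-1])

    def _locate(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cycle index and within-cycle fraction for each time."""
        idx = np.searchsorted(self.cycle_starts, t, side="right") - 1
        idx = np.clip(idx, 0, self.n_cycles - 1)
        frac = (t - self.cycle_starts[idx]) / self.cycle_durations[idx]
        return idx, np.clip(frac, 0.0, 1.0 - 1e-12)

    def _paced_value(self, frac: np.ndarray) -> np.ndarray:
        fi, fh, _ = self.paced_fractions
        up = frac < fi
        hold = (frac >= fi) & (frac < fi + fh)
        out = np.where(up, frac / fi, np.where(hold, 1.0, (1.0 - frac) / max(1e-12, 1.0 - fi - fh)))
        return out

    def value(self, t) -> np.ndarray:
        """Belt amplitude in [0, 1] at time(s) ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.n_cycles == 0:
            return np.zeros_like(t)
        idx, frac = self._locate(t)
        kinds = self.cycle_kinds[idx]
        out = np.zeros_like(t)
        sin_mask = kinds == KIND_SIN
        out[sin_mask] = 0.5 * (1.0 - np.cos(2 * np.pi * frac[sin_mask]))
        paced_mask = kinds == KIND_PACED
        out[paced_mask] = self._paced_value(frac[paced_mask])
        return out

    def rsa_waveform(self, t) -> np.ndarray:
        """Mean-centred, unit-amplitude breathing waveform for RSA coupling.

        Sinusoidal cycles give ``-cos(2*pi*frac)`` (amplitude exactly 1);
        paced cycles give the centred ramp-hold-ramp rescaled so its largest
        excursion is 1.  Flat cycles contribute 0.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.n_cycles == 0:
            return np.zeros_like(t)
        idx, frac = self._locate(t)
        kinds = self.cycle_kinds[idx]
        out = np.zeros_like(t)
        sin_mask = kinds == KIND_SIN
        out[sin_mask] = -np.cos(2 * np.pi * frac[sin_mask])
        paced_mask = kinds == KIND_PACED
        if np.any(paced_mask):
            fi, fh, fe = self.paced_fractions
            mean = fi / 2 + fh + fe / 2
            scale = max(mean, 1.0 - mean)
            out[paced_mask] = (self._paced_value(frac[paced_mask]) - mean) / scale
        return out

    def rsa_attenuation(self, t) -> np.ndarray:
        """Vagal low-pass factor ``min(1, cycle_duration / 15 s)`` per cycle."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.n_cycles == 0:
            return np.zeros_like(t)
        idx, _ = self._locate(t)
        return np.minimum(1.0, self.cycle_durations[idx] / RSA_REFERENCE_PERIOD_S)

    def breath_times(self, duration: float | None = None) -> np.ndarray:
        """One inspiratory-peak time per non-flat cycle, optionally clipped."""
        if self.n_cycles == 0:
            return np.empty(0)
        fi, fh, _ = self.paced_fractions
        offsets = np.where(
            self.cycle_kinds == KIND_PACED, (fi + fh / 2) * self.cycle_durations, 0.5 * self.cycle_durations
        )
        peaks = self.cycle_starts + offsets
        peaks = peaks[self.cycle_kinds != KIND_FLAT]
        if duration is not None:
            peaks = peaks[peaks < duration]
        return peaks

    def mean_rate_per_min(self, duration: float | None = None) -> float:
        """Breaths per minute implied by the cycle structure."""
        d = duration if duration is not None else self.duration
        if d <= 0:
            return 0.0
        return 60.0 * len(self.breath_times(d)) / d
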