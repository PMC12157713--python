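"""Ventilator-synchronized breath sampling: pressure simulation and detection.

The collection hardware watches the pressure in the ventilator's expiratory
line: exhalation starts when pressure drops below a user-set threshold and
ends when it rises back above it, and the sampling valve fills the Nalophan
bag only during detected exhalations.  This module simulates the pressure
signal (pressure-control ventilation looks like a PIP/PEEP square wave) and
implements the threshold detector and bag-fill accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PressureTrace",
    "BreathSegment",
    "simulate_pressure_trace",
    "detect_exhalations",
    "fill_bag",
]


@dataclass
class PressureTrace:
    """Expiratory-line pressure samples with the user-set detection threshold."""

    times: np.ndarray  # s, uniform grid
    pressure: np.ndarray  # cmH2O
    threshold: float  # cmH2O

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if len(self.times) != len(self.pressure):
            raise ValueError("times and pressure lengths differ")
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass
class BreathSegment:
    """One detected exhalation interval."""

    start_s: float
    end_s: float
    exhaled_volume: float = 0.0  # liters, simulation bookkeeping
    truncated: bool = False  # open at trace end, closed artificially

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("segment start must precede end")


def simulate_pressure_trace(
    rate_bpm: float,
    insp_frac: float,
    pip: float,
    peep: float,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 50.0,
) -> PressureTrace:
    """Square-wave pressure-control trace: PIP in inspiration, PEEP in expiration.

    Additive Gaussian noise with SD ``noise_sd``; reproducible per seed.
    The stored detection threshold defaults to midway between PEEP and PIP.
    """
    if duration_s <= 0 or rate_bpm <= 0:
        raise ValueError("duration and rate must be positive")
    if not 0 < insp_frac < 1:
        raise ValueError("insp_frac must be in (0, 1)")
    if not pip > peep >= 0:
        raise ValueError("need pip > peep >= 0")
    times = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    period = 60.0 / rate_bpm
    phase = np.mod(times, period) / period
    pressure = np.where(phase < insp_frac, float(pip), float(peep))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pressure = pressure + rng.normal(0.0, noise_sd, size=len(times))
    return PressureTrace(times, pressure, threshold=(pip + peep) / 2.0)


def detect_exhalations(p: PressureTrace, debounce: int = 2) -> list[BreathSegment]:
    """Threshold-crossing exhalation detector.

    A segment opens at the first sample strictly below the threshold that
    follows a sample at/above it (trace assumed to start "not exhaling"),
    and closes at the next sample at/above the threshold.  ``debounce``
    requires that many consecutive samples past the crossing before the
    state flips, rejecting noise spikes; the segment boundary is still the
    first sample of the run.  A segment still open at trace end is closed
    at the last sample and flagged ``truncated``.
    """
    if len(p.times) == 0:
        raise ValueError("empty trace")
    if debounce < 1:
        raise ValueError("debounce must be >= 1")
    below = p.pressure < p.threshold
    segments: list[BreathSegment] = []
    in_exh = False
    start = 0.0
    n = len(p.times)
    i = 0
    while i < n:
        if not in_exh:
            if below[i] and np.all(below[i : min(i + debounce, n)]):
                in_exh = True
                start = float(p.times[i])
        else:
            if not below[i] and not np.any(below[i : min(i + debounce, n)]):
                segments.append(BreathSegment(start, float(p.times[i])))
                in_exh = False
        i += 1
    if in_exh:
        end = float(p.times[-1])
        if end > start:
            segments.append(BreathSegment(start, end, truncated=True))
    return segments


def fill_bag(
    segments: list[BreathSegment], tidal_volume_l: float, bag_volume_l: float
) -> tuple[int, bool]:
    """How many exhalations fill the bag.

    Returns ``(n_breaths_used, filled)``: ``ceil(bag/tidal)`` breaths if
    enough detected exhalations exist, otherwise all of them with
    ``filled=False``.
    """
    if tidal_volume_l <= 0 or bag_volume_l <= 0:
        raise ValueError("volumes must be positive")
    needed = math.ceil(bag_volume_l / tidal_volume_l)
    if len(segments) >= needed:
        return needed, True
    return len(segments), False
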