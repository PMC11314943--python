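"""Clutter suppression and range-profile extraction.

An IR-UWB radar frame is a 2D matrix of received intensity: fast-time rows
(range bins, one per distance slice) by slow-time columns (successive
pulses).  Static returns — furniture, the bed, the walls — are constant
along slow time, so subtracting each range bin's slow-time mean removes
them while retaining anything that fluctuates pulse to pulse (residual
body motion, noise).  A 1D intensity profile per radar then feeds the
spatial echo-map generation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RadarFrame", "IntensityProfile", "clutter_suppress", "extract_profile"]


@dataclass
class RadarFrame:
    """One radar's raw frame: ``values[n, m]`` with range bin n, pulse m."""

    values: np.ndarray  # (n_bins, n_pulses)
    radar_id: str
    bin_length: float  # metres

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("frame values must be 2D (n_bins, n_pulses)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame contains non-finite values")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_pulses(self) -> int:
        return self.values.shape[1]


@dataclass
class IntensityProfile:
    """Non-negative reflected intensity per range bin for one radar."""

    values: np.ndarray  # (n_bins,)
    radar_id: str
    bin_length: float  # metres

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("profile must be 1D")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def clutter_suppress(frame: RadarFrame) -> RadarFrame:
    """Remove static clutter by per-bin slow-time mean subtraction.

    Each range bin's mean over the pulse axis is subtracted from that
    bin's series, exactly cancelling any component constant across slow
    time.  The output has zero slow-time mean in every bin, which also
    makes the operation idempotent.
    """
    if frame.n_pulses < 2:
        raise ValueError(
            "clutter suppression needs >= 2 pulses; on a single pulse the "
            "mean subtraction would null the signal"
        )
    out = frame.values - frame.values.mean(axis=1, keepdims=True)
    return replace(frame, values=out)


def extract_profile(frame: RadarFrame, method: str = "envelope", t: int | None = None) -> IntensityProfile:
    """Collapse a (clutter-suppressed) frame to a 1D intensity profile.

    method='column' takes the magnitude of a single slow-time column
    (default: the last pulse); method='envelope' takes the per-bin RMS
    over slow time, which is more robust to per-pulse fluctuation.
    """
    if method == "column":
        idx = frame.n_pulses - 1 if t is None else t
        if not (-frame.n_pulses <= idx < frame.n_pulses):
            raise IndexError(f"slow-time index {idx} out of range for {frame.n_pulses} pulses")
        prof = np.abs(frame.values[:, idx])
    elif method == "envelope":
        prof = np.sqrt(np.mean(frame.values**2, axis=1))
    else:
        raise ValueError(f"unknown profile method {method!r}")
    return IntensityProfile(values=prof, radar_id=frame.radar_id, bin_length=frame.bin_length)
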