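"""Core data containers shared across the pipeline.

The containers mirror the stages of a plethysmography session analysis:
a raw pressure waveform (:class:`RespirationTrace`), the stimulus log
(:class:`TrialEvent`), the inspiration-peak train extracted from the
waveform (:class:`PeakTrain`), and the instantaneous respiratory
frequency resampled onto a uniform grid (:class:`FreqSeries`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RespirationTrace", "TrialEvent", "PeakTrain", "FreqSeries"]

VEHICLE_LABEL = "vehicle"


@dataclass
class RespirationTrace:
    """A digitized respiratory pressure waveform from one chamber.

    Parameters
    ----------
    data : ndarray
        Pressure samples in arbitrary units.
    sample_rate_hz : float
        Digitization rate (600 Hz in the reference apparatus).
    chamber_id : str
        Identifier of the plethysmograph chamber ("A"/"B" for a
        simultaneously recorded pair).
    """

    data: np.ndarray
    sample_rate_hz: float
    chamber_id: str = "A"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("trace data must be one-dimensional")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.data.size / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.size) / self.sample_rate_hz


@dataclass
class TrialEvent:
    """One stimulus presentation within a session.

    ``log10_dilution`` is ``None`` for vehicle (mineral-oil) trials.
    Times are seconds from session start; windows downstream are
    half-open ``[start, end)``.
    """

    trial_index: int
    stimulus: str
    log10_dilution: float | None
    valve_open_s: float
    duration_s: float = 6.0

    @property
    def is_vehicle(self) -> bool:
        return self.log10_dilution is None

    def __post_init__(self) -> None:
        if self.valve_open_s < 0:
            raise ValueError("valve_open_s must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass
class PeakTrain:
    """Strictly increasing inspiration-peak times for one trace."""

    peak_times_s: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.peak_times_s.size > 1 and np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.peak_times_s.size)


@dataclass
class FreqSeries:
    """Instantaneous respiratory frequency on a uniform grid.

    ``values`` hold the frequency in Hz; samples outside the span of the
    peak train are invalid (``valid`` False, value NaN).  The grid starts
    at t = 0 of the source trace and runs at ``rate_hz`` (100 Hz by
    convention).
    """

    values: np.ndarray
    rate_hz: float = 100.0
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask must match values shape")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate_hz

    def __len__(self) -> int:
        return int(self.values.size)
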