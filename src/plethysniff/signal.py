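"""Respiratory signal chain: common-noise rejection, band-pass filtering,
inspiration-peak detection and instantaneous-frequency estimation.

The chain reproduces a standard semi-automated plethysmography analysis:
each chamber's pressure signal is cleaned of noise shared with the
simultaneously recorded partner chamber, band-passed 1-15 Hz (2nd-order
Butterworth, zero-phase), segmented into respiratory cycles at upward
zero crossings, and reduced to one inspiration peak per cycle.  The
reciprocal inter-peak interval, treated as a step function of time, is
then sampled onto a uniform 100 Hz grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .types import FreqSeries, PeakTrain, RespirationTrace

__all__ = [
    "FilterSpec",
    "common_noise_reject",
    "bandpass",
    "detect_peaks",
    "instantaneous_frequency",
]

log = logging.getLogger(__name__)

#: Relative amplitude gate for cycle peaks, in units of the MAD of the
#: filtered trace.  Sub-threshold wiggles (noise-split cycles) fall well
#: below this; genuine sniff cycles, whose harmonics are removed by the
#: 15 Hz cut-off, stay well above it.
PEAK_GATE_MAD = 0.5


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification for the respiratory band."""

    low_hz: float = 1.0
    high_hz: float = 15.0
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("require 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate_rate(self, sample_rate_hz: float) -> None:
        if self.high_hz >= sample_rate_hz / 2:
            raise ValueError(
                f"high_hz={self.high_hz} infeasible at sample rate "
                f"{sample_rate_hz} Hz (Nyquist {sample_rate_hz / 2} Hz)"
            )


def common_noise_reject(
    trace_a: RespirationTrace, trace_b: RespirationTrace | None
) -> tuple[RespirationTrace, RespirationTrace | None]:
    """Remove the component of each trace linearly shared with its partner.

    Each trace of a simultaneously recorded pair is regressed on the
    other (ordinary least squares on the mean-subtracted signals) and the
    fitted component is subtracted.  A fully common pair maps to zero;
    independent traces are returned essentially unchanged.  The
    suppression of a genuinely shared component scales with its share of
    the partner's total power, so the method is effective for the large
    shared transients (acoustic/mechanical, valve events) it exists to
    remove.

    With ``trace_b`` None (single-chamber recording) the input is passed
    through unchanged and a warning is logged.
    """
    if trace_b is None:
        log.warning(
            "common_noise_reject: single chamber %s, identity pass-through",
            trace_a.chamber_id,
        )
        return trace_a, None
    if trace_a.data.size != trace_b.data.size:
        raise ValueError("paired traces must have equal length")
    if trace_a.sample_rate_hz != trace_b.sample_rate_hz:
        raise ValueError("paired traces must share a sampling rate")

    a = trace_a.data - trace_a.data.mean()
    b = trace_b.data - trace_b.data.mean()
    var_a = float(a @ a)
    var_b = float(b @ b)
    cov = float(a @ b)
    beta_ab = cov / var_b if var_b > 0 else 0.0  # a on b
    beta_ba = cov / var_a if var_a > 0 else 0.0  # b on a
    cleaned_a = replace(trace_a, data=a - beta_ab * b)
    cleaned_b = replace(trace_b, data=b - beta_ba * a)
    return cleaned_a, cleaned_b


def bandpass(trace: RespirationTrace, spec: FilterSpec = FilterSpec()) -> RespirationTrace:
    """Band-pass a trace to the respiratory band (default 1-15 Hz).

    Zero-phase (forward-backward) application is the default so that
    peak times are not shifted; the effective roll-off is then twice the
    nominal order.
    """
    spec.validate_rate(trace.sample_rate_hz)
    sos = sps.butter(
        spec.order,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=trace.sample_rate_hz,
        output="sos",
    )
    if spec.zero_phase:
        filtered = sps.sosfiltfilt(sos, trace.data)
    else:
        filtered = sps.sosfilt(sos, trace.data)
    return replace(trace, data=filtered)


def _enforce_min_spacing(
    idx: np.ndarray, values: np.ndarray, min_gap_samples: float
) -> list[int]:
    """Greedy pass keeping, within any run closer than the minimum
    inter-peak gap, the larger peak (earlier wins ties)."""
    kept: list[int] = []
    for i in idx:
        if kept and i - kept[-1] < min_gap_samples:
            if values[i] > values[kept[-1]]:
                kept[-1] = int(i)
        else:
            kept.append(int(i))
    return kept


def detect_peaks(trace: RespirationTrace, max_freq_hz: float = 15.0) -> PeakTrain:
    """Detect one inspiration peak per respiratory cycle.

    Cycles are delimited by upward zero crossings of the band-passed
    (zero-mean) signal, with the trace edges closing the leading and
    trailing partial cycles; the peak is the maximum sample within each
    cycle (first maximum on exact ties).  Cycle peaks below a robust
    amplitude gate (``PEAK_GATE_MAD`` x MAD of the trace) are rejected,
    and a minimum inter-peak interval of ``1/max_freq_hz`` is enforced
    by keeping the larger of any two conflicting peaks.  An all-zero
    trace yields an empty train.
    """
    x = trace.data
    if x.size < 3:
        return PeakTrain(np.empty(0), source_id=trace.chamber_id)
    # upward zero crossings: boundary between sample i (<=0) and i+1 (>0)
    up = np.nonzero((x[:-1] <= 0) & (x[1:] > 0))[0] + 1
    bounds = np.concatenate(([0], up, [x.size]))
    mad = float(np.median(np.abs(x - np.median(x))))
    gate = PEAK_GATE_MAD * mad
    peak_idx = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e <= s:
            continue
        j = s + int(np.argmax(x[s:e]))
        if x[j] > gate:
            peak_idx.append(j)
    kept = _enforce_min_spacing(
        np.asarray(peak_idx, dtype=int),
        x,
        trace.sample_rate_hz / max_freq_hz,
    )
    times = np.asarray(kept, dtype=float) / trace.sample_rate_hz
    return PeakTrain(times, source_id=trace.chamber_id)


def instantaneous_frequency(
    peaks: PeakTrain,
    duration_s: float,
    out_rate_hz: float = 100.0,
) -> FreqSeries:
    """Instantaneous respiratory frequency as a resampled step function.

    For each inter-peak interval ``(t_i, t_{i+1}]`` the frequency
    ``1/(t_{i+1} - t_i)`` is assigned as a step function and sampled onto
    the uniform output grid (sample-and-hold, no interpolation, so
    threshold-crossing durations are preserved).  Samples at or before
    the first peak and after the last are invalid.  Fewer than two peaks
    yield an all-masked series.
    """
    n = int(round(duration_s * out_rate_hz))
    values = np.full(n, np.nan)
    pt = peaks.peak_times_s
    if len(pt) >= 2:
        grid = np.arange(n) / out_rate_hz
        intervals = np.diff(pt)
        # j such that pt[j] < t <= pt[j+1]
        j = np.searchsorted(pt, grid, side="left") - 1
        ok = (j >= 0) & (j < intervals.size)
        values[ok] = 1.0 / intervals[j[ok]]
    return FreqSeries(values=values, rate_hz=out_rate_hz)
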