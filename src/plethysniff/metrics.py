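"""Per-trial behavioral readouts from instantaneous-frequency series.

The headline readout is *investigatory sniffing time*: the duration,
out of a fixed 8 s analysis window beginning 1 s after the odor valve
opens, during which instantaneous respiratory frequency strictly exceeds
6 Hz.  Mice sniff above 6 Hz when actively investigating an odor, so a
hyposmic animal — one that fails to detect the stimulus — accumulates
less time above the threshold.  Also computed: the modal baseline
frequency over the 20 s before valve opening, and vehicle-trial
habituation curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import FreqSeries, TrialEvent

__all__ = [
    "WindowSpec",
    "investigatory_time",
    "baseline_modal_frequency",
    "habituation_curve",
    "session_table",
    "METRICS_COLUMNS",
]

log = logging.getLogger(__name__)

METRICS_COLUMNS = [
    "mouse_id",
    "group",
    "timepoint",
    "odor",
    "stimulus",
    "is_vehicle",
    "log10_dilution",
    "trial_index",
    "invest_time_s",
    "invest_pct",
    "baseline_mode_hz",
]


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window conventions for a trial.

    ``lag_s`` skips the odor-arrival latency and the brief valve-onset
    pressure artifact; ``window_s`` is the fixed denominator of the
    percent-time metric; ``threshold_hz`` is the investigatory-sniffing
    criterion (strict inequality); the baseline window is expressed
    relative to valve opening.
    """

    lag_s: float = 1.0
    window_s: float = 8.0
    threshold_hz: float = 6.0
    baseline_start_s: float = -20.0
    baseline_end_s: float = 0.0
    mode_bin_hz: float = 0.5

    def __post_init__(self) -> None:
        if self.lag_s < 0:
            raise ValueError("lag_s must be >= 0")
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if not 1.0 < self.threshold_hz < 15.0:
            raise ValueError("threshold_hz must lie within (1, 15)")
        if self.baseline_end_s <= self.baseline_start_s:
            raise ValueError("baseline window must have positive length")


def _window_slice(freq: FreqSeries, start_s: float, end_s: float) -> slice:
    i0 = int(round(start_s * freq.rate_hz))
    i1 = int(round(end_s * freq.rate_hz))
    return slice(i0, i1)


def investigatory_time(
    freq: FreqSeries, event: TrialEvent, spec: WindowSpec = WindowSpec()
) -> tuple[float, float]:
    """Time above the sniffing threshold in the lagged analysis window.

    Returns ``(invest_time_s, invest_pct)`` where the time is the count
    of grid samples strictly above ``threshold_hz`` divided by the grid
    rate, over the half-open window
    ``[valve_open + lag, valve_open + lag + window_s)``.  Invalid
    (peak-free) samples count as non-investigatory: the percentage is
    out of the fixed window, not of valid time.
    """
    start = event.valve_open_s + spec.lag_s
    sl = _window_slice(freq, start, start + spec.window_s)
    if sl.start < 0 or sl.stop > len(freq):
        raise ValueError(
            f"trial {event.trial_index}: analysis window [{start}, "
            f"{start + spec.window_s}) s falls outside the recording"
        )
    vals = freq.values[sl]
    valid = freq.valid[sl]
    if not valid.all():
        log.debug(
            "trial %d: %d invalid samples in analysis window counted as "
            "non-investigatory",
            event.trial_index,
            int((~valid).sum()),
        )
    count = int(np.sum(valid & (vals > spec.threshold_hz)))
    invest_time_s = count / freq.rate_hz
    invest_pct = invest_time_s / spec.window_s * 100.0
    return invest_time_s, invest_pct


def baseline_modal_frequency(
    freq: FreqSeries, event: TrialEvent, spec: WindowSpec = WindowSpec()
) -> float:
    """Most common respiratory frequency in the pre-odor baseline.

    Valid samples in ``[valve_open + baseline_start, valve_open +
    baseline_end)`` are histogrammed in 0.5 Hz bins centered on
    multiples of 0.5 Hz (edges at k*0.5 - 0.25), and the center of the
    fullest bin is returned; ties break toward the lower bin.  Returns
    NaN (logged) when the window holds no valid samples.
    """
    sl = _window_slice(
        freq,
        event.valve_open_s + spec.baseline_start_s,
        event.valve_open_s + spec.baseline_end_s,
    )
    sl = slice(max(sl.start, 0), min(sl.stop, len(freq)))
    vals = freq.values[sl][freq.valid[sl]]
    if vals.size == 0:
        log.warning("trial %d: no valid baseline samples", event.trial_index)
        return float("nan")
    half = spec.mode_bin_hz / 2.0
    edges = np.arange(-half, 15.0 + spec.mode_bin_hz, spec.mode_bin_hz)
    counts, _ = np.histogram(vals, bins=edges)
    k = int(np.argmax(counts))  # first max -> lower bin on ties
    return float(edges[k] + half)


def habituation_curve(
    freq: FreqSeries,
    vehicle_events: list[TrialEvent],
    spec: WindowSpec = WindowSpec(),
    statistic: str = "mean",
) -> np.ndarray:
    """Per-vehicle-trial frequency over the lagged analysis window.

    One value per vehicle presentation, in trial order, for comparison
    against the 6 Hz investigatory line: a novelty response on trial 1
    followed by decay below threshold indicates intact sniffing capacity
    with normal habituation.  ``statistic`` is the window mean of valid
    samples by default (``"peak"`` gives the window maximum).
    """
    if not vehicle_events:
        raise ValueError("need at least one vehicle event")
    if statistic not in ("mean", "peak"):
        raise ValueError("statistic must be 'mean' or 'peak'")
    out = []
    for ev in vehicle_events:
        start = ev.valve_open_s + spec.lag_s
        sl = _window_slice(freq, start, start + spec.window_s)
        vals = freq.values[sl][freq.valid[sl]]
        if vals.size == 0:
            out.append(np.nan)
        elif statistic == "mean":
            out.append(float(vals.mean()))
        else:
            out.append(float(vals.max()))
    return np.asarray(out)


def session_table(
    sessions: list[tuple[dict, FreqSeries, list[TrialEvent]]],
    spec: WindowSpec = WindowSpec(),
) -> pd.DataFrame:
    """Tidy per-trial metrics table for a set of sessions.

    ``sessions`` is a list of ``(meta, freq, events)`` where ``meta``
    carries at least ``mouse_id``, ``group``, ``odor`` and optionally
    ``timepoint``.  One row per trial (vehicle rows flagged); the
    baseline modal frequency is attached per trial.  Row order is
    deterministic (mouse, timepoint, odor, trial).  Duplicate trial keys
    raise.
    """
    rows = []
    for meta, freq, events in sessions:
        for ev in events:
            t, pct = investigatory_time(freq, ev, spec)
            rows.append(
                {
                    "mouse_id": meta["mouse_id"],
                    "group": meta["group"],
                    "timepoint": meta.get("timepoint", ""),
                    "odor": meta["odor"],
                    "stimulus": ev.stimulus,
                    "is_vehicle": ev.is_vehicle,
                    "log10_dilution": np.nan if ev.is_vehicle else ev.log10_dilution,
                    "trial_index": ev.trial_index,
                    "invest_time_s": t,
                    "invest_pct": pct,
                    "baseline_mode_hz": baseline_modal_frequency(freq, ev, spec),
                }
            )
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    if df.empty:
        return df
    key_cols = ["mouse_id", "timepoint", "odor", "trial_index"]
    if df.duplicated(subset=key_cols).any():
        dupes = df[df.duplicated(subset=key_cols, keep=False)]
        raise ValueError(
            "duplicate trial keys in session set:\n"
            + dupes[key_cols].drop_duplicates().to_string(index=False)
        )
    return df.sort_values(key_cols, kind="stable").reset_index(drop=True)
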