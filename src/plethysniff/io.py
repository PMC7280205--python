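"""CSV artifact I/O: waveforms, trial-event sidecars, ground truth,
metrics and results tables.

Dialect: comma-separated UTF-8 with a mandatory header row, dot
decimals, times in seconds from session start.  Floats are written at
full precision so write -> read round-trips exactly.  Malformed rows are
rejected with 1-based file line numbers (header is line 1).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import RespirationTrace, TrialEvent

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_events_csv",
    "read_events_csv",
    "write_cohort",
    "read_cohort",
    "read_session",
    "write_metrics_csv",
    "read_metrics_csv",
]

FLOAT_FMT = "%.17g"

EVENT_COLUMNS = [
    "session_id",
    "mouse_id",
    "group",
    "timepoint",
    "odor",
    "chamber_id",
    "pair_id",
    "trial_index",
    "stimulus",
    "log10_dilution",
    "valve_open_s",
    "duration_s",
]

GROUND_TRUTH_COLUMNS = [
    "session_id",
    "trial_index",
    "stimulus",
    "log10_dilution",
    "detected_flag",
    "bout_start_s",
    "bout_end_s",
    "bout_rate_hz",
    "gt_invest_time_s",
    "gt_invest_pct",
]


def _bad_rows(mask: pd.Series, path) -> None:
    if mask.any():
        lines = (mask[mask].index + 2).tolist()  # +1 header, +1 one-based
        raise ValueError(f"{path}: malformed rows at lines {lines[:10]}")


def write_trace_csv(trace: RespirationTrace, path) -> None:
    """Two-column (time_s, pressure_au) waveform CSV."""
    arr = np.column_stack([trace.times, trace.data])
    np.savetxt(
        path,
        arr,
        delimiter=",",
        header="time_s,pressure_au",
        comments="",
        fmt=FLOAT_FMT,
    )


def read_trace_csv(path, chamber_id: str = "A") -> RespirationTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "pressure_au"]:
        raise ValueError(f"{path}: expected header time_s,pressure_au")
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    _bad_rows(df.isna().any(axis=1), path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: trace needs at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform time grid")
    rate = 1.0 / dt[0]
    return RespirationTrace(df["pressure_au"].to_numpy(), rate, chamber_id=chamber_id)


def _session_id(meta: dict) -> str:
    tp = meta.get("timepoint") or "t0"
    return f"{meta['mouse_id']}_{meta['odor']}_{tp}".replace(" ", "-").replace(
        ",", ""
    )


def write_events_csv(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_events_csv(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"events sidecar not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("trial_index", "valve_open_s", "duration_s"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    _bad_rows(df[["trial_index", "valve_open_s", "duration_s"]].isna().any(axis=1), path)
    return df


def write_cohort(cohort, outdir) -> None:
    """Persist a simulated cohort: per-session waveform CSVs plus
    events and ground-truth sidecars."""
    outdir = Path(outdir)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    ev_rows, gt_rows, sess_rows = [], [], []
    for s in cohort.sessions:
        sid = _session_id(s.meta)
        sess_rows.append(
            {
                "session_id": sid,
                **s.meta,
                "chamber_id": s.chamber_id,
                "pair_id": s.pair_id or "",
                "sample_rate_hz": s.design.sample_rate_hz,
            }
        )
        for ev in s.events:
            ev_rows.append(
                {
                    "session_id": sid,
                    **s.meta,
                    "chamber_id": s.chamber_id,
                    "pair_id": s.pair_id or "",
                    "trial_index": ev.trial_index,
                    "stimulus": ev.stimulus,
                    "log10_dilution": "" if ev.is_vehicle else ev.log10_dilution,
                    "valve_open_s": ev.valve_open_s,
                    "duration_s": ev.duration_s,
                }
            )
        gt = s.ground_truth.copy()
        gt.insert(0, "session_id", sid)
        gt_rows.append(gt)
        if s.trace is not None:
            write_trace_csv(s.trace, outdir / "traces" / f"{sid}.csv")
    pd.DataFrame(sess_rows).to_csv(outdir / "sessions.csv", index=False)
    write_events_csv(pd.DataFrame(ev_rows, columns=EVENT_COLUMNS), outdir / "events.csv")
    pd.concat(gt_rows, ignore_index=True)[GROUND_TRUTH_COLUMNS].to_csv(
        outdir / "ground_truth.csv", index=False, float_format=FLOAT_FMT
    )


def _events_from_rows(rows: pd.DataFrame) -> list[TrialEvent]:
    events = []
    for _, r in rows.sort_values("trial_index").iterrows():
        dil = r["log10_dilution"]
        events.append(
            TrialEvent(
                trial_index=int(r["trial_index"]),
                stimulus=str(r["stimulus"]),
                log10_dilution=None if pd.isna(dil) or dil == "" else float(dil),
                valve_open_s=float(r["valve_open_s"]),
                duration_s=float(r["duration_s"]),
            )
        )
    return events


def read_session(indir, session_id: str) -> tuple[RespirationTrace, list[TrialEvent], dict]:
    """Load one session's trace, events and metadata from a cohort dir.

    Validates that every valve opening lies inside the recording.
    """
    indir = Path(indir)
    sessions = pd.read_csv(indir / "sessions.csv")
    row = sessions[sessions["session_id"] == session_id]
    if row.empty:
        raise ValueError(f"unknown session_id {session_id!r}")
    meta = row.iloc[0].to_dict()
    events_df = read_events_csv(indir / "events.csv")
    events = _events_from_rows(events_df[events_df["session_id"] == session_id])
    trace = read_trace_csv(
        indir / "traces" / f"{session_id}.csv", chamber_id=str(meta["chamber_id"])
    )
    for ev in events:
        if ev.valve_open_s >= trace.duration_s:
            raise ValueError(
                f"{session_id}: trial {ev.trial_index} valve opening at "
                f"{ev.valve_open_s} s beyond trace end {trace.duration_s} s"
            )
    return trace, events, meta


def read_cohort(indir) -> list[tuple[RespirationTrace, list[TrialEvent], dict]]:
    """Load every session of a cohort directory (deterministic order)."""
    indir = Path(indir)
    sessions_path = indir / "sessions.csv"
    if not sessions_path.exists():
        raise FileNotFoundError(f"sessions index not found: {sessions_path}")
    sessions = pd.read_csv(sessions_path)
    return [read_session(indir, sid) for sid in sessions["session_id"]]


def write_metrics_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_metrics_csv(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"metrics table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("invest_time_s", "invest_pct"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            _bad_rows(df[col].isna(), path)
    return df
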