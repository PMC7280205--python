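"""Synthetic plethysmography sessions with known ground truth.

Breathing is modelled as a two-state renewal process: eupnea (quiet
breathing, ~2-4 Hz) and investigatory sniffing (>6 Hz).  Each cycle
draws its rate from the active state's distribution (clipped so eupnea
stays strictly below and sniffing strictly above the 6 Hz criterion, and
everything within the 1-15 Hz analysis band) and contributes one
raised-cosine pressure cycle with a single inspiration peak at its
midpoint.  A session is the staircase paradigm: vehicle (mineral oil)
presented once per minute for 11 trials, then an ascending series of
seven log10 liquid dilutions (1e-8 .. 1e-2) of one odorant, 6 s delivery
each.  Detection of an odor trial is a Bernoulli draw from a
psychometric function of log10 dilution; a detected trial plants a
sniff bout shortly after odor arrival.  Vehicle trial 1 always evokes a
novelty bout whose probability then decays geometrically (habituation).
Valve-onset pressure artifacts (<500 ms), chamber-pair common-mode
noise, and per-chamber sensor noise complete the waveform.

Every generated quantity is recorded as ground truth (peak times, bout
placements, detection draws, and the investigatory time an ideal peak
detector would measure), so downstream stages can be tested for exact
and statistical recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import brentq

from .metrics import WindowSpec, investigatory_time
from .signal import instantaneous_frequency
from .types import VEHICLE_LABEL, PeakTrain, RespirationTrace, TrialEvent

__all__ = [
    "BreathingModelParams",
    "OdorKineticsParams",
    "DetectionModelParams",
    "SessionDesign",
    "Session",
    "Cohort",
    "simulate_breathing",
    "odor_concentration_profile",
    "simulate_session",
    "simulate_cohort",
    "psychometric",
    "expected_detected_count",
    "conditional_window_means",
    "calibrate_group_effect",
    "DEFAULT_ODORS",
]

DEFAULT_ODORS = ("heptanal", "isoamyl acetate", "1,7-octadiene")

# Hard clips keeping generated instantaneous rates inside the analysis
# band and on the correct side of the 6 Hz investigatory criterion.
_EUPNEA_CLIP = (1.2, 5.7)
_SNIFF_CLIP = (6.3, 14.5)


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class BreathingModelParams:
    """Two-state respiratory model parameters.

    Rates in Hz, durations in seconds, amplitudes in the arbitrary
    pressure units of the transducer.  ``sniff_rate_hz`` must exceed the
    6 Hz investigatory convention and ``eupnea_rate_hz`` must stay below
    it.  ``amplitude_sniff_ratio`` < 1 reflects the shallower, faster
    breaths of sniffing.  ``noise_sd_au`` is white sensor noise per
    chamber (an SNR convention, not a measured value).
    """

    eupnea_rate_hz: float = 3.0
    eupnea_sd_hz: float = 0.35
    sniff_rate_hz: float = 9.0
    sniff_sd_hz: float = 0.8
    bout_duration_s: float = 3.5
    bout_duration_shape: float = 4.0
    spont_bout_rate_per_min: float = 2.0
    spont_bout_duration_s: float = 1.0
    amplitude_au: float = 1.0
    amplitude_sniff_ratio: float = 0.6
    #: white sensor-noise SD referenced to 600 Hz digitization; the
    #: generator scales it by sqrt(rate/600) so the noise spectral
    #: density (hence in-band noise) is sample-rate independent
    noise_sd_au: float = 0.05
    reaction_mean_s: float = 0.5
    reaction_sd_s: float = 0.15

    def __post_init__(self) -> None:
        if not self.sniff_rate_hz > 6.0 > self.eupnea_rate_hz:
            raise ValueError("require sniff_rate_hz > 6 Hz > eupnea_rate_hz")
        for name in (
            "eupnea_rate_hz",
            "sniff_rate_hz",
            "bout_duration_s",
            "bout_duration_shape",
            "spont_bout_duration_s",
            "amplitude_au",
            "amplitude_sniff_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "eupnea_sd_hz",
            "sniff_sd_hz",
            "spont_bout_rate_per_min",
            "noise_sd_au",
            "reaction_sd_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class OdorKineticsParams:
    """First-order odor concentration kinetics inside the chamber.

    Odor arrives ``onset_delay_s`` after the valve opens (a few hundred
    ms in the reference apparatus), rises with time constant
    ``rise_tau_s`` during delivery, and clears with ``clear_tau_s`` after
    offset; the clearance constant must leave <1% of peak concentration
    10 s after offset.
    """

    onset_delay_s: float = 0.3
    rise_tau_s: float = 1.5
    clear_tau_s: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.onset_delay_s < 1.0:
            raise ValueError("onset_delay_s must lie in [0, 1) s")
        if self.rise_tau_s <= 0 or self.clear_tau_s <= 0:
            raise ValueError("time constants must be positive")
        if np.exp(-10.0 / self.clear_tau_s) >= 0.01:
            raise ValueError(
                "clear_tau_s too slow: concentration must fall below 1% of "
                "peak within 10 s of odor offset"
            )


@dataclass(frozen=True)
class DetectionModelParams:
    """Psychometric detection model and group-level deficit knobs.

    Detection probability at log10 dilution ``d`` is
    ``(1 - lapse) / (1 + 10**(-slope * (d - threshold)))`` with
    ``threshold = threshold_log10 + group_effect_log10``; a positive
    group effect shifts the curve toward higher concentrations
    (hyposmia).  ``response_gain`` scales odor-evoked bout durations
    (novelty and spontaneous bouts are untouched: motor capacity is
    intact).
    """

    threshold_log10: float = -5.5
    slope: float = 1.0
    lapse: float = 0.05
    group_effect_log10: float = 0.0
    response_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0 <= self.lapse <= 1:
            raise ValueError("lapse must lie in [0, 1]")
        if self.response_gain < 0:
            raise ValueError("response_gain must be non-negative")


@dataclass(frozen=True)
class SessionDesign:
    """Structure of one odor-staircase session.

    Defaults are the reference protocol: 11 vehicle presentations then
    seven ascending dilutions, one stimulus per minute, 6 s delivery,
    600 Hz digitization, 30 min habituation beforehand (habituation is
    metadata here, not simulated signal).  ``scaled()`` returns a
    shorter, lower-rate variant for simulation studies.
    """

    n_vehicle_trials: int = 11
    dilution_series: tuple[float, ...] = (-8.0, -7.0, -6.0, -5.0, -4.0, -3.0, -2.0)
    stimulus_duration_s: float = 6.0
    inter_stimulus_s: float = 60.0
    habituation_min: float = 30.0
    sample_rate_hz: float = 600.0
    pre_roll_s: float = 30.0
    tail_s: float = 15.0
    artifact_amplitude_au: float = 0.3
    artifact_duration_s: float = 0.3
    common_noise_sd_au: float = 0.02

    def __post_init__(self) -> None:
        dil = np.asarray(self.dilution_series)
        if dil.size and np.any(np.diff(dil) <= 0):
            raise ValueError("dilution_series must be strictly ascending")
        if self.inter_stimulus_s <= self.stimulus_duration_s + 10.0:
            raise ValueError(
                "inter_stimulus_s must exceed stimulus_duration_s + 10 s "
                "(chamber clearance)"
            )
        if self.sample_rate_hz < 30.0:
            raise ValueError("sample_rate_hz must be >= 30 Hz (2 x 15 Hz band)")
        if self.n_vehicle_trials < 1:
            raise ValueError("need at least one vehicle trial")
        if not 0 < self.artifact_duration_s < 0.5:
            raise ValueError("artifact_duration_s must lie in (0, 0.5) s")
        if self.tail_s < 10.0:
            raise ValueError("tail_s must cover the lagged analysis window")

    @property
    def n_trials(self) -> int:
        return self.n_vehicle_trials + len(self.dilution_series)

    @property
    def duration_s(self) -> float:
        return self.pre_roll_s + (self.n_trials - 1) * self.inter_stimulus_s + self.tail_s

    def trial_events(self, odor: str) -> list[TrialEvent]:
        """The deterministic stimulus schedule: vehicle block then the
        ascending staircase, one trial per inter-stimulus interval."""
        events = []
        for k in range(self.n_trials):
            vehicle = k < self.n_vehicle_trials
            events.append(
                TrialEvent(
                    trial_index=k,
                    stimulus=VEHICLE_LABEL if vehicle else odor,
                    log10_dilution=None
                    if vehicle
                    else float(self.dilution_series[k - self.n_vehicle_trials]),
                    valve_open_s=self.pre_roll_s + k * self.inter_stimulus_s,
                    duration_s=self.stimulus_duration_s,
                )
            )
        return events

    @classmethod
    def scaled(cls, **overrides) -> "SessionDesign":
        """Desk-scale variant: same trial structure, 20 s cadence and
        150 Hz sampling, for simulation studies that need many
        replicates."""
        kw = dict(
            inter_stimulus_s=20.0,
            sample_rate_hz=150.0,
            pre_roll_s=25.0,
            tail_s=12.0,
        )
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# breathing waveform


def _draw_cycles(
    rng: np.random.Generator,
    start: float,
    end: float,
    rate: float,
    sd: float,
    clip: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Fill [start, end) with whole cycles; returns (starts, periods).

    With sd == 0 exactly floor((end-start)*rate) cycles of period 1/rate
    are produced; a trailing remainder shorter than one period is left
    as a breathing pause.
    """
    length = end - start
    if length <= 0:
        return np.empty(0), np.empty(0)
    if sd == 0:
        n = int(np.floor(length * rate + 1e-9))
        periods = np.full(n, 1.0 / rate)
    else:
        n_max = int(length * (rate + 4 * sd)) + 8
        rates = np.clip(rng.normal(rate, sd, size=n_max), *clip)
        periods = 1.0 / rates
        ends = np.cumsum(periods)
        n = int(np.searchsorted(ends, length + 1e-12, side="right"))
        periods = periods[:n]
    if periods.size == 0:
        return np.empty(0), np.empty(0)
    starts = start + np.concatenate(([0.0], np.cumsum(periods[:-1])))
    return starts, periods


def simulate_breathing(
    params: BreathingModelParams,
    state_schedule: list[tuple[float, float, str]],
    duration_s: float,
    sample_rate_hz: float,
    seed: int | np.random.Generator,
    make_waveform: bool = True,
) -> tuple[RespirationTrace | None, dict]:
    """Generate a two-state breathing waveform with ground-truth peaks.

    ``state_schedule`` is a list of non-overlapping ``(start_s, end_s,
    state)`` intervals with state ``"eupnea"`` or ``"sniff"``; gaps are
    treated as eupnea.  Returns the noiseless trace (or None when
    ``make_waveform`` is False) and a ground-truth dict with per-cycle
    ``peak_times`` (the single inspiration maximum per cycle, at the
    cycle midpoint), ``cycle_rates`` and ``cycle_states``.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible simulation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sched = sorted(state_schedule, key=lambda s: s[0])
    covered = 0.0
    segments: list[tuple[float, float, str]] = []
    for s, e, state in sched:
        if state not in ("eupnea", "sniff"):
            raise ValueError(f"unknown state {state!r}")
        if s < -1e-9 or e > duration_s + 1e-9:
            raise ValueError(
                f"schedule interval [{s}, {e}] outside [0, {duration_s}]"
            )
        if s < covered - 1e-9:
            raise ValueError("schedule intervals overlap")
        if s > covered + 1e-12:
            segments.append((covered, s, "eupnea"))
        segments.append((max(s, covered), e, state))
        covered = e
    if covered < duration_s - 1e-12:
        segments.append((covered, duration_s, "eupnea"))

    starts_all, periods_all, states_all = [], [], []
    for s, e, state in segments:
        if state == "sniff":
            rate, sd, clip = params.sniff_rate_hz, params.sniff_sd_hz, _SNIFF_CLIP
        else:
            rate, sd, clip = params.eupnea_rate_hz, params.eupnea_sd_hz, _EUPNEA_CLIP
        st, pe = _draw_cycles(rng, s, e, rate, sd, clip)
        starts_all.append(st)
        periods_all.append(pe)
        states_all.append(np.repeat(state == "sniff", st.size))
    starts = np.concatenate(starts_all) if starts_all else np.empty(0)
    periods = np.concatenate(periods_all) if periods_all else np.empty(0)
    is_sniff = np.concatenate(states_all) if states_all else np.empty(0, bool)

    gt = {
        "peak_times": starts + periods / 2.0,
        "cycle_starts": starts,
        "cycle_periods": periods,
        "cycle_rates": 1.0 / periods if periods.size else periods,
        "cycle_states": np.where(is_sniff, "sniff", "eupnea"),
    }

    trace = None
    if make_waveform:
        n = int(round(duration_s * sample_rate_hz))
        t = np.arange(n) / sample_rate_hz
        pressure = np.zeros(n)
        if starts.size:
            amps = np.where(
                is_sniff,
                params.amplitude_au * params.amplitude_sniff_ratio,
                params.amplitude_au,
            )
            idx = np.searchsorted(starts, t, side="right") - 1
            idx_c = np.clip(idx, 0, starts.size - 1)
            in_cycle = (idx >= 0) & (t < starts[idx_c] + periods[idx_c])
            phase = (t[in_cycle] - starts[idx_c[in_cycle]]) / periods[idx_c[in_cycle]]
            pressure[in_cycle] = (
                amps[idx_c[in_cycle]] * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
            )
        trace = RespirationTrace(pressure, sample_rate_hz)
    return trace, gt


# ---------------------------------------------------------------------------
# odor kinetics


def odor_concentration_profile(
    kinetics: OdorKineticsParams,
    valve_open_s: float,
    duration_s: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Normalized chamber odor concentration on a uniform time grid.

    First-order step response: zero until odor arrival (valve opening
    plus transport delay), saturating rise during delivery, exponential
    clearance after (delayed) offset.  The peak sits at the end of
    delivery; values are within [0, 1].
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1:
        steps = np.diff(grid)
        if not np.allclose(steps, steps[0]):
            raise ValueError("grid must be uniform")
    if valve_open_s < 0:
        raise ValueError("valve_open_s must be >= 0")
    t_on = valve_open_s + kinetics.onset_delay_s
    t_off = t_on + duration_s
    c = np.zeros_like(grid)
    rising = (grid >= t_on) & (grid <= t_off)
    c[rising] = 1.0 - np.exp(-(grid[rising] - t_on) / kinetics.rise_tau_s)
    peak = 1.0 - np.exp(-duration_s / kinetics.rise_tau_s)
    falling = grid > t_off
    c[falling] = peak * np.exp(-(grid[falling] - t_off) / kinetics.clear_tau_s)
    return c


# ---------------------------------------------------------------------------
# detection model


def psychometric(
    log10_dilution: np.ndarray | float, detection: DetectionModelParams
) -> np.ndarray | float:
    """Detection probability at a log10 liquid dilution."""
    d = np.asarray(log10_dilution, dtype=float)
    theta = detection.threshold_log10 + detection.group_effect_log10
    expo = np.clip(-detection.slope * (d - theta), -30.0, 30.0)
    p = (1.0 - detection.lapse) / (1.0 + 10.0**expo)
    return float(p) if np.isscalar(log10_dilution) else p


def expected_detected_count(
    design: SessionDesign, detection: DetectionModelParams
) -> float:
    """Closed-form expected number of detected odor trials per session."""
    return float(np.sum(psychometric(np.asarray(design.dilution_series), detection)))


# ---------------------------------------------------------------------------
# sessions


@dataclass
class Session:
    """One simulated mouse-odor session with full ground truth."""

    mouse_id: str
    group: str
    odor: str
    timepoint: str
    design: SessionDesign
    events: list[TrialEvent]
    trace: RespirationTrace | None
    ground_truth: pd.DataFrame
    gt_peak_times: np.ndarray
    chamber_id: str = "A"
    pair_id: str | None = None

    @property
    def meta(self) -> dict:
        return {
            "mouse_id": self.mouse_id,
            "group": self.group,
            "odor": self.odor,
            "timepoint": self.timepoint,
        }


def _merge_intervals(intervals: list[tuple[float, float]], duration: float):
    clipped = [
        (max(0.0, s), min(duration, e)) for s, e in intervals if e > 0 and s < duration
    ]
    if not clipped:
        return []
    clipped.sort()
    merged = [list(clipped[0])]
    for s, e in clipped[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, sd: float
) -> np.ndarray:
    """Gaussian noise band-limited to 0.1-20 Hz (shared chamber noise)."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    high = min(20.0, 0.45 * fs)
    sos = sps.butter(2, [0.1, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _half_sine_artifact(
    n: int, fs: float, onset_s: float, dur_s: float, amp: float
) -> np.ndarray:
    i0 = int(round(onset_s * fs))
    i1 = min(n, i0 + int(round(dur_s * fs)))
    out = np.zeros(n)
    if i1 > i0:
        tt = (np.arange(i0, i1) / fs - onset_s) / dur_s
        out[i0:i1] = amp * np.sin(np.pi * tt)
    return out


def simulate_session(
    design: SessionDesign,
    breathing: BreathingModelParams,
    kinetics: OdorKineticsParams,
    detection: DetectionModelParams,
    mouse_id: str,
    group_label: str,
    seed: int | np.random.Generator,
    *,
    odor: str = "heptanal",
    timepoint: str = "",
    habituation_decay: float = 0.35,
    window: WindowSpec = WindowSpec(),
    make_waveform: bool = True,
    shared_noise: np.ndarray | None = None,
    chamber_id: str = "A",
    pair_id: str | None = None,
    _force_detect: bool | None = None,
) -> Session:
    """Simulate one complete odor-staircase session for one mouse.

    Emits the deterministic 11-vehicle + 7-odor trial schedule, draws
    detection per odor trial from the psychometric function (as
    parameterized by ``detection``, including any group threshold
    shift), plants odor-evoked, novelty and spontaneous sniff bouts,
    synthesizes the pressure waveform with valve artifacts and noise,
    and records ground truth per trial — including the investigatory
    time implied by the ground-truth peak train itself (what an ideal
    peak detector would measure).

    ``_force_detect`` overrides the Bernoulli detection draws (used by
    the effect-size calibration, which needs conditional means); the
    trial schedule and all other draws are unaffected.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible simulation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = design.trial_events(odor)
    duration = design.duration_s

    def reaction() -> float:
        return float(
            np.clip(
                rng.normal(breathing.reaction_mean_s, breathing.reaction_sd_s),
                0.1,
                1.5,
            )
        )

    def bout_duration(gain: float = 1.0) -> float:
        shape = breathing.bout_duration_shape
        d = rng.gamma(shape, breathing.bout_duration_s / shape) * gain
        return float(max(d, 0.3))

    records = []
    bouts: list[tuple[float, float]] = []
    for ev in events:
        detected = False
        bout = (np.nan, np.nan)
        if ev.is_vehicle:
            k = ev.trial_index  # 0-based within the vehicle block
            p = 1.0 if k == 0 else habituation_decay**k
            responded = rng.random() < p
            if responded:
                start = ev.valve_open_s + kinetics.onset_delay_s + reaction()
                bout = (start, start + bout_duration())
                bouts.append(bout)
            detected = responded
        else:
            p = psychometric(ev.log10_dilution, detection)
            detected = bool(rng.random() < p)
            if _force_detect is not None:
                detected = _force_detect
            if detected:
                start = ev.valve_open_s + kinetics.onset_delay_s + reaction()
                bout = (start, start + bout_duration(detection.response_gain))
                bouts.append(bout)
        records.append(
            {
                "trial_index": ev.trial_index,
                "stimulus": ev.stimulus,
                "log10_dilution": np.nan if ev.is_vehicle else ev.log10_dilution,
                "detected_flag": detected,
                "bout_start_s": bout[0],
                "bout_end_s": bout[1],
                "bout_rate_hz": breathing.sniff_rate_hz if detected else np.nan,
            }
        )

    n_spont = rng.poisson(breathing.spont_bout_rate_per_min * duration / 60.0)
    for _ in range(n_spont):
        s = rng.uniform(0.0, duration)
        bouts.append((s, s + rng.gamma(3.0, breathing.spont_bout_duration_s / 3.0)))

    sniff_intervals = _merge_intervals(bouts, duration)
    schedule = [(s, e, "sniff") for s, e in sniff_intervals]
    trace, gt = simulate_breathing(
        breathing,
        schedule,
        duration,
        design.sample_rate_hz,
        rng,
        make_waveform=make_waveform,
    )

    # investigatory time implied by the ground-truth peak train
    gt_freq = instantaneous_frequency(PeakTrain(gt["peak_times"]), duration)
    for rec, ev in zip(records, events):
        t_s, pct = investigatory_time(gt_freq, ev, window)
        rec["gt_invest_time_s"] = t_s
        rec["gt_invest_pct"] = pct
    ground_truth = pd.DataFrame(records)

    if make_waveform and trace is not None:
        data = trace.data.copy()
        fs = design.sample_rate_hz
        for ev in events:
            data += _half_sine_artifact(
                data.size,
                fs,
                ev.valve_open_s,
                design.artifact_duration_s,
                design.artifact_amplitude_au,
            )
        if shared_noise is None:
            shared_noise = _band_limited_noise(
                rng, data.size, fs, design.common_noise_sd_au
            )
        data += shared_noise
        if breathing.noise_sd_au > 0:
            sd = breathing.noise_sd_au * np.sqrt(fs / 600.0)
            data += rng.normal(0.0, sd, size=data.size)
        trace = RespirationTrace(data, fs, chamber_id=chamber_id)

    return Session(
        mouse_id=mouse_id,
        group=group_label,
        odor=odor,
        timepoint=timepoint,
        design=design,
        events=events,
        trace=trace,
        ground_truth=ground_truth,
        gt_peak_times=gt["peak_times"],
        chamber_id=chamber_id,
        pair_id=pair_id,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    """A two-group session set with its generative target effect.

    ``gt_effect_pct`` is the mean per-mouse ground-truth invest_pct of
    the first group minus the second, over odor trials — computed from
    planted bouts, not from the signal-processing pipeline.
    """

    sessions: list[Session]
    group_labels: tuple[str, str]
    gt_effect_pct: float
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def gt_metrics(self) -> pd.DataFrame:
        """Tidy ground-truth per-trial table (mirrors the pipeline's
        metrics table, but from ground-truth peaks)."""
        rows = []
        for s in self.sessions:
            df = s.ground_truth.copy()
            for k, v in s.meta.items():
                df[k] = v
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def simulate_cohort(
    n_per_group: int | tuple[int, int],
    design: SessionDesign,
    breathing: BreathingModelParams,
    kinetics: OdorKineticsParams,
    detection_by_group: dict[str, DetectionModelParams],
    seed: int,
    *,
    odors: tuple[str, ...] = DEFAULT_ODORS,
    timepoint: str = "",
    window: WindowSpec = WindowSpec(),
    make_waveform: bool = True,
    habituation_decay: float = 0.35,
) -> Cohort:
    """Simulate a two-group cohort, one session per mouse per odor.

    Mice are interleaved across groups and paired into simultaneously
    recorded chamber pairs per odor day; each pair shares a common-mode
    noise realization and the same stimulus schedule, exercising the
    common-noise rejection stage.  Returns the sessions together with
    the generative group difference in ground-truth invest_pct.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible simulation")
    labels = tuple(detection_by_group)
    if len(labels) != 2:
        raise ValueError("detection_by_group must name exactly two groups")
    if isinstance(n_per_group, int):
        n_a = n_b = n_per_group
    else:
        n_a, n_b = n_per_group
    if min(n_a, n_b) < 2:
        raise ValueError("need at least 2 mice per group")

    mice: list[tuple[str, str]] = []  # (mouse_id, group)
    for i in range(max(n_a, n_b)):
        if i < n_a:
            mice.append((f"{labels[0][:1]}{i + 1:02d}", labels[0]))
        if i < n_b:
            mice.append((f"{labels[1][:1]}{i + 1:02d}", labels[1]))

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(odors) * (len(mice) + (len(mice) + 1) // 2))
    it = iter(children)

    sessions: list[Session] = []
    for odor in odors:
        for k in range(0, len(mice), 2):
            pair = mice[k : k + 2]
            pair_id = f"{odor}:pair{k // 2}"
            noise_rng = np.random.default_rng(next(it))
            if make_waveform:
                n_samp = int(round(design.duration_s * design.sample_rate_hz))
                shared = _band_limited_noise(
                    noise_rng, n_samp, design.sample_rate_hz, design.common_noise_sd_au
                )
            else:
                shared = None
            for j, (mouse_id, group) in enumerate(pair):
                sessions.append(
                    simulate_session(
                        design,
                        breathing,
                        kinetics,
                        detection_by_group[group],
                        mouse_id,
                        group,
                        np.random.default_rng(next(it)),
                        odor=odor,
                        timepoint=timepoint,
                        window=window,
                        make_waveform=make_waveform,
                        shared_noise=shared,
                        chamber_id="AB"[j],
                        pair_id=pair_id if len(pair) == 2 else None,
                        habituation_decay=habituation_decay,
                    )
                )
        # odd mouse count: last pair holds a single session (pair_id None)

    gt = Cohort(sessions, labels, np.nan, seed=seed).gt_metrics()
    odor_rows = gt[gt["stimulus"] != VEHICLE_LABEL]
    per_mouse = odor_rows.groupby(["group", "mouse_id"])["gt_invest_pct"].mean()
    effect = float(per_mouse[labels[0]].mean() - per_mouse[labels[1]].mean())
    return Cohort(sessions, labels, effect, seed=seed)


# ---------------------------------------------------------------------------
# effect-size calibration


def conditional_window_means(
    design: SessionDesign,
    breathing: BreathingModelParams,
    kinetics: OdorKineticsParams,
    seed: int,
    n_sessions: int = 200,
    window: WindowSpec = WindowSpec(),
) -> tuple[float, float]:
    """Monte-Carlo conditional means of ground-truth invest_pct.

    Returns ``(m, b)``: the expected per-odor-trial invest_pct given a
    planted odor-evoked bout (``m``) and given none (``b``, spontaneous
    bouts only).  The bout model does not depend on dilution, so both
    are scalars.  Computed on ground-truth cycles only — no waveform or
    signal processing involved.
    """
    base = DetectionModelParams()
    vals_m, vals_b = [], []
    ss = np.random.SeedSequence(seed)
    for force, sink in ((True, vals_m), (False, vals_b)):
        for child in ss.spawn(n_sessions):
            s = simulate_session(
                design,
                breathing,
                kinetics,
                base,
                "cal",
                "cal",
                np.random.default_rng(child),
                make_waveform=False,
                window=window,
                _force_detect=force,
            )
            gt = s.ground_truth
            sink.extend(gt.loc[gt["stimulus"] != VEHICLE_LABEL, "gt_invest_pct"])
    return float(np.mean(vals_m)), float(np.mean(vals_b))


def calibrate_group_effect(
    target_diff_pct: float,
    design: SessionDesign,
    breathing: BreathingModelParams,
    kinetics: OdorKineticsParams,
    control_detection: DetectionModelParams,
    seed: int,
    n_cal_sessions: int = 200,
    window: WindowSpec = WindowSpec(),
) -> DetectionModelParams:
    """Solve the treated-group threshold shift for a target deficit.

    The expected per-trial invest_pct of a group is
    ``b + p̄ * (m - b)`` where ``p̄`` is the psychometric detection
    probability averaged over the dilution series and ``(m, b)`` are the
    conditional means from :func:`conditional_window_means`.  The
    treated group's ``group_effect_log10`` is solved by bisection so the
    expected ground-truth difference equals ``target_diff_pct``.
    """
    if target_diff_pct <= 0:
        raise ValueError("target_diff_pct must be positive")
    m, b = conditional_window_means(
        design, breathing, kinetics, seed, n_cal_sessions, window
    )
    dil = np.asarray(design.dilution_series)
    p_c = float(np.mean(psychometric(dil, control_detection)))

    def pbar(shift: float) -> float:
        det = replace(control_detection, group_effect_log10=shift)
        return float(np.mean(psychometric(dil, det)))

    target_p = p_c - target_diff_pct / (m - b)
    lo, hi = 0.0, 15.0
    if not pbar(hi) < target_p < p_c:
        raise ValueError(
            f"target difference {target_diff_pct} pct-points not attainable: "
            f"control expectation allows at most {(p_c - pbar(hi)) * (m - b):.1f}"
        )
    shift = brentq(lambda s: pbar(s) - target_p, lo, hi, xtol=1e-6)
    return replace(control_detection, group_effect_log10=float(shift))
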