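"""Generator tests: deterministic cycle counts, session structure,
psychometric detection, determinism and effect-size calibration."""

import numpy as np
import pytest
from dataclasses import replace

from plethysniff.simulate import (
    BreathingModelParams,
    DetectionModelParams,
    OdorKineticsParams,
    SessionDesign,
    calibrate_group_effect,
    expected_detected_count,
    odor_concentration_profile,
    psychometric,
    simulate_breathing,
    simulate_cohort,
    simulate_session,
)
from plethysniff.types import VEHICLE_LABEL


class TestSimulateBreathing:
    def test_zero_jitter_eupnea_peak_count_and_spacing(self, quiet_breathing):
        _, gt = simulate_breathing(
            quiet_breathing, [(0.0, 10.0, "eupnea")], 10.0, 600.0, seed=1
        )
        assert len(gt["peak_times"]) == 30
        assert np.allclose(np.diff(gt["peak_times"]), 1.0 / 3.0)

    def test_zero_jitter_sniff_peak_count(self, quiet_breathing):
        _, gt = simulate_breathing(
            quiet_breathing, [(0.0, 8.0, "sniff")], 8.0, 600.0, seed=1
        )
        assert len(gt["peak_times"]) == 72

    @pytest.mark.parametrize("rate,duration", [(3.0, 7.4), (2.2, 11.3), (4.9, 5.0)])
    def test_zero_jitter_count_is_floor_duration_times_rate(self, rate, duration):
        bp = BreathingModelParams(
            eupnea_rate_hz=rate, eupnea_sd_hz=0.0, sniff_sd_hz=0.0
        )
        _, gt = simulate_breathing(
            bp, [(0.0, duration, "eupnea")], duration, 300.0, seed=0
        )
        assert len(gt["peak_times"]) == int(np.floor(duration * rate + 1e-9))

    def test_empirical_rates_match_schedule_within_3_sem(self, breathing):
        sched = [(0.0, 30.0, "eupnea"), (30.0, 45.0, "sniff"), (45.0, 60.0, "eupnea")]
        _, gt = simulate_breathing(breathing, sched, 60.0, 600.0, seed=1)
        rates = gt["cycle_rates"]
        states = gt["cycle_states"]
        for state, mean in (("eupnea", 3.0), ("sniff", 9.0)):
            r = rates[states == state]
            sem = r.std(ddof=1) / np.sqrt(r.size)
            assert abs(r.mean() - mean) < 3 * sem + 1e-9

    def test_rates_stay_in_band_and_on_correct_side_of_6hz(self, breathing):
        _, gt = simulate_breathing(
            breathing,
            [(0.0, 60.0, "eupnea"), (60.0, 90.0, "sniff")],
            90.0,
            300.0,
            seed=5,
        )
        r = gt["cycle_rates"]
        s = gt["cycle_states"]
        assert np.all((r > 1.0) & (r < 15.0))
        assert np.all(r[s == "eupnea"] < 6.0)
        assert np.all(r[s == "sniff"] > 6.0)

    def test_one_waveform_maximum_per_cycle(self, quiet_breathing):
        trace, gt = simulate_breathing(
            quiet_breathing, [(0.0, 5.0, "eupnea")], 5.0, 600.0, seed=1
        )
        # local maxima of the noiseless waveform == ground-truth peaks
        x = trace.data
        locmax = np.nonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]) & (x[1:-1] > 0.1))[0] + 1
        assert locmax.size == len(gt["peak_times"])
        assert np.allclose(locmax / 600.0, gt["peak_times"], atol=1.5 / 600.0)

    def test_schedule_outside_duration_rejected(self, breathing):
        with pytest.raises(ValueError, match="outside"):
            simulate_breathing(breathing, [(0.0, 12.0, "sniff")], 10.0, 300.0, seed=1)

    def test_overlapping_schedule_rejected(self, breathing):
        with pytest.raises(ValueError, match="overlap"):
            simulate_breathing(
                breathing, [(0.0, 5.0, "sniff"), (4.0, 8.0, "eupnea")], 10.0, 300.0, 1
            )

    def test_seed_is_mandatory(self, breathing):
        with pytest.raises(ValueError, match="seed"):
            simulate_breathing(breathing, [], 10.0, 300.0, seed=None)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sniff_rate_hz=5.0),  # must exceed 6 Hz
            dict(eupnea_rate_hz=7.0),
            dict(eupnea_rate_hz=-1.0),
            dict(bout_duration_s=0.0),
        ],
    )
    def test_breathing_invariants(self, kwargs):
        with pytest.raises(ValueError):
            BreathingModelParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(onset_delay_s=1.5),
            dict(rise_tau_s=-1.0),
            dict(clear_tau_s=5.0),  # would leave >1% odor 10 s post-offset
        ],
    )
    def test_kinetics_invariants(self, kwargs):
        with pytest.raises(ValueError):
            OdorKineticsParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(slope=0.0),
            dict(lapse=1.5),
            dict(dilution_series=(-2.0, -3.0)),
            dict(inter_stimulus_s=12.0),
            dict(sample_rate_hz=20.0),
        ],
    )
    def test_detection_and_design_invariants(self, kwargs):
        with pytest.raises(ValueError):
            if "slope" in kwargs or "lapse" in kwargs:
                DetectionModelParams(**kwargs)
            else:
                SessionDesign(**kwargs)


class TestOdorProfile:
    def test_zero_before_arrival(self, kinetics):
        grid = np.arange(0, 40, 0.01)
        c = odor_concentration_profile(kinetics, 10.0, 6.0, grid)
        assert np.all(c[grid <= 10.0 + kinetics.onset_delay_s] == 0.0)

    def test_below_1pct_of_peak_10s_after_offset(self, kinetics):
        grid = np.arange(0, 40, 0.01)
        c = odor_concentration_profile(kinetics, 10.0, 6.0, grid)
        peak = c.max()
        t_off = 10.0 + kinetics.onset_delay_s + 6.0
        assert c[np.searchsorted(grid, t_off + 10.0)] < 0.01 * peak

    def test_peak_at_end_of_delivery_first_order(self, kinetics):
        grid = np.arange(0, 40, 0.01)
        c = odor_concentration_profile(kinetics, 10.0, 6.0, grid)
        t_off = 10.0 + kinetics.onset_delay_s + 6.0
        assert abs(grid[np.argmax(c)] - t_off) <= 0.01 + 1e-9
        # closed-form first-order step response value at the peak
        assert np.isclose(c.max(), 1.0 - np.exp(-6.0 / kinetics.rise_tau_s), atol=1e-6)

    def test_monotone_rise_and_fall(self, kinetics):
        grid = np.arange(0, 40, 0.01)
        c = odor_concentration_profile(kinetics, 5.0, 6.0, grid)
        rising = (grid >= 5.0) & (grid <= 5.0 + kinetics.onset_delay_s + 6.0)
        falling = grid > 5.0 + kinetics.onset_delay_s + 6.0
        assert np.all(np.diff(c[rising]) >= 0)
        assert np.all(np.diff(c[falling]) <= 0)
        assert np.all((c >= 0) & (c <= 1))


class TestSessionStructure:
    def test_default_design_emits_11_vehicle_then_7_ascending(self):
        d = SessionDesign()
        events = d.trial_events("heptanal")
        assert len(events) == 18
        assert sum(e.is_vehicle for e in events) == 11
        assert all(e.is_vehicle for e in events[:11])
        dils = [e.log10_dilution for e in events[11:]]
        assert dils == [-8.0, -7.0, -6.0, -5.0, -4.0, -3.0, -2.0]
        assert np.allclose(np.diff([e.valve_open_s for e in events]), 60.0)

    def test_session_ground_truth_one_row_per_trial(
        self, design, breathing, kinetics, detection
    ):
        s = simulate_session(
            design, breathing, kinetics, detection, "m1", "control", seed=2
        )
        assert len(s.events) == 18
        assert len(s.ground_truth) == 18
        assert (s.ground_truth["stimulus"] == VEHICLE_LABEL).sum() == 11

    def test_saturated_psychometric_plants_bout_in_all_7_odor_trials(
        self, design, breathing, kinetics
    ):
        det = DetectionModelParams(threshold_log10=-12.0, slope=6.0, lapse=0.0)
        s = simulate_session(design, breathing, kinetics, det, "m1", "c", seed=3)
        odor = s.ground_truth[s.ground_truth["stimulus"] != VEHICLE_LABEL]
        assert odor["detected_flag"].all()
        assert odor["bout_start_s"].notna().all()

    def test_vehicle_trial_1_always_evokes_novelty_bout(
        self, design, breathing, kinetics, detection
    ):
        for seed in range(5):
            s = simulate_session(
                design, breathing, kinetics, detection, "m", "c", seed=seed
            )
            assert bool(s.ground_truth.iloc[0]["detected_flag"])

    def test_seed_mandatory(self, design, breathing, kinetics, detection):
        with pytest.raises(ValueError, match="seed"):
            simulate_session(design, breathing, kinetics, detection, "m", "c", None)


class TestDetectionStatistics:
    def test_detected_counts_match_psychometric_expectation(
        self, breathing, kinetics
    ):
        # short sessions: the detection statistics depend only on the series
        d = SessionDesign.scaled(n_vehicle_trials=1)
        ctrl = DetectionModelParams()
        treated = replace(ctrl, group_effect_log10=3.0)
        counts = {"c": [], "t": []}
        for k in range(250):
            for key, det in (("c", ctrl), ("t", treated)):
                s = simulate_session(
                    d, breathing, kinetics, det, "m", key, seed=7000 + k,
                    make_waveform=False,
                )
                g = s.ground_truth
                counts[key].append(
                    g.loc[g["stimulus"] != VEHICLE_LABEL, "detected_flag"].sum()
                )
        diff = np.mean(counts["c"]) - np.mean(counts["t"])
        expected = expected_detected_count(d, ctrl) - expected_detected_count(d, treated)
        sem = np.sqrt(
            np.var(counts["c"], ddof=1) / 250 + np.var(counts["t"], ddof=1) / 250
        )
        assert abs(diff - expected) < 3 * sem + 1e-9
        assert np.mean(counts["t"]) < np.mean(counts["c"])

    def test_psychometric_shape(self, detection):
        d = np.array([-8.0, -5.5, -2.0])
        p = psychometric(d, detection)
        assert np.all(np.diff(p) > 0)
        assert abs(p[1] - (1 - detection.lapse) / 2) < 1e-12


class TestCohort:
    def test_null_cohort_effect_near_zero(self, design, breathing, kinetics, detection):
        c = simulate_cohort(
            (5, 5),
            design,
            breathing,
            kinetics,
            {"control": detection, "treated": detection},
            seed=17,
            make_waveform=False,
        )
        # zero expected difference; bound is ~3 SD of the sampling noise
        # (per-trial SD ~19 pct over 21 trials/mouse, 5 mice/group)
        assert abs(c.gt_effect_pct) < 8.0

    def test_same_seed_reproduces_cohort_exactly(
        self, design, breathing, kinetics, detection
    ):
        kw = dict(odors=("heptanal",))
        dets = {"control": detection, "treated": detection}
        a = simulate_cohort((2, 2), design, breathing, kinetics, dets, 5, **kw)
        b = simulate_cohort((2, 2), design, breathing, kinetics, dets, 5, **kw)
        for sa, sb in zip(a.sessions, b.sessions):
            assert np.array_equal(sa.trace.data, sb.trace.data)
            assert sa.ground_truth.equals(sb.ground_truth)

    def test_different_seed_same_schedule_different_noise(
        self, design, breathing, kinetics, detection
    ):
        dets = {"control": detection, "treated": detection}
        kw = dict(odors=("heptanal",))
        a = simulate_cohort((2, 2), design, breathing, kinetics, dets, 5, **kw)
        b = simulate_cohort((2, 2), design, breathing, kinetics, dets, 6, **kw)
        for sa, sb in zip(a.sessions, b.sessions):
            assert [e.valve_open_s for e in sa.events] == [
                e.valve_open_s for e in sb.events
            ]
            assert not np.array_equal(sa.trace.data, sb.trace.data)

    def test_too_few_mice_rejected(self, design, breathing, kinetics, detection):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_cohort(
                (1, 3),
                design,
                breathing,
                kinetics,
                {"a": detection, "b": detection},
                seed=1,
            )


class TestCalibration:
    def test_calibrated_effect_converges_to_target_at_200_mice(
        self, design, breathing, kinetics, detection
    ):
        target = 12.1
        treated = calibrate_group_effect(
            target, design, breathing, kinetics, detection, seed=21
        )
        assert treated.group_effect_log10 > 0
        c = simulate_cohort(
            (100, 100),
            design,
            breathing,
            kinetics,
            {"control": detection, "treated": treated},
            seed=99,
            odors=("heptanal",),
            make_waveform=False,
        )
        # law of large numbers: generative effect near the configured target
        assert abs(c.gt_effect_pct - target) < 3.5

    def test_unattainable_target_rejected(self, design, breathing, kinetics, detection):
        with pytest.raises(ValueError, match="not attainable"):
            calibrate_group_effect(
                80.0, design, breathing, kinetics, detection, seed=1, n_cal_sessions=20
            )
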