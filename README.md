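# plethysniff

Semi-automated quantification of odor-evoked investigatory sniffing from
whole-body plethysmography, for olfactory detection-sensitivity testing in
mice.

Mice respond to an odor they detect with stereotyped high-frequency sniffing
(> 6 Hz); hyposmic animals spend less time sniffing when odors of increasing
concentration are presented. `plethysniff` turns raw chamber-pressure
waveforms plus a stimulus log into that readout and its group-level
statistics:

1. **Signal chain** — common-noise rejection across the simultaneously
   recorded chamber pair, 1–15 Hz 2nd-order Butterworth band-pass
   (zero-phase), inspiration-peak detection (one maximum per respiratory
   cycle, cycles delimited by upward zero crossings), and instantaneous
   frequency `f(t) = 1/(t_{i+1} - t_i)` resampled as a step function onto a
   100 Hz grid.
2. **Metrics** — per trial, the time within the 8 s analysis window
   (starting 1 s after the odor valve opens) that `f(t)` strictly exceeds
   6 Hz, reported in seconds and as a percentage of the window; the modal
   baseline frequency over −20…0 s before valve opening; vehicle-trial
   habituation curves.
3. **Statistics** — a linear mixed model on `sqrt(invest_pct)` with a
   treatment fixed effect, odor covariate and crossed random intercepts for
   mouse and dilution; per-dilution treatment contrasts with
   Benjamini–Hochberg correction; permutation tests for ordinal pathology
   score tables.
4. **Simulator** — fully ground-truthed synthetic sessions of the
   odor-staircase paradigm (11 vehicle presentations, then liquid dilutions
   10⁻⁸ … 10⁻² of one odorant, one stimulus per minute, 6 s delivery,
   600 Hz digitization), with a psychometric detection model, valve
   artifacts and chamber-pair common-mode noise, so every pipeline stage is
   testable without animal recordings.

## Worked example

```python
from plethysniff import (
    BreathingModelParams, DetectionModelParams, OdorKineticsParams,
    SessionDesign, InvestigatorySniffingModel, calibrate_group_effect,
    simulate_cohort,
)
from plethysniff.pipeline import cohort_metrics

design = SessionDesign.scaled()          # 20 s cadence, 150 Hz (fast variant)
breathing, kinetics = BreathingModelParams(), OdorKineticsParams()
control = DetectionModelParams()
treated = calibrate_group_effect(        # plant a 12.1-point deficit
    12.1, design, breathing, kinetics, control, seed=11)

cohort = simulate_cohort(
    (5, 6), design, breathing, kinetics,
    {"control": control, "treated": treated}, seed=42,
    odors=("heptanal", "isoamyl acetate", "1,7-octadiene"))

metrics = cohort_metrics(cohort)         # signal chain + per-trial metrics
results = InvestigatorySniffingModel(
    metrics, group_order=("control", "treated")).fit()
print(results.summary())
```

This prints (numbers from this exact invocation):

```
Investigatory sniffing mixed model
==================================
response: invest_pct (transform: sqrt)
groups: control (reference) vs treated
random effects: ['dilution', 'mouse']
n trials: 231

treatment contrast (treated - control, sqrt scale): -1.7599 (SE 0.2951), p = 2.46e-09
raw-scale mean difference (control - treated): 12.71 percentage points (95% CI 9.21 to 16.22)
```

The treated group was simulated with a 12.1-point deficit in percent
investigatory time; this cohort realizes a 12.71-point generative
difference, and the full pipeline recovers exactly that, with the planted
value inside the 95% interval. `results.per_dilution()` gives the seven
BH-corrected per-dilution contrasts, and `results.plot_by_dilution()` the
familiar mean ± SEM staircase figure.

A command-line interface wraps the same stages:

```sh
plethysniff simulate --config cfg.yaml --seed 1 --out session_dir
plethysniff metrics  --in session_dir --out metrics.csv
plethysniff stats    --metrics metrics.csv --out results.csv
plethysniff run      --seed 1 --out bundle_dir     # all-in-one
```

## Layout

- `src/plethysniff/simulate.py` — generative model and effect calibration
- `src/plethysniff/signal.py` — filtering, peak detection, frequency series
- `src/plethysniff/metrics.py` — windowed sniffing metrics
- `src/plethysniff/stats.py` — mixed models, contrasts, BH, permutation tests
- `src/plethysniff/validation.py` — replicated parameter-recovery studies
- `src/plethysniff/pipeline.py`, `io.py`, `cli.py` — orchestration, CSV I/O, CLI
- `docs/methods.md` — model assumptions, conventions and limitations
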