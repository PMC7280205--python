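# Methods

## The readout

Whole-body plethysmography records chamber-pressure fluctuations from an
unrestrained mouse; each inspiration produces one pressure peak.
Investigatory sniffing — the stereotyped > 6 Hz respiratory mode mice enter
when they detect a novel stimulus — is quantified as the time, out of a
fixed 8 s analysis window beginning 1 s after the odor valve opens, during
which instantaneous respiratory frequency strictly exceeds 6 Hz. The 1 s
lag covers odor transport into the chamber (a few hundred ms) and skips the
brief (< 500 ms) valve-onset pressure artifact; the fixed 8 s denominator
makes the percent-time metric comparable across trials. Samples at exactly
6.000 Hz count as non-investigatory (strict inequality), and window samples
with no defined frequency (before the first or after the last detected
peak) count as non-investigatory rather than shrinking the denominator.

## Signal chain

- **Common-noise rejection.** Two chambers are recorded simultaneously and
  share acoustic/mechanical noise. Each trace is regressed on its partner
  (OLS on mean-subtracted signals) and the fitted component subtracted.
  This removes the linearly predictable shared part: a fully common pair
  maps to zero and independent traces pass through unchanged. Suppression
  of a shared component scales as its share of the partner's total power,
  so the stage is effective for large shared transients and only
  attenuates low-level shared noise; it degrades to an identity
  pass-through (with a logged warning) for single-chamber data. A
  samplewise-mean estimate of the shared component was rejected because it
  contains the target trace itself and therefore cancels genuine breathing
  signal even for independent chambers.
- **Band-pass.** 1–15 Hz Butterworth, 2nd order, applied forward–backward
  (zero phase) so peak times are not shifted; the effective roll-off is
  twice the nominal order. The band covers the full respiratory range
  (eupnea ≈ 2–4 Hz, sniffing 6–12 Hz).
- **Peak detection.** Respiratory cycles are delimited by upward zero
  crossings of the band-passed signal, with the trace edges closing the
  first and last partial cycles; the inspiration peak is each cycle's
  maximum sample (first maximum on exact ties, matching a brute-force
  scan). Cycle peaks must exceed a robust amplitude gate of 0.5 × MAD of
  the filtered trace. For the near-sinusoidal cycles this rejects
  noise-split micro-cycles (an order of magnitude smaller) while passing
  sniff cycles, whose band-passed amplitude is roughly 0.6 × MAD here; a
  conventional 3 × MAD gate would sit *above* the cycle amplitude of a
  quasi-sinusoidal signal and reject every true peak, which is why the
  lower constant is used. The gate scales with the trace, making detection
  equivariant to amplitude scaling. A minimum inter-peak interval of
  1/15 s is enforced by keeping the larger of two conflicting peaks.
- **Instantaneous frequency.** For peaks `t_i`, the frequency
  `1/(t_{i+1}−t_i)` is assigned to the half-open interval `(t_i, t_{i+1}]`
  as a step function and sampled onto a uniform 100 Hz grid by
  sample-and-hold (no interpolation, preserving threshold-crossing
  durations). Values are undefined outside `[t_1, t_last]`. Peak times are
  quantized to the digitization grid, so a constant true rate r is
  recovered within ~r²/fs Hz.

## Metrics conventions

- **Baseline modal frequency**: histogram of valid frequency samples over
  the 20 s before valve opening, 0.5 Hz bins *centered* on multiples of
  0.5 Hz (edges at k·0.5 − 0.25), ties toward the lower bin, bin center
  returned. Centering on the half-integer grid means pure breathing states
  at 3.0 or 9.0 Hz map to themselves.
- **Habituation curves**: per vehicle trial, the mean of valid frequency
  samples over the same lagged 8 s window (the window maximum is available
  via `statistic="peak"`); plotted against the 6 Hz line, trial 1 shows the
  novelty response and later trials its habituation.

## Statistical model

Per-trial percent investigatory time is bounded and right-skewed, so the
mixed model is fitted on `sqrt(invest_pct)`: treatment fixed effect, odor
as a fixed covariate, and crossed random intercepts for mouse and dilution
(variance components within a single grouping). Inference on the treatment
contrast is large-sample Wald (recorded in the result metadata). A
singular or non-converged fit drops the dilution component with a logged
warning; a constant response returns a zero contrast exactly. Because the
square-root-scale contrast is not directly interpretable, the headline
effect is reported on the raw scale as the difference of group means of
per-mouse mean `invest_pct`, with a Welch t 95% interval; no
back-transformation of the model contrast is attempted. Per-dilution
contrasts refit the model within each dilution (random mouse intercept,
falling back to OLS for near-degenerate responses) and are corrected
across the seven-dilution family with Benjamini–Hochberg; the family is
the dilutions within one timepoint × sex, the narrowest reading consistent
with the design. The per-dilution response is the same `invest_pct`
(configurable), keeping one response definition across both analyses.

Ordinal pathology scores (0–5 in 0.5 steps per section, averaged per
animal and region) are compared by a two-sided permutation test on the
difference of group means: exhaustive enumeration when the number of label
assignments is ≤ 20,000, otherwise Monte-Carlo with +1 smoothing (≥ 100
draws enforced), BH-corrected across regions.

## Generative model

Breathing is a two-state renewal process. Each cycle draws its rate from
the active state's normal distribution — eupnea 3.0 ± 0.35 Hz (clipped to
1.2–5.7), sniffing 9.0 ± 0.8 Hz (clipped to 6.3–14.5) — so every generated
rate stays inside the 1–15 Hz analysis band and on the correct side of the
6 Hz criterion. A cycle contributes one raised-cosine pressure cycle
(single maximum at the cycle midpoint = the ground-truth inspiration
peak); sniff cycles have 0.6 × the eupneic amplitude, reflecting
shallower, faster breaths.

A session is the staircase paradigm: 11 vehicle presentations then seven
ascending log10 dilutions (−8 … −2) of one odorant, one stimulus per
minute, 6 s delivery, 600 Hz digitization, 30 s pre-roll. Odor
concentration follows first-order kinetics (0.3 s transport delay, 1.5 s
rise and clearance constants, < 1% of peak remaining 10 s after offset).
Detection of an odor trial is Bernoulli with probability
`(1 − lapse)/(1 + 10^(−slope·(d − θ)))` at log10 dilution d (θ = −5.5,
slope = 1 per decade, lapse = 0.05). A detected trial plants a sniff bout
starting at valve opening + transport delay + a reaction time
(0.5 ± 0.15 s, truncated to 0.1–1.5 s) with gamma-distributed duration
(mean 3.5 s, shape 4). Vehicle trial 1 always evokes a novelty bout;
the bout probability then decays geometrically (factor 0.35 per trial),
reproducing the qualitative habituation pattern. Spontaneous bouts occur
at 2/min (mean 1 s) throughout. Hyposmia is modelled as a rightward
psychometric threshold shift (`group_effect_log10`) and optionally a bout
duration gain — detection is impaired while novelty and spontaneous
sniffing (motor capacity) are untouched.

Waveform nuisances: a 300 ms half-sine valve-onset transient (amplitude
0.3, shared within a chamber pair), band-limited (0.1–20 Hz) common-mode
noise shared by the pair (SD 0.02), and white per-chamber sensor noise
whose SD (0.05) is referenced to 600 Hz digitization and scaled by
√(fs/600) so the noise spectral density — and hence the in-band noise the
filter passes — is independent of the simulated sample rate. These levels
describe a clean laboratory signal with an in-band SNR of roughly 20:1;
none of the amplitude statistics are published for the reference
apparatus, so they are package conventions, chosen so that simple
cycle-maximum peak detection operates in its intended regime.

**What the simulator does not emulate**: movement and postural artifacts,
sighs and grooming bouts, drift in chamber temperature/humidity, sex or
individual differences in breathing frequency, arousal-driven
non-olfactory sniffing correlated with trial events, or real psychometric
shapes. Passing recovery tests therefore demonstrates that the pipeline
is faithful to this generative model, not that the defaults reproduce any
particular animal's signal statistics.

## Ground truth and effect-size calibration

Per trial the simulator records the planted bout and, independently of the
signal chain, the investigatory time implied by the *ground-truth* peak
train itself (what an ideal peak detector would measure). The generative
cohort effect is the group difference of per-mouse mean ground-truth
percent investigatory time over odor trials.

To plant a target group difference Δ, note the expected per-odor-trial
percent time is `b + p̄·(m − b)`, where p̄ is the psychometric detection
probability averaged over the seven dilutions and m/b are the conditional
means given a planted bout / no bout. m and b are estimated once by Monte
Carlo on ground-truth cycles (200 sessions each with detection forced
on/off; no waveform synthesis), and the treated group's threshold shift is
then solved by bisection so that `(p̄_control − p̄_treated)(m − b) = Δ`.
Calibration accuracy is limited by the Monte-Carlo error in m − b (~1–2%
relative, i.e. ~0.2 points on a 12-point effect).

## Validation studies

`plethysniff.validation.run_recovery_study` plants a reference effect
size, simulates full cohorts and compares the pipeline's recovered
raw-scale difference with the planted value across replicates (mean error,
95%-CI coverage, power at α = 0.05). The recovery studies and the
acceptance script use a desk-scale session design — identical trial
structure but 20 s inter-stimulus cadence, 25 s pre-roll and 150 Hz
sampling — so that 100 replicates of a full cohort run in minutes on one
CPU; the default `SessionDesign` keeps the reference protocol (60 s
cadence, 600 Hz). 150 Hz is still ten times the 15 Hz band edge, and the
20 s cadence preserves the > 10 s chamber-clearance margin after the 6 s
delivery.

## Numerical choices and degenerate inputs

- Windows are half-open `[start, end)` with sample counts computed by
  rounding window edges to the 100 Hz grid; investigatory time is
  `count/rate` so the 8 s window maximum is exact.
- Zero-jitter cycle filling yields exactly `floor(duration × rate)` cycles
  per state segment; a trailing remainder shorter than one period is left
  as a breathing pause.
- An all-zero trace yields an empty peak train (not an error); fewer than
  two peaks yield an all-masked frequency series; an empty baseline window
  yields NaN with a logged warning.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning (per mouse × odor × pair), so
  cohorts are bit-reproducible and stimulus schedules are seed-invariant.
- With zero cycle jitter, two simulated mice breathe exactly periodically
  at the same rate, making their signals mutually coherent; pairwise
  common-noise rejection would then (correctly, by its own criterion)
  remove breathing signal. This degenerate alignment does not arise with
  realistic jitter and is avoided in fidelity tests by processing such
  cohorts single-chamber.

## Known limitations

- The pairwise rejection stage cannot remove shared noise that is small
  relative to the partner's breathing signal (the projection coefficient
  shrinks with the shared-power fraction); the defaults keep common-mode
  noise modest accordingly.
- Wald inference on the mixed model is anti-conservative in principle at
  very small mouse counts; empirically the per-dilution BH family-wise
  false-positive rate is at or below nominal under the null (see the
  calibration tests), but no small-sample degrees-of-freedom correction is
  applied.
- The buried-pellet behavioral assay and histology image processing are
  out of scope; pathology enters only as ordinal score tables.
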