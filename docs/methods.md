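# Methods

## The RAP index and the derivation chain

Intracranial pressure (ICP) monitoring in moderate/severe traumatic brain
injury provides more than a number to threshold: the relationship between
slow ICP changes and the cardiac pulse amplitude of ICP (AMP) indexes the
brain's compensatory reserve.  On the flat part of the pressure–volume
curve, volume perturbations barely change pulse amplitude (AMP and mean
ICP decorrelate); as reserve is exhausted, both rise together.  RAP
captures this as a moving Pearson correlation:

* raw ICP and arterial pressure (ABP) waveforms (>= 100 Hz) are decimated
  to non-overlapping 10-s means (MAP is the 10-s mean of the ABP waveform,
  i.e. the time-averaged pressure — no systolic/diastolic weighting);
* AMP is the amplitude of the fundamental cardiac harmonic of each 10-s
  ICP block.  The fundamental is located as the spectral peak within the
  cardiac band 40–180 beats/min; its amplitude is computed from the
  spectral energy in the peak DFT bin ±2 neighbours, `2·sqrt(Σ|X|²)/N`,
  because the single-bin estimator loses up to ~36% amplitude when the
  heart rate falls between bins (scalloping); the energy-sum form is exact
  on-bin and within a few percent at worst-case offsets;
* RAP(t) = Pearson r over the 30 consecutive 10-s means of (ICP, AMP)
  ending at t (a 5-min window, right-aligned/causal), updated every
  minute; PRx is the same construction on (ICP, MAP);
* CPP = MAP − ICP;
* validity filtering blanks samples with ICP outside (−15, 100) mmHg or
  MAP outside (0, 200) mmHg, together with every derived value at the same
  timestamps;
* coarser resolutions (10/30/60 min) are non-overlapping block means of
  the minute-level series; blocks over 50% missing are missing, and
  correlation windows over 25% missing pairs are missing (a conservative
  default — the windows still contain ≥ 22 of 30 samples).

RAP is classified into three states: impaired reserve (RAP ∈ [0.4, 1]),
intact reserve ((0, 0.4)), exhausted reserve ([−1, 0]).  Boundaries go to
the outer states (0.4 → impaired, 0 → exhausted).  Subgroup comparisons
use the two-sided Mann–Whitney U test for two groups and one-way ANOVA for
more; per-sample threshold groupings (e.g. ICP below 20 vs above 22 mmHg)
exclude samples inside the dual-threshold dead zone.  The unit of analysis
is the caller's choice: `compare_groups` accepts either per-patient
summaries (one value per patient, the conservative default in the worked
examples) or pooled minute-level samples — both are legitimate readings of
subgroup testing on monitoring data, and they answer different questions.

## ARIMA structure analysis

The minute-level series are trend-heavy: ADF typically rejects a unit root
while KPSS rejects level-stationarity, the signature of trend dominance.
The pipeline therefore applies a first-order difference *after* temporal
resampling and fits ARMA(p, q) with a constant on the differenced series
(reported as ARIMA(p, 1, q) against the original).  A series is called
stationary only when ADF p < 0.05 *and* KPSS p > 0.05; KPSS p-values come
from truncated tables and are flagged when bounded; series under 20
samples return an insufficient-data marker rather than a verdict.

The optimal model is the AIC argmin over the exhaustive (p, q) grid
(default bounds 0–10, configurable).  Two estimation details matter:

* both available exact-MLE estimators (state-space optimizer and the
  innovations-algorithm MLE) give identical likelihoods but very different
  runtimes; the package picks the state-space path below 1500 samples and
  the innovations path above, where each is faster;
* an optimizer that stops without converging can report an inflated
  likelihood at near-boundary parameters and would otherwise win the
  argmin; non-converged fits are excluded from selection and recorded in
  the grid table as explicit markers (no silent gaps);
* mixed fits whose AR and MA inverse roots (nearly) coincide carry a
  common factor — a redundant parameter pair on a likelihood ridge, the
  classic Box–Jenkins overparameterization pathology — and are likewise
  excluded from selection (tolerance 0.02 on inverse-root distance).
  Without this guard, an exhaustive grid on a true ARMA(2,2) at n = 5000
  picks redundant (4,4)-type models in roughly a third of realizations.

AIC ties break to smaller p + q, then smaller p.  Population structure is
the componentwise median of per-patient optimal orders, with half-integer
medians rounded half-to-even.  Model adequacy is checked by the median
absolute residual, residual variance vs data variance, and the number of
ACF/PACF values at lags 1–30 exceeding the white-noise band ±1.96/√N; the
ARIMA(0, 0, 0) fit on the undifferenced series serves as the raw-data
baseline (its residuals are the demeaned data).  The constant is included
at every order (the general model includes an intercept; dropping it is a
configuration choice, not the default).

## Artifact discrimination

Expert cleaning removes artifact rows from exports, so aligning a clean
against a non-clean export (timestamp match within half the sampling
interval) recovers a ground-truth artifact mask.  Three feature families
separate artifact segments from clean data, each evaluated by a sliding
window (window/step 100/50 at 1-min, 50/25 at 10-min for the order rule;
50/25 for the other two; "sample size" in the published procedure is read
as the window stride, giving 50% overlap):

1. **Order deviation** — per window, the optimal ARIMA orders; flagged
   when any order differs from the clean reference model by more than 3.
   Per-window AIC selection at n = 100 occasionally lands spuriously far
   from the reference (measured null flag rate ~13% at these settings),
   which is the false-positive floor of this rule.
2. **Residual variance** — per window, residuals under the clean median
   model with coefficients re-estimated; flagged when variance strictly
   exceeds the recording's median of window variances.  By construction
   about half the clean windows exceed their own median: the rule is
   sensitive but false-positive-heavy, and the evaluator reports both.
3. **Residual cross-correlation** — RAP residuals vs parent (AMP
   recommended; ICP is unreliable) residuals per window; flagged when the
   maximum unnormalized cross-correlation (full lag range, sliding dot
   product) falls strictly below the recording's median of window maxima.

All thresholds are strict; ties never flag.  Detection is evaluated at
sample level: success = captured/true × 100, false positives = detected
outside truth.  Segment-level capture is available as an option.  Artifact
segments individually too short for model fitting are concatenated per
patient.

## The synthetic generator

No public archive of this kind of data exists, so every study above runs
on synthetic data designed to reproduce the features the pipeline
exercises — not waveform morphology:

* **Pulsatile waveforms.**  ICP = baseline + slow random-walk trend
  (N(0, trend_sd) steps every 10 s, interpolated) + respiratory
  oscillation + cardiac pulse (fundamental + 0.3× second harmonic) +
  white noise.  The pulse amplitude is
  `pulse_amplitude · exp(coupling·z(t) + jitter·η(t))` with z the
  standardized slow trend and η an independent smooth unit-variance
  process (beat-to-beat amplitude variability, default jitter 0.1).  The
  exponential keeps amplitude positive at any coupling in [−1, 1] (a
  linear form would clip and distort the high-coupling regime), and the
  jitter grades the within-window ICP–AMP correlation smoothly with
  |coupling| instead of saturating at ±1.  Defaults: 100 Hz, heart rate
  70/min, respiration 16/min, ICP baseline 15 mmHg, ABP 90 mmHg, pulse
  amplitude 2 mmHg, trend step 0.2 mmHg, noise 0.3 mmHg.  P1/P2/P3
  morphology is deliberately absent: AMP is spectral, so only the
  fundamental's amplitude matters downstream.
* **ARMA ground truth.**  Series of known (p, d, q) and coefficients with
  Gaussian innovations (stationarity and invertibility validated, long
  burn-in for slowly mixing components); d = 1 returns the cumulative sum.
* **Artifacts.**  Five event kinds — spike trains (short bursts of sharp
  alternating deflections, flush/ringing morphology), flatlines, steps,
  noise bursts, dropouts — at a Poisson event rate with uniform durations
  and magnitudes.  Magnitudes are multiples of an amplitude reference:
  the per-sample SD for pulsatile waveforms, the SD of first differences
  for trend-dominated index series (whose per-sample SD grows with
  recording length and is not a fluctuation scale).  The ground-truth mask
  marks exactly the modified samples.
* **Cohorts.**  Per-patient seeds spawn deterministically from a master
  seed; admission covariates follow severe-TBI conventions (age ≈
  N(43, 21) clipped, ~82% male, typical pupil and Marshall-grade
  frequencies), and the default waveform sampler ties coupling to
  Marshall grade (II 0.15 → IV 0.75, V 0.6) so injury severity orders
  group RAP by construction.

What passing tests show — and what they do not: the generators reproduce
the correlation structure, trend behaviour, ARIMA-visible dynamics and
artifact statistics the pipeline measures; they do not validate waveform
morphology, Lundberg plateau waves, hemodynamics, or clinical covariate
effects beyond the couplings built in.

## Benchmark study designs and problem sizes

The `rapkit.benchmark` module freezes the synthetic study conditions used
by the acceptance tests and `scripts/acceptance.py`:

* *Oracle equivalence*: 1000 random 5-min windows; pipeline RAP vs an
  independent two-pass Pearson computation, agreement to 1e-12.
* *Coupling recovery*: coupling 0.9/0/−0.9, five 2-h recordings each.
* *Order recovery*: ARMA(2,2) (φ = 0.75, −0.5; θ = 0.65, 0.35) and
  ARMA(3,3) (AR root pair 0.9∠±2π/7 plus real root −0.6; MA root pair
  0.8∠±2π/3 plus real root 0.5), n = 5000, 20 seeds, AIC grid over
  p, q ≤ 4.  Coefficients were designed for identifiability — root
  configurations with near AR/MA cancellation make the order genuinely
  unrecoverable at any sample size.  The reduced grid strictly contains
  the ±1 neighbourhoods of the true orders and keeps the full study at
  minutes of single-CPU time rather than the hours an 11×11 grid costs.
* *Stationarity*: 100 random walks of n = 1000, tested raw and
  differenced.
* *Residual reduction*: four 2-h coupled recordings; per signal, median
  |residual| of the grid-optimal model vs the ARIMA(0,0,0) baseline.
* *Resolution degradation*: one 30-day minute-level recording from an
  ARIMA(3,1,3) generator whose AR part contains a slow damped oscillation
  (root-pair modulus 0.995, period 300 min — Lundberg-style slow-wave
  activity).  Hourly aggregation maps that pair near modulus 0.74 with
  period 5 samples, which the hourly median model (1,1,1) cannot
  represent, while (3,1,3) captures it at minute resolution: model
  quality degrades with resolution by construction, as it does in
  practice through data loss.
* *Detector suite*: a 50-h minute-level ARIMA(1,1,1) recording with ~5%
  oscillatory-interference artifacts (spike trains at 6–10× the increment
  SD, 10–30 min events).  Interference is the artifact family visible to
  all three feature families; noise bursts are order-invisible (their
  differences fit low MA orders) and flatlines *lower* residual variance,
  so a mixed taxonomy would measure composition rather than power.  The
  cross-correlation detector runs on a separately constructed coupled
  pair sharing innovations, with artifact segments decoupled by replacing
  the parent's increments with an independent realization.

## Known limitations

* The d-order is fixed to {0, 1}; automatic differencing-order selection
  and seasonal terms are out of scope.
* The residual-variance detector's median threshold guarantees a high
  false-positive load on clean data; it is reported, not corrected.
* KPSS p-values are table-bounded; verdicts near the truncation points
  carry a flag rather than an exact p-value.
* The cohort covariate model is a sampling convenience, not an
  epidemiological model; subgroup tests on it validate plumbing and
  test behaviour, not clinical effect sizes.
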