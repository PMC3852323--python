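# Methods

## The calibration problem

Respiratory effort belts around the rib cage and abdomen measure dimensional
changes of the two moving compartments of the respiratory system.  After
calibration against a spirometer they can substitute for it in long-term,
unobtrusive monitoring.  The classical calibration is a multiple linear
regression with one sample of each belt per prediction,

    y[t] = b1 * x1[t] + b2 * x2[t] + e[t],

with `y` spirometer airflow, `x1`/`x2` the rib-cage/abdomen belt signals.
This assumes the belt waveforms already look like the airflow waveform.  They
do not: the belts observe (filtered) compartment *dimension*, through sensor
dynamics that differ between belt types, while the spirometer observes
*flow*, with its own dynamics and an inter-device latency.

## The MISO FIR model

`respcal` fits a multiple-input single-output FIR filter bank with an
integer delay:

    y[i + D] = beta1 . x1[i : i+N] + beta2 . x2[i : i+N] + e ,

i.e. each prediction uses N consecutive samples of each belt.  Row `i` of
the lagged design matrix `X` is `[x1[i..i+N-1], x2[i..i+N-1]]`, so signals
of length `L` give `n = L - N + 1` rows.  The taps
`beta = [beta1; beta2]` minimise `||y - X beta||` and are computed by an
SVD-based least-squares solve — the pseudo-inverse expression
`(X'X)^-1 X'y` is the mathematical definition, not the numerical recipe.
Rank-deficient problems return the minimum-norm solution with a warning.

**Window-to-taps convention.**  `N = floor(fs * T) + 1` with the inclusive
endpoint, which maps the two standard window choices 0.3 s and 0.15 s at
50 Hz onto N = 16 and N = 8.

**Anchoring.**  Row `i` (belt samples `i..i+N-1`) predicts `y[i + D]`.  The
anchoring of the window relative to the target is a free choice because the
delay element absorbs any constant lead or lag; it is fixed so that
serialized models are unambiguous.

**Delay estimation.**  `D` is found by sliding the spirometer signal
against the belt windows one sample at a time over ±1 s (configurable) and
re-solving the regression at every shift; the shift with minimal residual
RMS wins.  All candidate shifts are scored on the same fixed row window so
their residuals are comparable; this also allows one Gram-matrix
factorization to be reused across the grid (the final model is refit at the
chosen delay with the SVD path on all valid rows).  Numerical ties are
broken toward the smallest |d|, then toward negative d — the physically
minimal latency.

**Centering.**  Design-matrix columns and the target are centered by their
means over the training rows; the means are stored on the model and applied
at prediction.  Column centering (rather than centering the raw channels by
scalar means) makes an appended intercept column exactly inert, which is
the behaviour one wants from a model that claims an intercept is
unnecessary.  Subject-independent (pooled) models center each training
recording on its own — belt baselines are arbitrary per subject — and
re-center at prediction time on the evaluated segment.

**Nonlinear augmentation.**  Optional design-matrix columns (intercept,
squared belt samples, their cross product, each evaluated at the window's
first sample) are available behind `ExtraTerms` but off by default: for
common piezo and inductance belts the linear bank suffices.

**Reduction.**  With N = 1, no delay search and no extras the model is
exactly the standard two-coefficient regression; the two code paths agree
to 1e-10 and this is tested.

## Reference methods

* **Standard method** — ordinary least squares of flow on one sample of each
  belt; implemented as the degenerate N = 1, D = 0 FIR model so prediction
  and evaluation share one code path.
* **Five-feature minute-ventilation regression** — predicts minute
  ventilation (not the waveform) from the 10th and 90th percentiles of each
  belt over a segment plus the breathing frequency.  Percentiles use linear
  interpolation between order statistics (conventions differ, so this is
  explicit).  Breathing frequency is the dominant Welch-periodogram peak of
  the mean-removed belt-sum in 0.05–1.0 Hz; a rising-zero-crossing fallback
  is provided.  This model needs several (features, measured-MV) training
  segments — at least 6 for 5 slopes plus intercept — so it only enters the
  leave-one-subject-out comparison, not single-step cross-testing.

## Metrics

* `R^2 = 1 - SS_res / SS_tot` with `SS_tot` about the reference mean
  (switchable to raw sums of squares; airflow is near zero-mean so the two
  nearly coincide).  Negative values are meaningful: the prediction is
  worse than the mean.
* Relative RMSE: `100 * RMSE / RMS(y)` with the RMS over raw (not
  mean-removed) reference samples.
* Volume error: volumes are `(1/2) * trapz |flow| dt` (halved so inspired
  and expired volume are not double-counted); the error is signed with
  over-prediction positive.
* Bland–Altman data pairs the reference value with the error
  (reference − prediction) and reports bias ± 1.96 SD limits of agreement.

## Synthetic recordings

The generator realises the two-compartment picture the calibration
assumes plus the disturbances that break the standard method:

* **Breathing.**  Each breath is a raised-cosine inspiration (inspiratory
  fraction 0.4 of the period) followed by a gamma-like expiration
  `(1 + u/tau) exp(-u/tau)`, `tau = te/4`, normalized to end at exactly
  baseline volume.  Expiratory flow therefore starts at zero (continuous at
  the inspiration boundary), peaks early and decays — the asymmetric shape
  short FIR banks must and can correct.  Volume closes exactly each breath,
  so integrated flow over a breath vanishes up to trapezoid error.
* **Schedules.**  Metronome-controlled rates (0.10–0.33 Hz) or free
  breathing at 0.23 Hz nominal with 8 % breath-period jitter.  Tidal volume
  is 0.5 l with 5 % breath-to-breath jitter *in both modes*: subjects
  control timing, not depth.  The depth jitter also makes the two belt
  channels jointly identifiable — perfectly periodic noiseless compartments
  are collinear.
* **Sensors.**  Belts observe their compartment volume through short
  minimum-phase smoothing kernels (length 5, different per belt), a
  posture-dependent gain (supine 0.85/1.20, sitting 1/1, standing
  1.15/0.80 for rib cage/abdomen), a 0.01 Hz drift sinusoid of amplitude
  0.02 a.u., and white noise of sd 0.002 a.u. (~1 % of belt amplitude;
  inductance belts are clean, and belt noise acts as errors-in-variables
  that shrinks the fitted bank's high-frequency gain).  The spirometer is
  the analytic flow delayed by 5 samples (0.1 s) plus the same white noise.
* **Asynchrony.**  Thoracoabdominal asynchrony lags the abdominal
  compartment by a configurable number of samples (0.2 s in the TAA
  preset).  Note the MISO structure is transparent to TAA — each belt still
  maps to its own flow contribution — so the FIR bank tolerates it while
  the standard method's single weighted average does not.
* **Protocol presets.**  Thirteen scenarios mirror a twelve-step
  measurement protocol (free breathing supine/sitting/standing, the four
  controlled rates, two mid-step posture changes) plus the TAA variant of
  the 0.10 Hz step.  Cohorts draw per-subject kernels, compartment weights,
  gains and device delays around the presets, all from one root seed via
  deterministic substreams.

What the generator does **not** emulate: motion artefacts, sensor
saturation or detachment, cardiogenic oscillations, nonlinear
belt-to-volume compliance, posture-change transients (gains switch
instantaneously), or pathological flow shapes.  Passing tests therefore
demonstrate correctness of the estimation machinery and the qualitative
superiority of the FIR bank under rate transfer and TAA — not clinical
performance on human recordings.

## Known-system constructions

Recovery tests need a ground truth the model class can represent exactly.
With physiological sensors the exact belt-to-flow map is a derivative
composed with a kernel inverse — an IIR map no finite FIR matches to
1e-6.  `known_fir_recording` therefore builds the spirometer channel as an
*exact* FIR mixture of the generated belts plus an integer shift.  Kernels
of length exactly N make the (delay, taps) pair identifiable: with shorter
kernels a whole interval of delays fits exactly and "the" delay is
ill-posed.  These fits run with centering off (the constructed relation is
exact in raw coordinates) and with sensor texture on the belts (smooth
noiseless belts are numerically low-rank, which blurs the delay argmin).

## Problem sizes and numerical choices

Study-scale runs use one-minute steps at 50 Hz (3000 samples), ten-subject
cohorts and 100 replicate cohorts for the rate-transfer comparison; the
full acceptance run completes in well under a minute on a laptop core.
Delay-search ties use a relative tolerance of 1e-8 of the target RMS;
decimation uses a zero-phase windowed-sinc low-pass cut off at 0.8× the
target Nyquist with its length chosen to close the transition band before
the new Nyquist (> 40 dB alias suppression verified on white noise).
Degenerate inputs (constant reference, zero RMS or zero volume, constant
belts for the frequency estimator, empty channel overlap) raise typed
errors rather than returning NaN.

## Known limitations

* Delays are integer samples at the common rate; sub-sample latency is
  absorbed by the taps.
* No regularization: with very short segments or strongly collinear belts
  the minimum-norm fallback triggers (a warning is emitted) and
  out-of-sample behaviour degrades.
* The pooled subject-independent model carries a single delay (the mode of
  per-subject optima); subjects with deviant latency are not re-aligned.
* Minute-ventilation comparison assumes the spirometer flow is in l/s.
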