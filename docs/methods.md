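# Methods

`fetaldelta` implements an individualized early-warning analysis for fetal
cardiovascular decompensation during labor, built from three pieces: a
synthetic generator of RR-interval tachograms with the regime structure of a
graded umbilical-cord-occlusion (UCO) experiment, an HRV preprocessing stage
(quality filtering, 4 Hz resampling, windowed RMSSD), and a Gaussian-process
online change-point detector ("Delta point") whose output is scored against
sentinel annotations. This note records the model assumptions, the defaults
and why they were chosen, and the places where the design was genuinely open.

## The signal model

RMSSD — the root mean square of successive R-R interval differences over a
5-min window — is a short-term, vagally mediated HRV index that rises with
worsening fetal acidemia. The analysis treats the windowed RMSSD series
(5-min windows, 2.5-min steps, so a ~6 h record gives ~140 points) as a
stationary baseline process that, at a hidden per-fetus time, switches to a
rising regime. The detector's job is to localize that switch online, using
only past windows, with a controlled false-alarm rate.

Two versions of the series are computed from the same tachogram:

* **beat-exact** — successive differences of consecutive validated R-R
  intervals (the precision of a 1000 Hz fetal ECG channel);
* **resampled 4 Hz** — the R-R series interpolated onto a uniform 0.25 s grid
  with shape-preserving piecewise cubic Hermite interpolation (PCHIP), with
  RMSSD computed from differences of consecutive grid samples. This emulates
  the sampling rate of clinical ultrasound cardiotocography.

## Synthetic data generator

No public recordings exist for this experiment, so the generator is
first-class, tested code that emulates the study conditions:

* **Protocol.** 90 min baseline, then mild / moderate / severe UCO series
  (60 min, 60 min, up to 120 min), one 1-min occlusion every 2.5 min.
  Deceleration targets: −30 bpm (mild), −60 bpm (moderate); severe occlusions
  drive FHR toward a 65 bpm floor. Each deceleration is a trapezoid in FHR:
  45 s descent, 15 s nadir, 40 s recovery. The descent occupies most of the
  occlusion because variable decelerations deepen progressively during flow
  reduction; a 10 s descent would make the mechanical successive-difference
  contribution of moderate decelerations several times the baseline RMSSD,
  contradicting the flat pre-onset RMSSD tracings seen in real recordings.
  Severe decelerations deepen progressively from the moderate depth to the
  floor over the first 12 occlusions (~30 min), reflecting the gradual loss
  of compensation; an instantaneous full-depth onset is itself a regime
  change that any change-point detector must and does declare, which would
  mis-time fetuses whose decompensation falls late in the early-severe span.

* **Beat noise.** RR(t) = 60000/FHR(t) plus beat-to-beat noise: a
  unit-variance AR(1) sequence (φ = 0.3) scaled by
  1/√(2(1−φ)) so its successive-difference RMS equals the target RMSSD
  exactly (analytic calibration; verified within 10% by simulation), and
  multiplied by a slow amplitude modulation — Gaussian-smoothed white noise
  with ~7.5 min correlation time and 10% coefficient of variation,
  symmetric around 1. The modulation reproduces the window-to-window
  wandering of real RMSSD tracings and sets the scale against which the
  detector must discriminate; its timescale is the autonomic state-change
  timescale. Default baseline RMSSD is 3 ms at 160 bpm, a realistic
  near-term fetal sheep operating point.

* **Decompensation onset.** At the hidden onset time (drawn uniformly over
  the moderate stage plus the first quarter of the severe stage) the target
  RMSSD rises by an onset surge of 4 ms with a 50% transient overshoot
  decaying over ~7 min, then grows linearly at 6 ms/h. The surge models the
  rapid chemoreflex-mediated vagal activation at decompensation: published
  tracings show RMSSD rising severalfold within minutes of the event, and a
  purely linear 6 ms/h trend would put the first statistically significant
  window 5–10 min after onset, which is incompatible with the detection
  leads the method demonstrably achieves on real data.

* **Artifacts.** Non-physiologic beats (RR × 0.5 or × 2, equiprobable,
  always flagged) occur in bursts (log-normal duration around 7.5 min, ~70%
  of beats corrupted within a burst) whose number is set so the expected
  corrupted-beat fraction equals `artifact_rate` (default 2%). Bursts model
  electrode noise and disconnection episodes; window-level quality filtering
  is what must catch them.

What the generator does **not** model: raw ECG waveforms and R-peak detection
error, accelerations and behavioral-state cycling, blood-pressure or blood-gas
dynamics, unflagged physiologic ectopy, and the clinical 4 Hz acquisition
noise of autocorrelation-based ultrasound monitors (see "Known limitations").
Passing tests therefore demonstrate that the method recovers change points
under the stated regime structure and noise scales — not performance on real
monitor data.

## Quality filtering

Quality is assessed per 5-min window as a weighted sum (default equal
weights) of three fractions: time free of non-physiologic beats, time free of
inter-beat gaps longer than 2 s, and time outside a ±60 s reliability halo
around non-physiologic episodes (beat detection near noise is untrustworthy).
Windows with composite < 0.7 are masked — never deleted, so the time axis and
causal ordering are preserved. With the default artifact rate the discarded
fraction is ~3–6%, matching the discard range reported for real recordings.
Flagged beats are additionally excluded from RMSSD computation itself
(differences are never taken across an exclusion or a >2 s gap): a single
×2 outlier among 800 beats would otherwise inflate a window's RMSSD from
3 ms to ~18 ms, and no window-level threshold can compensate for that.
Unflagged beats are never filtered, mirroring the retention of ectopy in the
source pipeline.

## The Delta-point detector

* **Model.** A GP over window index with squared-exponential kernel plus
  independent noise, fit to the first 60 retained windows (~2.5 h — the
  baseline and mild stages, i.e., first-stage-of-labor data). Fitting is MAP
  with weak log-normal hyperpriors (lengthscale prior centered on 4 windows,
  the autonomic modulation timescale; variance priors centered on a 70/30
  signal/noise split of the training variance), optimized by L-BFGS-B from 5
  deterministic starts. Pure maximum likelihood on 60 points produces
  overconfident fits often enough to double the false-alarm rate; the weak
  priors regularize without moving well-identified optima. A constant
  training series triggers a 1e-6 (ms)² variance floor.

* **Online prediction.** For each later retained window, the predictive
  distribution conditions on all past retained windows (growing window,
  strictly causal). The reported predictive SD is the GP SD multiplied by a
  recalibration scale, and the two-sided tail probability is
  p = 2(1 − Φ(|obs − mean| / SD)).

* **Predictive-scale recalibration.** Plug-in GP predictives computed from
  hyperparameters estimated on 60 windows are systematically overconfident
  out of sample. The scale is therefore (i) warm-started by forward
  validation — hyperparameters are refit on the first 45 training windows
  and one-step standardized residuals are measured sequentially on the
  held-out last 15 (in-sample or leave-one-out residuals cannot measure this
  optimism because the hyperparameters have adapted to those same windows) —
  and (ii) updated online as 1.4826 × the median absolute value of the last
  10 one-step z-scores (winsorized at 3 recalibrated SDs), floored at 1.
  The 10-window memory matches the declaration interval so scale adaptation
  and interval evaluation operate on the same timescale. Conditioning values
  are clipped at prediction ± 3 recalibrated SD so one outlier cannot poison
  subsequent predictions, while genuine sustained level shifts still enter
  the conditioning set and are absorbed — this absorption is what makes the
  *first* strongly deviating window the most significant one, and hence
  makes the declared time land at the regime onset rather than at the end of
  the interval.

* **Suspects and declaration.** Windows with p < 0.05 are suspects
  (two-sided: a drop in RMSSD is also anomalous; the sign is recorded).
  Suspects are events of a doubly stochastic point process whose rate under
  the null is α, so post-training windows are partitioned into consecutive
  intervals of 10 (~25 min) and the first interval whose suspect count k has
  exact binomial tail P(K ≥ k | B(10, 0.05)) < 0.05 — i.e., k ≥ 3 at the
  defaults — is selected. The Delta point is the suspect with the smallest p
  in that interval (ties resolved to the earliest); the scan stops at the
  first qualifying interval (one declaration per record). Absence of a
  qualifying interval is a valid, undeclared result.

* **Timestamps.** A suspect's time is the *start* of its 5-min analysis
  window: the earliest observation that can belong to the new regime, the
  convention of run-length-based change-point reporting. Window centers are
  retained on the RMSSD series for plotting and alignment.

Determinism: the detector contains no random numbers; fixed inputs and
configuration give bit-identical results.

## Evaluation

A detection is a true positive if it is no later than 2 min after and no
earlier than 25 min (one declaration interval) before the sentinel,
boundaries inclusive; later detections (or no declaration) are false
negatives; earlier ones false positives. Accuracy = TP / number of records,
sensitivity = TP/(TP+FN), precision = TP/(TP+FP); zero-denominator ratios are
reported as NaN, never 0. Lead-time summaries use absolute
sentinel−detection differences with quantiles by linear interpolation
between order statistics — the unique common convention that reproduces both
published IQRs (10.5 and 44.25 → printed 44.3). The published
"mean ± SD lead" is reproduced by the population (n) SD of the absolute
differences; the sample (n−1) SD is also reported. The two precisions are
compared with an exact Wilcoxon signed-rank test on paired absolute
differences: zero differences dropped, average ranks for ties, and the exact
two-sided p computed from the full sign-assignment distribution (dynamic
program over doubled ranks) for n ≤ 20, with a tie-corrected normal
approximation beyond.

A bundled 14-row table transcribes the published per-animal sentinel and
detection clock times; `fetaldelta reproduce-table` re-derives every printed
performance number from it and exits non-zero on any disagreement.

## Numerical choices and degenerate inputs

* Window grid: anchored at the first sample; final partial window dropped
  (a 6 h record gives 143 windows).
* GP jitter 1e-12 on the kernel diagonal; predictive variance floored at
  1e-12; lengthscale bounded to [0.5, 60] windows.
* Binomial qualifying count computed by exact tail enumeration, never a
  normal approximation.
* Records shorter than training + one interval raise; the CLI records them
  as error rows and continues.
* Cohort seeds derive from the master seed via a single generator draw of
  integers below 2³¹.

## Known limitations

* **4 Hz baseline overestimation is not reproduced.** Real 4 Hz ultrasound
  (autocorrelation-based) monitors overestimate *low* baseline variability
  because each sample carries acquisition noise comparable to the true 2–4 ms
  beat-to-beat variability; this is the mechanism behind the degraded
  clinical-rate performance of the method. A shape-preserving interpolation
  of a clean tachogram, by contrast, is a smoothing operation: every
  interpolated sample lies between its bracketing beat values, and the mean
  squared grid-sample difference is provably at most on the order of the
  mean squared beat difference (measured ratio ≈ 0.63 at baseline). The
  package's 4 Hz pathway deliberately adds no acquisition noise (the
  resampler contract forbids it), so at baseline it *under*-reads RMSSD, and
  the corresponding directional check is expected to fail and documents
  this. The second mechanism — compression of the UCO-vs-baseline contrast
  at 4 Hz — does reproduce, through differential smoothing: during
  bradycardic decelerations the 0.25 s grid is fine relative to the long RR
  intervals, so deceleration-driven variability is attenuated more strongly
  than baseline variability.
* Detector recovery percentages are properties of the synthetic generator's
  onset model (surge + trend); the published real-data accuracy cannot be
  reproduced without the animal recordings.
* The interval-rate rule is a concretization of the "doubly stochastic point
  process" grouping as an exact binomial tail test; the original method's
  exact run-rate statistic is not fully specified by its description, so the
  binomial form is a declared substitute with the same null rate α.
* Clock-time parsing assumes a single experiment day (no midnight crossing),
  which holds for the bundled table.
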