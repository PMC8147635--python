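# Methods

This package re-implements, as tested and reusable code, a breath-analysis
workflow for discriminating oral squamous cell carcinoma (OSCC) patients
from non-cancer controls with a temperature-cycled metal-oxide (MOS)
electronic nose: raw conductivity tensors are compressed to 19-element
"breathprint" vectors, classified by a small tanh network trained with
resilient backpropagation, and evaluated with a blind-set rule,
Leave-10%-Out cross-validation, and ROC / confusion-matrix statistics,
optionally augmented by clinical covariates in a forward-stepwise logistic
regression. Because the original measurements are not redistributable, a
synthetic-data module generates cohorts with the statistical structure the
analysis assumes; everything below states what is modeled, what is not,
and which design choices were genuinely open.

## 1. The measurement and its synthetic emulation

One measurement drives three MOS sensors through a 64-step heat/cool ramp
(32 heating + 32 cooling steps, 260-340 degC) for 36 cycles of roughly 8 s
(about one breath per cycle), recording a 64 x 36 x 3 conductivity tensor
per participant. The generator (`breathprint.synthetic`) models this as a
sum of interpretable components:

* **Clean-air baseline** - a conductivity-vs-temperature curve (rising
  with temperature, slightly depressed on the cooling branch) that is
  nearly constant across cycles; amplitude `baseline_amplitude`
  (default 1.0, the unit of conductivity used throughout).
* **VOC response** - a unit-Frobenius-norm signature `S`: a smooth bump
  over a band of heating-branch temperature steps with a weaker echo at
  the mirrored cooling step, nonzero only on the NOx sensor channel,
  modulated across cycles by a breath-synchronous oscillation with a
  build-up envelope (exhaled VOCs accumulate over the first cycles). Its
  amplitude for participant *i* is
  `a_i = response_amplitude + effect_size * noise_sd * 1{case} + N(0, amp_jitter_sd)`:
  everyone responds (default `response_amplitude` 1.0), cases respond more
  strongly, and people differ (default jitter SD 0.05). The class label
  enters the tensor only through this amplitude.
* **Drift** - a Gaussian random walk across cycles per sensor
  (default 0.001 per cycle), added to every temperature step.
* **Noise** - i.i.d. Gaussian per data point (default SD 0.05, i.e. 5 % of
  the baseline amplitude).
* **Spikes** - Bernoulli per data point (default rate 2e-5, so roughly one
  participant in seven carries a spike) with magnitude ~0.6, i.e. large
  against any local structure. Spikes are kept sporadic deliberately: the
  preprocessing normalizes each participant to [0, 1] *before* shaving, so
  every spike irreversibly rescales that participant's whole tensor; at a
  few spikes per participant this multiplicative jitter would dominate the
  class signal and no analysis could meet the calibration below. The
  shaving stage is still exercised (and is tested against constructed
  spikes directly).
* **Device offset** - two devices with a small additive offset each;
  participants alternate devices.

Covariates (age, sex, toombak use, smoking pack-years) are drawn so that
controls are on average younger and more exposed to toombak and smoking
than cases, with sex-specific age means; only the direction and rough
magnitude matter for the covariate-regression stage.

The measurement order interleaves classes with no same-label run longer
than 5 by default; `arrangement="blocked"` draws alternating same-class
blocks of length 3-8 so that the block-size exclusion rule (below)
produces a non-empty blinded group, emulating clinic scheduling that
clusters patients and controls.

**Effect-size calibration.** The class difference is a pure mean shift
`delta = effect_size * noise_sd` along the known unit signature in
Gaussian noise, so the Bayes-optimal detector is the matched filter
`m = <x, S>` and its AUC is closed-form:

    AUC_Bayes = Phi( delta / ( sqrt(2) * sigma_m ) ),
    sigma_m^2 = noise_sd^2 + amp_jitter_sd^2 + Var_drift(S),

where `Var_drift(S)` is the drift random walk projected onto the
signature (computed exactly from the covariance `min(c, c')`).
`effect_size_for_auc` inverts this; the default effect size places the
Bayes AUC at 0.85 (about 2.7 noise SDs, a ~13 % amplitude increase in
cases). Spikes and the per-participant normalization are neglected in the
formula; a Monte-Carlo matched-filter test confirms the calibration to
within sampling error.

**What the generator does not model:** sensor chemistry and humidity,
the lung-rinse phase, inter-device sensitivity differences beyond an
additive offset, long-term sensor aging, and any real VOC effect size -
the synthetic effect sizes are free parameters of the simulation, not
estimates of biology. Passing tests therefore demonstrate that the
*pipeline* recovers signal of a known, calibrated size from data with
this covariance structure; they say nothing about the discriminability of
real breath.

## 2. Preprocessing chain (tensor -> 19-element breathprint)

Stages run in a fixed order; the chain is deterministic:

1. **Per-participant normalization** to [0, 1] (min -> 0, max -> 1 over
   all 6912 values). A constant tensor is an error (dead sensor), never
   silently mapped.
2. **Peak shaving**: per temperature step and sensor, values deviating
   from their running median along the cycle axis (window 5, edges
   clamped) by more than k = 4 robust SDs (1.4826 x MAD of the residuals)
   are replaced by that median. "Shaving" is not a standardized
   operation; a running-median replacement with a robust threshold is the
   conservative reading, and both window and k are exposed.
3. **Fourier clean-air compensation**: per temperature step and sensor,
   the 36-cycle series is Fourier-transformed, its lowest `fourier_cut`
   frequency bins (including DC) are zeroed, and the series is
   back-transformed. The clean-air signal varies slowly across cycles, so
   the default cut of 1 (DC only) is the least destructive choice;
   `fourier_cut = 0` is the identity to 1e-9.
4. **e-power**: elementwise natural exponential. Read plainly as
   x -> e^x; inputs are bounded by the preceding stages.
5. **NOx-sensor selection**: one 64 x 36 matrix per participant. Which of
   the three sensors is "the NOx sensor" is configurable
   (`nox_sensor_index`, default 0).
6. **Tucker compression**: higher-order orthogonal iteration (alternating
   least squares with orthonormal factors, HOSVD-initialized) on the
   participant-stacked matrices, leaving the participant mode
   uncompressed. Default ranks (19, 2, 1) for (temperature, cycle,
   sensor).
7. **Feature extraction**: each participant's 19 temperature-mode core
   coefficients paired with the *last* cycle component. With cycle rank 2
   the first cycle factor is (numerically) the cycle-constant profile -
   the e-power re-introduces a rank-one offset after the compensation
   removed it - so the second factor is the leading breath-synchronous
   contrast, which is where class information that survived DC removal
   lives. Cycle rank 1 (features = near-cycle-means, signal entering only
   through the tilt of the single factor) is available in config but
   measured weaker and less stable.
8. **Cohort rescaling**: per feature coordinate, affine map to [-1, 1]
   (min -> -1, max -> +1; constant coordinates to 0).

`BreathprintPreprocessor` packages the chain as a scikit-learn
transformer: `fit` learns the Tucker factors and the rescaling bounds on
a training cohort; `transform` applies them frozen, clipping held-out
participants outside the training range. This is the only leakage-free
way to preprocess a blinded group.

## 3. Classifier and training protocol

A fully connected tanh network 19 -> 17 -> 7 -> 1 (474 weights and
biases) maps a breathprint to a value in (-1, 1); targets are -1
(control) and +1 (case). Training is full-batch resilient
backpropagation (iRprop-: per-weight steps grow x1.2 on gradient-sign
agreement, shrink x0.5 on a flip, flipped gradients zeroed; step bounds
[1e-8, 0.05]), with initial step size `learn_rate = 0.001` and loss =
mean squared error. Training stops at the first of: MSE <= 0.0005;
5000 epochs; 30 consecutive epochs with unchanged error (tolerance
1e-12); 15 consecutive epochs of increasing error. On any stop short of
the minimal error the weights are re-initialized and training restarts,
up to 25 times, keeping the best attempt.

Two parameters of this protocol have no canonical rprop meaning and are
exposed as configuration:

* **alpha = 0.05**: classic rprop has neither a learning rate nor a
  momentum term. Interpreted as an L2 weight-decay added to the loss,
  a coefficient of 0.05 makes the stated minimal error unreachable: near
  the optimum the decay gradient `alpha * w` dominates the data gradient,
  and the sign-based update equilibrates at an MSE orders of magnitude
  above 0.0005 (measured ~4.5e-2 on a 4-point XOR problem). The default
  role is therefore momentum-style gradient smoothing
  (`g <- grad + alpha * g_prev` before the sign is taken), with
  `alpha_role="decay"` and `"none"` available.
* **step bound 0.05**: caps the per-weight rprop step. Measured over
  paired replicates it leaves cross-validated AUC unchanged relative to a
  bound of 1.0 while converging to the minimal-error stop about an order
  of magnitude faster; smaller caps gain nothing and slow training.

Gradient correctness is verified against central finite differences
(<= 1e-6 relative error) in the suite. `RpropNetClassifier` follows the
scikit-learn estimator contract (`fit` / `decision_function` / `predict`,
clonable parameters, trailing-underscore fitted attributes).

## 4. Evaluation

* **Blind-set rule** (block size 5): scanning in measurement order, any
  participant extending a same-label run beyond 5 is moved to the blinded
  group; the run counter keeps counting through excluded participants and
  resets when the other label is measured. Blinded participants never
  touch preprocessing fits, training, cross-validation, or threshold
  choice.
* **Leave-10%-Out cross-validation**: fold size ceil(0.10 n), hence
  ceil(n / fold size) folds, the last possibly smaller (n = 84 gives nine
  folds of 9 and one of 3). Fold assignment is seeded and stratified by
  class where possible (stratification stabilizes small folds; the
  partition rule itself does not prescribe it). Each fold's model is
  trained on the complement with a fold-specific derived seed; a single
  seeded partition is the default.
* **Threshold**: a value strictly greater than -0.21 is called positive.
  The default is a fixed operating point chosen for high sensitivity at
  acceptable specificity; a Youden-optimal mode is available since fixed
  thresholds are a manual rule.
* **Confusion metrics**: sensitivity, specificity, PPV, NPV and accuracy
  from counts, each also as a percentage rounded half-up to an integer.
  All percentages are derived from the counts; no externally quoted
  figure overrides count arithmetic (for counts TP=8 TN=13 FP=4 FN=2 the
  count-derived accuracy is 21/27 = 77.8 % -> 78 %). Undefined ratios
  (empty denominators) are flagged, not silently zeroed.
* **ROC / AUC**: threshold sweep over observed values, trapezoidal AUC;
  equals the tie-corrected Mann-Whitney probability estimate to 1e-9
  (checked against an independent rank-based oracle).
* **Covariate-augmented logistic regression**: forward-stepwise
  (conditional) selection of {e-nose value, gender, age, smoking
  pack-years, toombak use} against the case/control label: entry by Rao
  score test at p <= 0.05, removal by likelihood-ratio test at p >= 0.10
  (the common defaults of the named procedure; both exposed). Incomplete
  covariate rows are dropped listwise. Quasi-complete separation is
  flagged with a warning rather than raised. The ROC of the selected
  model's predicted probabilities is reported alongside the e-nose-only
  ROC.

## 5. Signal recovery: what the pipeline can and cannot reach

The recovery test generates 49-case / 35-control cohorts with the effect
size calibrated to a Bayes-optimal AUC of 0.85 and asks whether the mean
Leave-10%-Out AUC over 20 replicates recovers it. Two measured facts
shape the acceptance band:

* The 19-element features are **near-sufficient**: the class signal
  survives the chain essentially intact (a large-cohort linear read-out
  of the features reaches the Bayes level).
* The **training protocol, not the features, is the bottleneck**: the
  protocol trains to interpolation (MSE <= 0.0005 on ~75 participants
  with 474 parameters) with no regularization, so out-of-fold predictions
  carry substantial overfitting noise. On an idealized feature set - one
  clean feature at the same d' = 1.47 plus 18 uniform-noise features,
  n = 84 - the protocol reaches a mean CV AUC of only ~0.73 (computed in
  the suite). This small-sample ceiling applies to any implementation of
  the stated protocol.

The documented band for the 20-replicate mean is therefore **[0.66,
0.90]**: the measured protocol ceiling minus roughly three combined
standard errors on the low side, the Bayes target plus sampling slack on
the high side. The full pipeline lands near the ceiling (typically
0.70-0.73), i.e. the preprocessing loses little beyond what the protocol
itself forfeits. With effect size 0 the mean CV AUC must lie within three
standard errors of 0.5, and the calibrated effect must beat the null by a
wide margin.

## 6. Numerical and degenerate-input choices

* Tucker convergence: residual change < 1e-10, iteration cap 200, error
  carrying the relative residual on failure; factor SVDs use full
  matrices so requested ranks exist even when the projected stack is
  rank-deficient (small cohorts). Reported reconstruction errors come
  from explicit reconstruction, which is exact near zero where the
  norm-difference shortcut loses precision.
* Peak shaving with zero MAD falls back to the residual SD, and leaves
  the series untouched if that is also zero.
* Percentages round half-up (66.67 -> 67, 86.67 -> 87).
* CSV round trips are bit-exact (shortest-repr floats on write,
  round-trip float parsing on read); readers never silently drop rows.
* All randomness flows from single integer seeds through
  `numpy.random.SeedSequence`; one study seed fans out to per-stage
  seeds, and every output file digest is recorded in a run manifest.

## 7. Known limitations

* The exact compression used by the original proprietary software
  (Tucker ranks, feature mapping, scaling options) is unknown; this
  package fixes one documented, configurable reading and does not attempt
  bitwise reproduction of vendor feature values.
* Which physical sensor is "the NOx sensor", and whether the 64
  temperature steps fold into 32 heating + 32 cooling, are configurable
  assumptions, not facts.
* The Leave-10%-Out protocol is a single seeded partition by default;
  repeated partitions are available but not the default.
* Cross-validated features are computed once on the full training cohort
  (Tucker factors and rescaling included), not refit per fold - matching
  the original workflow at the cost of a small optimistic bias in the CV
  estimate; the blinded group is the leakage-free check.
* The stepwise procedure's reported AUC is in-sample for the selected
  model (as is conventional for this procedure) and is not a blinded
  estimate.
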