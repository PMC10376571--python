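# Methods

This note documents the models, parameter choices and numerical
decisions behind `emgexo`, and what the synthetic experiments do and do
not show about real recordings.

## Synthetic sEMG generator

**Gesture model.** A real acquisition of this kind records eight
differential forearm channels at 200 Hz over the 0–100 Hz band, with
five repeated gestures (four finger–thumb pinches and a closed hand).
The generator reproduces the one property the gesture pipeline needs:
*channel-pattern separability*.  Each gesture is an 8-vector of channel
RMS amplitudes (tens of mV, distinct per gesture) multiplying a
unit-RMS Gaussian carrier band-passed to 20–95 Hz (4th-order
Butterworth, per channel), plus a 2 mV common-mode noise floor.
Inter-subject variability is a per-subject log-normal channel gain
(σ = 0.10) and repetition jitter a ±5 % amplitude scale; both are
exposed on `AcquisitionProtocol` rather than asserted as physiological
truth.  The default protocol is 10 repetitions × 5 movements × 5
series × 5 subjects, 2 s per repetition — 1250 recordings, 250 per
gesture.  No power-line component is generated, so no notch stage
exists.

**Fatigue model.** Muscle fatigue is the decline of force output during
sustained activity; its canonical sEMG signature is spectral
compression toward lower frequencies with rising amplitude.  The three
muscular-condition levels map to carrier centre frequencies
80 → 60 → 45 Hz (±22 Hz band) and RMS gains 1.0 → 1.2 → 1.4 over a
20 mV base.  These values are configurable; the defaults make the
levels separable by the spectral features while overlapping enough that
the transition level is genuinely the hardest (as one would expect of
an intermediate state).  A rest generator (2 mV RMS) supplies the CFM
baseline.

**What this does not show.** The generator contains no motor-unit
physiology, no electrode-shift or skin-impedance drift, no
inter-gesture confusions from shared muscle synergies, and its
within-class variability is mild.  Near-perfect synthetic
classification therefore demonstrates pipeline correctness — features,
normalization hygiene, CV protocol — not expected clinical accuracy.

**Segmentation.** Window count is `floor((N − W)/step) + 1` with
`step = round(W·(1 − overlap))`; trailing samples are dropped.  The
round-to-nearest step matters only for configurations where the overlap
is not an exact sample count (30 % of 200 samples is exactly 140).

## Features

Kernels are implemented exactly as their defining sums; each is tested
against an independent naive-loop oracle at 1e-9 relative tolerance.
Deliberate conventions:

* **VAR** is the *uncentered* second moment Σx²/(N−1).  For zero-mean
  sEMG the distinction is minor, but the uncentered form is the one the
  pipeline standardizes on; `centered=True` gives the textbook variance.
* **ZC** comes in two variants: the gesture kernel counts pure strict
  sign alternations (threshold 0); the fatigue kernel additionally
  requires the consecutive-sample difference to reach a threshold
  (default 5 mV, mirroring the WAMP threshold).
* **MTW** emits one energy scalar per taper — Σ(Wx)² for Hamming,
  ΣWx² for the trapezoidal (10 % ramps) and Slepian (first DPSS,
  NW = 2.5, peak-normalized) tapers — so the per-channel fatigue block
  is the 9-vector [ACNI, ZC, MTW×3, CFM, ASD, MNF, MDF] and
  9×8 + 28 = 100 holds.  A `squared_weights` option provides the
  Σ(Wx)² variant for every taper.  The power rate PR = max(P)/min(P)
  is computed by `spectral_features` (min floored at 1e-12) but
  excluded from ψ.
* **Spectra** are Hamming-tapered periodograms over the positive
  (non-DC) bins; M is the number of those bins (ASD = total/M).  MDF is
  the first bin where cumulative power reaches half the total.
* **ACNI** uses uniform trapezoidal integration with Δ = 1/fs, scaled
  by 1/N.
* **Normalization**: min–max parameters are fit on training data only
  and applied unchanged to test data (values may leave [0, 1] there);
  constant columns map to 0 rather than dividing by zero.  The z-score
  uses the population standard deviation.

## Gesture classification

scikit-learn provides the estimators; the study protocol is authored
here.  The stratified 70/30 split leaves 175/75 examples per gesture
under the default protocol.  Grid search covers the named
hyperparameter families — LDA solver; SVM regularization C ∈
{0.1, 1, 10, 100}, kernel ∈ {linear, RBF, polynomial of degree 2–4},
kernel coefficient ∈ {scale, 0.01, 0.1}; KNN neighbours ∈ {1, 3, 5, 7, 9},
Euclidean/Manhattan distance, brute/tree search — with 5-fold stratified
CV on the training split only.  Grids are ordered simple-first so mean
accuracy ties resolve to the simpler configuration.  Both the fold mean
and the fold minimum are reported, since either may be quoted as "the"
training accuracy.  Metrics derive from the one-vs-rest confusion
reduction and are cross-checked in tests against brute-force recounts
of (true, predicted) pairs.

## Fatigue detection

One binary feedforward detector per level, trained on z-scored ψ
vectors; inference fuses the three scores by arg-max.  Defaults: one
hidden layer of 16 logistic units, lbfgs optimization (deterministic,
well-suited to the few-hundred-sample training sets used here), L2
penalty α = 0.01, at most 500 iterations.  The L2 penalty is essential:
at the sklearn default (1e-4) the 100-dimensional input lets the
network interpolate the training set (train NMSE ≈ 1e-7) and the
transition-level detector generalizes poorly.  NMSE is defined as
MSE/var(target) — 0 for perfect prediction, 1 for predicting the mean —
since detectors are compared by it; architecture selection is argmin
NMSE with ties to fewer hidden layers.  ROC curves are built by
explicit threshold sweeping with trapezoid AUC, equal to the
Mann–Whitney pairwise-concordance statistic (tested), and invariant to
monotone score transforms.  Training-set size for the studies is 100
windows per level with 40 per level held out — a realistic yield from
short sustained-contraction recordings segmented at 1 s / 30 % overlap.
Two optional feature-ranking methods (mutual information, max pairwise
Cohen's d) are provided for exploration and are off the default path.

## Fuzzy assistance velocity

The three detector scores are fuzzified over triangular Ruspini
partitions {low, medium, high} on [0, 1] (memberships sum to one, so
coverage is structural).  All 27 label combinations are enumerated into
rules whose crisp consequents follow a monotone policy keyed on the
fatigue score: high → increase, low → decrease, medium → hold unless
the nonfatigue score is clearly high (then decrease).  Product firing
strengths and Sugeno weighted averaging make the aggregated action a
convex combination in [−1, 1], and a piecewise-multilinear,
monotone-in-the-fatigue-score function of the inputs.  The rule count
(27 by default, 125 with five partitions) depends on granularity and is
reported, not forced.  The action scales a 0.1 mm/s-per-update ramp;
the command is clamped to [0, 10] mm/s (nominal actuator band
0–7 mm/s).  The fuzzy stage runs at the EMG window rate (0.7 s at the
default segmentation) and is zero-order-held between updates; whether
the published ramp slope is per control tick or per window update is
ambiguous, and per-update was chosen (configurable via `slope`).

## Actuator plant

The exoskeleton's driven element is modelled at the actuator level: a
first-order velocity lag (τ = 10 ms default) feeding an integrator,
discretized exactly under zero-order hold at ts = 1 ms, with hard
velocity saturation at ±7 mm/s and a 0.3 mm quantized position readout
(exact state kept internally).  τ = 0 degenerates to a pure integrator
and is used by analytic tests.  The full multi-bar finger linkage is
out of scope (its link parameters are not available); the MPC
manipulates exactly this actuator velocity, so the abstraction is the
controller-relevant one.  The 2 mm/s lower end of the nominal speed
band is documentation, not a deadband.  No payload or contact forces
are modelled.

## MPC

Standard dense receding-horizon formulation over the actuator model:
Hp = 20 predicted steps, Hc = 2 free moves (later moves held), cost
Σ W_MO(v−r)² + W_pos(p−r_p)² + W_MV Σ Δu² + ε‖U‖² + ρ‖slack‖² with
W_MO = 0.135 on velocity, W_pos = 0 (position reported, unweighted —
speed tracking deliberately predominates), W_MV = 0 and ε = 1e-8 for
strict convexity.  The ±0.007 m/s output band is soft: violations enter
through quadratic slack with penalty ρ (default 1.0), so the output can
exceed the band by a bounded amount that shrinks as ρ → ∞ (verified on
a penalty sweep).  The piecewise-quadratic objective is solved exactly
by an active-set Newton iteration on the Hc-dimensional move vector; a
scipy-based dense QP serves as the independent oracle in tests
(agreement to 1e-6 on horizons ≤ 5).  Hard-constraint mode uses a 1e10
penalty and raises if a residual violation remains.  The controller
uses direct state feedback of the simulated actuator; the qualitative
"robust/aggressive" presets scale the slack penalty (×10 / ×0.1).
Internally everything is SI (m, m/s); the mm-unit plant boundary is
converted explicitly, and all reported MSEs are in controller units.

**Dual reference.** The effective reference is the therapy velocity, the
EMG-derived assistance velocity wherever it is active (EMG priority), or
a normalized weighted blend.  With EMG priority the controller discards
the therapy trajectory on the active interval — the mechanism that
decouples fatigue compensation from the prescribed motion.

**Scenario geometry.** The ramp tracking scenario uses triangular
velocity cycles (constant-acceleration position): 2 s flexion ramp
0 → peak → 0 followed by the mirrored 2 s extension, i.e. a 4 s
opening/closing cycle matching the 2 s-per-movement acquisition
protocol; studies run 7 cycles (28 s, 28 000 steps).  The PWM scenario
is a ±amplitude square wave (default period 5.2 s).  The
fatigue-compensation study lowers the slack penalty to 0.01 so the
assistance channel may exceed the nominal band, consistent with
compensation velocities reaching 10 mm/s.

**Phase metrics.** Flexion/extension are distinguished by the sign of
the effective reference; per-phase Pearson correlations are computed
between the MPC command and the EMG (or effective) reference and are
NaN when a phase is empty or constant.

## Known limitations

* Synthetic separability is idealized (see above); classification and
  detection figures characterize the machinery, not clinical
  performance.
* The plant is an actuator abstraction without multibody dynamics,
  payload, or backlash; tracking errors are correspondingly optimistic
  relative to a physical testbed.
* The fuzzy rulebase realizes the published *behaviour*
  (increase/hold/decrease with a ramp), not any particular published
  rule table; its count is granularity-dependent.
* Correlation metrics in the compensation study depend on the synthetic
  assistance trace; slowly-varying assistance during a phase yields
  low-variance segments where Pearson correlation is weakly informative.
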