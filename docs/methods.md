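# Methods

## The measurement being modelled

A MOX chemiresistor's conductance responds to reducing volatiles: exposing
an n-type sensing layer (SnO₂ variants, here) to a sample's headspace makes
its resistance fall toward a gas-dependent plateau; the single p-type
channel (CuO) mirrors the excursion upward.  One acquisition is
baseline → exposure → recovery: clean filtered air, one minute of headspace
flow (the analysis time), then clean air again.  The class structure under
study is the grated-cheese taxonomy: seasoning (12/24 months) × rind
working process (washed/scraped) × rind class (≤18 %, 18–26 %, >26 % w/w),
plus zero-rind samples that carry no working process.  The packaged design
manifest reproduces the replica counts of the original campaign (452
replicas; 211 vs 241 per seasoning; 14 + 12 zero-rind).  The class-level
counts are spread over the concrete nominal rind percentages of each class
round-robin, deterministically.

## Synthetic response generator

No public acquisitions exist, so the generator is a first-class module, not
a fixture.  It uses the simplest kinetics consistent with the instrument's
curve shapes — first-order adsorption/desorption:

- baseline: R(t) = R₀;
- exposure: R(t) = R₀·(1 ∓ A·(1 − e^{−(t−t_on)/τ_resp})) (− for n-type,
  + for p-type);
- recovery: exponential return toward R₀ with time constant τ_rec.

The noise model is a multiplicative lognormal between-replica factor on the
amplitude (mean 1, CV `replica_cv`, drawn per replica × channel) plus
relative Gaussian measurement noise on R.  The noise-free normalized curve
is piecewise monotone, so its first derivative has exactly the two
opposite-sign spikes seen on the real instrument (exposure onset, gas
switch-off).

Key defaults (see `moxnose/data/default_generator.yaml`):

| parameter | default | meaning |
|---|---|---|
| baseline / exposure / recovery | 30 / 60 / 210 s | acquisition phases |
| sample rate | 1 Hz | configurable; features are rate-robust |
| per-channel amplitude A | 0.20–0.45 | fraction of baseline |
| τ_resp / τ_rec | 7 s / 20–30 s | response / recovery kinetics |
| noise_sd | 0.005 | relative measurement noise |
| replica_cv | 0.08 | between-replica amplitude CV |

Class effects are multiplicative and encode the direction of the contrasts
the real instrument shows, with magnitudes chosen once as plausible
calibration knobs:

- **seasoning**: the 24-month class responds deeper (amplitude ×1.0 vs
  ×0.75) and faster (τ_resp ×1.0 vs ×1.3254).  The τ ratio is calibrated so
  the two seasonings' median 10–90 % fall times differ by about 5 s
  (fall time ≈ τ·ln 9 for a long exposure).  Deeper responses also make the
  24-month total areas smaller on n-type channels, matching the reported
  ordering (larger areas for the younger cheese).
- **rind class**: amplitude ×0.78 / ×1.00 / ×1.28 for ≤18 % / 18–26 % /
  >26 %.  The effect is keyed to the *class*, not the nominal percentage:
  adjacent percentages across a class boundary (18 vs 20 %) differ by less
  than the between-replica CV, so any smooth percentage law would make the
  third cascade step unlearnable by construction; a class-level aroma
  signature is the modelling choice that keeps the synthetic task
  well-posed.
- **working process**: no kinetic effect; instead a per-channel amplitude
  re-weighting (SR ×1.25 on three channels, ×0.80 on four, ×1.0 on the
  reference channel).  WR and SR thus differ by their response *pattern*
  across the array rather than by overall intensity, which keeps the
  process direction orthogonal to the seasoning and rind directions in
  log-amplitude space.

Reproducibility: each replica's generator is seeded by a counter-based
scheme (`SeedSequence(seed, spawn_key=(replica_index,))`), so a replica's
curves do not depend on how many other replicas are simulated.

What the generator does **not** emulate: sensor drift across days, humidity
and temperature interference, carry-over between vials, heterogeneous
per-channel sampling, or any real headspace chemistry.  Passing tests
demonstrate that the pipeline recovers class structure *of this synthetic
form*; they say nothing about accuracy on real cheese.

## Feature extraction

Curves are normalized to the first acquisition value R₀; all features are
computed on r = R/R₀ and are therefore invariant to the channel's absolute
resistance scale (raw scales in the generator are arbitrary for this
reason).  Conventions and numerical choices:

- **ΔR/R₀** and the **derivative extremum** are evaluated over the exposure
  window only; this excludes the recovery spike by construction.  Areas and
  the transition time use the full acquisition, with the extremum defined
  globally (first sample attaining it, a deterministic tie-break).
- The derivative is central finite differences on a smoothed curve.
  Smoothing is a centered moving average specified in *seconds* (default
  5 s — the classic 5-sample window at 1 Hz) and implemented as the exact
  average of the linear interpolant with fractional trapezoid end-weights,
  so the operator is consistent across sampling rates.  A plain k-sample
  window is not, and an instantaneous-onset curve keeps an O(dt) rate
  sensitivity at the spike itself; for band-limited (smooth-onset) curves
  all five features change by well under 2 % when the rate doubles.
- 10–90 % transition levels are fractions of the realized amplitude
  |r_ext − 1| measured from baseline toward the extremum, with first
  crossings linearly interpolated between samples.  A flat curve has no
  amplitude: the feature is reported as undefined and the replica excluded
  (with a log record) rather than silently imputed.
- Areas use trapezoidal quadrature on the native grid; at 1 Hz this is
  within 1 % of dense-grid quadrature for the kinetics above.

## Statistical screening

One-way ANOVA (classical sums of squares, F = MSB/MSW with df (k−1, N−k))
feeds Tukey's HSD on every class pair with Tukey–Kramer standard errors for
unbalanced groups; tail probabilities come from the studentized-range
distribution with N−k degrees of freedom.  A feature is retained only when
*every* pairwise comparison is significant at α (default 0.05; `any_pair`
available as a config option).  Degenerate inputs (zero within-group
variance) are flagged, not crashed: F = ∞/p = 0 when means differ, F = 0 /
p = 1 when they do not, so constant features are never selected.

Screening scope defaults to the node's *training* rows to avoid selection
leakage into the held-out evaluation; `all_data` mode reproduces the
select-then-split workflow common in the instrument literature.  No
multiple-testing correction is applied across the 40 features — the screen
deliberately mirrors the original workflow, and the null behaviour
(per-feature false-selection rate ≤ α under the all-pairs rule) is verified
by Monte Carlo in the test suite.

The notch interval median ± 1.57·IQR/√n is provided as the standard
notched-boxplot heuristic: non-overlapping notches are informal ~95 %
evidence of differing medians, and on strongly separated synthetic groups
the heuristic co-occurs with Tukey significance in ≥ 90 % of cases.

## Cascade classifier

Topology: one root node (seasoning), one node per seasoning (process), one
node per seasoning × process (rind class) — 7 nodes; zero-rind replicas
appear only at the root.  Architecture follows the screened subset size d:
depth 1/2/3 for d ≤ 8 / ≤ 16 / ≥ 17, d tanh neurons per hidden layer,
winner-take-all output (argmax of the softmax scores; ties broken toward
the lowest class index, a measure-zero event).  The depth thresholds are a
package convention; only the 1–3 depth range and the width-follows-d rule
are inherited from the instrument literature.

Splits are per-node, stratified 2:1 (per-class counts within one of the
ratio), seeded.  Step-2/3 nodes are trained and scored on ground-truth-
routed rows (their true branch), which matches how per-branch accuracies
are conventionally reported; the evaluation additionally reports
cascade-routed metrics, where each test replica follows the predicted path
and conditional accuracies count only correctly-routed rows.

Training: features standardized by training-split mean/SD; L2-regularized
cross-entropy minimized with full-batch LBFGS (ridge penalty 0.1, iteration
budget 500, seeded).  With node training sets of 60–100 rows, held-out
early-stopping folds are too small to be informative and first-order
optimizers systematically underfit or overfit here; quasi-Newton plus an
explicit ridge is the standard small-sample regime and was adopted for that
reason.  A node that exhausts its budget is returned flagged
(`converged=False`) with its final loss logged.

## Problem sizes used by tests and the acceptance script

The test suite runs the full published-design scale (452 replicas × 8
channels, 301 samples per curve) for parameter recovery, a balanced
2×(1+2×3)-cell design with 21 replicas per cell for the chance-level check
(class imbalance would otherwise let a majority-class learner sit above the
nominal 1/3 chance), and 1000 Monte-Carlo null tables per group count for
the screening calibration.  The acceptance script repeats the full-scale
run from a single seed.

## Known limitations

- The generator's effect magnitudes are calibration knobs, not measured
  chemistry; only their directions are anchored to reported contrasts.
- Tukey p-values inherit the numerical accuracy of the studentized-range
  CDF (~1e-4 absolute), which is ample for screening at α = 0.05.
- The cascade trains its step-2/3 nodes on ground-truth routing; a
  deployment on unlabelled samples would route by prediction, and the
  cascade-routed metrics are the honest estimate of that setting.
- Model bundles store weights in NumPy `.npz` files: portable across
  platforms, but tied to the scikit-learn MLP layout used here.
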