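# Methods

## Scenario space and experimental design

A dissolution scenario is characterized by a single intragastric stress (IS)
pressure wave — timing *t* [min from capsule immersion] and magnitude *p*
[mbar] — followed by gastric emptying (GE) at 30 min, after which the medium
is intestinal and dissolution completes. Times are minutes from test start;
dissolved amounts are % of the labeled dose (capped at 110% to tolerate
analytical overshoot). GE time is stored per protocol rather than as a global
so the workflow generalizes beyond this study design.

The design is a *modified* central composite design: center (150 mbar,
12 min) replicated five times, factorial offsets (±50 mbar, ±3 min), and
per-factor axial offsets (±70 mbar, ±4 min). Because the axial distance
differs between factors (α = 1.4 for pressure, 4/3 for timing), the
generator takes explicit axial offsets instead of a single rotatability α — a
textbook rotatable CCD cannot reproduce this matrix. Run order interleaves
the center replicates at runs 1, 4, 7, 10, 13; the published order is kept as
the run order since no randomization is documented. Three additional runs
(80/150/220 mbar at 10 min) probe the pressure threshold where the capsule
becomes susceptible, and four verification runs at intermediate settings
(125/175 mbar × 10.5/13.5 min) are held out for model assessment. A 5-level
full-factorial comparison utility (25 runs) quantifies the experimental
effort the CCD saves.

## Synthetic capsule simulator

The generator is phenomenological, not mechanistic. Its components:

- **Opening threshold.** A capsule opens during the stress event iff
  `p ≥ floor + block / (1 + exp(s·(t − t50)))` — monotone non-increasing in
  time as the gelatin shell softens. Defaults `floor = 60` mbar,
  `block = 200` mbar, `s = 4` /min, `t50 = 9.9` min are *fixtures* chosen to
  bracket the observed categorical outcomes: no tested pressure (≤220 mbar)
  opens the capsule at 9 min, the 10-min threshold lies in (80, 150] mbar,
  and by 12 min even 80 mbar opens it. They reproduce the open/closed outcome
  of all 20 standard-matrix runs (closed: (200, 9), (100, 9), (150, 8),
  (80, 10)). Opening is deterministic by default; a stochastic-boundary
  option (logistic opening probability, one reproducible draw per condition)
  exists for robustness experiments.
- **Observation delay.** The sampled signal reacts 2 min after any pressure
  event (sampling-site transit); the delay applies to both the IS response
  and the GE burst, since it is a property of the sampling loop.
- **Release kinetics.** An opened capsule releases first-order toward a
  pre-GE plateau of 70% of dose (apparent loss to local precipitation at
  gastric pH; the value is a configuration knob, not a measured quantity) at
  0.5 /min for burst opening. Gradual (partial-disruption) opening at
  0.15 /min occurs only when the wave exceeds the threshold by less than
  40 mbar *and* the shell is still stiff (threshold more than 10 mbar above
  its floor): partial rupture is a stiff-shell phenomenon around the 10-min
  transition, whereas a softened shell always opens fully — this is what
  makes late-stress (≥11 min) profiles align regardless of pressure. A
  closed capsule leaks 1% of dose until GE; the same baseline is used before
  opening in the open branch so the pre-event level does not jump across the
  open/closed parameter boundary. From GE (+delay) every curve approaches
  100% first-order at 0.35 /min. Curves are continuous and monotone
  non-decreasing with limit 100%.
- **Noise.** Additive zero-mean Gaussian assay noise per sampled point,
  truncated to [0, 110]%; the underlying truth stays monotone, the samples
  need not. The default SD of 2.7% of dose was calibrated once so that the
  maximal relative SD across 5 simulated center replicates is ≈9%
  (Monte-Carlo mean), matching the reported repeatability magnitude of the
  center-point experiments. Because the noise is additive, the relative SD
  is unbounded at near-zero means, so the statistic is evaluated over
  sampling times whose replicate mean is ≥10% of dose.

What the simulator does **not** emulate: inter-capsule kinetic variability
(only additive assay noise), drug precipitation/redissolution chemistry,
temperature and flow-rate gradients (documented constants of the apparatus),
multi-event pressure trains. Passing tests therefore demonstrate the
*workflow's* correctness and its qualitative behavior under controlled
conditions, not quantitative agreement with any real formulation.

## Response-surface model

One full quadratic in (*p*, *t*) per sampling time, fitted by OLS on the 13
basic runs; center replicates enter as 5 separate rows, preserving pure-error
degrees of freedom. Factors stay in natural units (the published equation is
stated in natural units); for conditioning the design columns are scaled to
unit norm before solving, and the coefficients and standard errors are
back-scaled. Pure column scaling (no centering) was chosen deliberately: it
leaves the t statistics — hence p-values — of the natural-unit coefficients
exactly invariant, whereas centering would change the meaning of the
lower-order terms. Coefficient p-values are two-sided t-tests (equivalent to
single-term type-III ANOVA for this model); α = 0.05. Rank-deficient layouts
raise an error rather than silently pseudo-inverting. Reported predictions
are clipped to [0, 100]%; raw polynomial values remain available for
diagnostics. At least 7 runs are required (6 coefficients + 1 residual df).

## Two-step ML model

**Step 1 — classification.** Logistic regression of P(open | *p*, *t*) with a
ridge penalty of 1e−8 and an iteration cap of 200. The training classes
(16 basic + additional runs) are linearly separable, so the unpenalized
likelihood has no maximizer; the tiny penalty plus the cap keeps the weights
finite at the price of a very sharp z transition across the boundary — the
confidence z = 100 · P(open) is therefore near 0 or 100 almost everywhere,
which the susceptibility map reports honestly. Features are standardized
internally for the optimizer; stored weights are in natural units. Ties
(P = 0.5) are assigned to open.

**Step 2 — regression.** A random forest over long-format instances — one per
(run, sampling time) with features (class ∈ {1, 0}, *p*, *t*, time) and
target dissolved % — using one candidate feature per split, single-instance
leaves, 100% bootstrap bags, and a seeded RNG. The long format is the only
single-target encoding consistent with a scalar-output learner; the class
feature uses observed labels at training time and the step-1 prediction at
inference. The default of 5000 trees mirrors the original configuration;
tests and the acceptance script run 300 trees, where predictions have long
stabilized. Cross-validation is 10-fold *grouped by run* — all 34 instances
of a run share one fold — so within-profile leakage cannot inflate the CV
estimate; fold membership is recorded and assertable.

## Verification machinery

Replicate variability is summarized from the 5 center runs as the
per-sampling-time SD, maximized within three sections: before the IS event,
between IS and GE, and after GE. Sections are half-open intervals
([0, t_IS), [t_IS, GE), [GE, ∞)), so a sample exactly on a boundary belongs
to the later section; boundaries use the *nominal* IS timing, not timing +
observation delay. The acceptance band at point *i* of an observed profile is
[D_obs,i−1 − 2·SD_sec, D_obs,i+1 + 2·SD_sec], with the point's own value
substituted for the missing neighbor at the profile ends and the lower edge
floored at 0. On noisy data the raw neighbor formula can invert
(D_obs,i−1 > D_obs,i+1 + 4·SD); since cumulative dissolution is monotone up
to noise, the two neighbors are ordered before applying the margins, which
leaves monotone observations untouched and keeps every band non-empty.
Predictions are scored by the fraction of points strictly outside their
bands and by MAE/RMSE pooled over all points of all four verification tests
(single values, matching how the originals were reported). All sampled
points are counted, including the near-trivial pre-IS region.

## Numerical and design choices

- **Alignment tolerance.** Two profiles are called aligned when their mean
  absolute difference is ≤10% of dose — the f2 = 50 similarity boundary that
  is the standard equivalence criterion in dissolution testing.
- **Determinism.** One master seed drives everything: the simulator consumes
  it directly (per-run replicate streams via seed sequences), the forest uses
  a fixed offset of it. Rerunning a configuration reproduces every artifact
  byte-for-byte.
- **Grid simulation.** The standard grids are a pressure sweep (100–200 mbar
  in 20-mbar steps at stress timings 9, 9.5, 10, 10.5, 11, 12, 13, 14,
  15 min) and a timing sweep (9–15 min in 0.5-min steps at 100, 160,
  200 mbar); the 27 overlapping pairs are simulated once, giving 66 distinct
  profiles.
- **Problem sizes.** The test suite and acceptance script use 300-tree
  forests, 20-seed replicate studies, and 40-point random designs for
  boundary recovery; these sizes were chosen as the smallest at which the
  stochastic checks are stable across reruns.

## Known limitations

- The measured verification errors (pooled MAE ≈ 7.5 vs 9.5% of dose for ML
  vs RSM at seed 1) and outside-band fractions (≈21% vs 35%) are larger than
  the corresponding wet-lab magnitudes: the synthetic generator's opening
  transition is sharp and its verification scenarios sit close to it, which
  penalizes both models; the *ordering* (ML better than the polynomial on
  MAE, RMSE and outside fraction) is the reproducible finding.
- The classifier's z is poorly calibrated by construction (separable data,
  near-zero penalty); the susceptibility map is a decision surface, not a
  probability estimate.
- The forest cannot extrapolate outside the trained factor box, and its
  timing resolution is limited by the design's timing levels.
- Simulator rate/plateau parameters are free configuration knobs; any
  monotone threshold form consistent with the categorical outcomes would do,
  and the logistic was chosen for its two interpretable parameters (midpoint,
  steepness).
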