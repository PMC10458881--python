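# capstress

Predicting immediate-release capsule dissolution across the two-dimensional
space of intragastric stress (IS) timing and magnitude.

## The problem

In the fasted stomach, irregular wall contractions subject an oral dosage
form to pressure waves of highly variable timing and strength. For
pressure-sensitive formulations — here a soft gelatin capsule containing a
drug solution — whether and when such a wave ruptures the shell dominates the
whole dissolution profile. Biorelevant dissolution equipment can reproduce
any single motility scenario, but running every scenario in a population is
infeasible. `capstress` implements a workflow that covers the scenario space
with a small designed experiment and then predicts the dissolution profile
for *any* stress condition:

1. **Scenario design** — a modified two-factor central composite design (CCD)
   over stress pressure *p* ∈ [80, 220] mbar and timing *t* ∈ [8, 16] min
   (13 basic runs), plus 3 additional runs at the critical 10-min timing and
   4 held-out verification runs. Gastric emptying (GE) is fixed at 30 min;
   samples are taken at 3, 6, 9–30 (every minute) and 33–60 min (every
   3 min).
2. **Synthetic data** — a phenomenological capsule simulator (time-dependent
   opening threshold, 2-min observation delay, partial vs. burst opening,
   pre-GE plateau, GE burst, assay noise) stands in for wet-lab runs so the
   whole workflow is reproducible and testable.
3. **Response-surface model (RSM)** — at every sampling time *i* the
   dissolved amount is a full quadratic,
   `D_i = b_i0 + b_i1 p + b_i2 t + b_i12 pt + b_i11 p² + b_i22 t²`,
   fitted by OLS on the basic runs with per-coefficient t-test p-values
   (α = 0.05).
4. **Two-step ML model** — a ridge-stabilized logistic regression classifies
   a stress condition as *open*/*closed* with confidence z = 100 · P(open);
   a random forest over (class, *p*, *t*, sampling time) then predicts the
   profile, assessed with run-grouped 10-fold cross-validation.
5. **Verification** — predictions on the 4 held-out runs are scored with
   per-point acceptance bands `[D_obs,i−1 − 2·SD_sec, D_obs,i+1 + 2·SD_sec]`
   (section-wise maximal replicate SD from the 5 center runs), pooled MAE and
   RMSE.
6. **Grid simulation and susceptibility map** — predicted profiles over dense
   (pressure, timing) grids, and a map of z over the plane showing which
   conditions would open the capsule.

## Worked example

```python
import capstress as cs

result = cs.run_pipeline(cs.RunConfig(rf=cs.RfParams(n_trees=300), seed=1))
print(f"RSM  MAE {result.rsm_report.mae:.2f}  RMSE {result.rsm_report.rmse:.2f}  "
      f"outside {100 * result.rsm_report.outside_fraction:.1f}%")
print(f"ML   MAE {result.ml_report.mae:.2f}  RMSE {result.ml_report.rmse:.2f}  "
      f"outside {100 * result.ml_report.outside_fraction:.1f}%")
print(f"grid profiles: {len(result.grid)}")
```

prints

```
RSM  MAE 9.53  RMSE 13.26  outside 34.6%
ML   MAE 7.50  RMSE 11.54  outside 21.3%
grid profiles: 66
```

i.e. on the four held-out verification scenarios the two-step ML model is
closer to the observed profiles than the quadratic response surface (pooled
mean absolute error in % of dose), leaves fewer predicted points outside the
acceptance bands, and the fitted models then simulate 66 distinct profiles
across the customizable-stress grids. The same run is available from the
shell:

```
capstress run-all --seed 1 --n-trees 300 --out results/run1
```

which writes every intermediate artifact (design, simulated profiles and
labels, both fitted models, per-coefficient significance table, predictions,
evaluation reports, grid profiles, susceptibility map, run log).

## Layout

- `capstress.protocol` — scenario/profile/label types, sampling schedule
- `capstress.design` — modified CCD, additional/verification points, full factorial
- `capstress.simulator` — synthetic capsule dissolution generator
- `capstress.rsm` — per-timepoint quadratic response-surface model
- `capstress.ml` — classifier + random forest, grid simulation, susceptibility map
- `capstress.evaluation` — section SDs, acceptance bands, MAE/RMSE
- `capstress.io`, `capstress.pipeline`, `capstress.cli` — formats, orchestration, CLI

See `docs/methods.md` for the model assumptions, parameter meanings and
limitations.
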