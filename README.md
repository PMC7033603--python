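# gaitenv

Classify running environments — treadmill vs. outdoor sidewalk — from a
single lower-back accelerometer, and identify which gait features drive the
discrimination.

Laboratory running biomechanics is mostly collected on treadmills, but most
running happens outdoors, and gait on a treadmill is measurably more
regular and vertically dominated than gait on a real sidewalk. `gaitenv`
implements the full analysis pipeline for testing that contrast with
wearable data:

1. **Preprocessing** — 4th-order zero-phase Butterworth low-pass (10 Hz),
   5% edge trimming per segment, gravity alignment (mean-acceleration
   direction → vertical, 9.81 m/s² subtracted), heading alignment
   (principal horizontal variance axis → anterior-posterior).
2. **Step segmentation** — autocorrelation-derived step period,
   percentile-thresholded peak picking for initial contacts, duration
   outlier exclusion, 50-point time-normalization of each step.
3. **Features** — 25 per run: speed, step/stride-time CV, resultant RMS,
   and per axis (AP/ML/VT) step and stride regularity (unbiased
   autocorrelation at the step/stride lag), symmetry (their ratio), peak,
   RMS, RMS CV, and RMS ratio. The squared ratios obey
   `ratio_AP² + ratio_ML² + ratio_VT² = 1`.
4. **Selection** — forward-sequential search with an LDA wrapper and
   participant-wise 10-fold CV, iterated 100 times over fresh fold
   partitions; features selected in ≥ 10% of iterations are retained and
   ranked by mean selection order.
5. **Classification** — RBF-kernel SVM with inner 5-fold grid search over
   C and gamma (10⁻³…10³), evaluated by participant-wise 10-fold CV and on
   an independent both-environments cohort, repeated over iterations with
   per-participant correct-prediction counts.
6. **Statistics** — Welch t-tests (training) and paired t-tests (testing)
   per retained feature with Bonferroni control (9 features → 18
   comparisons → p < 0.003).

Because no public dataset accompanies the original cohorts, `gaitenv`
includes a first-class synthetic-data generator (`gaitenv.synth`) that
produces cohorts with planted, controllable gait structure — step period,
timing/amplitude jitter, left/right asymmetry, axis energy shares, sensor
tilt/heading misalignment, gravity, noise, and per-participant random
effects — so every stage can be tested against ground truth. See
`docs/methods.md` for the signal model and all defaults.

## Worked example

```python
from gaitenv import (CohortDesign, generate_cohort, extract_feature_table,
                     run_selection, run_experiment)

# 28 treadmill-only + 25 sidewalk-only participants (training),
# 16 running in both environments (independent testing): 85 runs.
ds = generate_cohort(CohortDesign(seed=1))
roles = dict(zip(ds.manifest["participant"], ds.manifest["role"]))
table = extract_feature_table(ds.runs, roles=roles)
train = table[table.role == "training"].reset_index(drop=True)
test = table[table.role == "testing"].reset_index(drop=True)

sel = run_selection(train, n_iterations=100, seed=2)
print(sel.rank_table())
ev = run_experiment(train, test, sel.retained, n_iterations=20, seed=3)
print(ev.summary())
```

Output:

```
                      mean_rank  retention_frequency
feature
ratio_ap               1.000000                 1.00
regularity_stride_ml   2.285714                 0.28
rms_cv_vt              2.511628                 0.43
step_time_cv           2.714286                 0.21
speed                  2.861538                 0.65
rms_cv_ap              3.066667                 0.15
rms_cv_ml              3.125000                 0.24
regularity_step_ap     3.214286                 0.14
peak_ml                4.846154                 0.13
cross-validated training accuracy: 92.83% (SD 1.69%)
independent test accuracy: 93.75% (SD 0.00%)
```

Reading this: nine features were retained; the AP acceleration ratio was
selected first in every iteration (mean rank 1.00), with variability
(RMS CV) and regularity features following — the planted
consistent-vs-variable contrast expressed through the feature set. The SVM
separates the environments at ~93% under participant-wise cross-validation
and on the 32 independent test rows (16 participants × 2 conditions). With
`effect_scale=0` the two environments are generated identically and
accuracy falls to chance.

The same pipeline is available from the shell:

```bash
gaitenv all --seed 1 --outdir out            # full pipeline + report bundle
gaitenv simulate --seed 1 --outdir cohort    # runs as CSV + JSON sidecars
gaitenv extract cohort/manifest.json --out features.csv
gaitenv select features.csv --seed 1 --out selection.json
gaitenv classify features.csv selection.json --seed 1 --outdir out
gaitenv stats features.csv selection.json --out comparisons.csv
```

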