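# gaitrisk

Fall-risk prediction for elderly nursing-home residents from a wearable
lumbar IMU worn during a six-minute walking test, combined with the Timed
Up and Go (TUG) clinical test.

Falls are a leading cause of accidental death above age 65, and the TUG
test — timing a stand / walk 3 m / turn / sit sequence — is the bedside
standard for screening, but its ~25 s duration reveals little about gait
dynamics. `gaitrisk` implements and evaluates three classifiers of
six-month fall risk on six-channel inertial recordings (trunk
accelerations a_ml, a_v, a_ap in m/s² and angular velocities ω_ml, ω_v,
ω_ap in °/s at 100 Hz):

* **TUG** — risk if the TUG time exceeds a threshold t\* chosen to
  maximize Youden's index J = Se + Sp − 1 on the cohort's ROC curve;
* **TUG+** — a three-question checklist adding two gait-variability
  indices measured during the six-minute walk: the standard deviation of
  anteroposterior acceleration (SDa_ap, higher = riskier) and the
  box-counting fractal dimension of vertical acceleration (Da_v, a
  complexity index in [1, 2], lower = riskier), with index thresholds
  fitted by exhaustive in-sample accuracy search (a logistic-regression
  fusion of the same three features is also provided);
* **CNN** — a small convolutional network scoring raw 20-s frames of the
  six-channel signal; a participant's risk is the mean frame score,
  strictly above 0.5.

Each channel's variability profile consists of SD (magnitude of
fluctuations) and D, the box-counting dimension of the signal's graph:
N(ε) boxes of side ε needed to cover the graph scale as ε^(−D), and D is
the slope of log N(ε) versus log(1/ε) over a dyadic grid.

Because the cohort that motivated this pipeline (73 participants: 23
fallers, 50 nonfallers over a six-month follow-up) has no public
recordings, the package includes a synthetic gait generator whose
cohorts reproduce the published group statistics — per-channel SD and D
medians and interquartile ranges, TUG time quartiles, and turnaround
bursts in ω_v every 25 m lap — so the entire pipeline is testable end to
end. See `docs/methods.md` for the signal model, the Hurst calibration
that ties generated roughness to measured D, and all numerical
conventions.

## Worked example

```python
import gaitrisk as gr

cohort = gr.generate_cohort(seed=7)           # 23 fallers, 50 nonfallers
table = gr.VariabilityExtractor().transform(cohort)
y = table["faller"].to_numpy()

tug = gr.TugThresholdClassifier().fit(table, y)
cm, m = gr.evaluate_classifier(tug.predict(table), y)
print(f"TUG : t* = {tug.threshold_:.1f} s  (J = {tug.youden_j_:.3f}, AUC = {tug.roc_.auc:.3f})")
print(f"      Se = {m.se:.3f}  Sp = {m.sp:.3f}  Acc = {m.acc:.3f}")

plus = gr.TugPlusClassifier().fit(table, y)
cm2, m2 = gr.evaluate_classifier(plus.predict(table), y)
r = plus.rule_
print(f"TUG+: SDa_ap* = {r.sd_aap_star:.3f} m/s^2, Da_v* = {r.d_av_star:.3f}")
print(f"      Se = {m2.se:.3f}  Sp = {m2.sp:.3f}  Acc = {m2.acc:.3f}")

stat, p = gr.mcnemar(tug.predict(table), plus.predict(table), y)
print(f"McNemar TUG vs TUG+: p = {p:.3f}")
```

prints

```
TUG : t* = 26.6 s  (J = 0.268, AUC = 0.657)
      Se = 0.348  Sp = 0.920  Acc = 0.740
TUG+: SDa_ap* = 0.167 m/s^2, Da_v* = 1.693
      Se = 0.739  Sp = 0.860  Acc = 0.822
McNemar TUG vs TUG+: p = 0.146
```

The Youden threshold for this synthetic cohort lands at 26.6 s (such
cutpoints range from roughly 13 to 32 s across published elderly
cohorts); adding the two walk indices raises in-sample sensitivity from
0.35 to 0.74 at a small specificity cost, lifting accuracy from 0.740 to
0.822 — the qualitative signature of augmenting a clinical test with
sensor-derived gait variability. The McNemar p-value compares the two
classifiers on their discordant participants. The CNN experiment
(`gr.run_ai_experiment(cohort, gr.CnnConfig(), seed=...)`) reserves a
balanced 8 + 8 test set, trains on the remaining 57 participants, and
reports held-out participant-level metrics.

The same steps are scriptable from a shell:

```
gaitrisk simulate --n-fallers 23 --n-nonfallers 50 --seed 7 --out cohort/
gaitrisk indices cohort/manifest.csv --out indices.csv
gaitrisk fit-thresholds indices.csv --out rule.json
gaitrisk classify indices.csv --rule rule.json --out pred.csv
gaitrisk evaluate pred.csv --truth cohort/manifest.csv --out metrics.json
```

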