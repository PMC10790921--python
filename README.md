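# cybervigil

A headless, seedable simulator of a three-screen network-defense vigilance
task, together with its scoring metrics and trend-analysis pipeline.

Vigilance decrement — the decline in correct detection of critical signals
with time on a monotonous sustained-attention task — is a central concern in
human-factors research on security operations centers, where analysts watch
SEIM (Security Event Information Management) consoles for hours. This
package lets researchers design, pilot, and power such experiments without
human participants: it simulates the full task (stimuli, synthetic
operators, outcome classification), scores the resulting event streams into
vigilance performance curves, and runs the standard nonparametric trend
analyses on them.

## The task

A simulated SEIM console across three screens, run for 60 minutes per trial:

* **Left — honeyfile monitoring.** Sixteen icons show the security status of
  decoy files. A compromised honeyfile flickers red/green at the scheduled
  salience frequency; the operator acknowledges with Ctrl+D. Hit = macro
  while a flicker is active (answers the oldest one); false alarm = macro
  with none active; miss = flicker times out unanswered.
* **Center — alert triage.** A self-paced, never-empty queue of SSLBL threat
  alerts (originating IP + true priority 1–5, lower = more severe). Hit =
  correct rating; false alarm = overestimated threat (rating too low);
  miss = underestimated threat (rating too high). Each rated alert grows the
  matching frequency-chart column on the right screen.
* **Right — anomaly detection.** Five frequency charts (one per alert type),
  columns indexed by IP, with admin-alert thresholds 3/5/7/9/11 for
  priorities 1–5. A column reaching threshold is a breach: correct IP entry
  is a hit (column resets), wrong IP or no breach is a false alarm, timeout
  is a miss. A scripted "AI" keeps the number of *near-critical* columns
  (one below threshold) tracking the scheduled cognitive load.

Task difficulty is the workload vector **w**(t) = [S(t), E(t), C(t)]:
flicker salience S(t) = (7/15)t + 20 Hz, event rate E(t) = (2/15)t + 8
events/min, cognitive load C(t) = (1/20)t + 1 near-critical columns
(t in minutes). *Dynamic* trials ramp all three linearly to their hardest
values at t = 60; *static* trials hold the hardest values (48 Hz, 16/min, 4)
throughout.

## Scoring and analysis

Outcomes are pooled into 2-minute buckets; per screen the score is
100·H/(H+M+F), and the total-task curve pools all nine counts into a single
ratio. The 30-point curves (per trial, and as cohort ensemble averages) are
then analyzed exactly as such data are analyzed in the vigilance
literature: Durbin-Watson residual autocorrelation with Savin-White 5%
bounds, the Mann-Kendall monotonic-trend test (tie-corrected variance,
continuity-corrected Z), and Sen's slope with a rank-method confidence
band, plus split-half reliability of the pooled minute-level series.

The synthetic operator converts stimuli into actions through a
parameterized detection/latency/error model with learning and fatigue
terms; shipped defaults make cohorts improve under static workload and
decline under dynamic workload (see `docs/methods.md` for the model and its
limits).

## Worked example

```python
from cybervigil import simulate_cohort, score_log, ensemble_average, trend_report

logs = simulate_cohort(6, base_seed=42)          # 6 operators x 2 trials
curves = {"static": [], "dynamic": []}
for lg in logs:
    curves[lg.meta["mode"]].append(score_log(lg))  # 30-bucket curves
report = trend_report(curves["static"], curves["dynamic"])
print(report[["Dynamic across all screens", "Static across all screens"]].to_string())
```

```
                                          Dynamic across all screens Static across all screens
Assumption tests and trend analyses
Durbin-Watson D Statistic                                       2.48                     2.077
D-lower                                                        1.352                     1.352
D-upper                                                        1.489                     1.489
Autocorrelation verdict                                none_detected             none_detected
Significant autocorrelation (D < d_upper)                         no                        no
Mann-Kendall MK statistic                                       -315                       169
Standard Error                                                56.051                    56.051
Z-stat                                                        -5.602                     2.997
P-value                                                          0.0                    0.0027
Trend                                                       Negative                  Positive
Sens slope s statistic                                         -0.46                     0.161
S-lower                                                       -0.534                     0.075
S-upper                                                       -0.362                     0.248
```

Reading it: the dynamic-cohort ensemble curve declines (Mann-Kendall
S = −315, Z = −5.60, Sen slope −0.46 percentage points per 2-min bucket,
95% band [−0.53, −0.36]) while the static cohort improves (S = 169,
Z = 3.00, slope +0.16) — the vigilance-decrement signature under rising
workload, and its absence when workload is merely hard but constant. The
standard error 56.051 is the Mann-Kendall null value √(30·29·65/18) for an
untied 30-bucket series, and 1.352/1.489 are the 5% Durbin-Watson bounds at
n = 30 with one regressor.

## Command line

```
cybervigil simulate --config run.toml --out logs/     # cohort -> JSONL logs + manifest
cybervigil score    --log logs/trial_p00_static.jsonl --width 2
cybervigil analyze  --in logs/ --out analysis/ [--plots]
cybervigil verify                                      # analytic self-checks
```

Config is TOML (JSON accepted) with `[trial]`, `[operator]` (optionally
`[operator.static]` / `[operator.dynamic]`), and `[cohort]` sections; every
run is reproducible from the config file and its seeds. Trial logs are JSON
Lines (header with config hash + one event per line); curves export as CSV
and the trend report as TSV/JSON.

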