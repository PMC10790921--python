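# Methods

## The task being simulated

`cybervigil` is a headless re-implementation of a three-screen cyber-defense
vigilance task: a simulated Security Event Information Management (SEIM)
console on which an operator must simultaneously (a) watch sixteen honeyfile
status icons for red/green flicker and acknowledge compromises with a Ctrl+D
macro, (b) triage a self-paced queue of SSLBL threat alerts by entering each
alert's priority rating (1–5, lower = more severe), and (c) watch five
frequency charts of alert counts per originating IP and raise an admin alert
when any column reaches its priority's anomaly threshold (3, 5, 7, 9, 11 for
priorities 1–5). Every operator-relevant event is classified into exactly one
of hit, miss, or false alarm per screen, which is the raw material for all
downstream analysis.

## Workload parameterization

Task difficulty is a three-component workload vector w(t) = [S(t), E(t),
C(t)] over a 60-minute trial (t in minutes):

* signal salience S(t): honeyfile flicker frequency, ramping linearly from
  20 Hz to 48 Hz in dynamic mode — S(t) = (7/15)t + 20. Detection of flicker
  approaches chance at 48 Hz, so higher frequency means *lower* salience.
* event rate E(t): left-screen critical-signal rate, ramping 8 → 16
  events/min — E(t) = (2/15)t + 8.
* cognitive load C(t): the number of *near-critical* chart columns (exactly
  one count below threshold) the operator must track, ramping 1 → 4 —
  C(t) = (1/20)t + 1, materialized to an integer by round-half-up.

Static mode pins all three at their hardest values (48 Hz, 16 events/min,
4 near-critical columns), which equal the dynamic ramp's endpoint. The
continuous load value is materialized at injection time; the rounding rule
(half-up) is a package choice, as is treating 48 Hz as the "most difficult"
salience constant (hardest to perceive within the perceptual band).

## Engine mechanics and outcome rules

The engine is a discrete-event simulation on a continuous clock (seconds,
t = 0 at trial start; scoring buckets are half-open `[t, t+width)`).

* Left: flicker onsets are a nonhomogeneous Poisson process with rate E(t),
  generated by thinning against the rate maximum. Each onset lands on a
  uniformly chosen currently-green icon; in the (practically unreachable)
  case that all sixteen icons are already flickering the onset is dropped
  but logged. A macro press answers the *oldest* active flicker (hit) or,
  with none active, scores a false alarm. A flicker unanswered for 10 s
  (configurable) times out as a miss.
* Center: the queue is self-paced and never empty — a new alert arrives the
  moment the previous one is rated; E(t) governs only left-screen signals.
  Rating r against true priority p: r = p hit, r < p false alarm
  (overestimated threat), r > p miss. Each rated alert increments the chart
  column of its *true* type (a config flag switches to the rated type).
* Right: the scripted "AI" keeps the number of near-critical columns at the
  rounded load target by injecting increments that raise columns to exactly
  threshold − 1, never across a threshold — so every breach is opened by the
  operator's own rating activity, coupling the right-screen signal rate to
  center throughput. A column reaching threshold opens a breach; the correct
  IP entry is a hit and resets the column; a wrong IP or an entry with no
  open breach is a false alarm; a breach unanswered for 15 s is a miss
  (column resets). Operator traffic can momentarily push *extra* columns to
  threshold − 1; the AI never removes these, so instantaneous load can
  overshoot the target until ratings consume it.

Every critical signal resolves exactly once (hit before timeout, else one
miss). Signals still open at the 60-minute cutoff are resolved as misses at
the trial end and fall into the final bucket. Simultaneous events process
stimulus-before-action, left-before-center-before-right. The literal
left-miss reading — any non-macro action during a flicker is a left miss —
is available behind `strict_miss_rule` but off by default, because it makes
left denominators depend on center throughput.

Timeout choices (flicker 10 s, breach 15 s) are package defaults chosen to
exceed plausible reaction latencies; they are not empirically derived.

## The synthetic operator

The operator model is *not* derived from human data (none are published for
this task); it exists so the scoring and trend pipeline has a realistic,
controllable test surface. Detection probability on each screen is

p(t) = base + learn·(t/60) − fatigue·W(t) − penalties(t), clamped to
[0.02, 0.98],

where W(t) is the cumulative normalized workload in hours (t/60 under
static, t²/7200 under dynamic — the normalized workload ramps 0 → 1), and
the penalties are coefficient-weighted normalized workload components:
salience (applied to the left screen only, since flicker perceptibility is
a left-screen property), event rate, and cognitive load (applied to all
screens, on the resource-control view that they drain a shared executive
pool). The clamp bounds are parameters so degenerate (perfect/inert)
operators remain expressible in tests.

Detected signals are answered after a log-normal latency (median 1.5 s,
sigma 0.4); center ratings occur every max(2 s, log-normal(3 s, 0.3))
regardless of correctness; incorrect ratings split evenly between one step
too severe (false alarm) and one step too lenient (miss); left and right
false alarms are independent Poisson streams (0.3 and 0.2 events/min).

Default coefficients — base (0.75, 0.80, 0.85), salience 0.12, load 0.10,
rate 0.08, learning 0.15, fatigue 0.10 — make learning dominate under
static workload (constant penalties, net drift ≈ +5 percentage points per
hour) and make rising penalties plus accelerating fatigue dominate under
dynamic workload (net drift ≈ −20 points). Cohorts of 25 such operators
(with ±20% per-participant multiplicative jitter, counterbalanced trial
order, all seeds derived from one base seed) therefore reproduce the
qualitative finding the pipeline is designed to detect: ensemble
performance improves under static workload and declines under dynamic
workload. This is a calibration of *direction*, not of any published
participant-level number.

What the generator does **not** emulate: reaction-time distributions and
accuracy levels of real analysts (unconstrained by published data),
within-trial breaks or attention lapses, strategic screen-prioritization
shifts, and any inter-screen interference beyond the shared probability
penalties. Passing simulation tests therefore demonstrates that the
pipeline recovers trends whose direction and rough magnitude are built into
the generator — not that real operators behave this way.

## Scoring

Per screen and bucket: 100·H/(H+M+F). The total-task curve pools all nine
counts into one ratio rather than averaging the three screen percentages —
the two differ whenever screens carry unequal traffic, and pooling is the
definition used here. Zero-denominator buckets are missing (NaN) and are
dropped pairwise by the trend statistics. Percentages are carried at full
precision and printed to 3 decimals. The minute-level pooled series (width
1) supports the split-half reliability coefficient: Pearson r between the
odd-timestamp (minutes 1, 3, …, 59) and even-timestamp (2, 4, …, 60)
halves, paired chronologically. Cohort curves combine by per-bucket
ensemble means with standard deviations for error bars.

## Trend statistics

* Mann-Kendall: S = Σ_{i<j} sgn(x_j − x_i); tie-corrected variance
  [n(n−1)(2n+5) − Σ t_p(t_p−1)(2t_p+5)]/18; continuity-corrected
  Z = (S∓1)/√var; two-sided normal p; direction called only at p < 0.05.
  Tie correction matters here because percentage series can tie. For an
  untied 30-bucket curve the null standard error is √(30·29·65/18) =
  56.051.
* Sen's slope: median of all pairwise slopes (x_j − x_i)/(j − i) using
  original bucket indices (so missing buckets keep their spacing); the
  confidence band uses the rank method with C = z_{1−α/2}·√var_S, ranks
  M₁ = (N−C)/2 and M₂ = (N+C)/2 rounded to the nearest integer and clipped.
  α = 0.05 by default.
* Durbin-Watson: computed on residuals of an OLS line in bucket index
  (intercept + one regressor); 5% Savin-White bounds for k = 1 are embedded
  for n ∈ {15…40, 45…100 by 5} with linear interpolation between tabulated
  sizes (n = 30 → 1.352/1.489). Both the standard three-zone verdict and
  the binary D < d_U rule are reported, because the binary rule appears in
  applied write-ups; a perfect linear fit leaves no residual variance and
  raises an error rather than reporting a meaningless statistic.
* Two-sided p-values are used throughout. A Z of 1.713 is significant only
  one-sided; the report keeps the two-sided convention and exposes the
  binary autocorrelation rule separately rather than silently switching
  conventions per column.
* The full report is 13 statistic rows × 8 columns (dynamic/static ×
  all-screens/left/center/right), serialized as TSV/JSON.

Minimum series lengths (4 non-missing values for MK/Sen, 6 for
Durbin-Watson) are validation floors, not statistical recommendations; the
intended operating point is the 30-point two-minute-bucket curve.

## Problem sizes and verification

The package's own verification battery uses: brute-force pairwise
enumeration oracles for S, var_S, and Sen's slope on 1,000 random series of
length ≤ 8 (exact / 1e-12); Sen-slope recovery on 500 linear-plus-noise
series (slope 0.4, noise sd 2, n = 30) to within ±0.05 in median;
nonhomogeneous-Poisson calibration of the left-signal count against the
numerically integrated rate schedule over 200 seeded streams (∫₀⁶⁰E dt =
720 dynamic, 960 static); and 100 cohort simulations of 25 operators × 2
trials, requiring the static-positive / dynamic-negative ensemble trend
direction in ≥ 90% of base seeds. One 60-minute trial simulates in a few
tens of milliseconds, so the full battery runs in minutes on one core.

## Known limitations

* The operator model is a plausibility device; none of its parameters are
  fitted to humans, and cohort-level numbers (slopes, prevalences,
  reliability coefficients) are properties of the generator, not
  predictions about analysts.
* The flicker frequency is carried symbolically (it modulates detection
  probability through the salience penalty); nothing is rendered, and the
  ambiguity between full color cycles and individual switches is moot
  until a GUI exists.
* Savin-White bounds cover 15 ≤ n ≤ 100 with one regressor only.
* The five alert-type names are configurable labels; only the priority →
  threshold mapping is behaviourally meaningful.
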