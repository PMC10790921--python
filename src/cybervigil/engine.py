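"""Discrete-event engine for the three-screen network-defense vigilance task.

The simulated console mirrors a Security Event Information Management (SEIM)
workstation spread over three screens:

* **left** — sixteen honeyfile status icons.  A compromised honeyfile makes
  its icon flicker red/green at the scheduled salience frequency; the
  operator acknowledges with a Ctrl+D macro.  Acknowledging the oldest
  active flicker is a hit; pressing the macro with no flicker active is a
  false alarm; a flicker left unanswered past ``flicker_timeout`` is a miss.
* **center** — a self-paced queue of SSLBL threat alerts, each carrying an
  originating IP and a true priority 1-5 (lower number = more severe).
  Rating the head alert with its true priority is a hit; a lower score
  (overestimated threat) is a false alarm; a higher score (underestimated
  threat) is a miss.  Every rated alert increments the matching frequency
  chart column on the right screen.
* **right** — five frequency charts (one per alert type), columns indexed
  by originating IP.  A column reaching its priority's admin-alert
  threshold opens a *breach*; entering that IP in the admin-alert box is a
  hit and resets the column, a wrong IP (or no open breach) is a false
  alarm, and a breach unanswered past ``breach_timeout`` is a miss.  A
  scripted "AI" keeps the number of near-critical columns (count exactly
  one below threshold) tracking the scheduled cognitive load.

Every critical signal resolves exactly once — a hit before its timeout,
otherwise a single miss.  Signals still open when the trial clock runs out
are resolved as misses at the trial end.  All randomness flows from the
config seed (stimuli) and an operator seed (responses), so identical seeds
reproduce bit-identical trial logs.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .schedule import WorkloadMode, WorkloadSchedule, round_half_up

__all__ = [
    "DEFAULT_ALERT_TYPES",
    "DEFAULT_ADMIN_THRESHOLDS",
    "TrialConfig",
    "StimulusEvent",
    "ActionEvent",
    "OutcomeRecord",
    "TrialLog",
    "TrialState",
    "TrialFinishedError",
    "generate_stimulus_stream",
    "run_trial",
    "ip_address",
    "parse_ip",
]

# Alert taxonomy: five operational alert categories, one per SSLBL priority
# rating 1-5 (1 = most severe).  Names are configurable; the priority ->
# admin-threshold map is the behaviourally meaningful part.
DEFAULT_ALERT_TYPES: tuple[tuple[str, int], ...] = (
    ("corporate_privacy_violation", 1),
    ("data_exfiltration", 2),
    ("server_security_misconfiguration", 3),
    ("unknown_traffic", 4),
    ("automated_scanning", 5),
)

DEFAULT_ADMIN_THRESHOLDS: dict[int, int] = {1: 3, 2: 5, 3: 7, 4: 9, 5: 11}


def ip_address(chart: int, ip_idx: int) -> str:
    """Render the (chart, column) pair as the IP string shown to the operator."""
    return f"10.0.{chart}.{ip_idx + 1}"


def parse_ip(ip: str) -> tuple[int, int]:
    """Inverse of :func:`ip_address`; raises ValueError on foreign addresses."""
    parts = ip.split(".")
    if len(parts) != 4 or parts[0] != "10" or parts[1] != "0":
        raise ValueError(f"not a monitored address: {ip!r}")
    return int(parts[2]), int(parts[3]) - 1


@dataclass(frozen=True)
class TrialConfig:
    """Static configuration of one trial.

    ``strict_miss_rule`` enables the literal left-screen miss rule (any
    action other than the macro while an icon flickers scores a left miss);
    the default resolves each flicker exactly once (hit before timeout,
    else one miss at timeout).  ``increment_by_rating`` makes center
    ratings grow the chart of the *rated* type rather than the alert's
    true type.
    """

    schedule: WorkloadSchedule
    seed: int
    icon_count: int = 16
    alert_types: tuple[tuple[str, int], ...] = DEFAULT_ALERT_TYPES
    admin_thresholds: Optional[dict[int, int]] = None
    ip_pool_size: int = 15
    flicker_timeout: float = 10.0
    breach_timeout: float = 15.0
    center_service_floor: float = 2.0
    strict_miss_rule: bool = False
    increment_by_rating: bool = False

    def __post_init__(self) -> None:
        if self.admin_thresholds is None:
            object.__setattr__(self, "admin_thresholds", dict(DEFAULT_ADMIN_THRESHOLDS))
        if self.icon_count < 1:
            raise ValueError("icon_count must be >= 1")
        if self.flicker_timeout <= 0 or self.breach_timeout <= 0:
            raise ValueError("timeouts must be positive")
        if self.center_service_floor < 0:
            raise ValueError("center_service_floor must be >= 0")
        thr = self.admin_thresholds
        prios = sorted(p for _, p in self.alert_types)
        if prios != sorted(thr):
            raise ValueError("alert_types priorities must match admin_thresholds keys")
        ordered = [thr[p] for p in sorted(thr)]
        if any(v < 2 for v in ordered):
            raise ValueError("admin thresholds must all be >= 2")
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise ValueError("admin thresholds must be strictly increasing with priority")

    @property
    def duration_s(self) -> float:
        return self.schedule.duration * 60.0

    def threshold_for_chart(self, chart: int) -> int:
        return self.admin_thresholds[self.alert_types[chart][1]]


@dataclass(frozen=True, slots=True)
class StimulusEvent:
    """A task-generated event: flicker onset, alert arrival, or AI injection."""

    timestamp: float
    screen: str
    kind: str  # flicker_onset | alert_arrival | ai_injection
    payload: dict


@dataclass(frozen=True, slots=True)
class ActionEvent:
    """An operator keystroke/entry: macro, alert rating, or admin alert."""

    timestamp: float
    action: str  # macro_ctrl_d | rate_alert | admin_alert
    score: Optional[int] = None  # rate_alert only, 1-5
    ip: Optional[str] = None  # admin_alert only

    def __post_init__(self) -> None:
        if self.action == "rate_alert" and self.score not in (1, 2, 3, 4, 5):
            raise ValueError(f"rate_alert score must be 1-5, got {self.score}")


@dataclass(frozen=True, slots=True)
class OutcomeRecord:
    """One classified outcome; signal_id is None for false alarms."""

    timestamp: float
    screen: str
    outcome: str  # hit | miss | false_alarm
    signal_id: Optional[str]


@dataclass
class TrialLog:
    """Complete record of one trial: config, stimuli, actions, outcomes."""

    config: TrialConfig
    operator_seed: Optional[int]
    stimuli: list[StimulusEvent]
    actions: list[ActionEvent]
    outcomes: list[OutcomeRecord]
    meta: dict = field(default_factory=dict)

    def outcome_counts(self) -> dict[str, dict[str, int]]:
        """Per-screen hit/miss/false_alarm totals."""
        counts = {s: {"hit": 0, "miss": 0, "false_alarm": 0} for s in ("left", "center", "right")}
        for rec in self.outcomes:
            counts[rec.screen][rec.outcome] += 1
        return counts


class TrialFinishedError(RuntimeError):
    """Raised when an action is applied to a finished trial."""


class TrialState:
    """Mutable in-flight state of a trial.

    Drives the outcome classification rules; :func:`run_trial` layers the
    stimulus schedule and the synthetic operator on top.  The state owns
    the signal-resolution bookkeeping so that every flicker and breach
    yields exactly one hit or miss.
    """

    def __init__(self, config: TrialConfig):
        self.config = config
        self.time = 0.0
        self.finished = False
        # left screen
        self.active_flickers: dict[int, tuple[float, str]] = {}  # icon -> (onset, signal_id)
        self._flick_heap: list[tuple[float, int, float]] = []  # (deadline, icon, onset)
        self._n_onsets = 0
        self._n_dropped = 0
        # center screen
        self.alert_queue: deque[tuple[int, int, str]] = deque()  # (type_idx, ip_idx, signal_id)
        self._n_alerts = 0
        # right screen
        n_charts = len(config.alert_types)
        self.columns: list[list[int]] = [[0] * config.ip_pool_size for _ in range(n_charts)]
        self.open_breaches: dict[tuple[int, int], tuple[float, str]] = {}
        self._breach_heap: list[tuple[float, int, int, float]] = []
        self._n_breaches = 0
        self.near_critical = 0
        self.new_breaches: list[tuple[float, int, int, str]] = []  # drained by the driver
        # logs
        self.stimuli: list[StimulusEvent] = []
        self.actions: list[ActionEvent] = []
        self.outcomes: list[OutcomeRecord] = []

    # -- time ---------------------------------------------------------------

    def advance_time(self, to: float) -> list[OutcomeRecord]:
        """Advance the clock, resolving any signals whose timeout has passed.

        Unanswered flickers become left misses at onset + flicker_timeout;
        unanswered breaches become right misses at open + breach_timeout
        (their columns reset to zero).  Returns the new outcome records.
        """
        if to < self.time:
            raise ValueError(f"cannot advance time backwards ({to} < {self.time})")
        produced: list[OutcomeRecord] = []
        fh, bh = self._flick_heap, self._breach_heap
        while (fh and fh[0][0] <= to) or (bh and bh[0][0] <= to):
            # resolve in deadline order across the two heaps
            if not bh or (fh and fh[0][0] <= bh[0][0]):
                deadline, icon, onset = heapq.heappop(fh)
                entry = self.active_flickers.get(icon)
                if entry is not None and entry[0] == onset:
                    del self.active_flickers[icon]
                    rec = OutcomeRecord(deadline, "left", "miss", entry[1])
                    self.outcomes.append(rec)
                    produced.append(rec)
            else:
                deadline, chart, ip_idx, opened = heapq.heappop(bh)
                entry = self.open_breaches.get((chart, ip_idx))
                if entry is not None and entry[0] == opened:
                    del self.open_breaches[(chart, ip_idx)]
                    self._reset_column(chart, ip_idx)
                    rec = OutcomeRecord(deadline, "right", "miss", entry[1])
                    self.outcomes.append(rec)
                    produced.append(rec)
        self.time = to
        return produced

    def finalize(self, at: Optional[float] = None) -> list[OutcomeRecord]:
        """End the trial, resolving still-open signals as misses at ``at``."""
        end = self.config.duration_s if at is None else at
        produced = self.advance_time(end)
        for icon in list(self.active_flickers):
            _, sig = self.active_flickers.pop(icon)
            rec = OutcomeRecord(end, "left", "miss", sig)
            self.outcomes.append(rec)
            produced.append(rec)
        for key in list(self.open_breaches):
            _, sig = self.open_breaches.pop(key)
            self._reset_column(*key)
            rec = OutcomeRecord(end, "right", "miss", sig)
            self.outcomes.append(rec)
            produced.append(rec)
        self.finished = True
        return produced

    # -- stimuli ------------------------------------------------------------

    def record_flicker_onset(self, t: float, u: float, frequency: float) -> Optional[str]:
        """Start a flicker on a uniformly chosen green icon (``u`` in [0,1)).

        Returns the signal id, or None when all icons are already
        flickering (the onset is dropped but still logged).
        """
        n = self.config.icon_count
        active = self.active_flickers
        greens = [i for i in range(n) if i not in active]
        self._n_onsets += 1
        if not greens:
            self._n_dropped += 1
            self.stimuli.append(
                StimulusEvent(t, "left", "flicker_onset", {"icon": None, "frequency_hz": frequency})
            )
            return None
        icon = greens[int(u * len(greens))]
        sig = f"L{self._n_onsets - 1}"
        active[icon] = (t, sig)
        heapq.heappush(self._flick_heap, (t + self.config.flicker_timeout, icon, t))
        self.stimuli.append(
            StimulusEvent(t, "left", "flicker_onset", {"icon": icon, "frequency_hz": frequency})
        )
        return sig

    def enqueue_alert(self, t: float, type_idx: int, ip_idx: int) -> str:
        """Add an alert to the center queue (arrival stimulus is logged)."""
        sig = f"C{self._n_alerts}"
        self._n_alerts += 1
        priority = self.config.alert_types[type_idx][1]
        self.alert_queue.append((type_idx, ip_idx, sig))
        self.stimuli.append(
            StimulusEvent(
                t,
                "center",
                "alert_arrival",
                {
                    "ip": ip_address(type_idx, ip_idx),
                    "alert_type": self.config.alert_types[type_idx][0],
                    "sslbl_priority": priority,
                },
            )
        )
        return sig

    def ai_topup(self, t: float, u_source) -> int:
        """Inject AI column increments until the near-critical count matches
        the scheduled cognitive-load target at time ``t`` (round-half-up).

        ``u_source`` is a callable returning uniforms in [0,1) (one draw
        per injection).  Injections only ever raise a column to exactly
        threshold − 1, never across a threshold.  Returns the number of
        injections performed.
        """
        target = round_half_up(self.config.schedule.cognitive_load_at(t / 60.0))
        n_inj = 0
        while self.near_critical < target:
            candidates = []
            for chart in range(len(self.columns)):
                thr = self.config.threshold_for_chart(chart)
                col = self.columns[chart]
                for ip_idx in range(self.config.ip_pool_size):
                    if col[ip_idx] < thr - 1 and (chart, ip_idx) not in self.open_breaches:
                        candidates.append((chart, ip_idx))
            if not candidates:
                break
            chart, ip_idx = candidates[int(u_source() * len(candidates))]
            thr = self.config.threshold_for_chart(chart)
            inc = thr - 1 - self.columns[chart][ip_idx]
            self.columns[chart][ip_idx] = thr - 1
            self.near_critical += 1
            n_inj += 1
            self.stimuli.append(
                StimulusEvent(
                    t,
                    "right",
                    "ai_injection",
                    {"chart": chart, "ip": ip_address(chart, ip_idx), "increment": inc},
                )
            )
        return n_inj

    # -- actions ------------------------------------------------------------

    def apply_action(self, action: ActionEvent) -> list[OutcomeRecord]:
        """Apply one operator action, returning the outcome records produced.

        Advances the clock to the action timestamp first, so timeouts due
        earlier resolve before the action is classified.
        """
        if self.finished:
            raise TrialFinishedError("trial already finished")
        produced = self.advance_time(action.timestamp)
        t = action.timestamp
        self.actions.append(action)
        if action.action == "macro_ctrl_d":
            produced.extend(self._apply_macro(t))
        elif action.action == "rate_alert":
            produced.extend(self._strict_left_miss(t))
            produced.extend(self._apply_rating(t, action.score))
        elif action.action == "admin_alert":
            produced.extend(self._strict_left_miss(t))
            produced.extend(self._apply_admin(t, action.ip))
        else:
            raise ValueError(f"unknown action {action.action!r}")
        return produced

    def _strict_left_miss(self, t: float) -> list[OutcomeRecord]:
        # literal rule: any non-macro action while an icon flickers is a left miss
        if not (self.config.strict_miss_rule and self.active_flickers):
            return []
        icon = next(iter(self.active_flickers))
        _, sig = self.active_flickers.pop(icon)
        rec = OutcomeRecord(t, "left", "miss", sig)
        self.outcomes.append(rec)
        return [rec]

    def _apply_macro(self, t: float) -> list[OutcomeRecord]:
        if self.active_flickers:
            icon = next(iter(self.active_flickers))  # oldest onset (insertion order)
            _, sig = self.active_flickers.pop(icon)
            rec = OutcomeRecord(t, "left", "hit", sig)
        else:
            rec = OutcomeRecord(t, "left", "false_alarm", None)
        self.outcomes.append(rec)
        return [rec]

    def _apply_rating(self, t: float, score: int) -> list[OutcomeRecord]:
        if not self.alert_queue:
            raise ValueError("rate_alert with an empty alert queue")
        type_idx, ip_idx, sig = self.alert_queue.popleft()
        priority = self.config.alert_types[type_idx][1]
        if score == priority:
            rec = OutcomeRecord(t, "center", "hit", sig)
        elif score < priority:  # lower score = more severe = overestimated threat
            rec = OutcomeRecord(t, "center", "false_alarm", None)
        else:
            rec = OutcomeRecord(t, "center", "miss", sig)
        self.outcomes.append(rec)
        produced = [rec]
        chart = type_idx
        if self.config.increment_by_rating:
            # grow the chart of the rated type instead of the true type
            chart = next(
                i for i, (_, p) in enumerate(self.config.alert_types) if p == score
            )
        self._increment_column(t, chart, ip_idx)
        return produced

    def _apply_admin(self, t: float, ip: str) -> list[OutcomeRecord]:
        try:
            key = parse_ip(ip)
        except ValueError:
            key = (-1, -1)
        entry = self.open_breaches.get(key)
        if entry is not None:
            del self.open_breaches[key]
            self._reset_column(*key)
            rec = OutcomeRecord(t, "right", "hit", entry[1])
        else:
            rec = OutcomeRecord(t, "right", "false_alarm", None)
        self.outcomes.append(rec)
        return [rec]

    # -- right-screen internals ---------------------------------------------

    def _increment_column(self, t: float, chart: int, ip_idx: int) -> None:
        thr = self.config.threshold_for_chart(chart)
        col = self.columns[chart]
        before = col[ip_idx]
        col[ip_idx] = before + 1
        if before + 1 == thr - 1:
            self.near_critical += 1
        elif before == thr - 1:
            self.near_critical -= 1
        if before + 1 >= thr and (chart, ip_idx) not in self.open_breaches:
            sig = f"R{self._n_breaches}"
            self._n_breaches += 1
            self.open_breaches[(chart, ip_idx)] = (t, sig)
            heapq.heappush(self._breach_heap, (t + self.config.breach_timeout, chart, ip_idx, t))
            self.new_breaches.append((t, chart, ip_idx, sig))

    def _reset_column(self, chart: int, ip_idx: int) -> None:
        thr = self.config.threshold_for_chart(chart)
        if self.columns[chart][ip_idx] == thr - 1:
            self.near_critical -= 1
        self.columns[chart][ip_idx] = 0

    def pop_new_breaches(self) -> list[tuple[float, int, int, str]]:
        out = self.new_breaches
        self.new_breaches = []
        return out


# ---------------------------------------------------------------------------
# Stimulus generation
# ---------------------------------------------------------------------------


def _left_onset_times(config: TrialConfig, rng: np.random.Generator) -> np.ndarray:
    """Flicker-onset times (s) from a nonhomogeneous Poisson process with
    rate E(t) events/min, by thinning against the rate maximum."""
    sched = config.schedule
    dur_min = sched.duration
    rate_max = max(sched.event_rate_at(0.0), sched.event_rate_at(dur_min))  # events/min
    n = rng.poisson(rate_max * dur_min)
    times_min = np.sort(rng.uniform(0.0, dur_min, size=n))
    if sched.mode is WorkloadMode.STATIC:
        return times_min * 60.0
    lo, hi = sched.event_rate_bounds
    rate = lo + (hi - lo) * times_min / dur_min  # E(t), linear ramp
    accept = rng.uniform(size=n) * rate_max < rate
    return times_min[accept] * 60.0


def _ai_step_times(config: TrialConfig) -> list[float]:
    """Times (s) at which the integer cognitive-load target steps up."""
    sched = config.schedule
    if sched.mode is WorkloadMode.STATIC:
        return []
    lo, hi = sched.load_bounds
    steps = []
    for k in range(round_half_up(lo), round_half_up(hi) + 1):
        # first t with round_half_up(C_load(t)) == k, i.e. C_load(t) = k - 0.5
        tc = (k - 0.5 - lo) * sched.duration / (hi - lo)
        if 0.0 < tc <= sched.duration:
            steps.append(tc * 60.0)
    return steps


def generate_stimulus_stream(config: TrialConfig) -> list[StimulusEvent]:
    """Generate the time-driven stimulus stream for a trial, without an
    operator in the loop.

    Contains the left flicker onsets (icons assigned under timeout-only
    dynamics), the initial center alert arrival (the queue is self-paced:
    later arrivals occur as the operator rates), and the AI injections at
    the load-target step times.  Deterministic given ``config.seed``.
    """
    state = TrialState(config)
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_onsets = np.random.default_rng(ss[0])
    rng_icons = np.random.default_rng(ss[1])
    rng_alerts = np.random.default_rng(ss[2])
    rng_ai = np.random.default_rng(ss[3])

    onsets = _left_onset_times(config, rng_onsets)
    icon_u = rng_icons.uniform(size=len(onsets))
    state.enqueue_alert(
        0.0, int(rng_alerts.integers(len(config.alert_types))), int(rng_alerts.integers(config.ip_pool_size))
    )
    state.ai_topup(0.0, lambda: float(rng_ai.uniform()))
    steps = deque(_ai_step_times(config))
    sched = config.schedule
    for i, t in enumerate(onsets):
        while steps and steps[0] <= t:
            ts = steps.popleft()
            state.advance_time(ts)
            state.ai_topup(ts, lambda: float(rng_ai.uniform()))
        state.advance_time(t)
        state.record_flicker_onset(t, float(icon_u[i]), sched.salience_at(t / 60.0))
    for ts in steps:
        state.advance_time(ts)
        state.ai_topup(ts, lambda: float(rng_ai.uniform()))
    return sorted(state.stimuli, key=lambda e: e.timestamp)


# ---------------------------------------------------------------------------
# Full coupled trial
# ---------------------------------------------------------------------------

# driver event kinds (heap tie-break: stimuli before actions, left < center < right)
_EV_FLICK = 0  # stimulus, left
_EV_AI = 1  # stimulus, right (load-target step)
_EV_MACRO = 2  # action, left
_EV_RATE = 3  # action, center
_EV_ADMIN = 4  # action, right


def run_trial(config: TrialConfig, operator, operator_seed: int) -> TrialLog:
    """Run one complete trial: stimuli + synthetic operator -> TrialLog.

    ``operator`` is an :class:`~cybervigil.operator_sim.OperatorParams`.
    The stimulus stream is driven by ``config.seed``; all operator
    randomness (detection draws, latencies, service times, false-alarm
    streams) by ``operator_seed``.  Identical seed pairs give identical
    logs.
    """
    from .operator_sim import _screen_prob_fns  # deferred: avoids import cycle

    state = TrialState(config)
    sched = config.schedule
    end = config.duration_s

    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_onsets = np.random.default_rng(ss[0])
    rng_icons = np.random.default_rng(ss[1])
    rng_alerts = np.random.default_rng(ss[2])
    rng_ai = np.random.default_rng(ss[3])
    ai_u = lambda: float(rng_ai.uniform())

    onsets = _left_onset_times(config, rng_onsets)
    n_onsets = len(onsets)
    icon_u = rng_icons.uniform(size=n_onsets)

    # pre-generated alert content (self-paced queue; generous upper bound)
    max_ratings = int(end / max(config.center_service_floor, 0.5)) + 8
    alert_types_arr = rng_alerts.integers(len(config.alert_types), size=max_ratings + 1)
    alert_ips_arr = rng_alerts.integers(config.ip_pool_size, size=max_ratings + 1)

    oss = np.random.SeedSequence(operator_seed).spawn(6)
    rng_left = np.random.default_rng(oss[0])
    rng_center = np.random.default_rng(oss[1])
    rng_right = np.random.default_rng(oss[2])
    rng_fa = np.random.default_rng(oss[3])

    p_left, p_center, p_right = _screen_prob_fns(operator, sched)

    left_u = rng_left.uniform(size=n_onsets)
    left_lat = operator.draw_latency(rng_left, n_onsets)
    service = operator.draw_service(rng_center, max_ratings, config.center_service_floor)
    center_u = rng_center.uniform(size=max_ratings)
    center_err = rng_center.uniform(size=max_ratings)
    right_pool = 4096
    right_u = rng_right.uniform(size=right_pool)
    right_lat = operator.draw_latency(rng_right, right_pool)
    right_i = 0

    heap: list[tuple[float, int, int, tuple]] = []
    seq = 0

    def push(t: float, kind: int, payload: tuple = ()) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, kind, seq, payload))
        seq += 1

    for i in range(n_onsets):
        push(float(onsets[i]), _EV_FLICK, (i,))
    for ts in _ai_step_times(config):
        push(ts, _EV_AI)

    # operator false-alarm streams: homogeneous Poisson presses/entries
    fa_left_rate, _, fa_right_rate = operator.false_alarm_rate
    for t in _poisson_times(rng_fa, fa_left_rate, end):
        push(t, _EV_MACRO)
    fa_right_times = _poisson_times(rng_fa, fa_right_rate, end)
    fa_right_charts = rng_fa.integers(len(config.alert_types), size=len(fa_right_times))
    fa_right_ips = rng_fa.integers(config.ip_pool_size, size=len(fa_right_times))
    for j, t in enumerate(fa_right_times):
        push(t, _EV_ADMIN, (ip_address(int(fa_right_charts[j]), int(fa_right_ips[j])),))

    # self-paced center queue: first alert at t=0, first rating after one service draw
    state.enqueue_alert(0.0, int(alert_types_arr[0]), int(alert_ips_arr[0]))
    state.ai_topup(0.0, ai_u)
    rating_idx = 0
    if service[0] <= end:
        push(float(service[0]), _EV_RATE, (0,))

    while heap:
        t, kind, _, payload = heapq.heappop(heap)
        if t > end:
            break
        if kind == _EV_FLICK:
            i = payload[0]
            state.advance_time(t)
            state.record_flicker_onset(t, float(icon_u[i]), sched.salience_at(t / 60.0))
            if left_u[i] < p_left(t):
                push(t + float(left_lat[i]), _EV_MACRO)
        elif kind == _EV_AI:
            state.advance_time(t)
            state.ai_topup(t, ai_u)
        elif kind == _EV_MACRO:
            state.apply_action(ActionEvent(t, "macro_ctrl_d"))
        elif kind == _EV_RATE:
            k = payload[0]
            type_idx, ip_idx, _sig = state.alert_queue[0]
            priority = config.alert_types[type_idx][1]
            if center_u[k] < p_center(t):
                score = priority
            elif center_err[k] < 0.5:
                score = priority - 1 if priority > 1 else priority + 1
            else:
                score = priority + 1 if priority < 5 else priority - 1
            state.apply_action(ActionEvent(t, "rate_alert", score=score))
            state.enqueue_alert(t, int(alert_types_arr[k + 1]), int(alert_ips_arr[k + 1]))
            state.ai_topup(t, ai_u)
            rating_idx = k + 1
            if rating_idx < max_ratings:
                t_next = t + float(service[rating_idx])
                if t_next <= end:
                    push(t_next, _EV_RATE, (rating_idx,))
        elif kind == _EV_ADMIN:
            state.apply_action(ActionEvent(t, "admin_alert", ip=payload[0]))
            state.ai_topup(t, ai_u)
        # operator reaction to any breach opened by this event
        for bt, chart, ip_idx, _sig in state.pop_new_breaches():
            if right_i >= right_pool:
                right_u = rng_right.uniform(size=right_pool)
                right_lat = operator.draw_latency(rng_right, right_pool)
                right_i = 0
            if right_u[right_i] < p_right(bt):
                push(bt + float(right_lat[right_i]), _EV_ADMIN, (ip_address(chart, ip_idx),))
            right_i += 1

    state.finalize(end)
    log = TrialLog(
        config=config,
        operator_seed=operator_seed,
        stimuli=state.stimuli,
        actions=state.actions,
        outcomes=state.outcomes,
        meta={"mode": sched.mode.value},
    )
    return log


def _poisson_times(rng: np.random.Generator, rate_per_min: float, end_s: float) -> np.ndarray:
    """Arrival times (s) of a homogeneous Poisson process on [0, end_s]."""
    if rate_per_min <= 0:
        return np.empty(0)
    n = rng.poisson(rate_per_min * end_s / 60.0)
    return np.sort(rng.uniform(0.0, end_s, size=n))
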