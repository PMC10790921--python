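"""Synthetic human operator for the vigilance task.

No participant-level behavioural data are published for this paradigm, so
the operator is a transparent parametric stand-in rather than a fitted
model.  Its detection probability combines, additively:

* a per-screen base detection probability,
* a practice (learning) gain that grows linearly with time on task,
* a fatigue loss proportional to the cumulative normalized workload
  already endured (the resource-control view: sustained demand drains the
  executive resources allocated to the task), and
* instantaneous workload penalties — salience (left screen only: a faster
  flicker is harder to see), event rate, and cognitive load — each scaled
  to its [0, 1] range.

The combined probability is clamped to [0.02, 0.98].  Under a static
schedule the workload penalties are constant, so the learning term
dominates and performance drifts up; under a dynamic schedule the rising
penalties and the accelerating fatigue term dominate and performance
drifts down.  The shipped defaults are calibrated so that 25-operator
cohorts reproduce the qualitative static-improvement / dynamic-decrement
pattern, which is what the downstream trend pipeline is tested against.

Detected signals are answered after a log-normal latency; center-screen
rating errors split evenly between one-step-too-severe (a false alarm)
and one-step-too-lenient (a miss); false alarms on the left and right
screens arrive as independent Poisson streams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .engine import TrialConfig, TrialLog, run_trial
from .schedule import WorkloadMode, WorkloadSchedule

__all__ = [
    "OperatorParams",
    "response_probability",
    "simulate_responses",
    "simulate_cohort",
    "PROB_FLOOR",
    "PROB_CEIL",
]

PROB_FLOOR = 0.02
PROB_CEIL = 0.98

_SCREENS = ("left", "center", "right")

DEFAULT_BOUNDS = {
    "salience": (20.0, 48.0),
    "event_rate": (8.0, 16.0),
    "load": (1.0, 4.0),
}


@dataclass(frozen=True)
class OperatorParams:
    """Parameter set of one synthetic operator.

    Probabilities are per screen (left, center, right); coefficients are
    probability changes per normalized unit: ``salience_coeff`` per unit
    of normalized flicker frequency, ``rate_coeff`` / ``load_coeff`` per
    unit of normalized event rate / cognitive load, ``learn_coeff`` per
    hour on task, ``fatigue_coeff`` per unit cumulative normalized
    workload.  ``latency`` and ``center_service_time`` are log-normal
    (median seconds, log-scale sigma); ``false_alarm_rate`` is events/min
    per screen (the center entry is unused — center false alarms arise
    from rating errors, not spontaneous entries).
    """

    base_detect: tuple[float, float, float] = (0.75, 0.80, 0.85)
    salience_coeff: float = 0.12
    load_coeff: float = 0.10
    rate_coeff: float = 0.08
    learn_coeff: float = 0.15
    fatigue_coeff: float = 0.10
    false_alarm_rate: tuple[float, float, float] = (0.3, 0.0, 0.2)
    latency: tuple[float, float] = (1.5, 0.4)
    center_service_time: tuple[float, float] = (3.0, 0.3)
    # combination clamp; override only for degenerate (perfect/inert) operators
    prob_floor: float = PROB_FLOOR
    prob_ceil: float = PROB_CEIL

    def __post_init__(self) -> None:
        if len(self.base_detect) != 3 or not all(0.0 <= p <= 1.0 for p in self.base_detect):
            raise ValueError("base_detect must be three probabilities in [0, 1]")
        if any(r < 0 for r in self.false_alarm_rate):
            raise ValueError("false_alarm_rate entries must be >= 0")
        for name in ("latency", "center_service_time"):
            med, sigma = getattr(self, name)
            if med <= 0 or sigma <= 0:
                raise ValueError(f"{name} (median, sigma) must both be positive")
        if not 0.0 <= self.prob_floor <= self.prob_ceil <= 1.0:
            raise ValueError("need 0 <= prob_floor <= prob_ceil <= 1")

    @classmethod
    def defaults(cls) -> "OperatorParams":
        return cls()

    # -- random draws --------------------------------------------------------

    def draw_latency(self, rng: np.random.Generator, n: int) -> np.ndarray:
        med, sigma = self.latency
        return med * np.exp(sigma * rng.standard_normal(n))

    def draw_service(self, rng: np.random.Generator, n: int, floor: float) -> np.ndarray:
        med, sigma = self.center_service_time
        return np.maximum(floor, med * np.exp(sigma * rng.standard_normal(n)))

    def jittered(self, rng: np.random.Generator, amount: float = 0.2) -> "OperatorParams":
        """Per-participant heterogeneity: one multiplicative jitter
        (uniform in 1 +/- amount) per base probability and coefficient."""
        m = rng.uniform(1.0 - amount, 1.0 + amount, size=8)
        base = tuple(min(1.0, p * m[i]) for i, p in enumerate(self.base_detect))
        return replace(
            self,
            base_detect=base,
            salience_coeff=self.salience_coeff * m[3],
            load_coeff=self.load_coeff * m[4],
            rate_coeff=self.rate_coeff * m[5],
            learn_coeff=self.learn_coeff * m[6],
            fatigue_coeff=self.fatigue_coeff * m[7],
        )

    # -- detection probability ----------------------------------------------

    def probability(self, screen: str, schedule: WorkloadSchedule, t: float) -> float:
        """Detection probability on ``screen`` at ``t`` minutes under
        ``schedule`` (instantaneous workload and accumulated fatigue both
        derived from the schedule)."""
        return response_probability(
            self,
            screen,
            schedule.workload_vector(t),
            t,
            cumulative_workload=schedule.cumulative_normalized_workload(t),
            bounds={
                "salience": schedule.salience_bounds,
                "event_rate": schedule.event_rate_bounds,
                "load": schedule.load_bounds,
            },
        )


def response_probability(
    params: OperatorParams,
    screen: str,
    workload: tuple[float, float, float],
    t: float,
    cumulative_workload: float = 0.0,
    bounds: dict = DEFAULT_BOUNDS,
) -> float:
    """Additive detection-probability combination, clamped to [0.02, 0.98].

    ``workload`` is the (salience, event_rate, load) triple at time ``t``
    (minutes); ``cumulative_workload`` is the time-integral of normalized
    workload over [0, t] in hours (see
    :meth:`WorkloadSchedule.cumulative_normalized_workload`).
    """
    if screen not in _SCREENS:
        raise ValueError(f"unknown screen {screen!r}")
    s, e, c = workload
    s_lo, s_hi = bounds["salience"]
    e_lo, e_hi = bounds["event_rate"]
    c_lo, c_hi = bounds["load"]
    s_norm = (s - s_lo) / (s_hi - s_lo)
    e_norm = (e - e_lo) / (e_hi - e_lo)
    c_norm = (c - c_lo) / (c_hi - c_lo)
    base = params.base_detect[_SCREENS.index(screen)]
    p = base + params.learn_coeff * (t / 60.0) - params.fatigue_coeff * cumulative_workload
    p -= params.load_coeff * c_norm + params.rate_coeff * e_norm
    if screen == "left":
        p -= params.salience_coeff * s_norm
    return min(params.prob_ceil, max(params.prob_floor, p))


def _screen_prob_fns(
    params: OperatorParams, sched: WorkloadSchedule
) -> tuple[Callable[[float], float], ...]:
    """Closed-form p(t) per screen with t in *seconds* (engine hot path).

    Equivalent to :func:`response_probability` evaluated along the
    schedule: under both modes the probability is a quadratic in t (the
    fatigue integral is linear for static, quadratic for dynamic), so the
    hot path evaluates three precomputed polynomials with a clamp.
    """
    dur = sched.duration
    floor, ceil = params.prob_floor, params.prob_ceil
    fns = []
    for screen in _SCREENS:
        base = params.base_detect[_SCREENS.index(screen)]
        pen = params.load_coeff + params.rate_coeff
        if screen == "left":
            pen += params.salience_coeff
        if sched.mode is WorkloadMode.STATIC:
            a = base - pen
            b = (params.learn_coeff - params.fatigue_coeff) / 3600.0
            c = 0.0
        else:
            a = base
            b = params.learn_coeff / 3600.0 - pen / (dur * 60.0)
            c = -params.fatigue_coeff / (3600.0 * 2.0 * 60.0 * dur)
        fns.append(
            lambda tau, a=a, b=b, c=c: min(ceil, max(floor, a + b * tau + c * tau * tau))
        )
    return tuple(fns)


def simulate_responses(
    params: OperatorParams, config: TrialConfig, seed: int
) -> list:
    """Simulate the operator against a trial's stimulus stream and return
    the resulting action stream (``ActionEvent`` list).

    The operator's responses are state-coupled (the center queue is
    self-paced and right-screen breaches depend on the operator's own
    ratings), so the responses are produced by running the full coupled
    trial; this is a convenience view of :func:`~cybervigil.engine.run_trial`.
    """
    return run_trial(config, params, seed).actions


def simulate_cohort(
    n: int,
    params_static: Optional[OperatorParams] = None,
    params_dynamic: Optional[OperatorParams] = None,
    base_seed: int = 0,
    duration: float = 60.0,
    config_kwargs: Optional[dict] = None,
) -> list[TrialLog]:
    """Simulate ``n`` participants, each completing one static and one
    dynamic trial with counterbalanced order.

    Participants with even index run static-first, giving a
    ceil(n/2)/floor(n/2) order split.  Each participant's parameters get
    one multiplicative +/-20% jitter (shared between their two trials);
    all seeds derive from ``base_seed``.  Returns the 2n trial logs in
    performed order, with ``meta`` carrying participant, mode, and order.
    """
    if n < 2:
        raise ValueError("need n >= 2 participants to counterbalance trial order")
    params_static = params_static or OperatorParams.defaults()
    params_dynamic = params_dynamic or OperatorParams.defaults()
    config_kwargs = config_kwargs or {}
    ss = np.random.SeedSequence(base_seed)
    logs: list[TrialLog] = []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        seeds = rng.integers(2**31, size=4)
        p_s = params_static.jittered(rng)
        p_d = params_dynamic.jittered(rng)
        static_first = i % 2 == 0
        order = "static_first" if static_first else "dynamic_first"
        trials = [
            (WorkloadMode.STATIC, p_s, int(seeds[0]), int(seeds[1])),
            (WorkloadMode.DYNAMIC, p_d, int(seeds[2]), int(seeds[3])),
        ]
        if not static_first:
            trials.reverse()
        for mode, p, cfg_seed, op_seed in trials:
            config = TrialConfig(
                schedule=WorkloadSchedule(mode=mode, duration=duration),
                seed=cfg_seed,
                **config_kwargs,
            )
            log = run_trial(config, p, op_seed)
            log.meta.update({"participant": i, "order": order, "mode": mode.value})
            logs.append(log)
    return logs
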