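"""Neurocognitive workload schedules for the three-screen vigilance task.

Task difficulty is parameterized by three time-varying workload factors:

* **signal salience** ``S(t)`` — the flicker frequency (Hz) of critical
  left-screen honeyfile icons.  Detection of a flickering icon gets harder
  as the frequency approaches the perceptual limit of 48 Hz.
* **event rate** ``E(t)`` — the rate (events/min) at which critical
  left-screen signals are presented, spanning 8–16 events per minute.
* **cognitive load** ``C_load(t)`` — the target number of *near-critical*
  right-screen chart columns (columns sitting exactly one count below their
  admin-alert threshold) that the operator must hold in working memory,
  bounded between 1 and 4 elements.

Two protocols are supported.  In *dynamic* mode each factor ramps linearly
from its easiest value at ``t = 0`` to its hardest value at ``t = 60`` min.
In *static* mode all three are held constant at their most difficult
processing values (48 Hz, 16 events/min, 4 near-critical signals), i.e. the
dynamic end-point.

Note on symbols: the literature uses ``C(t)`` both for cognitive load and
for center-screen performance; here the workload component is always
``C_load`` and the performance curve is ``perf_C`` (see :mod:`.scoring`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "WorkloadMode",
    "WorkloadSchedule",
    "salience_at",
    "event_rate_at",
    "cognitive_load_at",
    "workload_vector",
    "round_half_up",
]


class WorkloadMode(str, Enum):
    """Trial protocol: constant-at-hardest or linearly ramping workload."""

    STATIC = "static"
    DYNAMIC = "dynamic"


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (2.5 -> 3).

    Used when the continuous cognitive-load target is materialized into an
    integer number of near-critical columns.
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class WorkloadSchedule:
    """The (mode, S(t), E(t), C_load(t)) parameterization of a trial.

    Parameters
    ----------
    mode
        ``WorkloadMode.STATIC`` or ``WorkloadMode.DYNAMIC``.
    duration
        Trial duration in minutes (default 60).
    salience_bounds
        (min, max) flicker frequency in Hz, default (20, 48).
    event_rate_bounds
        (min, max) critical-signal rate in events/min, default (8, 16).
    load_bounds
        (min, max) near-critical column count, default (1, 4).
    """

    mode: WorkloadMode
    duration: float = 60.0
    salience_bounds: tuple[float, float] = (20.0, 48.0)
    event_rate_bounds: tuple[float, float] = (8.0, 16.0)
    load_bounds: tuple[float, float] = (1.0, 4.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", WorkloadMode(self.mode))
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        for name in ("salience_bounds", "event_rate_bounds", "load_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be (min, max) with min < max, got {(lo, hi)}")

    # -- internal -----------------------------------------------------------

    def _check_t(self, t: float) -> None:
        if not 0 <= t <= self.duration:
            raise ValueError(f"t={t} outside trial window [0, {self.duration}] min")

    def _ramp(self, bounds: tuple[float, float], t: float) -> float:
        self._check_t(t)
        lo, hi = bounds
        if self.mode is WorkloadMode.STATIC:
            return hi
        return lo + (hi - lo) * t / self.duration

    # -- workload components ------------------------------------------------

    def salience_at(self, t: float) -> float:
        """Flicker frequency S(t) in Hz at time ``t`` minutes.

        Dynamic mode ramps (7/15)t + 20 over the default 60-min trial;
        static mode holds the hardest-to-detect constant of 48 Hz.
        """
        return self._ramp(self.salience_bounds, t)

    def event_rate_at(self, t: float) -> float:
        """Critical-signal rate E(t) in events/min at time ``t`` minutes.

        Dynamic mode ramps (2/15)t + 8 over the default trial; static mode
        holds the maximum of 16 events/min.
        """
        return self._ramp(self.event_rate_bounds, t)

    def cognitive_load_at(self, t: float) -> float:
        """Continuous near-critical-column target C_load(t) at ``t`` minutes.

        Dynamic mode ramps (1/20)t + 1 over the default trial; static mode
        holds the working-memory ceiling of 4.  The engine materializes this
        to an integer by round-half-up at injection time.
        """
        return self._ramp(self.load_bounds, t)

    def workload_vector(self, t: float) -> tuple[float, float, float]:
        """The workload vector w = (S(t), E(t), C_load(t)) at ``t`` minutes."""
        return (
            self.salience_at(t),
            self.event_rate_at(t),
            self.cognitive_load_at(t),
        )

    def normalized_workload(self, t: float) -> float:
        """Mean of the three components, each rescaled to [0, 1] over its bounds."""
        s, e, c = self.workload_vector(t)
        comps = []
        for value, (lo, hi) in zip(
            (s, e, c), (self.salience_bounds, self.event_rate_bounds, self.load_bounds)
        ):
            comps.append((value - lo) / (hi - lo))
        return sum(comps) / 3.0

    def cumulative_normalized_workload(self, t: float) -> float:
        """Time-integral of :meth:`normalized_workload` over [0, t], in hours.

        Closed form: the normalized workload is constant 1 in static mode
        (giving t/60) and ramps linearly 0 -> 1 in dynamic mode (giving
        t^2 / (2 * 60 * duration)).  Used as the fatigue driver of the
        synthetic operator; ranges over [0, 1] for a 60-min trial in static
        mode and [0, 0.5] in dynamic mode.
        """
        self._check_t(t)
        if self.mode is WorkloadMode.STATIC:
            return t / 60.0
        return t * t / (2.0 * 60.0 * self.duration)


# ---------------------------------------------------------------------------
# Functional surface (thin wrappers over the dataclass methods)
# ---------------------------------------------------------------------------


def salience_at(schedule: WorkloadSchedule, t: float) -> float:
    """Flicker frequency S(t) in Hz at time ``t`` minutes."""
    return schedule.salience_at(t)


def event_rate_at(schedule: WorkloadSchedule, t: float) -> float:
    """Critical-signal rate E(t) in events/min at time ``t`` minutes."""
    return schedule.event_rate_at(t)


def cognitive_load_at(schedule: WorkloadSchedule, t: float) -> float:
    """Continuous cognitive-load target C_load(t) at time ``t`` minutes."""
    return schedule.cognitive_load_at(t)


def workload_vector(schedule: WorkloadSchedule, t: float) -> tuple[float, float, float]:
    """(S(t), E(t), C_load(t)) at time ``t`` minutes."""
    return schedule.workload_vector(t)
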