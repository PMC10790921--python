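"""Vigilance performance curves: bucketed correct-detection percentages.

Outcomes are aggregated into half-open time buckets ``[t, t + width)``
(width 2 min by default).  Per screen the bucket score is
``100 * H / (H + M + F)``; the total-task score pools the nine counts into
one ratio, ``100 * (H_L + H_C + H_R) / sum(all hits, misses and false
alarms)`` — pooling, not averaging, so screens with more traffic weigh
more.  A bucket with zero denominator is *missing* (NaN) and is excluded
pairwise from downstream trend tests.  A minute-level pooled series (width
1) feeds the split-half reliability check, and cohort curves are combined
by per-bucket ensemble averaging with standard deviations for error bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import TrialLog

__all__ = [
    "BucketCounts",
    "VigilanceCurve",
    "bucket_counts",
    "detection_percentages",
    "minute_detection_series",
    "ensemble_average",
    "score_log",
]

_SCREENS = ("left", "center", "right")
_OUTCOMES = ("hit", "miss", "false_alarm")


@dataclass(frozen=True)
class BucketCounts:
    """Hit/miss/false-alarm counts for one time bucket, per screen.

    ``counts[screen]`` is a (hits, misses, false_alarms) triple; the
    interval is the half-open ``[start, start + width)`` in minutes.
    """

    index: int
    start_min: float
    width_min: float
    counts: dict[str, tuple[int, int, int]]

    def pooled(self) -> tuple[int, int, int]:
        h = sum(self.counts[s][0] for s in _SCREENS)
        m = sum(self.counts[s][1] for s in _SCREENS)
        f = sum(self.counts[s][2] for s in _SCREENS)
        return h, m, f


@dataclass
class VigilanceCurve:
    """Per-bucket detection percentages for each screen and pooled total.

    Arrays are aligned on ``starts_min``; missing buckets (zero
    denominator) are NaN.  ``sd`` holds per-bucket standard deviations
    when the curve is an ensemble average, else None.
    """

    width_min: float
    starts_min: np.ndarray
    perf_L: np.ndarray
    perf_C: np.ndarray
    perf_R: np.ndarray
    perf_T: np.ndarray
    sd: Optional[dict[str, np.ndarray]] = None
    n_curves: int = 1

    @property
    def n_buckets(self) -> int:
        return len(self.starts_min)

    def series(self, which: str) -> np.ndarray:
        """Series by name: 'total', 'left', 'center' or 'right'."""
        return {
            "total": self.perf_T,
            "left": self.perf_L,
            "center": self.perf_C,
            "right": self.perf_R,
        }[which]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bucket_start_min": self.starts_min,
                "perf_L": self.perf_L,
                "perf_C": self.perf_C,
                "perf_R": self.perf_R,
                "perf_T": self.perf_T,
            }
        )
        if self.sd is not None:
            for key in ("left", "center", "right", "total"):
                df[f"sd_{key}"] = self.sd[key]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.3f")


def bucket_counts(log: TrialLog, width: float = 2.0) -> list[BucketCounts]:
    """Aggregate a trial log's outcomes into half-open buckets of ``width``
    minutes.  ``width`` must divide the trial duration; an outcome stamped
    exactly at the trial end (a signal force-resolved at the final instant)
    lands in the last bucket."""
    duration = log.config.schedule.duration
    n_buckets = duration / width
    if abs(n_buckets - round(n_buckets)) > 1e-9:
        raise ValueError(f"bucket width {width} min does not divide duration {duration} min")
    n_buckets = int(round(n_buckets))
    width_s = width * 60.0
    tallies = np.zeros((n_buckets, 3, 3), dtype=np.int64)
    for rec in log.outcomes:
        b = int(rec.timestamp // width_s)
        if b == n_buckets and rec.timestamp == duration * 60.0:
            b -= 1
        tallies[b, _SCREENS.index(rec.screen), _OUTCOMES.index(rec.outcome)] += 1
    return [
        BucketCounts(
            index=b,
            start_min=b * width,
            width_min=width,
            counts={s: tuple(int(x) for x in tallies[b, i]) for i, s in enumerate(_SCREENS)},
        )
        for b in range(n_buckets)
    ]


def detection_percentages(counts: Sequence[BucketCounts]) -> VigilanceCurve:
    """Turn bucketed counts into a vigilance performance curve.

    Per screen: ``100 * H / (H + M + F)``; total: the pooled single ratio
    over all nine counts.  Zero-denominator buckets are NaN.
    """
    if not counts:
        raise ValueError("no buckets")
    width = counts[0].width_min
    starts = np.array([c.start_min for c in counts])
    out = {}
    for i, s in enumerate(_SCREENS):
        h = np.array([c.counts[s][0] for c in counts], dtype=float)
        tot = np.array([sum(c.counts[s]) for c in counts], dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[s] = np.where(tot > 0, 100.0 * h / tot, np.nan)
    hp = np.array([c.pooled()[0] for c in counts], dtype=float)
    totp = np.array([sum(c.pooled()) for c in counts], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        perf_T = np.where(totp > 0, 100.0 * hp / totp, np.nan)
    return VigilanceCurve(
        width_min=width,
        starts_min=starts,
        perf_L=out["left"],
        perf_C=out["center"],
        perf_R=out["right"],
        perf_T=perf_T,
    )


def score_log(log: TrialLog, width: float = 2.0) -> VigilanceCurve:
    """Convenience: bucket a log and compute its performance curve."""
    return detection_percentages(bucket_counts(log, width))


def minute_detection_series(log: TrialLog) -> np.ndarray:
    """Pooled per-minute detection percentages of a 60-min trial
    (60 values, NaN where a minute has no outcomes).  Feeds the
    split-half reliability coefficient."""
    if abs(log.config.schedule.duration - 60.0) > 1e-9:
        raise ValueError("minute-level series is defined for 60-min trials")
    return score_log(log, width=1.0).perf_T


def ensemble_average(curves: Sequence[VigilanceCurve]) -> VigilanceCurve:
    """Per-bucket arithmetic mean over curves (ignoring missing values),
    with per-bucket standard deviations for error bars.

    All curves must share the same bucket structure.
    """
    if not curves:
        raise ValueError("no curves to average")
    ref = curves[0]
    for c in curves[1:]:
        if c.width_min != ref.width_min or not np.array_equal(c.starts_min, ref.starts_min):
            raise ValueError("curves have mismatched bucket structures")
    means: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    for key in ("left", "center", "right", "total"):
        stack = np.vstack([c.series(key) for c in curves])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN buckets stay NaN
            means[key] = np.nanmean(stack, axis=0)
            sds[key] = np.nanstd(stack, axis=0, ddof=0)
    return VigilanceCurve(
        width_min=ref.width_min,
        starts_min=ref.starts_min.copy(),
        perf_L=means["left"],
        perf_C=means["center"],
        perf_R=means["right"],
        perf_T=means["total"],
        sd=sds,
        n_curves=len(curves),
    )
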