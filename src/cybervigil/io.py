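"""Serialization: JSON Lines trial logs, CSV outcome tables, run configs.

A trial log file is one JSON object per line.  The first line is a header
carrying the schema version, the full trial config, the seeds and a
config hash; every following line is an event with ``record_type`` in
{stimulus, action, outcome}.  Timestamps must be non-decreasing within
each stream; the reader validates this and reports the offending line.

Run configuration files are TOML (or a JSON mirror) with sections
``trial``, ``operator`` (optionally ``operator.static`` /
``operator.dynamic``), and ``cohort``.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Any, Optional

from .engine import ActionEvent, OutcomeRecord, StimulusEvent, TrialConfig, TrialLog
from .operator_sim import OperatorParams
from .schedule import WorkloadSchedule

__all__ = [
    "SCHEMA_VERSION",
    "TrialLogParseError",
    "write_trial_log",
    "read_trial_log",
    "outcomes_to_csv",
    "config_to_dict",
    "config_from_dict",
    "config_hash",
    "load_run_config",
]

SCHEMA_VERSION = 1


class TrialLogParseError(ValueError):
    """Malformed trial-log file; message names the offending line number."""


def config_to_dict(config: TrialConfig) -> dict:
    sched = config.schedule
    return {
        "schedule": {
            "mode": sched.mode.value,
            "duration": sched.duration,
            "salience_bounds": list(sched.salience_bounds),
            "event_rate_bounds": list(sched.event_rate_bounds),
            "load_bounds": list(sched.load_bounds),
        },
        "seed": config.seed,
        "icon_count": config.icon_count,
        "alert_types": [[name, prio] for name, prio in config.alert_types],
        "admin_thresholds": {str(k): v for k, v in config.admin_thresholds.items()},
        "ip_pool_size": config.ip_pool_size,
        "flicker_timeout": config.flicker_timeout,
        "breach_timeout": config.breach_timeout,
        "center_service_floor": config.center_service_floor,
        "strict_miss_rule": config.strict_miss_rule,
        "increment_by_rating": config.increment_by_rating,
    }


def config_from_dict(d: dict) -> TrialConfig:
    sd = d["schedule"]
    schedule = WorkloadSchedule(
        mode=sd["mode"],
        duration=sd["duration"],
        salience_bounds=tuple(sd["salience_bounds"]),
        event_rate_bounds=tuple(sd["event_rate_bounds"]),
        load_bounds=tuple(sd["load_bounds"]),
    )
    return TrialConfig(
        schedule=schedule,
        seed=d["seed"],
        icon_count=d["icon_count"],
        alert_types=tuple((n, p) for n, p in d["alert_types"]),
        admin_thresholds={int(k): v for k, v in d["admin_thresholds"].items()},
        ip_pool_size=d["ip_pool_size"],
        flicker_timeout=d["flicker_timeout"],
        breach_timeout=d["breach_timeout"],
        center_service_floor=d["center_service_floor"],
        strict_miss_rule=d["strict_miss_rule"],
        increment_by_rating=d["increment_by_rating"],
    )


def config_hash(config: TrialConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of the config."""
    payload = json.dumps(config_to_dict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


def write_trial_log(log: TrialLog, path) -> None:
    """Write a trial log as JSON Lines (lossless round-trip)."""
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "record_type": "header",
            "schema_version": SCHEMA_VERSION,
            "config": config_to_dict(log.config),
            "config_hash": config_hash(log.config),
            "operator_seed": log.operator_seed,
            "meta": log.meta,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for ev in log.stimuli:
            fh.write(
                json.dumps(
                    {
                        "record_type": "stimulus",
                        "timestamp": ev.timestamp,
                        "screen": ev.screen,
                        "kind": ev.kind,
                        "payload": ev.payload,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
        for ev in log.actions:
            fh.write(
                json.dumps(
                    {
                        "record_type": "action",
                        "timestamp": ev.timestamp,
                        "action": ev.action,
                        "score": ev.score,
                        "ip": ev.ip,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
        for rec in log.outcomes:
            fh.write(
                json.dumps(
                    {
                        "record_type": "outcome",
                        "timestamp": rec.timestamp,
                        "screen": rec.screen,
                        "outcome": rec.outcome,
                        "signal_id": rec.signal_id,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_trial_log(path) -> TrialLog:
    """Read a JSON Lines trial log, validating schema and timestamp order."""
    path = Path(path)
    stimuli: list[StimulusEvent] = []
    actions: list[ActionEvent] = []
    outcomes: list[OutcomeRecord] = []
    header: Optional[dict] = None
    last_ts = {"stimulus": -1.0, "action": -1.0, "outcome": -1.0}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TrialLogParseError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            rtype = rec.get("record_type")
            if lineno == 1:
                if rtype != "header":
                    raise TrialLogParseError(f"{path}: missing header on line 1")
                if rec.get("schema_version") != SCHEMA_VERSION:
                    raise TrialLogParseError(
                        f"{path}: line 1: unsupported schema version {rec.get('schema_version')!r}"
                    )
                header = rec
                continue
            if rtype not in last_ts:
                raise TrialLogParseError(f"{path}: line {lineno}: unknown record_type {rtype!r}")
            ts = rec.get("timestamp")
            if not isinstance(ts, (int, float)):
                raise TrialLogParseError(f"{path}: line {lineno}: missing timestamp")
            if ts < last_ts[rtype]:
                raise TrialLogParseError(
                    f"{path}: line {lineno}: non-monotone timestamp in {rtype} stream"
                )
            last_ts[rtype] = ts
            if rtype == "stimulus":
                stimuli.append(StimulusEvent(ts, rec["screen"], rec["kind"], rec["payload"]))
            elif rtype == "action":
                actions.append(ActionEvent(ts, rec["action"], score=rec["score"], ip=rec["ip"]))
            else:
                outcomes.append(OutcomeRecord(ts, rec["screen"], rec["outcome"], rec["signal_id"]))
    if header is None:
        raise TrialLogParseError(f"{path}: missing header (empty file)")
    return TrialLog(
        config=config_from_dict(header["config"]),
        operator_seed=header.get("operator_seed"),
        stimuli=stimuli,
        actions=actions,
        outcomes=outcomes,
        meta=header.get("meta", {}),
    )


def outcomes_to_csv(log: TrialLog, path) -> None:
    """Export the outcome stream as CSV (timestamp_s, screen, outcome, signal_id)."""
    with Path(path).open("w") as fh:
        fh.write("timestamp_s,screen,outcome,signal_id\n")
        for rec in log.outcomes:
            sig = rec.signal_id if rec.signal_id is not None else ""
            fh.write(f"{rec.timestamp},{rec.screen},{rec.outcome},{sig}\n")


# ---------------------------------------------------------------------------
# Run configuration (TOML or JSON)
# ---------------------------------------------------------------------------

_OPERATOR_FIELDS = {
    "base_detect",
    "salience_coeff",
    "load_coeff",
    "rate_coeff",
    "learn_coeff",
    "fatigue_coeff",
    "false_alarm_rate",
    "latency",
    "center_service_time",
}

_TRIAL_FIELDS = {
    "icon_count",
    "ip_pool_size",
    "flicker_timeout",
    "breach_timeout",
    "center_service_floor",
    "strict_miss_rule",
    "increment_by_rating",
}


def _operator_from_section(section: dict) -> OperatorParams:
    kwargs: dict[str, Any] = {}
    for key, value in section.items():
        if key not in _OPERATOR_FIELDS:
            raise ValueError(f"unknown operator parameter {key!r}")
        kwargs[key] = tuple(value) if isinstance(value, list) else value
    return OperatorParams(**kwargs)


def load_run_config(path) -> dict:
    """Load a run config file (TOML, or JSON if the suffix is .json).

    Returns a dict with keys ``n``, ``base_seed``, ``duration``,
    ``params_static``, ``params_dynamic``, and ``config_kwargs`` — the
    inputs of :func:`~cybervigil.operator_sim.simulate_cohort`.
    """
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        with path.open("rb") as fh:
            raw = tomllib.load(fh)
    trial = raw.get("trial", {})
    cohort = raw.get("cohort", {})
    op = dict(raw.get("operator", {}))
    op_static = op.pop("static", {})
    op_dynamic = op.pop("dynamic", {})
    base_op = _operator_from_section(op) if op else OperatorParams.defaults()
    params_static = _operator_from_section({**op, **op_static}) if op_static else base_op
    params_dynamic = _operator_from_section({**op, **op_dynamic}) if op_dynamic else base_op
    config_kwargs = {}
    for key, value in trial.items():
        if key == "duration":
            continue
        if key not in _TRIAL_FIELDS:
            raise ValueError(f"unknown trial parameter {key!r}")
        config_kwargs[key] = value
    return {
        "n": int(cohort.get("n", 25)),
        "base_seed": int(cohort.get("base_seed", 0)),
        "duration": float(trial.get("duration", 60.0)),
        "params_static": params_static,
        "params_dynamic": params_dynamic,
        "config_kwargs": config_kwargs,
    }
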