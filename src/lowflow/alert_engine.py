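"""Per-minute low-flow advisory engine.

Seven rules are evaluated once per minute against the live flowsheet; an
advisory (modelled on an EHR Best Practice Advisory) fires only when all
hold simultaneously:

1. a volatile agent (sevoflurane, isoflurane or desflurane) is the set
   agent — N2O alone never fires, N2O alongside a volatile agent can;
2. that agent is in use (dial concentration > 0);
3. total fresh gas flow has exceeded the threshold (strictly) for at least
   the last ``lookback`` consecutive evaluated minutes;
4. the procedure-start event has occurred (excludes induction);
5. the procedure-stop event has not occurred (excludes emergence);
6. the patient is older than the age cutoff;
7. the advisory is neither snoozed nor disabled.

Consecutive firing minutes are grouped into *episodes*; the episode count
is the headline alert-burden metric, with raw per-minute firings retained
alongside. A gap in the minute grid resets the consecutive-minutes counter
(unknown flow is not evidence of high flow). The alert *mode* (passive /
noninterruptive / interruptive) changes event metadata only, never the
firing logic: passive events are logged but flagged non-displayed, and
interruptive events additionally require acknowledgment.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .agents import AgentKind, VOLATILE_AGENTS
from .flowsheet import CaseRecord, DeviceMinute

__all__ = [
    "AlertMode",
    "AlertConfig",
    "AlertEngineState",
    "AlertEvent",
    "EngineContractError",
    "evaluate_minute",
    "snooze",
    "disable",
    "enable",
    "run_engine",
    "count_episodes",
    "write_alert_log",
]


class EngineContractError(RuntimeError):
    """Minutes were fed to the engine out of order."""


class AlertMode(str, Enum):
    PASSIVE = "passive"
    NONINTERRUPTIVE = "noninterruptive"
    INTERRUPTIVE = "interruptive"


RULE_IDS = ("rule1", "rule2", "rule3", "rule4", "rule5", "rule6", "rule7")


@dataclass(frozen=True)
class AlertConfig:
    """The advisory policy.

    Attributes
    ----------
    threshold:
        FGF threshold in L/min; the flow must strictly exceed it (default
        0.7).
    lookback:
        Consecutive above-threshold minutes required before firing
        (default 5) — brief reactive flow increases should not alert.
    snooze_duration:
        Minutes an operator snooze suppresses firing (default 10).
    age_cutoff:
        Years; only patients strictly older can trigger the advisory
        (default 1).
    mode:
        Display semantics attached to emitted events.
    snooze_resets_counter:
        If True, a snooze also zeroes the consecutive-minutes counter;
        by default the condition keeps being tracked during the snooze.
    """

    threshold: float = 0.7
    lookback: int = 5
    snooze_duration: int = 10
    age_cutoff: float = 1.0
    mode: AlertMode = AlertMode.NONINTERRUPTIVE
    evaluation_interval: int = 1
    snooze_resets_counter: bool = False

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.lookback < 1:
            raise ValueError("lookback must be >= 1")
        if self.snooze_duration < 0:
            raise ValueError("snooze_duration must be >= 0")
        if self.evaluation_interval != 1:
            raise ValueError("evaluation_interval is fixed at 1 minute")


@dataclass(slots=True)
class AlertEngineState:
    """Mutable evaluation state carried minute to minute."""

    consecutive_above: int = 0
    snoozed_until: Optional[int] = None
    disabled: bool = False
    last_fired: Optional[int] = None
    last_t: Optional[int] = None
    last_episode_id: int = 0
    transitions: list = field(default_factory=list)

    def copy(self) -> "AlertEngineState":
        return AlertEngineState(
            consecutive_above=self.consecutive_above,
            snoozed_until=self.snoozed_until,
            disabled=self.disabled,
            last_fired=self.last_fired,
            last_t=self.last_t,
            last_episode_id=self.last_episode_id,
            transitions=list(self.transitions),
        )


@dataclass(frozen=True, slots=True)
class AlertEvent:
    """One emitted advisory (one firing minute)."""

    case_id: str
    t: int
    mode: AlertMode
    rule_trace: dict
    episode_id: int
    displayed: bool
    requires_acknowledgment: bool


def set_agent_of(minute: DeviceMinute) -> Optional[AgentKind]:
    """The volatile agent with the highest dial setting this minute.

    Ties break by the fixed agent order (sevo, iso, des); None when no
    volatile agent appears on the dial row at all.
    """
    best = None
    best_val = -1.0
    for a in VOLATILE_AGENTS:
        v = minute.dial_pct.get(a)
        if v is not None and v > best_val:
            best, best_val = a, v
    return best


def evaluate_minute(
    state: AlertEngineState,
    minute: DeviceMinute,
    case: CaseRecord,
    config: AlertConfig,
) -> tuple[AlertEngineState, Optional[AlertEvent]]:
    """Advance the engine by one minute; emit an event iff all rules hold.

    Minutes must be processed in strictly increasing ``t``. A missing grid
    minute (jump larger than the evaluation interval) resets the
    consecutive-above counter before this minute is counted.
    """
    if state.last_t is not None and minute.t <= state.last_t:
        raise EngineContractError(
            f"minutes must be evaluated in increasing order "
            f"(t={minute.t} after t={state.last_t})"
        )
    new = state.copy()
    if state.last_t is not None and minute.t - state.last_t > config.evaluation_interval:
        new.consecutive_above = 0  # grid gap: unknown flow breaks the run
    new.last_t = minute.t

    agent = set_agent_of(minute)
    r1 = agent is not None
    r2 = r1 and minute.dial_pct.get(agent, 0.0) > 0.0
    above = minute.fgf_total > config.threshold
    if r1 and r2 and above:
        new.consecutive_above += 1
    else:
        new.consecutive_above = 0
    r3 = new.consecutive_above >= config.lookback
    r4 = case.procedure_start is not None and minute.t >= case.procedure_start
    r5 = case.procedure_stop is not None and minute.t < case.procedure_stop
    r6 = case.patient_age > config.age_cutoff
    not_snoozed = new.snoozed_until is None or minute.t >= new.snoozed_until
    r7 = not_snoozed and not new.disabled

    if not (r1 and r2 and r3 and r4 and r5 and r6 and r7):
        return new, None

    if new.last_fired is not None and minute.t - new.last_fired == 1:
        episode_id = new.last_episode_id  # uninterrupted run of firings
    else:
        episode_id = new.last_episode_id + 1
        new.last_episode_id = episode_id
    new.last_fired = minute.t
    event = AlertEvent(
        case_id=case.case_id,
        t=minute.t,
        mode=config.mode,
        rule_trace={
            "rule1": r1, "rule2": r2, "rule3": r3, "rule4": r4,
            "rule5": r5, "rule6": r6, "rule7": r7,
        },
        episode_id=episode_id,
        displayed=config.mode is not AlertMode.PASSIVE,
        requires_acknowledgment=config.mode is AlertMode.INTERRUPTIVE,
    )
    return new, event


def snooze(state: AlertEngineState, t: int, config: AlertConfig) -> AlertEngineState:
    """Snooze the advisory at minute ``t`` for ``config.snooze_duration``.

    Condition tracking continues during the snooze (unless the config opts
    into counter reset), so the first eligible firing minute is
    ``t + snooze_duration`` when the rules still hold there.
    """
    new = state.copy()
    new.snoozed_until = t + config.snooze_duration
    if config.snooze_resets_counter:
        new.consecutive_above = 0
    new.transitions.append((t, "snooze"))
    return new


def disable(state: AlertEngineState, t: Optional[int] = None) -> AlertEngineState:
    new = state.copy()
    new.disabled = True
    new.transitions.append((t, "disable"))
    return new


def enable(state: AlertEngineState, t: Optional[int] = None) -> AlertEngineState:
    new = state.copy()
    new.disabled = False
    new.transitions.append((t, "enable"))
    return new


def _sorted_actions(actions) -> list[tuple[int, str]]:
    if actions is None:
        return []
    if isinstance(actions, dict):
        flat = []
        for t, acts in actions.items():
            if isinstance(acts, str):
                acts = [acts]
            flat.extend((t, a) for a in acts)
    else:
        flat = [(t, a) for t, a in actions]
    for _, a in flat:
        if a not in ("snooze", "disable", "enable", "acknowledge"):
            raise ValueError(f"unknown scripted action {a!r}")
    return sorted(flat, key=lambda x: x[0])


def run_engine(
    case: CaseRecord,
    config: AlertConfig,
    actions: Optional[Iterable[tuple[int, str]]] = None,
) -> list[AlertEvent]:
    """Fold :func:`evaluate_minute` over a whole case, deterministically.

    ``actions`` scripts operator behaviour as ``(t, action)`` pairs with
    action in {snooze, disable, enable, acknowledge}: an action at time
    ``a`` takes effect *after* the evaluation of minute ``a`` (the operator
    reacts to what that minute displayed), and before any later minute.
    ``acknowledge`` is recorded but changes no firing logic.
    """
    queue = _sorted_actions(actions)
    qi = 0
    state = AlertEngineState()
    events: list[AlertEvent] = []

    def apply(t: int, action: str) -> None:
        nonlocal state
        if action == "snooze":
            state = snooze(state, t, config)
        elif action == "disable":
            state = disable(state, t)
        elif action == "enable":
            state = enable(state, t)
        else:  # acknowledge
            state.transitions.append((t, "acknowledge"))

    for minute in case.minutes:
        while qi < len(queue) and queue[qi][0] < minute.t:
            apply(*queue[qi])
            qi += 1
        state, event = evaluate_minute(state, minute, case, config)
        if event is not None:
            events.append(event)
        while qi < len(queue) and queue[qi][0] == minute.t:
            apply(*queue[qi])
            qi += 1
    while qi < len(queue):
        apply(*queue[qi])
        qi += 1
    return events


def count_episodes(events: Sequence[AlertEvent]) -> int:
    """Number of distinct firing episodes in an event log."""
    return len({(e.case_id, e.episode_id) for e in events})


def write_alert_log(events: Sequence[AlertEvent], path, format: str = "csv") -> None:
    """Persist an alert log (case_id, t, episode_id, mode, flags, trace)."""
    path = os.fspath(path)
    cols = [
        "case_id", "t_min", "episode_id", "mode", "displayed",
        "requires_acknowledgment", "rule_trace",
    ]
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for e in events:
                w.writerow(
                    [
                        e.case_id, e.t, e.episode_id, e.mode.value,
                        e.displayed, e.requires_acknowledgment,
                        json.dumps(e.rule_trace, separators=(",", ":")),
                    ]
                )
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for e in events:
                fh.write(
                    json.dumps(
                        {
                            "case_id": e.case_id,
                            "t": e.t,
                            "episode_id": e.episode_id,
                            "mode": e.mode.value,
                            "displayed": e.displayed,
                            "requires_acknowledgment": e.requires_acknowledgment,
                            "rule_trace": e.rule_trace,
                        },
                        separators=(",", ":"),
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}")
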