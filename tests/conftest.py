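"""Shared builders and the independent brute-force advisory oracle.

The oracle deliberately re-examines the full trailing window of the raw
trace at every minute (O(n*w)) and replays the scripted action history
from scratch, so it shares no state-machine logic with the engine it
checks.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pytest

from lowflow import (
    AgentKind,
    AlertConfig,
    CaseRecord,
    DeviceMinute,
    VOLATILE_AGENTS,
)

SEVO = AgentKind.SEVOFLURANE
ISO = AgentKind.ISOFLURANE
DES = AgentKind.DESFLURANE


def constant_case(
    n_minutes: int,
    fgf: float = 1.0,
    dial: float = 2.0,
    agent: AgentKind = SEVO,
    procedure_start: int = 0,
    procedure_stop: Optional[int] = None,
    age: float = 30.0,
    et: float = 1.0,
    case_id: str = "case-1",
) -> CaseRecord:
    """A gridded case with constant dial/flow/end-tidal settings."""
    stop = n_minutes if procedure_stop is None else procedure_stop
    minutes = [
        DeviceMinute(t=t, dial_pct={agent: dial}, fgf_total=fgf, et_pct={agent: et})
        for t in range(n_minutes)
    ]
    return CaseRecord(
        case_id=case_id,
        patient_age=age,
        procedure_start=procedure_start,
        procedure_stop=stop,
        minutes=minutes,
    )


def trace_case(
    fgf_by_minute: Sequence[float],
    dial: float = 2.0,
    agent: AgentKind = SEVO,
    procedure_start: int = 0,
    procedure_stop: Optional[int] = None,
    age: float = 30.0,
) -> CaseRecord:
    case = constant_case(
        len(fgf_by_minute),
        dial=dial,
        agent=agent,
        procedure_start=procedure_start,
        procedure_stop=procedure_stop,
        age=age,
    )
    for m, f in zip(case.minutes, fgf_by_minute):
        m.fgf_total = f
    return case


def brute_force_alerts(
    case: CaseRecord,
    config: AlertConfig,
    actions: Iterable[tuple[int, str]] = (),
) -> tuple[list[int], int]:
    """Reference evaluation: (firing minutes, episode count).

    Every minute is judged by directly re-scanning the trailing
    ``lookback`` grid minutes of the trace and re-deriving the
    snooze/disable status from the complete action history (actions take
    effect after their own minute).
    """
    actions = list(actions)
    minutes = {m.t: m for m in case.minutes}
    snooze_times = sorted(t for t, a in actions if a == "snooze")
    toggles = sorted((t, a) for t, a in actions if a in ("disable", "enable"))

    def window_satisfied(t: int) -> bool:
        for u in range(t - config.lookback + 1, t + 1):
            m = minutes.get(u)
            if m is None:
                return False
            dials = [m.dial_pct[a] for a in VOLATILE_AGENTS if a in m.dial_pct]
            if not dials or max(dials) <= 0.0:
                return False
            if not m.fgf_total > config.threshold:
                return False
        return True

    fired: list[int] = []
    for t in sorted(minutes):
        if not window_satisfied(t):
            continue
        if case.procedure_start is None or t < case.procedure_start:
            continue
        if case.procedure_stop is None or t >= case.procedure_stop:
            continue
        if case.patient_age <= config.age_cutoff:
            continue
        disabled = False
        for at, act in toggles:
            if at < t:
                disabled = act == "disable"
        if disabled:
            continue
        last_snooze = max((s for s in snooze_times if s < t), default=None)
        if last_snooze is not None and t < last_snooze + config.snooze_duration:
            continue
        fired.append(t)

    episodes = sum(1 for i, t in enumerate(fired) if i == 0 or t != fired[i - 1] + 1)
    return fired, episodes


def random_trace(rng, with_actions: bool = True):
    """A randomized case (gaps, agent churn, N2O-only rows) plus actions."""
    n = int(rng.integers(60, 301))
    present = rng.random(n) > 0.05  # ~5% missing grid minutes
    fgf_choices = [0.3, 0.6, 0.69, 0.7, 0.71, 0.9, 1.5, 3.0, 6.0]
    start = int(rng.integers(0, 20))
    stop = int(rng.integers(max(start + 1, n - 30), n + 5))
    age = float(rng.choice([0.5, 0.9, 2.0, 30.0, 80.0], p=[0.05, 0.05, 0.1, 0.6, 0.2]))
    minutes = []
    for t in range(n):
        if not present[t]:
            continue
        roll = rng.random()
        if roll < 0.70:
            dial = {SEVO: float(rng.choice([0.0, 1.0, 2.0]))}
        elif roll < 0.80:
            dial = {ISO: 1.2, SEVO: 1.2}  # tie between volatile agents
        elif roll < 0.90:
            dial = {DES: float(rng.choice([0.0, 6.0]))}
        elif roll < 0.95:
            dial = {}  # nothing set
        else:
            dial = {}  # N2O-only minute: carrier flow recorded, no volatile
        fgf = float(rng.choice(fgf_choices))
        minutes.append(DeviceMinute(t=t, dial_pct=dial, fgf_total=fgf))
    case = CaseRecord(
        case_id="rand",
        patient_age=age,
        procedure_start=start,
        procedure_stop=stop,
        minutes=minutes,
    )
    actions: list[tuple[int, str]] = []
    if with_actions:
        times = rng.choice(n, size=min(n, 8), replace=False)
        kinds = rng.choice(
            ["snooze", "snooze", "disable", "enable"], size=len(times)
        )
        actions = sorted(zip((int(t) for t in times), (str(k) for k in kinds)))
    return case, actions


@pytest.fixture(scope="session")
def default_config() -> AlertConfig:
    return AlertConfig()
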