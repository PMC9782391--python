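"""Anesthetic-consumption reporting: phases, volumes, MAC-hours, mL/MAC-hr.

The efficiency ("gas mileage") metric is mL of liquid volatile agent
consumed per MAC-hour delivered, computed over the *maintenance* phase:

* induction window: [first minute with dial > 0, procedure_start)
* maintenance window: [procedure_start, min(procedure_stop,
  anesthetic_gas_stop)) where anesthetic_gas_stop is the minute of the
  last nonzero dial setting
* set_agent_volume: cumulative liquid consumption difference across the
  maintenance window when the ventilator reports a running total,
  otherwise the per-minute vaporizer-output calculation
* age_adjusted_MAC: mean of recorded end-tidal concentrations over the
  window divided by the patient's age-adjusted MAC (ratio of the mean,
  not mean of ratios — they coincide because the denominator is constant
  within a case)
* MAC_hours = age_adjusted_MAC x window duration in hours
* ml_per_MAC_hr = set_agent_volume / MAC_hours

All windows are half-open ``[start, stop)`` in integer minutes — a
minute's record describes the minute beginning at its timestamp — which
prevents double counting at phase boundaries and makes per-professional
volumes over a partition of maintenance sum exactly to the case volume.

Cohort reporting applies the stated exclusion filters (excluded
locations; more than one volatile agent with a nonzero dial entry; fewer
than 15 minutes of recorded agent delivery) before aggregation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .agents import AgentKind, AgentTable, VOLATILE_AGENTS, default_table
from .alert_engine import AlertEvent
from .flowsheet import CaseRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseWindows",
    "CaseMetrics",
    "ExclusionReport",
    "VolumeResult",
    "MetricsError",
    "DEFAULT_EXCLUDED_LOCATIONS",
    "compute_phases",
    "agent_volume",
    "mac_hours",
    "ml_per_mac_hour",
    "per_professional_metrics",
    "apply_exclusions",
    "aggregate_cohort",
]

DEFAULT_EXCLUDED_LOCATIONS = frozenset(
    {"pediatric induction", "non-OR anesthesia", "labor_and_delivery"}
)

#: Cases with fewer recorded delivery minutes than this are excluded
#: ("short delivery"); exactly this many minutes is included (strict <).
MIN_DELIVERY_MINUTES = 15

_CUMULATIVE_DISCREPANCY_WARN = 0.10  # relative gap between volume paths


class MetricsError(ValueError):
    """A metrics precondition failed (missing events, no end-tidal data...)."""


@dataclass(frozen=True)
class PhaseWindows:
    """Half-open phase intervals of a case, in minutes."""

    induction: Optional[tuple[int, int]]
    maintenance: Optional[tuple[int, int]]
    anesthetic_gas_stop: Optional[int]

    @property
    def empty(self) -> bool:
        return self.maintenance is None or self.maintenance[0] >= self.maintenance[1]


@dataclass(frozen=True)
class VolumeResult:
    """Liquid volume over a window plus which data path produced it."""

    ml: float
    source: str  # "cumulative" | "calculated"

    def __float__(self) -> float:
        return self.ml


@dataclass(frozen=True)
class CaseMetrics:
    case_id: str
    agent: Optional[AgentKind]
    scope: str  # "case" or a professional_id
    set_agent_volume_ml: float
    age_adjusted_mac: float
    mac_hours: float
    ml_per_mac_hour: float  # NaN when mac_hours == 0 (flagged)
    case_duration_hr: float
    volume_source: str
    et_coverage: float  # fraction of window minutes with an et reading
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ExclusionReport:
    included: list[str]
    excluded: list[tuple[str, tuple[str, ...]]]  # (case_id, reasons)

    def reasons_for(self, case_id: str) -> tuple[str, ...]:
        for cid, reasons in self.excluded:
            if cid == case_id:
                return reasons
        return ()


# ---------------------------------------------------------------------------
# phase segmentation


def _volatile_dial_positive(minute) -> bool:
    return any(minute.dial_pct.get(a, 0.0) > 0.0 for a in VOLATILE_AGENTS)


def compute_phases(case: CaseRecord) -> PhaseWindows:
    """Segment a case into induction and maintenance windows.

    Requires both procedure events. A case whose dial is never above zero
    yields empty windows (flagged for downstream exclusion) rather than an
    error.
    """
    if case.procedure_start is None or case.procedure_stop is None:
        raise MetricsError(
            f"case {case.case_id}: procedure start/stop events are required"
        )
    dial_on = [m.t for m in case.minutes if _volatile_dial_positive(m)]
    if not dial_on:
        return PhaseWindows(induction=None, maintenance=None, anesthetic_gas_stop=None)
    first_dial, gas_stop = dial_on[0], dial_on[-1]
    maintenance_end = min(case.procedure_stop, gas_stop)
    return PhaseWindows(
        induction=(min(first_dial, case.procedure_start), case.procedure_start),
        maintenance=(case.procedure_start, maintenance_end),
        anesthetic_gas_stop=gas_stop,
    )


# ---------------------------------------------------------------------------
# volume and MAC-hours over a window


def _cumulative_at(case: CaseRecord, t_exclusive: int, agent: AgentKind) -> Optional[float]:
    """Ventilator running total at the end of minute ``t_exclusive - 1``.

    The running total recorded at minute t includes minute t's consumption,
    so the total 'at the end of' a half-open window [a, b) is the last
    reading strictly before b. None when the agent has no readings before
    that point (treated as 0 by the caller only if the agent reports
    cumulative data at all).
    """
    last = None
    for m in case.minutes:
        if m.t >= t_exclusive:
            break
        if m.cumulative_liquid_ml and agent in m.cumulative_liquid_ml:
            last = m.cumulative_liquid_ml[agent]
    return last


def _has_cumulative(case: CaseRecord, agent: AgentKind) -> bool:
    return any(
        m.cumulative_liquid_ml and agent in m.cumulative_liquid_ml for m in case.minutes
    )


def _calculated_volume(
    case: CaseRecord, window: tuple[int, int], agent: AgentKind, table: AgentTable
) -> float:
    start, stop = window
    total = 0.0
    for m in case.minutes:
        if start <= m.t < stop:
            dial = m.dial_pct.get(agent, 0.0)
            if dial > 0.0:
                total += table.liquid_ml_consumed(agent, m.fgf_total, dial, 1.0)
    return total


def agent_volume(
    case: CaseRecord,
    window: tuple[int, int],
    agent: AgentKind,
    table: Optional[AgentTable] = None,
    source: str = "auto",
) -> VolumeResult:
    """Liquid agent consumed (mL) over a half-open minute window.

    Ventilator cumulative readings take precedence when present
    (difference of running totals at the window boundaries); otherwise the
    volume is reconstructed minute by minute from dial, FGF and the
    agent's vapor yield. ``source`` forces a path ("cumulative" /
    "calculated"). When both paths are available and disagree by more
    than 10%, the discrepancy is logged.
    """
    table = table or default_table()
    start, stop = window
    if stop <= start:
        return VolumeResult(0.0, "calculated" if source != "cumulative" else "cumulative")

    use_cum = source == "cumulative" or (source == "auto" and _has_cumulative(case, agent))
    calc = None
    if source in ("auto", "calculated") and not (source == "auto" and use_cum):
        calc = _calculated_volume(case, window, agent, table)
    if not use_cum:
        return VolumeResult(calc, "calculated")

    end_val = _cumulative_at(case, stop, agent) or 0.0
    start_val = _cumulative_at(case, start, agent) or 0.0
    vol = end_val - start_val
    if vol < -1e-9:
        raise MetricsError(
            f"case {case.case_id}: cumulative volume for {agent.value} decreases "
            f"across window [{start}, {stop})"
        )
    vol = max(vol, 0.0)
    if source == "auto":
        check = _calculated_volume(case, window, agent, table)
        if check > 0 and abs(vol - check) / check > _CUMULATIVE_DISCREPANCY_WARN:
            logger.warning(
                "case %s: cumulative (%.2f mL) and calculated (%.2f mL) volumes "
                "disagree by >10%% over [%d, %d)",
                case.case_id, vol, check, start, stop,
            )
    return VolumeResult(vol, "cumulative")


def mac_hours(
    case: CaseRecord,
    window: tuple[int, int],
    agent: AgentKind,
    table: Optional[AgentTable] = None,
) -> float:
    """MAC-hours of exposure over a window.

    mean(end-tidal %) / age-adjusted MAC% x window hours. Raises when the
    window holds no end-tidal readings for the agent — 'no data' is
    distinct from a measured zero.
    """
    table = table or default_table()
    start, stop = window
    if stop <= start:
        raise MetricsError(f"case {case.case_id}: empty window [{start}, {stop})")
    readings = [
        m.et_pct[agent] for m in case.minutes if start <= m.t < stop and agent in m.et_pct
    ]
    if not readings:
        raise MetricsError(
            f"case {case.case_id}: no end-tidal {agent.value} readings in "
            f"[{start}, {stop})"
        )
    mac_pct = table.age_adjusted_mac_pct(agent, case.patient_age)
    mean_et = sum(readings) / len(readings)
    return mean_et / mac_pct * (stop - start) / 60.0


def _et_coverage(case: CaseRecord, window: tuple[int, int], agent: AgentKind) -> float:
    start, stop = window
    if stop <= start:
        return 0.0
    n = sum(1 for m in case.minutes if start <= m.t < stop and agent in m.et_pct)
    return n / (stop - start)


def _maintenance_agents(case: CaseRecord, window: tuple[int, int]) -> list[AgentKind]:
    start, stop = window
    present = []
    for a in VOLATILE_AGENTS:
        if any(
            start <= m.t < stop and m.dial_pct.get(a, 0.0) > 0.0 for m in case.minutes
        ):
            present.append(a)
    return present


def _metrics_over_window(
    case: CaseRecord,
    window: tuple[int, int],
    agent: AgentKind,
    scope: str,
    table: AgentTable,
) -> CaseMetrics:
    flags: list[str] = []
    vol = agent_volume(case, window, agent, table)
    start, stop = window
    duration_hr = max(stop - start, 0) / 60.0
    if stop <= start:
        return CaseMetrics(
            case_id=case.case_id, agent=agent, scope=scope,
            set_agent_volume_ml=0.0, age_adjusted_mac=0.0, mac_hours=0.0,
            ml_per_mac_hour=float("nan"), case_duration_hr=0.0,
            volume_source=vol.source, et_coverage=0.0,
            flags=("empty_window", "undefined_metric"),
        )
    mh = mac_hours(case, window, agent, table)
    mac_pct = table.age_adjusted_mac_pct(agent, case.patient_age)
    coverage = _et_coverage(case, window, agent)
    if coverage < 0.8:
        flags.append("sparse_end_tidal")
    if mh > 0:
        ratio = vol.ml / mh
    else:
        ratio = float("nan")
        flags.append("undefined_metric")
        logger.warning(
            "case %s (%s): MAC-hours is zero; mL/MAC-hr undefined", case.case_id, scope
        )
    return CaseMetrics(
        case_id=case.case_id,
        agent=agent,
        scope=scope,
        set_agent_volume_ml=vol.ml,
        age_adjusted_mac=mh / duration_hr if duration_hr > 0 else 0.0,
        mac_hours=mh,
        ml_per_mac_hour=ratio,
        case_duration_hr=duration_hr,
        volume_source=vol.source,
        et_coverage=coverage,
        flags=tuple(flags),
    )


def ml_per_mac_hour(
    case: CaseRecord, table: Optional[AgentTable] = None
) -> CaseMetrics:
    """Case-level efficiency metrics over the maintenance window.

    Requires a single volatile agent during maintenance (multi-agent cases
    are excluded upstream).
    """
    table = table or default_table()
    phases = compute_phases(case)
    if phases.empty:
        raise MetricsError(f"case {case.case_id}: no volatile agent delivery recorded")
    agents_present = _maintenance_agents(case, phases.maintenance)
    if len(agents_present) != 1:
        raise MetricsError(
            f"case {case.case_id}: expected exactly one volatile agent in "
            f"maintenance, found {[a.value for a in agents_present]}"
        )
    return _metrics_over_window(case, phases.maintenance, agents_present[0], "case", table)


def per_professional_metrics(
    case: CaseRecord, table: Optional[AgentTable] = None
) -> list[CaseMetrics]:
    """Metrics per professional over (their interval n maintenance).

    The maintenance phase may be split among professionals, and intervals
    of different professionals may overlap (supervision), so per-role sums
    can each equal the case total.
    """
    table = table or default_table()
    phases = compute_phases(case)
    if phases.empty:
        raise MetricsError(f"case {case.case_id}: no volatile agent delivery recorded")
    agents_present = _maintenance_agents(case, phases.maintenance)
    if len(agents_present) != 1:
        raise MetricsError(f"case {case.case_id}: multiple agents in maintenance")
    agent = agents_present[0]
    m_start, m_stop = phases.maintenance
    out = []
    for p in case.professionals:
        lo, hi = max(p.t_in, m_start), min(p.t_out, m_stop)
        if hi <= lo:
            logger.warning(
                "case %s: professional %s interval [%d, %d) outside maintenance; clipped",
                case.case_id, p.professional_id, p.t_in, p.t_out,
            )
            continue
        out.append(
            _metrics_over_window(case, (lo, hi), agent, p.professional_id, table)
        )
    return out


# ---------------------------------------------------------------------------
# cohort filters and aggregation


def apply_exclusions(
    cohort: Iterable[CaseRecord],
    excluded_locations: frozenset[str] = DEFAULT_EXCLUDED_LOCATIONS,
    min_delivery_minutes: int = MIN_DELIVERY_MINUTES,
    multi_agent_scope: str = "case",
) -> ExclusionReport:
    """Partition a cohort into reportable and excluded cases.

    Exclusion reasons: ``location`` (machine-incompatible or atypical
    sites), ``multi_agent`` (a nonzero dial entry for more than one
    volatile agent — scanned over the whole recorded case by default, or
    only maintenance with ``multi_agent_scope='maintenance'``), and
    ``short_delivery`` (fewer than 15 recorded delivery minutes; exactly
    15 is included).
    """
    included, excluded = [], []
    for case in cohort:
        reasons = []
        if case.location in excluded_locations:
            reasons.append("location")

        if multi_agent_scope == "maintenance" and case.procedure_start is not None:
            phases = compute_phases(case)
            window = phases.maintenance or (0, 0)
            scan = [m for m in case.minutes if window[0] <= m.t < window[1]]
        else:
            scan = case.minutes
        agents_used = {
            a for m in scan for a in VOLATILE_AGENTS if m.dial_pct.get(a, 0.0) > 0.0
        }
        if len(agents_used) > 1:
            reasons.append("multi_agent")

        delivery_minutes = sum(1 for m in case.minutes if _volatile_dial_positive(m))
        if delivery_minutes < min_delivery_minutes:
            reasons.append("short_delivery")

        if reasons:
            excluded.append((case.case_id, tuple(reasons)))
        else:
            included.append(case.case_id)
    return ExclusionReport(included=included, excluded=excluded)


def _period_of(case: CaseRecord, period: str) -> str:
    if case.start_date is None:
        return "all"
    if period == "month":
        return f"{case.start_date.year:04d}-{case.start_date.month:02d}"
    raise ValueError(f"unknown period {period!r}")


def aggregate_cohort(
    cases: Sequence[CaseRecord],
    alerts: Sequence[AlertEvent],
    period: str = "month",
    table: Optional[AgentTable] = None,
    cost_per_ml: Optional[dict[AgentKind, float]] = None,
    exclusions: Optional[ExclusionReport] = None,
) -> pd.DataFrame:
    """Per-period, per-agent cohort summary.

    Columns: n_cases, mean mL/MAC-hr, total volume, alert episodes per
    case and per case-hour, and optional cost and CO2e. Excluded cases
    never contribute. Months inside the cohort's span with no included
    cases appear as explicit all-null rows rather than being dropped.
    """
    table = table or default_table()
    if exclusions is None:
        exclusions = apply_exclusions(cases)
    keep = set(exclusions.included)
    episodes_by_case: dict[str, set] = {}
    for e in alerts:
        episodes_by_case.setdefault(e.case_id, set()).add(e.episode_id)

    rows = []
    months_seen = []
    for case in cases:
        if case.case_id not in keep:
            continue
        try:
            cm = ml_per_mac_hour(case, table)
        except MetricsError as exc:
            logger.warning("aggregate: dropping case %s: %s", case.case_id, exc)
            continue
        per = _period_of(case, period)
        months_seen.append(per)
        rows.append(
            {
                "period": per,
                "agent": cm.agent.value,
                "case_id": cm.case_id,
                "ml_per_mac_hour": cm.ml_per_mac_hour,
                "volume_ml": cm.set_agent_volume_ml,
                "mac_hours": cm.mac_hours,
                "case_hours": cm.case_duration_hr,
                "episodes": len(episodes_by_case.get(case.case_id, ())),
                "cost": (
                    cm.set_agent_volume_ml * cost_per_ml[cm.agent]
                    if cost_per_ml and cm.agent in cost_per_ml
                    else math.nan
                ),
                "co2e_kg": table.co2e_kg(cm.agent, cm.set_agent_volume_ml),
            }
        )

    agg_cols = [
        "period", "agent", "n_cases", "mean_ml_per_mac_hour", "total_volume_ml",
        "total_mac_hours", "episodes_per_case", "episodes_per_case_hour",
        "total_cost", "total_co2e_kg",
    ]
    if not rows:
        return pd.DataFrame(columns=agg_cols)
    df = pd.DataFrame(rows)
    grouped = (
        df.dropna(subset=["ml_per_mac_hour"])
        .groupby(["period", "agent"], as_index=False)
        .agg(
            n_cases=("case_id", "nunique"),
            mean_ml_per_mac_hour=("ml_per_mac_hour", "mean"),
            total_volume_ml=("volume_ml", "sum"),
            total_mac_hours=("mac_hours", "sum"),
            episodes=("episodes", "sum"),
            case_hours=("case_hours", "sum"),
            total_cost=("cost", lambda s: s.sum(min_count=1)),  # null, not 0, when unpriced
            total_co2e_kg=("co2e_kg", "sum"),
        )
    )
    grouped["episodes_per_case"] = grouped["episodes"] / grouped["n_cases"]
    grouped["episodes_per_case_hour"] = grouped["episodes"] / grouped["case_hours"]
    grouped = grouped.drop(columns=["episodes", "case_hours"])

    # pad empty months inside the span with explicit nulls
    if period == "month" and months_seen and "all" not in months_seen:
        span = pd.period_range(min(months_seen), max(months_seen), freq="M")
        have = set(grouped["period"])
        pad = [
            {"period": str(p), "agent": None, "n_cases": 0}
            for p in span
            if str(p) not in have
        ]
        if pad:
            grouped = pd.concat([grouped, pd.DataFrame(pad)], ignore_index=True)
    return grouped.sort_values(["period", "agent"], na_position="last").reset_index(
        drop=True
    )[[c for c in agg_cols if c in grouped.columns]]
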