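"""Per-minute intraoperative flowsheet data model, validation and file I/O.

The native clock is integer minutes relative to the first record of a case
(the alert rules are evaluated every minute, so the minute grid is the
engine's natural time base). Gaps in the grid are preserved — missing
minutes are never imputed.

Two documented on-disk dialects:

``csv``
    A directory of three RFC-4180 CSV files (UTF-8, header row):
    ``minutes.csv`` (one row per case-minute), ``cases.csv`` (one row per
    case) and ``professionals.csv`` (one row per sign-in interval).
    Missing optional values are empty cells, never zero.
``jsonl``
    One JSON object per line, one case per object, minutes nested.

Column/key reference (csv dialect):

* ``cases.csv``: case_id, location, patient_age_years, procedure_start_min,
  procedure_stop_min, start_date (ISO date or empty)
* ``minutes.csv``: case_id, t_min, dial_<agent>_pct (sevoflurane /
  isoflurane / desflurane), fgf_total_l_min, flow_<gas>_l_min (oxygen / air
  / nitrous_oxide), et_<agent>_pct, cum_<agent>_ml
* ``professionals.csv``: case_id, professional_id, role, t_in_min, t_out_min
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .agents import AgentKind, VOLATILE_AGENTS

logger = logging.getLogger(__name__)

__all__ = [
    "DeviceMinute",
    "CaseRecord",
    "ProfessionalInterval",
    "SchemaError",
    "FlowsheetValidationError",
    "read_cases",
    "write_cases",
    "normalize_to_minute_grid",
]

GAS_FLOW_KINDS = (AgentKind.OXYGEN, AgentKind.AIR, AgentKind.NITROUS_OXIDE)

_GAS_FLOW_TOL = 1e-6


class SchemaError(ValueError):
    """A required column or key is missing from an input file."""


class FlowsheetValidationError(ValueError):
    """Row-level content violates a flowsheet invariant."""


@dataclass(slots=True)
class DeviceMinute:
    """One per-minute flowsheet row.

    ``dial_pct`` maps agents to the set (dial) vaporizer concentration in
    vol%; ``fgf_total`` is the total fresh gas flow in L/min (the sum over
    O2, air and N2O); ``gas_flows`` optionally breaks that total down;
    ``et_pct`` carries measured end-tidal concentrations; and
    ``cumulative_liquid_ml`` is the ventilator's running total of liquid
    agent consumed, when the machine reports one.
    """

    t: int
    dial_pct: dict[AgentKind, float] = field(default_factory=dict)
    fgf_total: float = 0.0
    gas_flows: Optional[dict[AgentKind, float]] = None
    et_pct: dict[AgentKind, float] = field(default_factory=dict)
    cumulative_liquid_ml: Optional[dict[AgentKind, float]] = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise FlowsheetValidationError(f"t must be >= 0, got {self.t}")
        if self.fgf_total < 0:
            raise FlowsheetValidationError(f"fgf_total must be >= 0, got {self.fgf_total}")
        for m in (self.dial_pct, self.et_pct, self.gas_flows, self.cumulative_liquid_ml):
            if m:
                for k, v in m.items():
                    if v < 0:
                        raise FlowsheetValidationError(
                            f"negative value {v} for {AgentKind(k).value} at t={self.t}"
                        )
        if self.gas_flows:
            total = sum(self.gas_flows.values())
            if abs(total - self.fgf_total) > _GAS_FLOW_TOL:
                raise FlowsheetValidationError(
                    f"gas_flows sum {total} != fgf_total {self.fgf_total} at t={self.t}"
                )


@dataclass(slots=True)
class ProfessionalInterval:
    """A professional's signed-in interval [t_in, t_out) within a case."""

    professional_id: str
    role: str
    t_in: int
    t_out: int

    def __post_init__(self) -> None:
        if self.t_in >= self.t_out:
            raise FlowsheetValidationError(
                f"professional {self.professional_id}: t_in {self.t_in} >= t_out {self.t_out}"
            )


@dataclass(slots=True)
class CaseRecord:
    """A surgical case: metadata, event times and its ordered minutes."""

    case_id: str
    location: str = "OR"
    patient_age: float = 40.0
    procedure_start: Optional[int] = None
    procedure_stop: Optional[int] = None
    minutes: list[DeviceMinute] = field(default_factory=list)
    professionals: list[ProfessionalInterval] = field(default_factory=list)
    start_date: Optional[_dt.date] = None

    def validate(self) -> None:
        """Raise :class:`FlowsheetValidationError` on any invariant breach."""
        if self.patient_age <= 0:
            raise FlowsheetValidationError(
                f"case {self.case_id}: patient_age must be > 0, got {self.patient_age}"
            )
        if (
            self.procedure_start is not None
            and self.procedure_stop is not None
            and not self.procedure_start < self.procedure_stop
        ):
            raise FlowsheetValidationError(
                f"case {self.case_id}: procedure_start {self.procedure_start} "
                f"is not before procedure_stop {self.procedure_stop}"
            )
        prev_t = None
        prev_cum: dict[AgentKind, float] = {}
        for m in self.minutes:
            if prev_t is not None and m.t <= prev_t:
                raise FlowsheetValidationError(
                    f"case {self.case_id}: minutes not strictly increasing at t={m.t}"
                )
            prev_t = m.t
            if m.cumulative_liquid_ml:
                for agent, v in m.cumulative_liquid_ml.items():
                    if v < prev_cum.get(agent, 0.0) - 1e-9:
                        raise FlowsheetValidationError(
                            f"case {self.case_id}: cumulative_liquid_ml for "
                            f"{AgentKind(agent).value} decreases at t={m.t} "
                            f"({prev_cum[agent]} -> {v})"
                        )
                    prev_cum[agent] = v

    def minute_at(self, t: int) -> Optional[DeviceMinute]:
        for m in self.minutes:
            if m.t == t:
                return m
        return None


# ---------------------------------------------------------------------------
# minute-grid normalization


def normalize_to_minute_grid(case: CaseRecord) -> CaseRecord:
    """Align a case's records to the integer minute grid.

    Non-integer timestamps are snapped to the floor minute (with a warning);
    rows are sorted by time; duplicate minutes raise. Gaps remain explicit —
    the record count is never increased. Idempotent on already-gridded
    cases.
    """
    snapped = []
    for m in case.minutes:
        t_int = math.floor(m.t)
        if t_int != m.t:
            logger.warning(
                "case %s: record at t=%s snapped to minute %d", case.case_id, m.t, t_int
            )
            m = replace(m, t=t_int)
        snapped.append(m)
    snapped.sort(key=lambda m: m.t)
    seen: set[int] = set()
    dups = sorted({m.t for m in snapped if m.t in seen or seen.add(m.t)})
    if dups:
        raise FlowsheetValidationError(
            f"case {case.case_id}: duplicate minute(s) {dups} after grid alignment"
        )
    if snapped == case.minutes:
        return case
    return replace(case, minutes=snapped)


# ---------------------------------------------------------------------------
# CSV dialect

_CASE_COLS = [
    "case_id",
    "location",
    "patient_age_years",
    "procedure_start_min",
    "procedure_stop_min",
    "start_date",
]
_MINUTE_COLS = (
    ["case_id", "t_min"]
    + [f"dial_{a.value}_pct" for a in VOLATILE_AGENTS]
    + ["fgf_total_l_min"]
    + [f"flow_{g.value}_l_min" for g in GAS_FLOW_KINDS]
    + [f"et_{a.value}_pct" for a in VOLATILE_AGENTS]
    + [f"cum_{a.value}_ml" for a in VOLATILE_AGENTS]
)
_PROF_COLS = ["case_id", "professional_id", "role", "t_in_min", "t_out_min"]

_REQUIRED_MINUTE_COLS = ["case_id", "t_min", "fgf_total_l_min"]


def _fmt(v) -> str:
    """Stable cell formatting: None -> empty; floats via str (round-trips)."""
    if v is None:
        return ""
    if isinstance(v, float):
        return str(int(v)) if v.is_integer() else str(v)
    return str(v)


def _num(cell: str) -> Optional[float]:
    return None if cell in ("", None) else float(cell)


def _agent_map(row: dict, prefix: str, suffix: str, kinds) -> dict[AgentKind, float]:
    out = {}
    for k in kinds:
        v = _num(row.get(f"{prefix}{k.value}{suffix}", ""))
        if v is not None:
            out[k] = v
    return out


def _write_csv_dir(cases: list[CaseRecord], path: str) -> None:
    os.makedirs(path, exist_ok=True)

    with open(os.path.join(path, "cases.csv"), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CASE_COLS)
        for c in cases:
            w.writerow(
                [
                    c.case_id,
                    c.location,
                    _fmt(float(c.patient_age)),
                    _fmt(c.procedure_start),
                    _fmt(c.procedure_stop),
                    c.start_date.isoformat() if c.start_date else "",
                ]
            )

    with open(os.path.join(path, "minutes.csv"), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_MINUTE_COLS)
        for c in cases:
            for m in c.minutes:
                row = [c.case_id, _fmt(m.t)]
                row += [_fmt(m.dial_pct.get(a)) for a in VOLATILE_AGENTS]
                row.append(_fmt(float(m.fgf_total)))
                gf = m.gas_flows or {}
                row += [_fmt(gf.get(g)) for g in GAS_FLOW_KINDS]
                row += [_fmt(m.et_pct.get(a)) for a in VOLATILE_AGENTS]
                cum = m.cumulative_liquid_ml or {}
                row += [_fmt(cum.get(a)) for a in VOLATILE_AGENTS]
                w.writerow(row)

    with open(
        os.path.join(path, "professionals.csv"), "w", newline="", encoding="utf-8"
    ) as fh:
        w = csv.writer(fh)
        w.writerow(_PROF_COLS)
        for c in cases:
            for p in c.professionals:
                w.writerow([c.case_id, p.professional_id, p.role, p.t_in, p.t_out])


def _read_csv_dir(path: str) -> list[CaseRecord]:
    cases: dict[str, CaseRecord] = {}

    with open(os.path.join(path, "cases.csv"), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ("case_id", "patient_age_years") if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"cases.csv: missing required column(s) {missing}")
        for row in reader:
            start = _num(row.get("procedure_start_min", ""))
            stop = _num(row.get("procedure_stop_min", ""))
            date_cell = row.get("start_date", "")
            cases[row["case_id"]] = CaseRecord(
                case_id=row["case_id"],
                location=row.get("location", "OR") or "OR",
                patient_age=float(row["patient_age_years"]),
                procedure_start=None if start is None else int(start),
                procedure_stop=None if stop is None else int(stop),
                start_date=_dt.date.fromisoformat(date_cell) if date_cell else None,
            )

    with open(os.path.join(path, "minutes.csv"), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = [c for c in _REQUIRED_MINUTE_COLS if c not in fields]
        if missing:
            raise SchemaError(f"minutes.csv: missing required column(s) {missing}")
        if not any(f"dial_{a.value}_pct" in fields for a in VOLATILE_AGENTS):
            raise SchemaError("minutes.csv: no dial_<agent>_pct column present")
        for lineno, row in enumerate(reader, start=2):
            cid = row["case_id"]
            if cid not in cases:
                raise FlowsheetValidationError(
                    f"minutes.csv line {lineno}: unknown case_id {cid!r}"
                )
            try:
                gas_flows = _agent_map(row, "flow_", "_l_min", GAS_FLOW_KINDS)
                cum = _agent_map(row, "cum_", "_ml", VOLATILE_AGENTS)
                minute = DeviceMinute(
                    t=int(float(row["t_min"])) if float(row["t_min"]).is_integer() else float(row["t_min"]),
                    dial_pct=_agent_map(row, "dial_", "_pct", VOLATILE_AGENTS),
                    fgf_total=float(row["fgf_total_l_min"]),
                    gas_flows=gas_flows or None,
                    et_pct=_agent_map(row, "et_", "_pct", VOLATILE_AGENTS),
                    cumulative_liquid_ml=cum or None,
                )
            except (ValueError, FlowsheetValidationError) as exc:
                raise FlowsheetValidationError(
                    f"minutes.csv line {lineno} (case {cid}): {exc}"
                ) from exc
            cases[cid].minutes.append(minute)

    prof_path = os.path.join(path, "professionals.csv")
    if os.path.exists(prof_path):
        with open(prof_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                cid = row["case_id"]
                if cid not in cases:
                    raise FlowsheetValidationError(
                        f"professionals.csv line {lineno}: unknown case_id {cid!r}"
                    )
                cases[cid].professionals.append(
                    ProfessionalInterval(
                        professional_id=row["professional_id"],
                        role=row["role"],
                        t_in=int(float(row["t_in_min"])),
                        t_out=int(float(row["t_out_min"])),
                    )
                )

    return list(cases.values())


# ---------------------------------------------------------------------------
# JSONL dialect


def _case_to_obj(c: CaseRecord) -> dict:
    def agent_keys(m: Optional[dict]) -> Optional[dict]:
        if m is None:
            return None
        return {k.value: v for k, v in m.items()}

    return {
        "case_id": c.case_id,
        "location": c.location,
        "patient_age": c.patient_age,
        "procedure_start": c.procedure_start,
        "procedure_stop": c.procedure_stop,
        "start_date": c.start_date.isoformat() if c.start_date else None,
        "professionals": [
            {
                "professional_id": p.professional_id,
                "role": p.role,
                "t_in": p.t_in,
                "t_out": p.t_out,
            }
            for p in c.professionals
        ],
        "minutes": [
            {
                "t": m.t,
                "dial_pct": agent_keys(m.dial_pct),
                "fgf_total": m.fgf_total,
                "gas_flows": agent_keys(m.gas_flows),
                "et_pct": agent_keys(m.et_pct),
                "cumulative_liquid_ml": agent_keys(m.cumulative_liquid_ml),
            }
            for m in c.minutes
        ],
    }


def _case_from_obj(obj: dict, lineno: int) -> CaseRecord:
    def kind_keys(m: Optional[dict]) -> Optional[dict]:
        if m is None:
            return None
        return {AgentKind(k): v for k, v in m.items()}

    for key in ("case_id", "patient_age", "minutes"):
        if key not in obj:
            raise SchemaError(f"jsonl line {lineno}: missing required key {key!r}")
    try:
        return CaseRecord(
            case_id=obj["case_id"],
            location=obj.get("location", "OR"),
            patient_age=obj["patient_age"],
            procedure_start=obj.get("procedure_start"),
            procedure_stop=obj.get("procedure_stop"),
            start_date=(
                _dt.date.fromisoformat(obj["start_date"]) if obj.get("start_date") else None
            ),
            professionals=[ProfessionalInterval(**p) for p in obj.get("professionals", [])],
            minutes=[
                DeviceMinute(
                    t=m["t"],
                    dial_pct=kind_keys(m.get("dial_pct")) or {},
                    fgf_total=m.get("fgf_total", 0.0),
                    gas_flows=kind_keys(m.get("gas_flows")),
                    et_pct=kind_keys(m.get("et_pct")) or {},
                    cumulative_liquid_ml=kind_keys(m.get("cumulative_liquid_ml")),
                )
                for m in obj["minutes"]
            ],
        )
    except FlowsheetValidationError as exc:
        raise FlowsheetValidationError(
            f"jsonl line {lineno} (case {obj.get('case_id')}): {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# public I/O


def write_cases(cases: Iterable[CaseRecord], path, format: str = "csv") -> None:
    """Losslessly serialize a cohort.

    ``csv`` writes a three-file directory at ``path``; ``jsonl`` writes a
    single file. Column order is stable and missing optionals are written as
    empty cells/nulls, so write -> read -> write is byte-identical.
    """
    cases = list(cases)
    path = os.fspath(path)
    if format == "csv":
        _write_csv_dir(cases, path)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for c in cases:
                fh.write(json.dumps(_case_to_obj(c), separators=(",", ":")) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cases(path, format: str = "csv") -> list[CaseRecord]:
    """Parse a cohort, sort minutes, and validate every case.

    Out-of-order minutes are sorted with a logged warning; duplicate minutes
    and non-monotone cumulative volumes raise
    :class:`FlowsheetValidationError` naming the case; missing required
    columns raise :class:`SchemaError` naming the column.
    """
    path = os.fspath(path)
    if format == "csv":
        cases = _read_csv_dir(path)
    elif format == "jsonl":
        cases = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    cases.append(_case_from_obj(json.loads(line), lineno))
    else:
        raise ValueError(f"unknown format {format!r}")

    out = []
    for c in cases:
        ts = [m.t for m in c.minutes]
        if ts != sorted(ts):
            logger.warning("case %s: minutes out of time order; sorting", c.case_id)
        c = normalize_to_minute_grid(c)
        c.validate()
        out.append(c)
    return out
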