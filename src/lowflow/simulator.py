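"""Synthetic OR cohort generator with a probabilistic response to alerts.

Each simulated case follows the canonical phase structure of a volatile
anesthetic: a short high-flow induction before the procedure-start event,
a maintenance segment whose fresh gas flow is drawn from a two-mode
mixture (a low-flow practice mode near 0.5 L/min and a high-flow mode
near 2 L/min), and a high-flow emergence with the vaporizer dialed to
zero after the gas stops. End-tidal concentration relaxes exponentially
toward the patient's age-adjusted MAC multiplied by the target MAC
multiple, and the ventilator's cumulative liquid consumption column is
written exactly from the vaporizer-output formula, so the metrics
module's two volume paths agree by construction.

Maintenance flow is piecewise-constant and quantized to the charting
resolution (0.1 L/min): anesthesia machines deliver the flow the
clinician dialed, so the signal steps between set points rather than
wandering minute to minute. (Minute-level noise around the alert
threshold would make the advisory flap and is not a feature of charted
flowsheet data.) Induction and emergence flows carry mild per-minute
variation, away from any threshold.

Practitioner behaviour is memoryless per alert episode: the advisory
engine runs concurrently with generation, and each new firing episode
independently triggers, with probability ``response_probability``, a
reduction of the fresh gas flow to ``response_fgf`` after
``response_latency`` minutes. :func:`estimate_response_probability`
recovers that probability from a cohort and its alert log with a
binomial confidence interval.

Defaults are literature-plausible for a general OR case mix (mean
maintenance ~110 min, mostly sevoflurane, adult ages with occasional
infants); no claim is made that they match any particular institution.
Reproducibility: identical params and seed give a byte-identical cohort.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .agents import AgentKind, AgentTable, default_table
from .alert_engine import (
    AlertConfig,
    AlertEngineState,
    AlertEvent,
    evaluate_minute,
)
from .flowsheet import CaseRecord, DeviceMinute, ProfessionalInterval

__all__ = [
    "SimParams",
    "ResponseEstimate",
    "simulate_case",
    "simulate_cohort",
    "estimate_response_probability",
]


@dataclass(frozen=True)
class SimParams:
    """Cohort-generation parameters (all times in minutes, flows in L/min)."""

    n_cases: int = 100
    seed: int = 0

    # case-length structure
    maintenance_mean_min: float = 110.0  # lognormal mean of maintenance length
    maintenance_sd_min: float = 55.0
    min_maintenance_min: int = 20
    induction_min_range: tuple[int, int] = (5, 15)  # uniform inclusive
    emergence_min_range: tuple[int, int] = (3, 8)

    # flows
    induction_fgf_mean: float = 6.0
    induction_fgf_sd: float = 1.0
    maint_fgf_low_mean: float = 0.5
    maint_fgf_low_sd: float = 0.1
    maint_fgf_high_mean: float = 2.0
    maint_fgf_high_sd: float = 0.3
    high_flow_weight: float = 0.5  # mixture weight of the high-flow mode
    fgf_jitter_sd: float = 0.05  # induction/emergence only
    fgf_resolution: float = 0.1  # charting quantum for maintenance set points
    emergence_fgf: float = 8.0

    # patient / agent mix
    agent_mix: tuple[tuple[AgentKind, float], ...] = (
        (AgentKind.SEVOFLURANE, 0.70),
        (AgentKind.ISOFLURANE, 0.15),
        (AgentKind.DESFLURANE, 0.15),
    )
    age_log_median: float = 40.0
    age_log_sigma: float = 0.6
    infant_probability: float = 0.03  # uniform(0.2, 1.0) years
    target_mac: float = 1.0
    et_tau_min: float = 5.0

    # practitioner response to the advisory
    response_probability: float = 0.7
    response_latency: int = 2
    response_fgf: float = 0.5
    alert_config: AlertConfig = field(default_factory=AlertConfig)

    # cohort calendar for period aggregation
    start_date: _dt.date = _dt.date(2021, 1, 1)
    cases_per_day: int = 2

    location: str = "OR"

    def __post_init__(self) -> None:
        if not 0.0 <= self.response_probability <= 1.0:
            raise ValueError("response_probability must be in [0, 1]")
        if not 0.0 <= self.high_flow_weight <= 1.0:
            raise ValueError("high_flow_weight must be in [0, 1]")
        if abs(sum(w for _, w in self.agent_mix) - 1.0) > 1e-9:
            raise ValueError("agent_mix weights must sum to 1")

    @property
    def maintenance_fgf_mean(self) -> float:
        """Analytic mean of the maintenance FGF mixture (pre-response)."""
        w = self.high_flow_weight
        return (1 - w) * self.maint_fgf_low_mean + w * self.maint_fgf_high_mean


@dataclass(frozen=True)
class ResponseEstimate:
    """Recovered per-episode response probability with its binomial CI."""

    p_hat: float
    ci_low: float
    ci_high: float
    n_episodes: int
    n_responded: int
    defined: bool

    def covers(self, p: float) -> bool:
        return self.defined and self.ci_low <= p <= self.ci_high


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _simulate_case(
    params: SimParams, case_index: int, table: AgentTable
) -> tuple[CaseRecord, dict]:
    rng = np.random.default_rng([params.seed & 0x7FFFFFFF, case_index])

    agents = [a for a, _ in params.agent_mix]
    weights = [w for _, w in params.agent_mix]
    agent = agents[rng.choice(len(agents), p=weights)]

    if rng.random() < params.infant_probability:
        age = float(rng.uniform(0.2, 1.0))
    else:
        age = float(
            np.clip(
                np.exp(rng.normal(math.log(params.age_log_median), params.age_log_sigma)),
                1.5,
                95.0,
            )
        )

    mu, sigma = _lognormal_params(params.maintenance_mean_min, params.maintenance_sd_min)
    maint_len = max(params.min_maintenance_min, int(round(float(np.exp(rng.normal(mu, sigma))))))
    induction_len = int(rng.integers(params.induction_min_range[0], params.induction_min_range[1] + 1))
    emergence_len = int(rng.integers(params.emergence_min_range[0], params.emergence_min_range[1] + 1))

    high_mode = bool(rng.random() < params.high_flow_weight)
    if high_mode:
        draw = rng.normal(params.maint_fgf_high_mean, params.maint_fgf_high_sd)
    else:
        draw = rng.normal(params.maint_fgf_low_mean, params.maint_fgf_low_sd)
    q = params.fgf_resolution
    base_fgf = float(max(0.2, round(round(draw / q) * q, 6)))
    response_level = float(max(0.2, round(round(params.response_fgf / q) * q, 6)))

    procedure_start = induction_len
    gas_stop = procedure_start + maint_len  # last nonzero dial is gas_stop - 1
    procedure_stop = gas_stop
    n_minutes = gas_stop + emergence_len

    mac_pct = table.age_adjusted_mac_pct(agent, age)
    target_et = mac_pct * params.target_mac
    dial_maint = round(1.2 * target_et, 2)
    dial_induction = round(min(2.0 * dial_maint, 3.0 * table.properties[agent].mac40), 2)

    induction_flows = np.maximum(
        1.0, rng.normal(params.induction_fgf_mean, params.induction_fgf_sd, induction_len)
    )
    jitter = rng.normal(0.0, params.fgf_jitter_sd, n_minutes)

    case_id = f"sim-{params.seed}-{case_index:05d}"
    case = CaseRecord(
        case_id=case_id,
        location=params.location,
        patient_age=age,
        procedure_start=procedure_start,
        procedure_stop=procedure_stop,
        start_date=params.start_date + _dt.timedelta(days=case_index // params.cases_per_day),
    )

    # co-run the advisory engine so practitioner response can alter flows
    state = AlertEngineState()
    seen_episodes: set[int] = set()
    episode_responses: list[bool] = []
    response_from: Optional[int] = None
    cum_ml = 0.0
    last_et = 0.0

    for t in range(n_minutes):
        if t < procedure_start:
            fgf = float(induction_flows[t])
            dial = dial_induction
        elif t < gas_stop:
            if response_from is not None and t >= response_from:
                fgf = response_level
            else:
                fgf = base_fgf
            dial = dial_maint
        else:
            fgf = float(max(1.0, params.emergence_fgf + jitter[t]))
            dial = 0.0

        if dial > 0.0:
            last_et = target_et * (1.0 - math.exp(-(t + 1) / params.et_tau_min))
            et = last_et
        else:
            et = last_et * math.exp(-(t - gas_stop + 1) / params.et_tau_min)

        cum_ml += table.liquid_ml_consumed(agent, fgf, dial, 1.0)
        o2 = fgf / 2.0
        minute = DeviceMinute(
            t=t,
            dial_pct={agent: dial},
            fgf_total=fgf,
            gas_flows={AgentKind.OXYGEN: o2, AgentKind.AIR: fgf - o2},
            et_pct={agent: round(et, 4)},
            cumulative_liquid_ml={agent: cum_ml},
        )
        case.minutes.append(minute)

        state, event = evaluate_minute(state, minute, case, params.alert_config)
        if event is not None and event.episode_id not in seen_episodes:
            seen_episodes.add(event.episode_id)
            responded = bool(rng.random() < params.response_probability)
            episode_responses.append(responded)
            if responded and response_from is None:
                response_from = t + 1 + params.response_latency

    # professionals: one attending over the whole case, plus either a single
    # in-room clinician or a mid-maintenance handoff (overlap exercised)
    case.professionals.append(
        ProfessionalInterval("att-%05d" % case_index, "attending", 0, n_minutes)
    )
    if rng.random() < 0.5 and maint_len >= 4:
        handoff = procedure_start + maint_len // 2
        case.professionals.append(
            ProfessionalInterval("crna-%05d-a" % case_index, "crna", 0, handoff)
        )
        case.professionals.append(
            ProfessionalInterval("crna-%05d-b" % case_index, "crna", handoff, n_minutes)
        )
    else:
        case.professionals.append(
            ProfessionalInterval("crna-%05d" % case_index, "crna", 0, n_minutes)
        )

    truth = {
        "case_id": case_id,
        "agent": agent.value,
        "age": age,
        "fgf_mode": "high" if high_mode else "low",
        "base_fgf": base_fgf,
        "maintenance_min": maint_len,
        "n_episodes": len(episode_responses),
        "n_responded": int(sum(episode_responses)),
        "responded_any": bool(any(episode_responses)),
        "response_from": response_from,
    }
    return case, truth


def simulate_case(params: SimParams, case_index: int) -> CaseRecord:
    """Generate one deterministic synthetic case (seeded by params + index)."""
    case, _ = _simulate_case(params, case_index, default_table())
    return case


def simulate_cohort(params: SimParams) -> tuple[list[CaseRecord], pd.DataFrame]:
    """Generate ``params.n_cases`` cases plus the latent ground-truth table."""
    table = default_table()
    cases, truths = [], []
    for i in range(params.n_cases):
        case, truth = _simulate_case(params, i, table)
        cases.append(case)
        truths.append(truth)
    columns = [
        "case_id", "agent", "age", "fgf_mode", "base_fgf", "maintenance_min",
        "n_episodes", "n_responded", "responded_any", "response_from",
    ]
    return cases, pd.DataFrame(truths, columns=columns)


def estimate_response_probability(
    cohort: Sequence[CaseRecord],
    alert_log: Sequence[AlertEvent],
    threshold: float = 0.7,
    window_minutes: int = 5,
    alpha: float = 0.05,
) -> ResponseEstimate:
    """Fraction of firing episodes followed by a flow at or below threshold.

    An episode counts as responded when any recorded minute in
    ``(t0, t0 + window_minutes]`` after its first firing minute ``t0`` has
    ``fgf_total <= threshold``; the window should cover the assumed
    response latency plus charting tolerance. The Wilson score interval
    gives the (1 - alpha) CI. With zero episodes the estimate is
    explicitly undefined rather than zero.
    """
    by_case = {c.case_id: c for c in cohort}
    first_fire: dict[tuple[str, int], int] = {}
    for e in alert_log:
        key = (e.case_id, e.episode_id)
        if key not in first_fire or e.t < first_fire[key]:
            first_fire[key] = e.t

    n = len(first_fire)
    if n == 0:
        return ResponseEstimate(
            p_hat=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            n_episodes=0, n_responded=0, defined=False,
        )
    responded = 0
    for (case_id, _), t0 in first_fire.items():
        case = by_case[case_id]
        if any(
            t0 < m.t <= t0 + window_minutes and m.fgf_total <= threshold
            for m in case.minutes
        ):
            responded += 1
    lo, hi = proportion_confint(responded, n, alpha=alpha, method="wilson")
    return ResponseEstimate(
        p_hat=responded / n, ci_low=float(lo), ci_high=float(hi),
        n_episodes=n, n_responded=responded, defined=True,
    )
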