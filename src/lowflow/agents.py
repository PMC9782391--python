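"""Volatile-agent constants and conversions.

Physical/pharmacologic properties of the three volatile anesthetics
(sevoflurane, isoflurane, desflurane) plus the inert carrier gases, with

* vapor <-> liquid volume conversion (ideal gas at a configurable
  reference temperature, default 21 degC),
* age-adjusted MAC via the Nickalls-Mapleson power relation
  ``MAC(age) = MAC40 * 10**(-0.00269 * (age - 40))``,
* GWP100-based CO2-equivalent accounting.

Constants live in an editable YAML table (``data/agents.yaml``), not in
code; :func:`load_agent_table` reads an alternative table from disk.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import yaml

__all__ = [
    "AgentKind",
    "AgentProperties",
    "AgentTable",
    "VOLATILE_AGENTS",
    "UnsupportedAgentError",
    "default_table",
    "load_agent_table",
    "vapor_volume_per_ml_liquid",
    "liquid_ml_consumed",
    "age_adjusted_mac_pct",
    "gwp_range",
]

#: mL occupied by one mole of ideal gas at 0 degC, 1 atm.
MOLAR_VOLUME_STP_ML = 22_414.0
_KELVIN_0C = 273.15

#: Exponent of the Nickalls-Mapleson iso-MAC age relation (per year).
MAC_AGE_SLOPE = -0.00269
MAC_REFERENCE_AGE = 40.0


class UnsupportedAgentError(ValueError):
    """Raised when a MAC/vapor operation is requested for a non-volatile gas."""


class AgentKind(str, Enum):
    """Gases the engine and flowsheet know about.

    Exactly three members are volatile anesthetic agents; only those carry
    :class:`AgentProperties`. Nitrous oxide, oxygen and air are carrier
    gases: N2O alone never satisfies the alert rules and contributes no MAC
    in this version.
    """

    SEVOFLURANE = "sevoflurane"
    ISOFLURANE = "isoflurane"
    DESFLURANE = "desflurane"
    NITROUS_OXIDE = "nitrous_oxide"
    OXYGEN = "oxygen"
    AIR = "air"

    @property
    def is_volatile(self) -> bool:
        return self in VOLATILE_AGENTS


# Fixed order; also the tie-break order for "set agent" in the alert engine.
VOLATILE_AGENTS: tuple[AgentKind, ...] = (
    AgentKind.SEVOFLURANE,
    AgentKind.ISOFLURANE,
    AgentKind.DESFLURANE,
)


@dataclass(frozen=True)
class AgentProperties:
    """Per-agent physical and pharmacologic constants.

    Attributes
    ----------
    molecular_weight:
        g/mol of the agent.
    liquid_density:
        g/mL of the liquid at room temperature.
    mac40:
        Minimum alveolar concentration (vol%) at the reference age of 40.
    gwp100:
        Global warming potential relative to CO2, 100-year horizon.
    """

    molecular_weight: float
    liquid_density: float
    mac40: float
    gwp100: float

    def __post_init__(self) -> None:
        for name in ("molecular_weight", "liquid_density", "mac40", "gwp100"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AgentProperties.{name} must be strictly positive")


@dataclass(frozen=True)
class AgentTable:
    """Constants table for the volatile agents at one reference temperature."""

    properties: Mapping[AgentKind, AgentProperties]
    reference_temperature_c: float = 21.0
    _vapor_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def molar_volume_ml(self) -> float:
        """Ideal-gas molar volume (mL/mol) at the reference temperature."""
        t_kelvin = self.reference_temperature_c + _KELVIN_0C
        return MOLAR_VOLUME_STP_ML * t_kelvin / _KELVIN_0C

    def _props(self, agent: AgentKind) -> AgentProperties:
        agent = AgentKind(agent)
        if agent not in self.properties:
            raise UnsupportedAgentError(
                f"{agent.value} is not a volatile agent with tabulated properties"
            )
        return self.properties[agent]

    def vapor_volume_per_ml_liquid(self, agent: AgentKind) -> float:
        """mL of agent vapor produced per mL of liquid agent vaporized.

        ``(density / MW) * molar_volume`` at the reference temperature; for
        sevoflurane at 21 degC this is roughly 183 mL vapor per mL liquid.
        """
        agent = AgentKind(agent)
        if agent not in self._vapor_cache:
            p = self._props(agent)
            self._vapor_cache[agent] = (
                p.liquid_density / p.molecular_weight * self.molar_volume_ml
            )
        return self._vapor_cache[agent]

    def liquid_ml_consumed(
        self,
        agent: AgentKind,
        fgf_l_per_min: float,
        dial_pct: float,
        duration_min: float,
    ) -> float:
        """Liquid agent (mL) vaporized at a dial setting over an interval.

        The vaporizer adds ``dial_pct`` percent of agent vapor to the fresh
        gas flow, so the vapor volume delivered is
        ``(dial_pct/100) * FGF[L/min] * 1000 * duration[min]`` and the liquid
        drawn from the vaporizer is that divided by the vapor yield per mL
        liquid. Linear in each argument and exactly additive over any
        partition of the interval.
        """
        if fgf_l_per_min < 0 or dial_pct < 0 or duration_min < 0:
            raise ValueError("fgf, dial_pct and duration must all be >= 0")
        vapor_ml = dial_pct / 100.0 * fgf_l_per_min * 1000.0 * duration_min
        return vapor_ml / self.vapor_volume_per_ml_liquid(agent)

    def age_adjusted_mac_pct(self, agent: AgentKind, age_years: float) -> float:
        """Age-adjusted MAC (vol%) for a volatile agent.

        MAC declines with age; the Nickalls-Mapleson relation
        ``MAC40 * 10**(-0.00269*(age-40))`` is the standard AIMS
        implementation and equals ``mac40`` exactly at age 40.
        """
        if age_years <= 0:
            raise ValueError(f"age must be > 0, got {age_years}")
        p = self._props(agent)
        return p.mac40 * 10.0 ** (MAC_AGE_SLOPE * (age_years - MAC_REFERENCE_AGE))

    def gwp_range(self) -> tuple[float, float]:
        """(min, max) GWP100 over the tabulated volatile agents."""
        values = [p.gwp100 for p in self.properties.values()]
        if not values:
            raise ValueError("agent table is empty")
        return (min(values), max(values))

    def co2e_kg(self, agent: AgentKind, liquid_ml: float) -> float:
        """kg CO2-equivalent of releasing ``liquid_ml`` of liquid agent."""
        p = self._props(agent)
        return liquid_ml * p.liquid_density * p.gwp100 / 1000.0


def load_agent_table(path) -> AgentTable:
    """Read an :class:`AgentTable` from a YAML constants file.

    Schema: top-level ``reference_temperature_c`` (optional, default 21) and
    ``agents``, a mapping of agent name to ``mw_g_per_mol``,
    ``density_g_per_ml``, ``mac40_pct``, ``gwp100``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _table_from_dict(raw)


def _table_from_dict(raw: dict) -> AgentTable:
    props = {}
    for name, entry in raw["agents"].items():
        props[AgentKind(name)] = AgentProperties(
            molecular_weight=float(entry["mw_g_per_mol"]),
            liquid_density=float(entry["density_g_per_ml"]),
            mac40=float(entry["mac40_pct"]),
            gwp100=float(entry["gwp100"]),
        )
    return AgentTable(
        properties=props,
        reference_temperature_c=float(raw.get("reference_temperature_c", 21.0)),
    )


@functools.lru_cache(maxsize=1)
def default_table() -> AgentTable:
    """The packaged constants table (``data/agents.yaml``)."""
    ref = importlib.resources.files("lowflow").joinpath("data/agents.yaml")
    return _table_from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


# Module-level conveniences over the packaged table.

def vapor_volume_per_ml_liquid(agent: AgentKind) -> float:
    return default_table().vapor_volume_per_ml_liquid(agent)


def liquid_ml_consumed(
    agent: AgentKind, fgf_l_per_min: float, dial_pct: float, duration_min: float
) -> float:
    return default_table().liquid_ml_consumed(agent, fgf_l_per_min, dial_pct, duration_min)


def age_adjusted_mac_pct(agent: AgentKind, age_years: float) -> float:
    return default_table().age_adjusted_mac_pct(agent, age_years)


def gwp_range() -> tuple[float, float]:
    return default_table().gwp_range()
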