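"""Classification taxonomies for the reproductive-health sub-account.

A sub-account cross-tabulates public expenditure along three axes:
financing agents (who manages the money), health providers (who finally
receives it) and health functions (what it buys).  The default taxonomy
mirrors the Burundian public sector: six financing agents, a three-tier
facility system plus national administration, and three service functions
(maternal health, family planning, other) plus two administrative
functions reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import yaml


class Function(str, Enum):
    """Health function: the activity a payment ultimately buys."""

    MATERNAL_HEALTH = "MATERNAL_HEALTH"
    FAMILY_PLANNING = "FAMILY_PLANNING"
    OTHER_HEALTH = "OTHER_HEALTH"
    ADMIN_MOH = "ADMIN_MOH"
    ADMIN_MFP = "ADMIN_MFP"


#: Functions counted as reproductive health in totals.  Administrative
#: functions are RH-attributable (they enter RH totals) but are reported
#: on separate rows; OTHER_HEALTH is the non-RH residual.
RH_SERVICE_FUNCTIONS = frozenset({Function.MATERNAL_HEALTH, Function.FAMILY_PLANNING})
ADMIN_FUNCTIONS = frozenset({Function.ADMIN_MOH, Function.ADMIN_MFP})
RH_FUNCTIONS = RH_SERVICE_FUNCTIONS | ADMIN_FUNCTIONS
#: Functions a facility service can belong to (columns of a share matrix).
SERVICE_FUNCTIONS = (
    Function.MATERNAL_HEALTH,
    Function.FAMILY_PLANNING,
    Function.OTHER_HEALTH,
)


class Tier(str, Enum):
    """Health provider tier (final recipient of funds)."""

    PHC_CLINIC = "PHC_CLINIC"
    REF_HOSPITAL_1_2 = "REF_HOSPITAL_1_2"
    REF_HOSPITAL_3 = "REF_HOSPITAL_3"
    ADMIN_NATIONAL = "ADMIN_NATIONAL"


#: Tiers that deliver services (receive service-linked funds).
FACILITY_TIERS = (Tier.PHC_CLINIC, Tier.REF_HOSPITAL_1_2, Tier.REF_HOSPITAL_3)


class Earmark(str, Enum):
    """How a budget line is targeted, which selects the estimation strategy.

    EARMARKED_RH lines pass through unchanged to their stated function;
    FACILITY_NONEARMARKED lines are apportioned across tiers and functions
    by distribution factors; ADMIN_NATIONAL lines are national overhead
    apportioned by the direct-RH share.
    """

    EARMARKED_RH = "EARMARKED_RH"
    FACILITY_NONEARMARKED = "FACILITY_NONEARMARKED"
    ADMIN_NATIONAL = "ADMIN_NATIONAL"


@dataclass(frozen=True)
class Agent:
    agent_id: str
    display_name: str
    aliases: tuple[str, ...] = ()


# The six public financing agents of the Burundian system.  The education
# ministry appears under two names in official documents; the results-table
# name is canonical and the other is an alias.
DEFAULT_AGENTS = (
    Agent("MSPLS", "Ministry of Public Health and Fight against AIDS"),
    Agent("MFP", "Civil Service Mutual Insurance (MFP)"),
    Agent(
        "MHER",
        "Ministry of Higher Education and Research",
        aliases=("Ministry of National Education",),
    ),
    Agent("MPS", "Ministry of Public Security"),
    Agent("MDN", "Ministry of National Defense"),
    Agent("MNS", "Ministry of National Solidarity, Human and Gender Rights"),
)


@dataclass
class AgentTaxonomy:
    """Registry of financing agents; custom sets may be loaded from YAML."""

    agents: dict[str, Agent] = field(
        default_factory=lambda: {a.agent_id: a for a in DEFAULT_AGENTS}
    )

    def __contains__(self, agent_id: str) -> bool:
        return agent_id in self.agents

    def __iter__(self):
        return iter(self.agents.values())

    def resolve(self, name: str) -> Agent:
        """Look up an agent by id, display name, or alias."""
        if name in self.agents:
            return self.agents[name]
        for a in self.agents.values():
            if name == a.display_name or name in a.aliases:
                return a
        raise KeyError(f"unknown financing agent: {name!r}")

    def admin_function(self, agent_id: str) -> Function:
        """Administrative function bucket for a national-level entry.

        MFP overhead is social-security administration; everything else is
        ministry-of-health-side public administration.
        """
        return Function.ADMIN_MFP if agent_id == "MFP" else Function.ADMIN_MOH


def load_taxonomy(path) -> AgentTaxonomy:
    """Read an agent taxonomy from a YAML file.

    Expected layout::

        agents:
          - agent_id: MSPLS
            display_name: Ministry of Public Health ...
            aliases: [ ... ]
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    agents = {}
    for row in doc["agents"]:
        a = Agent(
            agent_id=row["agent_id"],
            display_name=row.get("display_name", row["agent_id"]),
            aliases=tuple(row.get("aliases", ())),
        )
        agents[a.agent_id] = a
    return AgentTaxonomy(agents=agents)


def dump_taxonomy(tax: AgentTaxonomy, path) -> None:
    doc = {
        "agents": [
            {
                "agent_id": a.agent_id,
                "display_name": a.display_name,
                "aliases": list(a.aliases),
            }
            for a in tax
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
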