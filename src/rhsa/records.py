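"""Transaction, service-volume and unit-cost records, with CSV round-trip.

Money is carried as :class:`decimal.Decimal` so that accounting identities
(conservation of allocated funds) can be checked exactly; binary floats
appear only at the reporting edge.  CSV files are UTF-8 with a header row
and "." decimal separator; lines starting with ``#`` are metadata comments
(the synthetic generator records its seed there) and are skipped on read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Sequence

from .taxonomy import (
    AgentTaxonomy,
    Earmark,
    FACILITY_TIERS,
    Function,
    RH_SERVICE_FUNCTIONS,
    Tier,
)


class LedgerFormatError(ValueError):
    """A CSV row could not be parsed; names the row number and field."""

    def __init__(self, row: int, field: str, message: str):
        super().__init__(f"row {row}, field {field!r}: {message}")
        self.row = row
        self.field = field


@dataclass(frozen=True)
class LedgerEntry:
    """One public budget transaction on a cash basis.

    An entry belongs to the year the money was paid out, in nominal local
    currency.  ``earmark`` selects the allocation strategy; earmarked
    entries must say which reproductive-health function they target.
    """

    year: int
    agent_id: str
    amount: Decimal
    earmark: Earmark
    function_hint: Function | None = None
    tier_hint: Tier | None = None
    category: str = ""


@dataclass(frozen=True)
class ServiceVolumeRecord:
    """Annual count of one service delivered by one facility tier."""

    year: int
    tier: Tier
    service_code: str
    volume: int


@dataclass(frozen=True)
class UnitCost:
    """Cost per service unit in nominal local currency, with its function."""

    service_code: str
    cost: Decimal
    function: Function


@dataclass(frozen=True)
class DemographyParams:
    """Population and the fixed fractions used for per-capita indicators.

    ``wcba_fraction`` is the share of the population who are women of
    childbearing age (15-49); ``delivery_fraction`` the expected annual
    deliveries as a share of population; ``annual_growth`` projects
    population to years missing from ``population_by_year``.
    """

    population_by_year: dict[int, float]
    wcba_fraction: float = 0.237
    delivery_fraction: float = 0.05
    annual_growth: float = 0.024

    def population(self, year: int) -> float:
        if year in self.population_by_year:
            return self.population_by_year[year]
        if not self.population_by_year:
            raise ValueError("no population data")
        anchor = min(self.population_by_year, key=lambda y: abs(y - year))
        return self.population_by_year[anchor] * (1.0 + self.annual_growth) ** (
            year - anchor
        )


@dataclass(frozen=True)
class Violation:
    row: int | None
    field: str
    message: str


def validate_ledger(
    entries: Sequence[LedgerEntry], taxonomy: AgentTaxonomy | None = None
) -> list[Violation]:
    """Check a parsed ledger against the sub-account's structural rules.

    Returns one :class:`Violation` per problem (empty list iff valid):
    negative amounts, earmarked entries without a reproductive-health
    function hint, agents absent from the taxonomy, admin-tier hints on
    service-linked funds.
    """
    taxonomy = taxonomy or AgentTaxonomy()
    out: list[Violation] = []
    for i, e in enumerate(entries, start=1):
        if e.amount < 0:
            out.append(Violation(i, "amount", f"negative amount {e.amount}"))
        if e.agent_id not in taxonomy:
            out.append(Violation(i, "agent_id", f"unknown agent {e.agent_id!r}"))
        if e.earmark is Earmark.EARMARKED_RH:
            if e.function_hint not in RH_SERVICE_FUNCTIONS:
                out.append(
                    Violation(
                        i,
                        "function_hint",
                        "earmarked entry must target MATERNAL_HEALTH or "
                        "FAMILY_PLANNING",
                    )
                )
        if e.earmark is Earmark.FACILITY_NONEARMARKED and e.tier_hint is Tier.ADMIN_NATIONAL:
            out.append(
                Violation(i, "tier_hint", "facility funds cannot target ADMIN_NATIONAL")
            )
    return out


# ---------------------------------------------------------------------------
# CSV round-trip

LEDGER_COLUMNS = (
    "year",
    "agent_id",
    "amount",
    "earmark",
    "function_hint",
    "tier_hint",
    "category",
)
VOLUME_COLUMNS = ("year", "tier", "service_code", "volume")
COST_COLUMNS = ("service_code", "cost", "function")


def _open_rows(path):
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return list(csv.DictReader(lines))


def read_ledger_csv(path) -> list[LedgerEntry]:
    entries = []
    for i, row in enumerate(_open_rows(path), start=1):
        try:
            year = int(row["year"])
        except (ValueError, TypeError) as exc:
            raise LedgerFormatError(i, "year", str(exc)) from exc
        try:
            amount = Decimal(row["amount"])
        except InvalidOperation as exc:
            raise LedgerFormatError(i, "amount", f"not a number: {row['amount']!r}") from exc
        try:
            earmark = Earmark(row["earmark"])
        except ValueError as exc:
            raise LedgerFormatError(i, "earmark", str(exc)) from exc
        fh_ = row.get("function_hint") or None
        th = row.get("tier_hint") or None
        try:
            function_hint = Function(fh_) if fh_ else None
        except ValueError as exc:
            raise LedgerFormatError(i, "function_hint", str(exc)) from exc
        try:
            tier_hint = Tier(th) if th else None
        except ValueError as exc:
            raise LedgerFormatError(i, "tier_hint", str(exc)) from exc
        entries.append(
            LedgerEntry(
                year=year,
                agent_id=row["agent_id"],
                amount=amount,
                earmark=earmark,
                function_hint=function_hint,
                tier_hint=tier_hint,
                category=row.get("category", "") or "",
            )
        )
    return entries


def write_ledger_csv(entries: Iterable[LedgerEntry], path, header_comment: str | None = None):
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(LEDGER_COLUMNS)
        for e in entries:
            w.writerow(
                [
                    e.year,
                    e.agent_id,
                    str(e.amount),
                    e.earmark.value,
                    e.function_hint.value if e.function_hint else "",
                    e.tier_hint.value if e.tier_hint else "",
                    e.category,
                ]
            )


def read_volumes_csv(path) -> list[ServiceVolumeRecord]:
    recs = []
    for i, row in enumerate(_open_rows(path), start=1):
        try:
            tier = Tier(row["tier"])
        except ValueError as exc:
            raise LedgerFormatError(i, "tier", str(exc)) from exc
        if tier not in FACILITY_TIERS:
            raise LedgerFormatError(i, "tier", "volumes must belong to a facility tier")
        try:
            volume = int(row["volume"])
        except ValueError as exc:
            raise LedgerFormatError(i, "volume", str(exc)) from exc
        if volume < 0:
            raise LedgerFormatError(i, "volume", f"negative volume {volume}")
        recs.append(
            ServiceVolumeRecord(
                year=int(row["year"]),
                tier=tier,
                service_code=row["service_code"],
                volume=volume,
            )
        )
    return recs


def write_volumes_csv(recs: Iterable[ServiceVolumeRecord], path, header_comment=None):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(VOLUME_COLUMNS)
        for r in recs:
            w.writerow([r.year, r.tier.value, r.service_code, r.volume])


def read_costs_csv(path) -> list[UnitCost]:
    out = []
    for i, row in enumerate(_open_rows(path), start=1):
        try:
            cost = Decimal(row["cost"])
        except InvalidOperation as exc:
            raise LedgerFormatError(i, "cost", f"not a number: {row['cost']!r}") from exc
        if cost < 0:
            raise LedgerFormatError(i, "cost", f"negative cost {cost}")
        try:
            fn = Function(row["function"])
        except ValueError as exc:
            raise LedgerFormatError(i, "function", str(exc)) from exc
        out.append(UnitCost(service_code=row["service_code"], cost=cost, function=fn))
    return out


def write_costs_csv(costs: Iterable[UnitCost], path, header_comment=None):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(COST_COLUMNS)
        for c in costs:
            w.writerow([c.service_code, str(c.cost), c.function.value])
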