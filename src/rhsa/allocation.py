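"""The three-strategy allocation engine.

Turns a public ledger plus service volumes and unit costs into an
agent x provider x function expenditure cube:

1. *Earmarked pass-through* — budget lines explicitly targeted at a
   reproductive-health function map one-to-one to a cube cell.
2. *Facility distribution factors* — non-earmarked funds sent to health
   providers are apportioned across facility tiers in proportion to each
   tier's bottom-up expenditure estimate (volume x unit cost), and within
   a tier across functions by the tier's expenditure-share row.
3. *Administrative apportionment* — national-level overhead is split by
   the ratio of direct RH spending to all direct spending, computed from
   the cells strategies 1-2 already filled; the non-RH remainder stays in
   the cube as a residual so that conservation holds.

All arithmetic is exact rational (``fractions.Fraction``): tier-weight
vectors and share rows sum to exactly 1, so the sum of all cube cells
equals the adjusted ledger total identically, not merely to a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .monetary import MonetaryContext, adjust, as_fraction
from .records import LedgerEntry, ServiceVolumeRecord, UnitCost
from .taxonomy import (
    AgentTaxonomy,
    Earmark,
    FACILITY_TIERS,
    Function,
    RH_FUNCTIONS,
    SERVICE_FUNCTIONS,
    Tier,
)


class AllocationError(ValueError):
    pass


class MissingUnitCostError(AllocationError):
    def __init__(self, service_code: str):
        super().__init__(f"no unit cost for service_code {service_code!r}")
        self.service_code = service_code


class ZeroTierError(AllocationError):
    """Funds were directed at a tier whose estimated total is zero."""


# ---------------------------------------------------------------------------
# Strategy 2a: bottom-up facility totals, T = sum over services V * C


def estimate_tier_totals(
    volumes: Sequence[ServiceVolumeRecord],
    costs: Sequence[UnitCost],
    year: int,
) -> dict[Tier, Fraction]:
    """Estimate each facility tier's total expenditure from volumes x costs."""
    cost_by_code = {c.service_code: c for c in costs}
    totals: dict[Tier, Fraction] = {t: Fraction(0) for t in FACILITY_TIERS}
    for v in volumes:
        if v.year != year:
            continue
        if v.service_code not in cost_by_code:
            raise MissingUnitCostError(v.service_code)
        totals[v.tier] += Fraction(v.volume) * as_fraction(cost_by_code[v.service_code].cost)
    return totals


def tier_weights_from_totals(totals: Mapping[Tier, Fraction]) -> dict[Tier, Fraction]:
    """Normalize facility totals into an apportionment weight vector."""
    grand = sum(totals.values(), Fraction(0))
    if grand <= 0:
        raise ZeroTierError("all facility tier totals are zero; no basis for weights")
    return {t: totals[t] / grand for t in totals}


# ---------------------------------------------------------------------------
# Strategy 2b: within-tier function shares


@dataclass(frozen=True)
class ShareMatrix:
    """Provider-tier x function expenditure shares.

    Each defined row is a probability vector over (maternal health, family
    planning, other); a tier whose bottom-up total is zero has no row and
    allocating to it is an error.
    """

    shares: dict[Tier, dict[Function, Fraction]]

    def __post_init__(self):
        for tier, row in self.shares.items():
            s = sum(row.values(), Fraction(0))
            if abs(s - 1) > Fraction(1, 10**9):
                raise AllocationError(f"share row for {tier.value} sums to {float(s)}, not 1")
            if any(v < 0 for v in row.values()):
                raise AllocationError(f"negative share in row {tier.value}")

    def row(self, tier: Tier) -> dict[Function, Fraction]:
        if tier not in self.shares:
            raise ZeroTierError(f"share row undefined for tier {tier.value}")
        return self.shares[tier]

    def rh_share(self, tier: Tier) -> Fraction:
        row = self.row(tier)
        return row[Function.MATERNAL_HEALTH] + row[Function.FAMILY_PLANNING]


def compute_share_matrix(
    volumes: Sequence[ServiceVolumeRecord],
    costs: Sequence[UnitCost],
    year: int,
) -> ShareMatrix:
    """Divide each tier's bottom-up total across the three service functions.

    share(tier, f) = sum over services of f (volume x cost) / tier total.
    Tiers with zero total get no row (allocation to them is an error
    downstream, never a silent zero).
    """
    cost_by_code = {c.service_code: c for c in costs}
    spend: dict[Tier, dict[Function, Fraction]] = {
        t: {f: Fraction(0) for f in SERVICE_FUNCTIONS} for t in FACILITY_TIERS
    }
    for v in volumes:
        if v.year != year:
            continue
        if v.service_code not in cost_by_code:
            raise MissingUnitCostError(v.service_code)
        c = cost_by_code[v.service_code]
        spend[v.tier][c.function] += Fraction(v.volume) * as_fraction(c.cost)
    rows = {}
    for t, by_fn in spend.items():
        total = sum(by_fn.values(), Fraction(0))
        if total > 0:
            rows[t] = {f: by_fn[f] / total for f in SERVICE_FUNCTIONS}
    return ShareMatrix(shares=rows)


# ---------------------------------------------------------------------------
# The expenditure cube


@dataclass
class AllocationCube:
    """Year x agent x tier x function amounts (international dollars).

    Includes the non-RH residual cells so that the cube conserves the
    adjusted ledger total exactly; reproductive-health totals are taken
    over the RH functions only.  ``provenance`` records which ledger
    categories fed each cell.
    """

    cells: dict[tuple[int, str, Tier, Function], Fraction] = field(default_factory=dict)
    provenance: dict[tuple[int, str, Tier, Function], set] = field(default_factory=dict)

    def add(self, year: int, agent_id: str, tier: Tier, function: Function,
            amount: Fraction, category: str = "") -> None:
        if amount < 0:
            raise AllocationError("cube cells cannot receive negative amounts")
        key = (year, agent_id, tier, function)
        self.cells[key] = self.cells.get(key, Fraction(0)) + amount
        if category:
            self.provenance.setdefault(key, set()).add(category)

    def merge(self, other: "AllocationCube") -> None:
        for key, amt in other.cells.items():
            self.cells[key] = self.cells.get(key, Fraction(0)) + amt
        for key, cats in other.provenance.items():
            self.provenance.setdefault(key, set()).update(cats)

    # -- aggregations -------------------------------------------------

    def total(self, year: int | None = None, agent_id: str | None = None) -> Fraction:
        return sum(
            (
                a
                for (y, g, _, _), a in self.cells.items()
                if (year is None or y == year) and (agent_id is None or g == agent_id)
            ),
            Fraction(0),
        )

    def rh_total(self, year: int | None = None) -> Fraction:
        return sum(
            (
                a
                for (y, _, _, f), a in self.cells.items()
                if f in RH_FUNCTIONS and (year is None or y == year)
            ),
            Fraction(0),
        )

    def rh_by_agent(self, year: int) -> dict[str, Fraction]:
        out: dict[str, Fraction] = {}
        for (y, g, _, f), a in self.cells.items():
            if y == year and f in RH_FUNCTIONS:
                out[g] = out.get(g, Fraction(0)) + a
        return out

    def rh_by_tier(self, year: int) -> dict[Tier, Fraction]:
        out: dict[Tier, Fraction] = {}
        for (y, _, t, f), a in self.cells.items():
            if y == year and f in RH_FUNCTIONS:
                out[t] = out.get(t, Fraction(0)) + a
        return out

    def rh_by_function(self, year: int) -> dict[Function, Fraction]:
        out: dict[Function, Fraction] = {}
        for (y, _, _, f), a in self.cells.items():
            if y == year and f in RH_FUNCTIONS:
                out[f] = out.get(f, Fraction(0)) + a
        return out

    def direct_totals(self, year: int) -> tuple[Fraction, Fraction]:
        """(direct RH, all direct) over facility-tier cells only.

        Direct expenditure is money used for service provision; national
        administrative cells never enter the apportionment base.
        """
        rh = Fraction(0)
        total = Fraction(0)
        for (y, _, t, f), a in self.cells.items():
            if y != year or t is Tier.ADMIN_NATIONAL:
                continue
            total += a
            if f in RH_FUNCTIONS:
                rh += a
        return rh, total

    def years(self) -> list[int]:
        return sorted({y for (y, _, _, _) in self.cells})

    def to_frame(self):
        """Long-format pandas view (amounts as floats, for reporting/export)."""
        import pandas as pd

        rows = [
            {
                "year": y,
                "agent_id": g,
                "tier": t.value,
                "function": f.value,
                "amount_intl": float(a),
            }
            for (y, g, t, f), a in sorted(
                self.cells.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value, kv[0][3].value)
            )
        ]
        return pd.DataFrame(rows, columns=["year", "agent_id", "tier", "function", "amount_intl"])


# ---------------------------------------------------------------------------
# Strategy 1: earmarked pass-through


def allocate_earmarked(
    entries: Iterable[LedgerEntry],
    default_tier: Tier = Tier.PHC_CLINIC,
    ctx: MonetaryContext | None = None,
) -> AllocationCube:
    """Pass earmarked reproductive-health lines through unchanged.

    Each entry maps one-to-one to a cube cell at its hinted function; the
    tier defaults to the configured program tier when the ledger does not
    say (national vertical programs spend through PHC clinics by default).
    """
    cube = AllocationCube()
    for e in entries:
        if e.earmark is not Earmark.EARMARKED_RH:
            raise AllocationError("allocate_earmarked expects only EARMARKED_RH entries")
        if e.function_hint is None:
            raise AllocationError(f"earmarked entry {e.category!r} lacks a function hint")
        amt = adjust(e.amount, e.year, ctx) if ctx else as_fraction(e.amount)
        tier = e.tier_hint or default_tier
        cube.add(e.year, e.agent_id, tier, e.function_hint, amt, e.category)
    return cube


# ---------------------------------------------------------------------------
# Strategy 2: facility funds via distribution factors


def allocate_facility_funds(
    entries: Iterable[LedgerEntry],
    tier_weights: Mapping[Tier, Fraction],
    share_matrix: ShareMatrix,
    ctx: MonetaryContext | None = None,
) -> AllocationCube:
    """Apportion non-earmarked facility funds by the distribution factors.

    An entry without a tier hint is split across tiers by ``tier_weights``
    (normally the bottom-up tier-total proportions); with a hint the whole
    amount goes to that tier.  Within a tier the amount splits by the
    tier's function-share row.  Conservation: every entry's full amount is
    distributed (weights and shares each sum to exactly 1).
    """
    wsum = sum(tier_weights.values(), Fraction(0))
    if wsum != 1:
        raise AllocationError(f"tier weights sum to {float(wsum)}, not 1")
    cube = AllocationCube()
    for e in entries:
        if e.earmark is not Earmark.FACILITY_NONEARMARKED:
            raise AllocationError(
                "allocate_facility_funds expects only FACILITY_NONEARMARKED entries"
            )
        amt = adjust(e.amount, e.year, ctx) if ctx else as_fraction(e.amount)
        if e.tier_hint is not None:
            weights = {e.tier_hint: Fraction(1)}
        else:
            weights = dict(tier_weights)
        for tier, w in weights.items():
            if w == 0:
                continue
            row = share_matrix.row(tier)  # raises ZeroTierError if undefined
            for fn, s in row.items():
                if s == 0:
                    continue
                cube.add(e.year, e.agent_id, tier, fn, amt * w * s, e.category)
    return cube


# ---------------------------------------------------------------------------
# Strategy 3: national administrative funds


def admin_distribution_factor(direct_rh_total, direct_total) -> Fraction:
    """Share of direct spending that is reproductive health.

    The ratio of direct RH expenditure to all direct expenditure, both
    taken from the facility-level cells strategies 1-2 produced.
    """
    direct_rh_total = as_fraction(direct_rh_total)
    direct_total = as_fraction(direct_total)
    if direct_total <= 0:
        raise AllocationError("total direct expenditures are zero; no basis for apportionment")
    factor = direct_rh_total / direct_total
    if not 0 <= factor <= 1:
        raise AllocationError(f"distribution factor {float(factor)} outside [0, 1]")
    return factor


def allocate_admin(
    entries: Iterable[LedgerEntry],
    factor: Fraction,
    taxonomy: AgentTaxonomy | None = None,
    ctx: MonetaryContext | None = None,
) -> AllocationCube:
    """Apportion national overhead by the direct-RH distribution factor.

    ``amount x factor`` is RH-attributable administration (booked to the
    agent's admin function at the national tier); the remainder stays in
    the cube as non-RH residual so totals conserve.
    """
    taxonomy = taxonomy or AgentTaxonomy()
    cube = AllocationCube()
    for e in entries:
        if e.earmark is not Earmark.ADMIN_NATIONAL:
            raise AllocationError("allocate_admin expects only ADMIN_NATIONAL entries")
        amt = adjust(e.amount, e.year, ctx) if ctx else as_fraction(e.amount)
        fn = taxonomy.admin_function(e.agent_id)
        if factor > 0:
            cube.add(e.year, e.agent_id, Tier.ADMIN_NATIONAL, fn, amt * factor, e.category)
        if factor < 1:
            cube.add(
                e.year, e.agent_id, Tier.ADMIN_NATIONAL, Function.OTHER_HEALTH,
                amt * (1 - factor), e.category,
            )
    return cube


# ---------------------------------------------------------------------------
# Composition


@dataclass(frozen=True)
class PipelineConfig:
    earmarked_default_tier: Tier = Tier.PHC_CLINIC
    taxonomy: AgentTaxonomy = field(default_factory=AgentTaxonomy)


def run_pipeline(
    ledger: Sequence[LedgerEntry],
    volumes: Sequence[ServiceVolumeRecord],
    costs: Sequence[UnitCost],
    ctx: MonetaryContext,
    config: PipelineConfig | None = None,
) -> AllocationCube:
    """Run all three strategies plus monetary adjustment, per year.

    Deterministic; each study year is an independent slice.  The returned
    cube is in constant base-year international dollars and conserves the
    adjusted ledger total per agent-year exactly.
    """
    config = config or PipelineConfig()
    cube = AllocationCube()
    years = sorted({e.year for e in ledger})
    for year in years:
        year_entries = [e for e in ledger if e.year == year]
        earmarked = [e for e in year_entries if e.earmark is Earmark.EARMARKED_RH]
        facility = [e for e in year_entries if e.earmark is Earmark.FACILITY_NONEARMARKED]
        admin = [e for e in year_entries if e.earmark is Earmark.ADMIN_NATIONAL]

        year_cube = AllocationCube()
        try:
            year_cube.merge(
                allocate_earmarked(earmarked, config.earmarked_default_tier, ctx)
            )
        except AllocationError as exc:
            raise AllocationError(f"[strategy 1, year {year}] {exc}") from exc

        if facility:
            try:
                totals = estimate_tier_totals(volumes, costs, year)
                weights = tier_weights_from_totals(totals)
                shares = compute_share_matrix(volumes, costs, year)
                year_cube.merge(allocate_facility_funds(facility, weights, shares, ctx))
            except AllocationError as exc:
                raise AllocationError(f"[strategy 2, year {year}] {exc}") from exc

        if admin:
            direct_rh, direct_total = year_cube.direct_totals(year)
            try:
                factor = admin_distribution_factor(direct_rh, direct_total)
                year_cube.merge(allocate_admin(admin, factor, config.taxonomy, ctx))
            except AllocationError as exc:
                raise AllocationError(f"[strategy 3, year {year}] {exc}") from exc

        cube.merge(year_cube)
    return cube


def conservation_audit(
    cube: AllocationCube, ledger: Sequence[LedgerEntry], ctx: MonetaryContext
) -> dict[tuple[int, str], Fraction]:
    """Exact per-agent-year residuals (cube minus adjusted ledger).

    An all-zero result certifies conservation; any nonzero residual is an
    engine defect, never rounding, because the arithmetic is rational.
    """
    expected: dict[tuple[int, str], Fraction] = {}
    for e in ledger:
        key = (e.year, e.agent_id)
        expected[key] = expected.get(key, Fraction(0)) + adjust(e.amount, e.year, ctx)
    residuals = {}
    for key, exp in expected.items():
        residuals[key] = cube.total(year=key[0], agent_id=key[1]) - exp
    return residuals
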