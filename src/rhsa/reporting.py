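"""Summary indicators and presentation tables.

Tables follow the sub-account reporting convention: amounts in thousands
of constant base-year international dollars with each row's share of the
reproductive-health total in parentheses.  Rounding is half away from
zero and happens only at this rendering step — the engine keeps full
precision.  Percentage cells are rendered at one decimal with a trailing
``.0`` dropped (so 76.0 prints as "76" but 76.2 as "76.2"); top-level
health-share tables print integer percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .allocation import AllocationCube
from .monetary import as_fraction
from .records import DemographyParams
from .taxonomy import AgentTaxonomy, Function, Tier


def round_half_away(x, decimals: int = 0) -> Decimal:
    """Round to ``decimals`` places, ties away from zero (ledger convention)."""
    if isinstance(x, Fraction):
        # exact: quantize the exact decimal expansion via a high-precision ratio
        x = Decimal(x.numerator) / Decimal(x.denominator)
    elif not isinstance(x, Decimal):
        x = Decimal(repr(x)) if isinstance(x, float) else Decimal(x)
    q = Decimal(1).scaleb(-decimals)
    return x.quantize(q, rounding=ROUND_HALF_UP)


def share_percent(part, whole, decimals: int = 1) -> Decimal:
    """``100 * part / whole`` rounded half away from zero."""
    part, whole = as_fraction(part), as_fraction(whole)
    if whole <= 0:
        raise ValueError(f"whole must be > 0, got {float(whole)}")
    return round_half_away(100 * part / whole, decimals)


def growth_percent(v_from, v_to, decimals: int = 1) -> Decimal:
    """Percent change from ``v_from`` to ``v_to``."""
    v_from, v_to = as_fraction(v_from), as_fraction(v_to)
    if v_from <= 0:
        raise ValueError(f"baseline must be > 0, got {float(v_from)}")
    return round_half_away(100 * (v_to - v_from) / v_from, decimals)


def per_capita_indicators(
    rh_total, year: int, demo: DemographyParams
) -> tuple[float, float]:
    """(spending per woman of childbearing age, spending per delivery).

    Denominators are fixed fractions of the (possibly growth-projected)
    population: WCBA 15-49 as ``wcba_fraction`` of population, expected
    deliveries as ``delivery_fraction``.
    """
    pop = demo.population(year)
    if pop <= 0:
        raise ValueError(f"population for {year} must be > 0")
    rh = float(rh_total)
    return rh / (pop * demo.wcba_fraction), rh / (pop * demo.delivery_fraction)


def implied_gdp(rh_total, rh_share_of_gdp_percent) -> Fraction:
    """Back out GDP from an RH total and its printed share of GDP."""
    share = as_fraction(rh_share_of_gdp_percent)
    if share <= 0:
        raise ValueError("share of GDP must be > 0")
    return as_fraction(rh_total) / (share / 100)


@dataclass(frozen=True)
class SummaryIndicators:
    """Headline indicators for one study: totals, shares, per-capita."""

    rh_total: dict[int, float]
    health_total: dict[int, float] | None
    rh_share_of_health: dict[int, Decimal] | None
    per_wcba: dict[int, float]
    per_delivery: dict[int, float]
    growth: dict[tuple[int, int], Decimal]

    def to_dict(self) -> dict:
        out = {
            "rh_total": {str(y): v for y, v in self.rh_total.items()},
            "per_wcba": {str(y): v for y, v in self.per_wcba.items()},
            "per_delivery": {str(y): v for y, v in self.per_delivery.items()},
            "growth_percent": {f"{a}->{b}": float(v) for (a, b), v in self.growth.items()},
        }
        if self.health_total is not None:
            out["health_total"] = {str(y): v for y, v in self.health_total.items()}
            out["rh_share_of_health_percent"] = {
                str(y): float(v) for y, v in self.rh_share_of_health.items()
            }
        return out


def summarize(
    cube: AllocationCube,
    demo: DemographyParams,
    health_totals: Mapping[int, object] | None = None,
) -> SummaryIndicators:
    """Compute the headline indicators from an allocation cube.

    ``health_totals`` (total public health expenditure per year, same
    units as the cube) is external context the sub-account itself cannot
    derive; when given, RH shares of health spending are included.
    """
    years = cube.years()
    rh = {y: cube.rh_total(y) for y in years}
    per_wcba, per_delivery = {}, {}
    for y in years:
        per_wcba[y], per_delivery[y] = per_capita_indicators(rh[y], y, demo)
    growth = {}
    for a, b in zip(years, years[1:]):
        growth[(a, b)] = growth_percent(rh[a], rh[b])
    if len(years) > 2:
        growth[(years[0], years[-1])] = growth_percent(rh[years[0]], rh[years[-1]], 0)
    share = None
    ht = None
    if health_totals is not None:
        ht = {y: float(as_fraction(health_totals[y])) for y in years}
        share = {y: share_percent(rh[y], health_totals[y], 0) for y in years}
    return SummaryIndicators(
        rh_total={y: float(v) for y, v in rh.items()},
        health_total=ht,
        rh_share_of_health=share,
        per_wcba=per_wcba,
        per_delivery=per_delivery,
        growth=growth,
    )


# ---------------------------------------------------------------------------
# "amount (share)" tables


def format_percent_cell(value: Decimal) -> str:
    s = str(value)
    if s.endswith(".0"):
        s = s[:-2]
    return s


def render_share_table(
    rows: Mapping[str, Mapping[int, object]],
    totals: Mapping[int, object],
    years: Sequence[int],
    decimals: int = 1,
    thousands: bool = False,
) -> pd.DataFrame:
    """Render rows of "amount (share-of-total)" cells.

    ``rows`` maps row label -> year -> amount; ``totals`` gives the
    denominator per year.  With ``thousands`` the amount is first scaled
    to thousands and rounded half away from zero, as the published
    sub-account tables do.
    """
    data = {}
    for label, by_year in rows.items():
        cells = []
        for y in years:
            amt = as_fraction(by_year.get(y, 0))
            pct = share_percent(amt, totals[y], decimals)
            shown = round_half_away(amt / 1000 if thousands else amt, 0)
            cells.append(f"{shown:,} ({format_percent_cell(pct)})")
        data[label] = cells
    return pd.DataFrame(data, index=[str(y) for y in years]).T


def _marginal_tables(cube: AllocationCube, taxonomy: AgentTaxonomy, years):
    rh_totals = {y: cube.rh_total(y) for y in years}
    agents = {
        taxonomy.agents[g].display_name if g in taxonomy.agents else g: {
            y: cube.rh_by_agent(y).get(g, Fraction(0)) for y in years
        }
        for g in sorted({g for (_, g, _, _) in cube.cells})
    }
    tier_labels = {
        Tier.PHC_CLINIC: "Primary Health Care Clinics",
        Tier.REF_HOSPITAL_1_2: "Primary and Secondary Reference Hospitals",
        Tier.REF_HOSPITAL_3: "Tertiary Reference Hospitals",
        Tier.ADMIN_NATIONAL: "National Administration",
    }
    tiers = {
        tier_labels[t]: {y: cube.rh_by_tier(y).get(t, Fraction(0)) for y in years}
        for t in Tier
    }
    fn_labels = {
        Function.FAMILY_PLANNING: "Family Planning",
        Function.MATERNAL_HEALTH: "Maternal Health",
        Function.ADMIN_MOH: "Public Administration (except MFP)",
        Function.ADMIN_MFP: "Social Security Administration (MFP)",
    }
    fns = {
        fn_labels[f]: {y: cube.rh_by_function(y).get(f, Fraction(0)) for y in years}
        for f in fn_labels
    }
    return rh_totals, agents, tiers, fns


def build_agent_table(cube: AllocationCube, years=None, taxonomy=None, thousands=False):
    """RH expenditure by financing agent, "amount (share of RH total)"."""
    taxonomy = taxonomy or AgentTaxonomy()
    years = list(years) if years else cube.years()
    rh_totals, agents, _, _ = _marginal_tables(cube, taxonomy, years)
    return render_share_table(agents, rh_totals, years, thousands=thousands)


def build_provider_table(cube: AllocationCube, years=None, taxonomy=None, thousands=False):
    """RH expenditure by health provider tier."""
    taxonomy = taxonomy or AgentTaxonomy()
    years = list(years) if years else cube.years()
    rh_totals, _, tiers, _ = _marginal_tables(cube, taxonomy, years)
    return render_share_table(tiers, rh_totals, years, thousands=thousands)


def build_function_table(cube: AllocationCube, years=None, taxonomy=None, thousands=False):
    """RH expenditure by health function (admin functions on separate rows)."""
    taxonomy = taxonomy or AgentTaxonomy()
    years = list(years) if years else cube.years()
    rh_totals, _, _, fns = _marginal_tables(cube, taxonomy, years)
    return render_share_table(fns, rh_totals, years, thousands=thousands)
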