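"""Published Burundi 2010-2012 sub-account results as an in-code fixture.

The raw Burundian budget ledgers behind the published sub-account are not
public, so the published result tables — absolute amounts in thousands of
constant 2012 international dollars, plus the facility expenditure-share
matrix and context totals — ship here as the bridge between the engine's
reporting layer and the published study.  Every *derived* number (the
parenthetical shares, growth rates, column sums, GDP ratios) is
recomputed from these absolutes by :func:`verify_tables`; only the
absolutes themselves are data.
"""

from __future__ import annotations

import csv
from fractions import Fraction
from pathlib import Path

from .allocation import ShareMatrix
from .reporting import format_percent_cell, growth_percent, implied_gdp, share_percent
from .taxonomy import Function, Tier

YEARS = (2010, 2011, 2012)

#: Total public RH expenditure and total public health expenditure,
#: thousands of constant 2012 Int$ (study years 2010-2012).
RH_TOTAL = {2010: 35_463, 2011: 40_110, 2012: 41_163}
HEALTH_TOTAL = {2010: 238_334, 2011: 236_667, 2012: 220_158}
#: Published RH spending as a percentage of GDP.
RH_GDP_SHARE_PERCENT = {2010: Fraction("0.59"), 2011: Fraction("0.62"), 2012: Fraction("0.57")}
#: Published shares of RH in public health spending (integer percent).
RH_HEALTH_SHARE_PERCENT = {2010: 15, 2011: 17, 2012: 19}

#: RH expenditure by financing agent (thousands Int$).
AGENT_TABLE = {
    "MSPLS": {2010: 25_874, 2011: 30_565, 2012: 31_292},
    "MFP": {2010: 7_453, 2011: 7_515, 2012: 7_909},
    "MHER": {2010: 576, 2011: 517, 2012: 582},
    "MPS": {2010: 697, 2011: 649, 2012: 587},
    "MDN": {2010: 818, 2011: 809, 2012: 747},
    "MNS": {2010: 45, 2011: 55, 2012: 46},
}
#: Published agent shares (percent, one decimal where printed).
AGENT_SHARES = {
    "MSPLS": {2010: "73", 2011: "76.2", 2012: "76"},
    "MFP": {2010: "21", 2011: "18.7", 2012: "19.2"},
    "MHER": {2010: "1.6", 2011: "1.3", 2012: "1.4"},
    "MPS": {2010: "2", 2011: "1.6", 2012: "1.4"},
    "MDN": {2010: "2.3", 2011: "2", 2012: "1.8"},
    "MNS": {2010: "0.1", 2011: "0.1", 2012: "0.1"},
}

#: RH expenditure by health provider (thousands Int$).
PROVIDER_TABLE = {
    "PHC_CLINIC": {2010: 18_239, 2011: 18_776, 2012: 21_599},
    "REF_HOSPITAL_1_2": {2010: 6_215, 2011: 12_372, 2012: 9_243},
    "REF_HOSPITAL_3": {2010: 4_898, 2011: 2_850, 2012: 3_889},
    "ADMIN_MOH": {2010: 3_131, 2011: 3_216, 2012: 3_383},
    "ADMIN_MFP": {2010: 2_981, 2011: 2_896, 2012: 3_048},
}
PROVIDER_SHARES = {
    "PHC_CLINIC": {2010: "51.4", 2011: "46.8", 2012: "52.5"},
    "REF_HOSPITAL_1_2": {2010: "17.5", 2011: "30.8", 2012: "22.5"},
    "REF_HOSPITAL_3": {2010: "13.8", 2011: "7.1", 2012: "9.4"},
    "ADMIN_MOH": {2010: "8.8", 2011: "8", 2012: "8.2"},
    "ADMIN_MFP": {2010: "8.4", 2011: "7.2", 2012: "7.4"},
}

#: RH expenditure by health function (thousands Int$).
FUNCTION_TABLE = {
    "FAMILY_PLANNING": {2010: 1_765, 2011: 3_679, 2012: 5_102},
    "MATERNAL_HEALTH": {2010: 27_586, 2011: 30_319, 2012: 29_630},
    "ADMIN_MOH": {2010: 3_131, 2011: 3_216, 2012: 3_383},
    "ADMIN_MFP": {2010: 2_981, 2011: 2_896, 2012: 3_048},
}
FUNCTION_SHARES = {
    "FAMILY_PLANNING": {2010: "5", 2011: "9.2", 2012: "12.4"},
    "MATERNAL_HEALTH": {2010: "77.8", 2011: "75.6", 2012: "72"},
    "ADMIN_MOH": {2010: "8.8", 2011: "8", 2012: "8.2"},
    "ADMIN_MFP": {2010: "8.4", 2011: "7.2", 2012: "7.4"},
}

#: Health-ministry RH expenditure by spending category (thousands Int$).
#: Contraceptives procured for 2011 were paid out in 2012 and sit in 2012
#: on the cash basis; no 2010 contraceptive spending was reported.
MSPLS_CATEGORY_TABLE = {
    "Construction, rehabilitation and equipment": {2010: 6_350, 2011: 6_323, 2012: 1_166},
    "Hospital endowment": {2010: 1_361, 2011: 1_202, 2012: 1_203},
    "National Reproductive Health Programme": {2010: 526, 2011: 648, 2012: 568},
    "Performance-Based Financing subsidies": {2010: 4_281, 2011: 9_851, 2012: 14_404},
    "Salaries and wages, peripheral level": {2010: 10_665, 2011: 9_799, 2012: 10_581},
    "Central administration and central programs": {2010: 2_618, 2011: 2_652, 2012: 2_820},
    "Medical Health Card": {2010: 73, 2011: 90, 2012: 75},
    "Contraceptives": {2012: 474},
}
MSPLS_CATEGORY_SHARES = {
    "Construction, rehabilitation and equipment": {2010: "24.5", 2011: "20.7", 2012: "3.7"},
    "Hospital endowment": {2010: "5.3", 2011: "3.9", 2012: "3.8"},
    "National Reproductive Health Programme": {2010: "2", 2011: "2.1", 2012: "1.8"},
    "Performance-Based Financing subsidies": {2010: "16.5", 2011: "32.2", 2012: "46"},
    "Salaries and wages, peripheral level": {2010: "41.2", 2011: "32.1", 2012: "33.8"},
    "Central administration and central programs": {2010: "10.1", 2011: "8.7", 2012: "9"},
    "Medical Health Card": {2010: "0.3", 2011: "0.3", 2012: "0.2"},
    "Contraceptives": {2012: "1.5"},
}

#: Facility expenditure shares by tier and year (percent of tier total).
#: Component values; the published RH-total row differs from the component
#: sum by up to 0.1 due to rounding, so components are authoritative.
SHARE_MATRIX_PERCENT = {
    2010: {
        Tier.PHC_CLINIC: {"MATERNAL_HEALTH": "24.7", "FAMILY_PLANNING": "2.04", "OTHER_HEALTH": "73.26"},
        Tier.REF_HOSPITAL_1_2: {"MATERNAL_HEALTH": "13.3", "FAMILY_PLANNING": "0.1", "OTHER_HEALTH": "86.6"},
        Tier.REF_HOSPITAL_3: {"MATERNAL_HEALTH": "10.1", "FAMILY_PLANNING": "0.3", "OTHER_HEALTH": "89.6"},
    },
    2011: {
        Tier.PHC_CLINIC: {"MATERNAL_HEALTH": "26.6", "FAMILY_PLANNING": "2.4", "OTHER_HEALTH": "71.0"},
        Tier.REF_HOSPITAL_1_2: {"MATERNAL_HEALTH": "13.1", "FAMILY_PLANNING": "0.1", "OTHER_HEALTH": "86.8"},
        Tier.REF_HOSPITAL_3: {"MATERNAL_HEALTH": "9.3", "FAMILY_PLANNING": "0.2", "OTHER_HEALTH": "90.5"},
    },
    2012: {
        Tier.PHC_CLINIC: {"MATERNAL_HEALTH": "25.8", "FAMILY_PLANNING": "2.2", "OTHER_HEALTH": "72.0"},
        Tier.REF_HOSPITAL_1_2: {"MATERNAL_HEALTH": "13.2", "FAMILY_PLANNING": "0.2", "OTHER_HEALTH": "86.6"},
        Tier.REF_HOSPITAL_3: {"MATERNAL_HEALTH": "9.8", "FAMILY_PLANNING": "0.2", "OTHER_HEALTH": "90.0"},
    },
}

#: 2012 census-projected population (persons).
POPULATION_2012 = 9_859_000


def share_matrix(year: int) -> ShareMatrix:
    """The published facility share matrix for a study year, as fractions."""
    rows = {}
    for tier, row in SHARE_MATRIX_PERCENT[year].items():
        rows[tier] = {Function(f): Fraction(p) / 100 for f, p in row.items()}
    return ShareMatrix(shares=rows)


# ---------------------------------------------------------------------------
# Fixture directory round-trip (used by the CLI's table verifier, so a
# fixture can be inspected or fault-injected on disk)

_TABLES = {
    "agents": (AGENT_TABLE, AGENT_SHARES),
    "providers": (PROVIDER_TABLE, PROVIDER_SHARES),
    "functions": (FUNCTION_TABLE, FUNCTION_SHARES),
    "mspls_categories": (MSPLS_CATEGORY_TABLE, MSPLS_CATEGORY_SHARES),
}


def write_fixture(outdir) -> None:
    """Dump the published tables to CSV files in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, (amounts, shares) in _TABLES.items():
        with open(outdir / f"{name}.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "year", "amount_thousands", "printed_share"])
            for label, by_year in amounts.items():
                for y, amt in by_year.items():
                    w.writerow([label, y, amt, shares[label][y]])
    with open(outdir / "context.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "rh_total", "health_total", "rh_gdp_share_percent"])
        for y in YEARS:
            w.writerow([y, RH_TOTAL[y], HEALTH_TOTAL[y], str(RH_GDP_SHARE_PERCENT[y])])


def load_fixture(indir):
    """Read a fixture directory back into the in-code table structure."""
    indir = Path(indir)
    tables = {}
    for name in _TABLES:
        path = indir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"fixture table missing: {path}")
        amounts: dict[str, dict[int, int]] = {}
        shares: dict[str, dict[int, str]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                y = int(row["year"])
                amounts.setdefault(row["row"], {})[y] = int(row["amount_thousands"])
                shares.setdefault(row["row"], {})[y] = row["printed_share"]
        tables[name] = (amounts, shares)
    context = {"rh_total": {}, "health_total": {}, "rh_gdp_share_percent": {}}
    with open(indir / "context.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            y = int(row["year"])
            context["rh_total"][y] = int(row["rh_total"])
            context["health_total"][y] = int(row["health_total"])
            context["rh_gdp_share_percent"][y] = Fraction(row["rh_gdp_share_percent"])
    return tables, context


def verify_tables(tables=None, context=None) -> list[tuple[str, bool, str]]:
    """Recompute every derived published number from the absolute figures.

    Returns ``(check name, passed, detail)`` triples.  Checks: column sums
    against the RH totals (providers within the published +/-1 rounding
    slack), every parenthetical share, the RH share of health spending,
    RH growth, and the implied-GDP growth.
    """
    if tables is None:
        tables = {k: v for k, v in _TABLES.items()}
        context = {
            "rh_total": dict(RH_TOTAL),
            "health_total": dict(HEALTH_TOTAL),
            "rh_gdp_share_percent": dict(RH_GDP_SHARE_PERCENT),
        }
    rh_total = context["rh_total"]
    results: list[tuple[str, bool, str]] = []

    def check(name, ok, detail=""):
        results.append((name, bool(ok), detail))

    # column sums
    for name, slack in (("agents", 0), ("functions", 0), ("providers", 1), ("mspls_categories", 1)):
        amounts, _ = tables[name]
        denom = (
            tables["agents"][0]["MSPLS"]
            if name == "mspls_categories"
            else rh_total
        )
        for y in YEARS:
            s = sum(by_year.get(y, 0) for by_year in amounts.values())
            ok = abs(s - denom[y]) <= slack
            check(f"{name}_column_sum_{y}", ok, f"sum {s} vs total {denom[y]}")

    # parenthetical shares
    for name, (amounts, shares) in tables.items():
        denom = tables["agents"][0]["MSPLS"] if name == "mspls_categories" else rh_total
        for label, by_year in amounts.items():
            for y, amt in by_year.items():
                got = format_percent_cell(share_percent(amt, denom[y], 1))
                want = shares[label][y]
                check(
                    f"{name}_share_{label}_{y}", got == want, f"computed {got}, printed {want}"
                )

    # RH share of total health spending (integer percent)
    for y in YEARS:
        got = int(share_percent(rh_total[y], context["health_total"][y], 0))
        check(
            f"rh_share_of_health_{y}",
            got == RH_HEALTH_SHARE_PERCENT[y],
            f"computed {got}, printed {RH_HEALTH_SHARE_PERCENT[y]}",
        )

    # growth of the RH total
    g_10_12 = growth_percent(rh_total[2010], rh_total[2012], 0)
    check("rh_growth_2010_2012", g_10_12 == 16, f"computed {g_10_12}, printed 16")
    g_11_12 = growth_percent(rh_total[2011], rh_total[2012], 1)
    check("rh_growth_2011_2012", float(g_11_12) == 2.6, f"computed {g_11_12}, printed 2.6")

    # implied GDP growth from the GDP-share row
    gdp = {y: implied_gdp(rh_total[y], context["rh_gdp_share_percent"][y]) for y in (2010, 2012)}
    g_gdp = growth_percent(gdp[2010], gdp[2012], 0)
    check("implied_gdp_growth_2010_2012", g_gdp == 20, f"computed {g_gdp}, printed 20")

    return results
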