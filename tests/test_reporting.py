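"""Indicators and 'amount (share)' table rendering."""

from decimal import Decimal
from fractions import Fraction

import pytest

from rhsa import (
    DemographyParams,
    build_agent_table,
    build_function_table,
    build_provider_table,
    growth_percent,
    implied_gdp,
    per_capita_indicators,
    share_percent,
    summarize,
)
from rhsa.reporting import format_percent_cell, render_share_table, round_half_away

F = Fraction


class TestSharePercent:
    @pytest.mark.parametrize(
        "part, whole, decimals, expected",
        [
            (31_292, 41_163, 0, Decimal("76")),   # health ministry share, 2012
            (0, 5, 1, Decimal("0.0")),
            (18_239, 35_463, 1, Decimal("51.4")),  # PHC clinics share, 2010
            (14_404, 31_292, 1, Decimal("46.0")),  # PBF subsidies share, 2012
        ],
    )
    def test_published_parentheticals_are_rounded_shares(self, part, whole, decimals, expected):
        assert share_percent(part, whole, decimals) == expected

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            share_percent(1, 0)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(Decimal("0.5"), 0) == 1
        assert round_half_away(Decimal("-0.5"), 0) == -1
        assert round_half_away(F(145, 1000) * 100, 0) == 15


class TestGrowthPercent:
    def test_published_growth_rates(self):
        assert growth_percent(35_463, 41_163, 0) == 16
        assert growth_percent(40_110, 41_163, 1) == Decimal("2.6")

    def test_no_change_is_zero(self):
        assert growth_percent(7, 7, 3) == 0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            growth_percent(0, 5)


class TestPerCapita:
    def test_zero_spending_gives_zero_indicators(self):
        demo = DemographyParams({2012: 1e6})
        assert per_capita_indicators(0, 2012, demo) == (0, 0)

    def test_denominators_are_fixed_population_fractions(self):
        demo = DemographyParams({2012: 10_000_000}, wcba_fraction=0.237, delivery_fraction=0.05)
        per_wcba, per_delivery = per_capita_indicators(47_400_000, 2012, demo)
        assert per_wcba == pytest.approx(20.0)
        assert per_delivery == pytest.approx(47_400_000 / 500_000)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            per_capita_indicators(1, 2012, DemographyParams({2012: 0.0}))


class TestImpliedGdp:
    def test_full_share_returns_the_total(self):
        assert implied_gdp(123, 100) == 123

    def test_division_example(self):
        got = implied_gdp(41_163, F("0.57"))
        assert got == F(41_163 * 10_000, 57)
        assert float(got) == pytest.approx(7_221_579, abs=1)

    def test_nonpositive_share_rejected(self):
        with pytest.raises(ValueError):
            implied_gdp(1, 0)


class TestTableRendering:
    def test_single_row_cube_renders_amount_at_100_percent(self, scenario):
        from rhsa import allocate_earmarked

        cube = allocate_earmarked(scenario.ledger[:1])
        tbl = build_agent_table(cube)
        assert len(tbl) == 1
        assert tbl.iloc[0, 0].endswith("(100)")

    def test_percent_cells_drop_trailing_zero_decimal(self):
        assert format_percent_cell(Decimal("76.0")) == "76"
        assert format_percent_cell(Decimal("76.2")) == "76.2"
        assert format_percent_cell(Decimal("0.1")) == "0.1"

    def test_published_agent_marginals_render_published_cells(self):
        """Thousands + parenthetical shares reproduce the published table."""
        from rhsa import printed

        rows = {k: {y: v * 1000 for y, v in d.items()} for k, d in printed.AGENT_TABLE.items()}
        totals = {y: v * 1000 for y, v in printed.RH_TOTAL.items()}
        tbl = render_share_table(rows, totals, printed.YEARS, thousands=True)
        assert tbl.loc["MSPLS", "2010"] == "25,874 (73)"
        assert tbl.loc["MSPLS", "2011"] == "30,565 (76.2)"
        assert tbl.loc["MFP", "2012"] == "7,909 (19.2)"
        assert tbl.loc["MNS", "2011"] == "55 (0.1)"

    def test_rendered_shares_are_self_consistent(self, pipeline_cube):
        """Recomputing each parenthetical from the rendered amounts agrees."""
        for build in (build_agent_table, build_provider_table, build_function_table):
            tbl = build(pipeline_cube, thousands=True)
            for year in tbl.columns:
                amounts, pcts = {}, {}
                for label in tbl.index:
                    amt_s, pct_s = tbl.loc[label, year].rsplit(" (", 1)
                    amounts[label] = int(amt_s.replace(",", ""))
                    pcts[label] = pct_s.rstrip(")")
                total = sum(amounts.values())
                for label in tbl.index:
                    if amounts[label] == 0:
                        continue
                    recomputed = format_percent_cell(share_percent(amounts[label], total, 1))
                    # rendered amounts are themselves rounded; allow 0.1pp
                    assert abs(Decimal(recomputed) - Decimal(pcts[label])) <= Decimal("0.1")

    def test_table_column_sums_equal_the_rh_total(self, pipeline_cube):
        for build in (build_agent_table, build_function_table):
            tbl = build(pipeline_cube, thousands=True)
            for year in tbl.columns:
                total = sum(
                    int(cell.rsplit(" (", 1)[0].replace(",", "")) for cell in tbl[year]
                )
                rh = float(pipeline_cube.rh_total(int(year))) / 1000
                assert abs(total - rh) <= len(tbl)  # per-row rounding only


class TestSummarize:
    def test_growth_and_shares_from_cube(self, pipeline_cube, scenario):
        health = {y: pipeline_cube.total(y) * 2 for y in pipeline_cube.years()}
        ind = summarize(pipeline_cube, scenario.demography, health)
        years = pipeline_cube.years()
        assert set(ind.rh_total) == set(years)
        assert all(0 <= float(v) <= 100 for v in ind.rh_share_of_health.values())
        assert (years[0], years[-1]) in ind.growth
        d = ind.to_dict()
        assert "rh_share_of_health_percent" in d and "per_wcba" in d
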