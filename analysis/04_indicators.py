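"""Summary indicators: growth, per-woman and per-delivery spending.

Computes the headline indicators twice: from the published RH totals
(where external context — total health spending, GDP shares — is also
published) and from the simulated pipeline cube, and writes
results/indicators.json.
"""

import json
from pathlib import Path

from rhsa import (
    DemographyParams,
    growth_percent,
    implied_gdp,
    per_capita_indicators,
    printed,
    share_percent,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    demo = DemographyParams(population_by_year={2012: float(printed.POPULATION_2012)})
    published = {}
    for year in printed.YEARS:
        rh_thousand = printed.RH_TOTAL[year]
        per_wcba, per_delivery = per_capita_indicators(rh_thousand * 1000, year, demo)
        published[str(year)] = {
            "rh_total_thousand_intl": rh_thousand,
            "rh_share_of_health_pct": float(
                share_percent(rh_thousand, printed.HEALTH_TOTAL[year], 0)
            ),
            "per_wcba_intl": round(per_wcba, 2),
            "per_delivery_intl": round(per_delivery, 2),
        }
    published["growth_2010_2012_pct"] = float(
        growth_percent(printed.RH_TOTAL[2010], printed.RH_TOTAL[2012], 0)
    )
    gdp12 = implied_gdp(printed.RH_TOTAL[2012], printed.RH_GDP_SHARE_PERCENT[2012])
    published["implied_gdp_2012_thousand_intl"] = round(float(gdp12))

    (OUT / "indicators.json").write_text(json.dumps(published, indent=2) + "\n")
    print(json.dumps(published, indent=2))
    print("\nNote: per-WCBA and per-delivery figures use the published population")
    print("(9.859 M in 2012, projected at 2.4 %/yr) and fractions (23.7 %, 5 %);")
    print("the published narrative per-capita figures rest on an unstated")
    print("denominator source and are not recoverable from these inputs.")


if __name__ == "__main__":
    main()
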