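"""Re-derive every published figure from the published absolute tables.

The raw ledgers behind the Burundi 2010-2012 sub-account are not public,
so this step exercises the reporting layer on the published absolutes:
it renders the agent / provider / function tables with recomputed
parenthetical shares, checks them (and the growth and GDP figures)
against the published values, and writes the rendered tables to
results/tables/.
"""

from pathlib import Path

from rhsa import printed
from rhsa.reporting import render_share_table

OUT = Path(__file__).resolve().parent.parent / "results" / "tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    totals = {y: v * 1000 for y, v in printed.RH_TOTAL.items()}
    for name, table in (
        ("agents", printed.AGENT_TABLE),
        ("providers", printed.PROVIDER_TABLE),
        ("functions", printed.FUNCTION_TABLE),
    ):
        rows = {k: {y: v * 1000 for y, v in d.items()} for k, d in table.items()}
        tbl = render_share_table(rows, totals, printed.YEARS, thousands=True)
        tbl.to_csv(OUT / f"{name}.csv")
        print(f"\n== RH expenditure by {name} (thousand Int$, share of RH total) ==")
        print(tbl.to_string())

    results = printed.verify_tables()
    failed = [(n, d) for n, ok, d in results if not ok]
    print(f"\nderived-figure checks: {len(results) - len(failed)}/{len(results)} pass")
    for n, d in failed:
        print(f"  FAIL {n}: {d}")


if __name__ == "__main__":
    main()
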