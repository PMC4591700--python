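"""Generate the synthetic Burundi-like study inputs.

Writes a complete input set — ledger, service volumes, unit costs,
monetary/demography config — plus the construction ground truth into
results/scenario/.  The scenario is calibrated to the published setting:
the 2012 facility share matrix as target, a 47/37/16 facility-tier
split, and a 2 % / 82 % / 16 % earmarked / facility / administrative
budget mix.
"""

from pathlib import Path

from rhsa import compute_share_matrix, generate_scenario
from rhsa.taxonomy import FACILITY_TIERS

OUT = Path(__file__).resolve().parent.parent / "results" / "scenario"
SEED = 1


def main() -> None:
    scenario = generate_scenario(seed=SEED)
    scenario.write(OUT)
    print(f"scenario seed={SEED}: {len(scenario.ledger)} ledger entries, "
          f"{len(scenario.volumes)} volume records -> {OUT}")

    sm = compute_share_matrix(scenario.volumes, scenario.costs, scenario.config.base_year)
    print("implied facility share matrix (base year, % of tier total):")
    for tier in FACILITY_TIERS:
        row = sm.row(tier)
        cells = ", ".join(f"{f.value}={float(s) * 100:.1f}" for f, s in row.items())
        print(f"  {tier.value}: {cells}")
    err = max(
        abs(sm.row(t)[f] - s)
        for t, row in scenario.config.target_shares.shares.items()
        for f, s in row.items()
    )
    print(f"max calibration error vs target: {float(err):.2e} (back-solved volumes)")


if __name__ == "__main__":
    main()
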