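# rhsa — reproductive-health sub-account estimation

`rhsa` implements the reproductive-health sub-account (RHS), the
adaptation of National Health Accounts used to track public spending on
reproductive health in settings with weak routine financial data. It was
built around the Burundi 2010–2012 public-sector sub-account: six public
financing agents, a three-tier facility system (PHC clinics,
primary/secondary referral hospitals, third-tier hospitals) plus national
administration, and three health functions (maternal health, family
planning, other), with administrative spending reported separately.

It is aimed at health-economics and health-financing analysts who need to
turn a public budget ledger plus routine service statistics into an
agent × provider × function expenditure matrix, with every apportionment
step explicit, exact and auditable.

## The method

A budget line is allocated by one of three strategies according to its
earmark class:

1. **Earmarked pass-through.** A line explicitly targeted at a
   reproductive-health function (e.g. the National Reproductive Health
   Programme, contraceptive procurement) passes through unchanged to that
   function's cell.
2. **Facility distribution factors.** Non-earmarked funds sent to health
   providers (salaries, buildings, PBF subsidies) are apportioned by a
   bottom-up expenditure model. Each tier's total expenditure is

   `T_h = Σ_s V_hs · C_s`

   where `V_hs` is the annual volume of service `s` at tier `h` and `C_s`
   its unit cost. Funds split across tiers in proportion to `T_h`, and
   within a tier across functions by the tier's expenditure-share row
   `share(h, f) = Σ_{s∈f} V_hs·C_s / T_h`.
3. **Administrative apportionment.** National-level overhead is split by
   the distribution factor `direct RH expenditure / total direct
   expenditure`, computed from the cells strategies 1–2 already filled;
   the non-RH remainder stays in the cube as a residual so totals
   conserve.

All amounts are first inflated to constant base-year local currency with
a chained annual-inflation product and then divided by a PPP factor to
give international dollars. The engine works in exact rational
arithmetic, so "allocated funds sum to the ledger total" is an identity,
not a tolerance.

Because the raw Burundian ledgers are not public, the package also ships
(a) the published 2010–2012 result tables as an in-code fixture whose
every derived figure (shares, growth rates, column sums, implied-GDP
ratios) is recomputed from the published absolutes, and (b) a synthetic
ledger generator that back-solves service volumes from a target share
matrix and emits a ground-truth allocation cube for end-to-end testing.

## Worked example

```python
from rhsa import generate_scenario, run_pipeline, conservation_audit, summarize

s = generate_scenario(seed=1)                      # calibrated synthetic inputs
cube = run_pipeline(s.ledger, s.volumes, s.costs, s.ctx)

print(cube.cells == s.ground_truth.cells)          # True  (exact recovery)
residuals = conservation_audit(cube, s.ledger, s.ctx)
print(all(v == 0 for v in residuals.values()))     # True  (exact conservation)
print(round(float(cube.rh_total(2012)) / 1000))    # 72476 (thousand Int$)
```

The same pipeline is available from the shell:

```sh
rhsa simulate --seed 1 --out scenario/
rhsa run --config scenario/run_config.yaml   # writes cube, tables, indicators
rhsa validate --ledger scenario/ledger.csv
rhsa verify-tables                           # 85/85 checks passed
```

`rhsa verify-tables` recomputes every derived figure of the published
tables from the published absolutes; on the bundled fixture it prints
`85/85 checks passed`. Numbered drivers under `analysis/` narrate the
full study: simulate inputs, allocate, re-derive the published tables,
and compute the summary indicators (e.g. RH spending grew 16 % from
2010 to 2012 and reached 19 % of public health spending; family-planning
spending nearly tripled; PBF subsidies reached 46 % of health-ministry
RH spending in 2012).

## Layout

- `src/rhsa/` — the library: `taxonomy` and `records` (classifications,
  CSV I/O, validation), `monetary` (deflation + PPP), `allocation` (the
  three strategies and the cube), `reporting` (indicators and tables),
  `synthetic` (generator with ground truth), `printed` (published-table
  fixture), `cli`.
- `analysis/` — numbered drivers over the library.
- `tests/` — unit, property and acceptance tests.
- `docs/methods.md` — modelling assumptions, parameter choices,
  numerical conventions and limitations.
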