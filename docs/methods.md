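# Methods

## Scope and accounting frame

The package estimates *public* expenditure on reproductive health by
financing agent, health provider and health function, following the
sub-account adaptation of National Health Accounts. The accounting unit
is the financing agent — the institution that receives funds and decides
how they are spent — not the ultimate source of the money; non-earmarked
budget support that a government allocates at its own discretion is
therefore treated as public expenditure. Donor-managed and private
(household, firm) financing are out of scope, as is sub-national
disaggregation.

Reproductive health covers two service functions: maternal health
(ante-/postpartum care, delivery attendance, related prevention and
treatment) and family planning (counselling, contraceptive provision,
sterilization). Administrative and leadership activities at the health
ministry and the civil-service insurance fund are RH-attributable in
proportion to a distribution factor and are reported on separate rows.
Other RH-adjacent areas (reproductive cancers, fertility treatment,
adolescent sexual education, gender-based violence) are excluded.

Entries are booked on a cash basis: a transaction belongs to the year it
was paid out, so commodities procured for one year but paid the next are
counted in the payment year. Years are independent slices; no flow
spans years.

## Allocation model

Let `x` be a ledger entry with amount `a` (nominal local currency),
year `y`, agent `g`, and earmark class `k`.

**Strategy 1 (earmarked).** If `k = EARMARKED_RH`, the full adjusted
amount is booked to the entry's hinted function at its hinted tier. When
the ledger does not name a tier, a configurable default applies;
the default is `PHC_CLINIC`, reflecting that vertical RH-program spending
in this setting flows predominantly through primary care. This is an
assumption, surfaced as a single config knob.

**Strategy 2 (facility distribution factors).** Facility tier `h` has a
bottom-up expenditure estimate `T_h = Σ_s V_hs · C_s` over the service
volumes `V_hs` (annual statistical directories) and unit costs `C_s`
(micro-costing study). Non-earmarked facility funds split across tiers
with weights `T_h / Σ T` — unless the entry carries a tier hint, in
which case all weight is on that tier — and within a tier across the
three service functions by the share row `share(h,f)`. Salaries and
similar agent-level lines are split by the same tier weights rather than
payroll location; this is the package's choice where the procedure is
underdetermined, and it is overridable per entry via tier hints. A tier
with `T_h = 0` has an undefined share row; directing funds at it raises
an error rather than silently allocating zero, because it signals
inconsistent inputs.

**Strategy 3 (administrative apportionment).** Direct expenditure is
everything strategies 1–2 booked to facility tiers (funds used directly
for service provision). The distribution factor is
`φ = direct RH / direct total`; each national-administration entry
contributes `a·φ` to its agent's admin function (`ADMIN_MFP` for the
insurance fund, `ADMIN_MOH` otherwise) and `a·(1−φ)` to a non-RH
residual cell. Admin cells never enter the factor's denominator.

**Monetary adjustment.** Amounts are inflated to base-year prices by
`Π_{y' = y+1..base} (1 + r_{y'})`, where the rate recorded for year `y'`
moves prices from `y'−1` to `y'` — one fixed convention, not an option,
so that two runs can never disagree silently — then divided by the
base-year PPP factor. Only forward adjustment is supported. Both steps
are linear, so conservation can be audited at any currency stage.

## Numerical conventions

The engine computes in `fractions.Fraction`. Ledger money is parsed as
`decimal.Decimal` and lifted to rationals; binary floats appear only in
the pandas/report layer. Rational arithmetic is what makes the invariants
*identities*: tier-weight vectors and share rows sum to exactly 1, the
cube (including the admin residual) sums to exactly the adjusted ledger
total per agent-year, and the conservation audit reports exact residuals.
Rounding — half away from zero — happens once, at table rendering:
amounts to thousands, shares to one decimal (integer-percent tables to
zero), with a trailing `.0` dropped, matching the published presentation.
Self-consistency of rendered tables (shares recomputed from rendered
amounts) holds to the printed precision; provider-column sums may differ
from the RH total by ±1 thousand, as in the published tables themselves.

The published facility share matrix has three cells where the printed
"other health" residual contradicts row normalization by 0.1 (the
source's own footnote attributes this to rounding); the fixture stores
the maternal and family-planning components as printed and derives the
residual as their complement.

## Synthetic data generator

The generator emulates the study conditions rather than sampling freely:

- three study years with the last as the monetary base year;
- a public ledger of ~1.2·10^11 francs in the first year, growing 23 %
  nominally per year so that real spending rises over the period as in
  the published setting; inflation defaults 9.6 % and 18 % for the two
  later years and a PPP factor of 500 francs per international dollar
  (round values in the range of the national series for those years —
  the study does not print the ones it used);
- budget mix 2 % earmarked / 82 % facility / 16 % national
  administration, matching the published admin-to-total proportions, with
  the earmarked slice small as in the category breakdown;
- facility totals split 47/37/16 across the three tiers and the
  published 2012 share matrix as the calibration target;
- agent weights dominated by the health ministry (~70 %) and the
  civil-service insurance fund (~21 %).

Volumes are **back-solved**: target tier totals times target shares give
per-function spending, divided equally over that function's services and
by unit cost to give integer counts. Construction, not sampling, is what
yields an exact ground truth; the only randomness is how class totals
split into ledger lines (integer splits that conserve totals to the
franc) and an optional log-normal perturbation of volumes for robustness
experiments. Count rounding leaves a calibration error below 10⁻⁸
relative — well under the 10⁻⁶ the tests require. One seeded
pseudo-random stream drives everything; the seed is written into every
output file header, and identical (config, seed) pairs produce
byte-identical files.

The ground truth is built per entry with the implied distribution
factors, which is also the brute-force oracle the aggregate engine is
tested against. What passing these tests shows is that the engine
implements the allocation arithmetic exactly; they cannot show that real
ledgers are classified correctly, that unit costs are accurate, or that
the earmark partition is clean — the binding limitations of any real
sub-account exercise.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `wcba_fraction` | 0.237 | — | census share of women 15–49 |
| `delivery_fraction` | 0.05 | — | expected deliveries / population |
| `annual_growth` | 0.024 | /yr | population projection between census years |
| `ppp_factor` | 500 (synthetic) | BIF per Int$ | base-year conversion |
| `earmarked_default_tier` | `PHC_CLINIC` | — | tier for earmarked lines without a hint |
| `tier_split` | 0.47/0.37/0.16 | — | facility-total proportions in the study setting |

Per-capita indicators use the 2012 population (9.859 M) projected to
other years at 2.4 %/yr. Note the published narrative per-woman and
per-delivery figures are **not** recoverable from the published
population, fractions and totals (the arithmetic here gives ≈ $17.6 per
WCBA and ≈ $75 per delivery for 2010 against the narrative's ≈ $20 and
$83.2); the denominator source behind the narrative figures is unstated,
so these two numbers are documented as non-reproducible and the
operation is validated on synthetic arithmetic instead.

## Known limitations

- Point estimates only: no uncertainty propagation on unit costs or
  volumes (the perturbation harness quantifies sensitivity, not
  confidence).
- The allocation requires a pre-resolved, disjoint ledger; overlapping
  budget categories must be netted out upstream, and the validator flags
  only structural problems, not double counting it cannot see.
- The service catalogue behind the share matrix is a configurable
  stand-in; the published work does not enumerate its exact service
  list.
- Tier attribution of earmarked program spending and the salary split
  across tiers are assumptions (documented above), not data.
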