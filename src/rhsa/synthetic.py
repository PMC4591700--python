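"""Synthetic Burundi-like sub-account inputs with exact ground truth.

Generates a complete, internally consistent input set — service volumes,
unit costs, a public ledger with the three earmark classes, and a
monetary context — together with the allocation cube those inputs imply,
so the whole pipeline can be tested end-to-end without any external data.

Volumes are *back-solved* from target facility expenditure shares and
fixed unit costs (deterministic construction, not sampling), so the
implied share matrix matches the requested one to well under 1e-6; the
pseudo-random stream only shapes how budget totals split into ledger
lines.  The ground-truth cube is computed per ledger entry from the
implied distribution factors, which doubles as the brute-force oracle
for the aggregate engine.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from decimal import Decimal
from fractions import Fraction
from pathlib import Path

import yaml

from .allocation import AllocationCube, ShareMatrix
from .monetary import MonetaryContext, adjust, as_fraction
from .records import (
    DemographyParams,
    LedgerEntry,
    ServiceVolumeRecord,
    UnitCost,
    write_costs_csv,
    write_ledger_csv,
    write_volumes_csv,
)
from .taxonomy import (
    Earmark,
    FACILITY_TIERS,
    Function,
    SERVICE_FUNCTIONS,
    Tier,
)
from . import printed


class SyntheticConfigError(ValueError):
    pass


#: Default service catalogue: unit costs in nominal Burundian francs per
#: service, in the range of published micro-costing work (an antenatal
#: visit on the order of a thousand francs, an institutional delivery a
#: few thousand, an inpatient day the most expensive).
DEFAULT_CATALOGUE = (
    UnitCost("anc_visit", Decimal(1200), Function.MATERNAL_HEALTH),
    UnitCost("delivery", Decimal(6000), Function.MATERNAL_HEALTH),
    UnitCost("fp_consultation", Decimal(800), Function.FAMILY_PLANNING),
    UnitCost("contraceptive_cycle", Decimal(400), Function.FAMILY_PLANNING),
    UnitCost("opd_visit", Decimal(1500), Function.OTHER_HEALTH),
    UnitCost("inpatient_day", Decimal(9000), Function.OTHER_HEALTH),
)

#: Baseline agent weights for non-earmarked funds (hundredths): the health
#: ministry dominates, social security second, the employer ministries and
#: the solidarity ministry marginal.
DEFAULT_AGENT_WEIGHTS = {
    "MSPLS": Fraction(70, 100),
    "MFP": Fraction(21, 100),
    "MHER": Fraction(2, 100),
    "MPS": Fraction(2, 100),
    "MDN": Fraction(4, 100),
    "MNS": Fraction(1, 100),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions the generator emulates.

    Defaults mirror the published Burundi 2010-2012 setting: three study
    years; a public health budget on the order of 1.2e11 francs a year;
    facility totals split roughly half / 40 % / 16 % across the three
    tiers; the published 2012 facility share matrix as the calibration
    target; a small earmarked slice, a dominant facility slice and a
    ~16 % national-administration slice.
    """

    start_year: int = 2010
    n_years: int = 3
    scale: int = 120_000_000_000  # nominal BIF in the first year, public ledger total
    annual_nominal_growth: Fraction = Fraction(23, 100)  # nominal budget growth/yr
    facility_scale: int = 300_000_000_000  # all-source facility expenditure
    tier_split: dict[Tier, Fraction] = field(
        default_factory=lambda: {
            Tier.PHC_CLINIC: Fraction(47, 100),
            Tier.REF_HOSPITAL_1_2: Fraction(37, 100),
            Tier.REF_HOSPITAL_3: Fraction(16, 100),
        }
    )
    target_shares: ShareMatrix = field(default_factory=lambda: printed.share_matrix(2012))
    earmark_mix: dict[Earmark, Fraction] = field(
        default_factory=lambda: {
            Earmark.EARMARKED_RH: Fraction(2, 100),
            Earmark.FACILITY_NONEARMARKED: Fraction(82, 100),
            Earmark.ADMIN_NATIONAL: Fraction(16, 100),
        }
    )
    catalogue: tuple[UnitCost, ...] = DEFAULT_CATALOGUE
    agent_weights: dict[str, Fraction] = field(
        default_factory=lambda: dict(DEFAULT_AGENT_WEIGHTS)
    )
    ppp_factor: Fraction = Fraction(500)
    inflation: dict[int, Fraction] = field(
        default_factory=lambda: {2011: Fraction("0.096"), 2012: Fraction("0.18")}
    )
    earmarked_default_tier: Tier = Tier.PHC_CLINIC

    def __post_init__(self):
        for name, vec in (("tier_split", self.tier_split), ("earmark_mix", self.earmark_mix)):
            if sum(vec.values(), Fraction(0)) != 1:
                raise SyntheticConfigError(f"{name} fractions must sum to 1")
        by_fn: dict[Function, int] = {f: 0 for f in SERVICE_FUNCTIONS}
        for c in self.catalogue:
            by_fn[c.function] += 1
        for tier, row in self.target_shares.shares.items():
            for f, s in row.items():
                if s > 0 and by_fn.get(f, 0) == 0:
                    raise SyntheticConfigError(
                        f"target share for {f.value} in {tier.value} is positive "
                        "but no service in the catalogue maps to it"
                    )

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    @property
    def base_year(self) -> int:
        return self.years[-1]

    def monetary_context(self) -> MonetaryContext:
        return MonetaryContext(
            base_year=self.base_year,
            ppp_factor=self.ppp_factor,
            inflation_by_year=self.inflation,
        )


@dataclass
class SyntheticScenario:
    """Generated inputs plus the allocation cube they imply."""

    seed: int
    config: SyntheticConfig
    ledger: list[LedgerEntry]
    volumes: list[ServiceVolumeRecord]
    costs: list[UnitCost]
    ctx: MonetaryContext
    ground_truth: AllocationCube
    demography: DemographyParams

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = f"seed={self.seed}"
        write_ledger_csv(self.ledger, outdir / "ledger.csv", header_comment=stamp)
        write_volumes_csv(self.volumes, outdir / "volumes.csv", header_comment=stamp)
        write_costs_csv(self.costs, outdir / "unit_costs.csv", header_comment=stamp)
        with open(outdir / "ground_truth.csv", "w", encoding="utf-8") as fh:
            fh.write(f"# {stamp}\n")
            fh.write("year,agent_id,tier,function,amount_intl_exact\n")
            for (y, g, t, f), a in sorted(
                self.ground_truth.cells.items(),
                key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value, kv[0][3].value),
            ):
                fh.write(f"{y},{g},{t.value},{f.value},{a}\n")
        cfg = {
            "seed": self.seed,
            "monetary": {
                "base_year": self.ctx.base_year,
                "ppp_factor": str(self.ctx.ppp_factor),
                "inflation": {y: str(r) for y, r in sorted(self.ctx.inflation_by_year.items())},
            },
            "demography": {
                "population_by_year": self.demography.population_by_year,
                "wcba_fraction": self.demography.wcba_fraction,
                "delivery_fraction": self.demography.delivery_fraction,
                "annual_growth": self.demography.annual_growth,
            },
            "earmarked_default_tier": self.config.earmarked_default_tier.value,
        }
        with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)
        run_cfg = {
            "ledger": "ledger.csv",
            "volumes": "volumes.csv",
            "unit_costs": "unit_costs.csv",
            "earmarked_default_tier": self.config.earmarked_default_tier.value,
            "monetary": cfg["monetary"],
            "demography": cfg["demography"],
            "output_dir": "out",
        }
        with open(outdir / "run_config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(run_cfg, fh, sort_keys=False)


def read_ground_truth_csv(path) -> AllocationCube:
    cube = AllocationCube()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("year,"):
                continue
            y, g, t, f, a = line.strip().split(",")
            cube.add(int(y), g, Tier(t), Function(f), Fraction(a))
    return cube


# ---------------------------------------------------------------------------
# integer splitting helpers (exact: parts always sum to the total)


def _split_weighted(total: int, weights: dict[str, Fraction]) -> dict[str, int]:
    """Largest-remainder apportionment of an integer total by weights."""
    wsum = sum(weights.values(), Fraction(0))
    raw = {k: total * w / wsum for k, w in weights.items()}
    parts = {k: int(v) for k, v in raw.items()}  # floor for nonneg
    rem = total - sum(parts.values())
    order = sorted(weights, key=lambda k: (raw[k] - parts[k], k), reverse=True)
    for k in order[:rem]:
        parts[k] += 1
    return parts


def _split_random(rng: random.Random, total: int, k: int) -> list[int]:
    """Split an integer into k non-negative parts uniformly at random."""
    if k == 1:
        return [total]
    cuts = sorted(rng.randint(0, total) for _ in range(k - 1))
    bounds = [0, *cuts, total]
    return [bounds[i + 1] - bounds[i] for i in range(k)]


def _jittered_weights(rng: random.Random, base: dict[str, Fraction]) -> dict[str, Fraction]:
    out = {}
    for k, w in base.items():
        jitter = Fraction(Decimal(repr(round(0.8 + 0.4 * rng.random(), 6))))
        out[k] = w * jitter
    return out


# ---------------------------------------------------------------------------
# construction


def _back_solve_volumes(
    config: SyntheticConfig, year: int
) -> list[ServiceVolumeRecord]:
    """Choose integer service counts whose volume x cost composition hits
    the target tier totals and share matrix (up to sub-ppm count rounding)."""
    volumes: list[ServiceVolumeRecord] = []
    by_fn: dict[Function, list[UnitCost]] = {f: [] for f in SERVICE_FUNCTIONS}
    for c in config.catalogue:
        by_fn[c.function].append(c)
    for tier in FACILITY_TIERS:
        tier_total = Fraction(config.facility_scale) * config.tier_split.get(tier, Fraction(0))
        if tier_total == 0:
            continue
        row = config.target_shares.row(tier)
        for fn in SERVICE_FUNCTIONS:
            fn_spend = tier_total * row.get(fn, Fraction(0))
            services = by_fn[fn]
            if fn_spend == 0:
                continue
            per_service = fn_spend / len(services)
            for svc in services:
                count = round(per_service / as_fraction(svc.cost))
                volumes.append(ServiceVolumeRecord(year, tier, svc.service_code, count))
    return volumes


def _implied_factors(volumes, costs, year):
    """Exact tier weights and share rows implied by the emitted inputs."""
    cost_by_code = {c.service_code: c for c in costs}
    spend: dict[Tier, dict[Function, Fraction]] = {
        t: {f: Fraction(0) for f in SERVICE_FUNCTIONS} for t in FACILITY_TIERS
    }
    for v in volumes:
        if v.year != year:
            continue
        c = cost_by_code[v.service_code]
        spend[v.tier][c.function] += Fraction(v.volume) * as_fraction(c.cost)
    totals = {t: sum(row.values(), Fraction(0)) for t, row in spend.items()}
    grand = sum(totals.values(), Fraction(0))
    weights = {t: totals[t] / grand for t in totals if grand > 0}
    shares = {
        t: {f: spend[t][f] / totals[t] for f in SERVICE_FUNCTIONS}
        for t in totals
        if totals[t] > 0
    }
    return weights, shares


def _ledger_for_year(
    rng: random.Random, config: SyntheticConfig, year: int
) -> list[LedgerEntry]:
    # nominal budget outgrows inflation, so real spending rises over the study
    budget = round(
        config.scale * (1 + config.annual_nominal_growth) ** (year - config.start_year)
    )
    mix_parts = _split_weighted(budget, {e.value: w for e, w in config.earmark_mix.items()})
    entries: list[LedgerEntry] = []

    # earmarked RH lines: vertical-program and commodity spending (MSPLS)
    e_total = mix_parts[Earmark.EARMARKED_RH.value]
    nrhp_mh, nrhp_fp, contraceptives = _split_random(rng, e_total, 3)
    for amount, fn, cat in (
        (nrhp_mh, Function.MATERNAL_HEALTH, "National Reproductive Health Programme"),
        (nrhp_fp, Function.FAMILY_PLANNING, "National Reproductive Health Programme"),
        (contraceptives, Function.FAMILY_PLANNING, "Contraceptives"),
    ):
        if amount > 0:
            entries.append(
                LedgerEntry(year, "MSPLS", Decimal(amount), Earmark.EARMARKED_RH,
                            function_hint=fn, category=cat)
            )

    # non-earmarked facility funds across the six agents
    f_total = mix_parts[Earmark.FACILITY_NONEARMARKED.value]
    agent_parts = _split_weighted(f_total, _jittered_weights(rng, config.agent_weights))
    for agent_id, amount in agent_parts.items():
        if amount == 0:
            continue
        if agent_id == "MSPLS":
            pbf, endowment, salaries = _split_random(rng, amount, 3)
            if pbf:
                entries.append(
                    LedgerEntry(year, agent_id, Decimal(pbf),
                                Earmark.FACILITY_NONEARMARKED, category="PBF subsidies")
                )
            if endowment:
                # hospital endowment goes to referral hospitals by name
                entries.append(
                    LedgerEntry(year, agent_id, Decimal(endowment),
                                Earmark.FACILITY_NONEARMARKED,
                                tier_hint=Tier.REF_HOSPITAL_1_2,
                                category="Hospital endowment")
                )
            if salaries:
                entries.append(
                    LedgerEntry(year, agent_id, Decimal(salaries),
                                Earmark.FACILITY_NONEARMARKED, category="Salaries and wages")
                )
        else:
            entries.append(
                LedgerEntry(year, agent_id, Decimal(amount),
                            Earmark.FACILITY_NONEARMARKED, category="Health service funding")
            )

    # national administrative overhead (health ministry + social security)
    a_total = mix_parts[Earmark.ADMIN_NATIONAL.value]
    moh, mfp = _split_random(rng, a_total, 2)
    if moh:
        entries.append(
            LedgerEntry(year, "MSPLS", Decimal(moh), Earmark.ADMIN_NATIONAL,
                        category="Central administration")
        )
    if mfp:
        entries.append(
            LedgerEntry(year, "MFP", Decimal(mfp), Earmark.ADMIN_NATIONAL,
                        category="Social security administration")
        )
    return entries


def _construct_ground_truth(
    config: SyntheticConfig,
    ledger: list[LedgerEntry],
    volumes: list[ServiceVolumeRecord],
    costs: list[UnitCost],
    ctx: MonetaryContext,
) -> AllocationCube:
    """Per-entry allocation with the implied distribution factors.

    This is the construction oracle: each ledger line is allocated on its
    own, in exact rational arithmetic, and the cells summed.
    """
    cube = AllocationCube()
    for year in sorted({e.year for e in ledger}):
        weights, shares = _implied_factors(volumes, costs, year)
        year_entries = [e for e in ledger if e.year == year]
        admin_entries = []
        direct_rh = Fraction(0)
        direct_total = Fraction(0)
        for e in year_entries:
            adj = adjust(e.amount, e.year, ctx)
            if e.earmark is Earmark.EARMARKED_RH:
                tier = e.tier_hint or config.earmarked_default_tier
                cube.add(year, e.agent_id, tier, e.function_hint, adj, e.category)
                direct_rh += adj
                direct_total += adj
            elif e.earmark is Earmark.FACILITY_NONEARMARKED:
                w = {e.tier_hint: Fraction(1)} if e.tier_hint else weights
                for tier, wt in w.items():
                    for fn, s in shares[tier].items():
                        part = adj * wt * s
                        if part:
                            cube.add(year, e.agent_id, tier, fn, part, e.category)
                        if fn is not Function.OTHER_HEALTH:
                            direct_rh += part
                direct_total += adj
            else:
                admin_entries.append((e, adj))
        factor = direct_rh / direct_total if direct_total else Fraction(0)
        for e, adj in admin_entries:
            fn = Function.ADMIN_MFP if e.agent_id == "MFP" else Function.ADMIN_MOH
            if factor:
                cube.add(year, e.agent_id, Tier.ADMIN_NATIONAL, fn, adj * factor, e.category)
            if factor != 1:
                cube.add(year, e.agent_id, Tier.ADMIN_NATIONAL, Function.OTHER_HEALTH,
                         adj * (1 - factor), e.category)
    return cube


def generate_scenario(
    config: SyntheticConfig | None = None, seed: int = 1
) -> SyntheticScenario:
    """Generate a full input set and its ground-truth allocation cube.

    Reproducible: one pseudo-random stream, seeded here, drives every
    random choice; the same (config, seed) pair always yields identical
    records and byte-identical files.
    """
    config = config or SyntheticConfig()
    rng = random.Random(seed)
    ctx = config.monetary_context()
    costs = list(config.catalogue)
    volumes: list[ServiceVolumeRecord] = []
    ledger: list[LedgerEntry] = []
    for year in config.years:
        volumes.extend(_back_solve_volumes(config, year))
        ledger.extend(_ledger_for_year(rng, config, year))
    ground_truth = _construct_ground_truth(config, ledger, volumes, costs, ctx)
    demography = DemographyParams(
        population_by_year={config.base_year: float(printed.POPULATION_2012)}
    )
    return SyntheticScenario(
        seed=seed, config=config, ledger=ledger, volumes=volumes, costs=costs,
        ctx=ctx, ground_truth=ground_truth, demography=demography,
    )


def perturb_scenario(
    scenario: SyntheticScenario, noise_level: float, seed: int | None = None
) -> SyntheticScenario:
    """Multiply service volumes by log-normal noise and rebuild ground truth.

    ``noise_level`` is the standard deviation of log-volume; 0 returns an
    identical scenario.  The ground truth is reconstructed from the
    perturbed volumes, so recovery stays exact — the perturbation models
    measurement variation in the service statistics, shifting the implied
    distribution factors.
    """
    if noise_level < 0:
        raise SyntheticConfigError(f"noise_level must be >= 0, got {noise_level}")
    if noise_level == 0:
        return scenario
    rng = random.Random(scenario.seed + 1 if seed is None else seed)
    volumes = [
        replace(v, volume=max(0, round(v.volume * rng.lognormvariate(0.0, noise_level))))
        for v in scenario.volumes
    ]
    ground_truth = _construct_ground_truth(
        scenario.config, scenario.ledger, volumes, scenario.costs, scenario.ctx
    )
    return replace(scenario, volumes=volumes, ground_truth=ground_truth)
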