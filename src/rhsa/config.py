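"""Run configuration: one YAML file naming inputs and study parameters.

Layout::

    ledger: ledger.csv            # paths, relative to the config file
    volumes: volumes.csv
    unit_costs: unit_costs.csv
    taxonomy: taxonomy.yaml       # optional; default six-agency taxonomy
    earmarked_default_tier: PHC_CLINIC
    monetary:
      base_year: 2012
      ppp_factor: "500"
      inflation: {2011: "0.096", 2012: "0.18"}
    demography:
      population_by_year: {2012: 9859000}
      wcba_fraction: 0.237
      delivery_fraction: 0.05
      annual_growth: 0.024
    health_totals: {2010: ..., 2011: ..., 2012: ...}   # optional context
    output_dir: out/

Every referenced file is checked for existence before any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import yaml

from .monetary import MonetaryContext
from .records import DemographyParams
from .taxonomy import AgentTaxonomy, Tier, load_taxonomy


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    ledger_path: Path
    volumes_path: Path
    unit_costs_path: Path
    ctx: MonetaryContext
    demography: DemographyParams
    taxonomy: AgentTaxonomy = field(default_factory=AgentTaxonomy)
    earmarked_default_tier: Tier = Tier.PHC_CLINIC
    health_totals: dict[int, Fraction] | None = None
    output_dir: Path = Path("out")


def load_run_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    base = path.parent

    def input_path(key):
        if key not in doc:
            raise ConfigError(f"config is missing required key {key!r}")
        p = base / doc[key]
        if not p.exists():
            raise ConfigError(f"input file for {key!r} not found: {p}")
        return p

    mon = doc.get("monetary") or {}
    try:
        ctx = MonetaryContext(
            base_year=int(mon["base_year"]),
            ppp_factor=Fraction(str(mon["ppp_factor"])),
            inflation_by_year={int(y): Fraction(str(r)) for y, r in (mon.get("inflation") or {}).items()},
        )
    except KeyError as exc:
        raise ConfigError(f"monetary section is missing {exc}") from exc

    demo_doc = doc.get("demography") or {}
    demography = DemographyParams(
        population_by_year={int(y): float(p) for y, p in (demo_doc.get("population_by_year") or {}).items()},
        wcba_fraction=float(demo_doc.get("wcba_fraction", 0.237)),
        delivery_fraction=float(demo_doc.get("delivery_fraction", 0.05)),
        annual_growth=float(demo_doc.get("annual_growth", 0.024)),
    )

    taxonomy = AgentTaxonomy()
    if "taxonomy" in doc:
        taxonomy = load_taxonomy(input_path("taxonomy"))

    health_totals = None
    if "health_totals" in doc:
        health_totals = {int(y): Fraction(str(v)) for y, v in doc["health_totals"].items()}

    return RunConfig(
        ledger_path=input_path("ledger"),
        volumes_path=input_path("volumes"),
        unit_costs_path=input_path("unit_costs"),
        ctx=ctx,
        demography=demography,
        taxonomy=taxonomy,
        earmarked_default_tier=Tier(doc.get("earmarked_default_tier", "PHC_CLINIC")),
        health_totals=health_totals,
        output_dir=base / doc.get("output_dir", "out"),
    )
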