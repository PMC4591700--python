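"""Constant-currency deflation and PPP conversion.

Nominal local-currency amounts are first inflated to base-year price
levels with a chained annual-inflation product, then divided by a
purchasing-power-parity factor to express them in international dollars.
Both steps are linear, so conservation checks commute with the currency
stage.

Convention: the inflation rate recorded for year *y* moves money from
year *y-1* prices to year *y* prices.  Only forward adjustment (study
years at or before the base year) is supported; there is exactly one
convention so that results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from numbers import Rational


def as_fraction(x) -> Fraction:
    """Lift ints, Decimals, strings, Fractions (and floats) to Fraction."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, (int, Rational, Decimal)):
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(Decimal(x))
    if isinstance(x, float):
        return Fraction(Decimal(repr(x)))
    raise TypeError(f"cannot interpret {x!r} as an exact number")


class MonetaryConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MonetaryContext:
    """Inflation series, base year and PPP factor for one study.

    ``inflation_by_year[y]`` is the annual rate (e.g. ``0.18`` for 18 %)
    taking prices from year ``y-1`` to year ``y``; ``ppp_factor`` is
    local-currency units per international dollar in the base year.
    """

    base_year: int
    ppp_factor: Fraction
    inflation_by_year: dict[int, Fraction] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "ppp_factor", as_fraction(self.ppp_factor))
        object.__setattr__(
            self,
            "inflation_by_year",
            {int(y): as_fraction(r) for y, r in self.inflation_by_year.items()},
        )
        if self.ppp_factor <= 0:
            raise MonetaryConfigError(f"ppp_factor must be > 0, got {self.ppp_factor}")
        for y, r in self.inflation_by_year.items():
            if r <= -1:
                raise MonetaryConfigError(f"inflation rate for {y} must be > -1, got {r}")


def deflate_to_base(amount, year: int, ctx: MonetaryContext) -> Fraction:
    """Express a nominal amount of ``year`` in constant base-year prices.

    Multiplies by ``prod(1 + r_y)`` over every year in
    ``(year, base_year]``; identity when ``year == base_year``.
    """
    amount = as_fraction(amount)
    if year > ctx.base_year:
        raise MonetaryConfigError(
            f"year {year} is after base year {ctx.base_year}; only forward "
            "adjustment to the base year is supported"
        )
    factor = Fraction(1)
    for y in range(year + 1, ctx.base_year + 1):
        if y not in ctx.inflation_by_year:
            raise MonetaryConfigError(f"missing inflation rate for year {y}")
        factor *= 1 + ctx.inflation_by_year[y]
    return amount * factor


def to_intl_dollars(amount_constant, ctx: MonetaryContext) -> Fraction:
    """Convert a constant base-year local-currency amount to international $."""
    return as_fraction(amount_constant) / ctx.ppp_factor


def adjust(amount, year: int, ctx: MonetaryContext) -> Fraction:
    """Full pipeline: nominal -> constant base-year -> international dollars."""
    return to_intl_dollars(deflate_to_base(amount, year, ctx), ctx)
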