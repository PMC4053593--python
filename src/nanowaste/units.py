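"""Unit-tagged quantities, interval envelopes and Monte-Carlo propagation.

This is the numeric substrate of the assessment framework.  All mass flows are
carried as nonnegative ``[low, high]`` envelopes (:class:`UncertainInterval`),
mirroring how the source literature reports parameters as ranges
(e.g. a market penetration of "0.2-0.5").  A closed, hand-defined unit
registry covers exactly the units that occur in nanowaste inventories:
masses, an annual mass rate, market counts, mass-per-mass concentrations and
one volume-per-mass by-product rate.  No general dimensional algebra is
attempted: concentrations normalise internally to a dimensionless mass
fraction (g/g), which is all the product-chain model needs.

Dimensionless fractions (market penetration, end-of-life factors, treatment
shares) are carried with ``unit=None``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UNIT_REGISTRY",
    "Quantity",
    "UncertainInterval",
    "SampleSummary",
    "UnitError",
    "convert_unit",
    "interval",
    "interval_mul",
    "interval_product",
    "propagate_mc",
]


class UnitError(ValueError):
    """Raised for unknown units or conversions across dimensions."""


# unit -> (dimension, factor to the dimension's base unit)
# bases: mass = Mg, mass_rate = Mg/year, count = units,
#        mass_fraction = g/g, volume_per_mass = L/g, volume = L
UNIT_REGISTRY: dict[str, tuple[str, float]] = {
    "Mg": ("mass", 1.0),
    "kg": ("mass", 1e-3),
    "g": ("mass", 1e-6),
    "mg": ("mass", 1e-9),
    "Mg/year": ("mass_rate", 1.0),
    "units": ("count", 1.0),
    "units/year": ("count_rate", 1.0),
    "mg/kg": ("mass_fraction", 1e-6),
    "g/kg": ("mass_fraction", 1e-3),
    "kg/Mg": ("mass_fraction", 1e-3),
    "g/Mg": ("mass_fraction", 1e-6),
    "percent": ("mass_fraction", 1e-2),
    "g/g": ("mass_fraction", 1.0),
    "L/g": ("volume_per_mass", 1.0),
    "L": ("volume", 1.0),
}

#: dimensions whose units express a mass-per-mass concentration
FRACTION_DIMENSION = "mass_fraction"


def _lookup(unit: str) -> tuple[str, float]:
    try:
        return UNIT_REGISTRY[unit]
    except KeyError:
        known = ", ".join(sorted(UNIT_REGISTRY))
        raise UnitError(f"unknown unit {unit!r}; registry: {known}") from None


def dimension_of(unit: str) -> str:
    """Return the dimension name of a registry unit."""
    return _lookup(unit)[0]


@dataclass(frozen=True)
class Quantity:
    """A nonnegative scalar tagged with a registry unit.

    Dimensionless fractions are plain floats elsewhere in the package and are
    never wrapped in a Quantity.
    """

    value: float
    unit: str

    def __post_init__(self) -> None:
        _lookup(self.unit)
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(
                f"Quantity value must be finite and nonnegative, got {self.value!r}"
            )

    def to(self, target_unit: str) -> "Quantity":
        return convert_unit(self, target_unit)


def convert_unit(q: Quantity, target_unit: str) -> Quantity:
    """Convert ``q`` to another unit of the same dimension.

    Raises :class:`UnitError` naming both units on a dimension mismatch.
    """
    dim_from, f_from = _lookup(q.unit)
    dim_to, f_to = _lookup(target_unit)
    if dim_from != dim_to:
        raise UnitError(
            f"cannot convert {q.unit!r} ({dim_from}) to {target_unit!r} ({dim_to})"
        )
    return Quantity(q.value * f_from / f_to, target_unit)


@dataclass(frozen=True)
class UncertainInterval:
    """A ``[low, high]`` envelope with a unit tag and literature provenance.

    ``unit=None`` marks a dimensionless fraction.  A point value is the
    degenerate interval ``low == high``.
    """

    low: float
    high: float
    unit: str | None = None
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.unit is not None:
            _lookup(self.unit)
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("interval endpoints must be finite")
        if self.low < 0 or self.high < 0:
            raise ValueError(
                f"interval endpoints must be nonnegative, got [{self.low}, {self.high}]"
            )
        if self.low > self.high:
            raise ValueError(f"interval low {self.low} exceeds high {self.high}")
        object.__setattr__(self, "sources", tuple(self.sources))

    @property
    def is_point(self) -> bool:
        return self.low == self.high

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    def to(self, target_unit: str) -> "UncertainInterval":
        """Express a dimensional interval in another unit of the same dimension."""
        if self.unit is None:
            raise UnitError("cannot convert a dimensionless interval")
        lo = convert_unit(Quantity(self.low, self.unit), target_unit).value
        hi = convert_unit(Quantity(self.high, self.unit), target_unit).value
        return replace(self, low=lo, high=hi, unit=target_unit)

    def as_fraction(self) -> "UncertainInterval":
        """Normalise a concentration interval to a dimensionless mass fraction."""
        if self.unit is None:
            return self
        dim, factor = _lookup(self.unit)
        if dim != FRACTION_DIMENSION:
            raise UnitError(f"{self.unit!r} is not a concentration unit")
        return UncertainInterval(
            self.low * factor, self.high * factor, None, self.sources
        )


def interval(
    value: float | Sequence[float],
    unit: str | None = None,
    sources: Iterable[str] = (),
) -> UncertainInterval:
    """Build an interval from a scalar (point value) or a ``[low, high]`` pair."""
    if isinstance(value, (int, float)):
        lo = hi = float(value)
    else:
        vals = list(value)
        if len(vals) != 2:
            raise ValueError(f"expected a scalar or [low, high], got {value!r}")
        lo, hi = float(vals[0]), float(vals[1])
    return UncertainInterval(lo, hi, unit, tuple(sources))


def _compose_units(a: str | None, b: str | None) -> tuple[str | None, float, float]:
    """Resolve the unit of a product and per-operand scale factors.

    Supported compositions: dimensionless x dimensionless, dimensional x
    dimensionless, and (mass | mass rate) x mass-per-mass concentration (the
    concentration is normalised to g/g so the mass unit is preserved).
    """
    if a is None and b is None:
        return None, 1.0, 1.0
    if b is None:
        return a, 1.0, 1.0
    if a is None:
        return b, 1.0, 1.0
    dim_a, _ = _lookup(a)
    dim_b, factor_b = _lookup(b)
    if dim_b == FRACTION_DIMENSION and dim_a in ("mass", "mass_rate"):
        return a, 1.0, factor_b
    if dim_a == FRACTION_DIMENSION and dim_b in ("mass", "mass_rate"):
        _, factor_a = _lookup(a)
        return b, factor_a, 1.0
    raise UnitError(f"cannot multiply units {a!r} and {b!r}")


def interval_mul(a: UncertainInterval, b: UncertainInterval) -> UncertainInterval:
    """Endpoint product of two nonnegative envelopes.

    For nonnegative factors the product over the boxed domain attains its
    extrema at ``(low, low)`` and ``(high, high)``, so the envelope is exactly
    ``[a.low * b.low, a.high * b.high]``.  Provenance is concatenated.
    """
    unit, fa, fb = _compose_units(a.unit, b.unit)
    return UncertainInterval(
        a.low * fa * b.low * fb,
        a.high * fa * b.high * fb,
        unit,
        a.sources + b.sources,
    )


def interval_product(factors: Iterable[UncertainInterval]) -> UncertainInterval:
    """Fold :func:`interval_mul` over a chain of factors (at least one)."""
    factors = list(factors)
    if not factors:
        raise ValueError("interval_product requires at least one factor")
    out = factors[0]
    for f in factors[1:]:
        out = interval_mul(out, f)
    return out


@dataclass(frozen=True)
class SampleSummary:
    """Summary statistics of a seeded Monte-Carlo propagation."""

    n: int
    seed: int
    unit: str | None
    min: float
    max: float
    mean: float
    q05: float
    q50: float
    q95: float
    samples: np.ndarray = field(repr=False, compare=False, default=None)


def propagate_mc(
    params: Sequence[UncertainInterval],
    n: int,
    seed: int,
    keep_samples: bool = False,
) -> SampleSummary:
    """Monte-Carlo propagation of a monotone product chain.

    Each parameter is sampled independently and uniformly on its interval (the
    literature supplies ranges only, no distributional shape), the per-draw
    product is formed, and summary statistics are returned.  Deterministic for
    a fixed ``seed``; for a nonnegative product chain every sample lies inside
    the analytic envelope of :func:`interval_product`.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    params = list(params)
    if not params:
        raise ValueError("propagate_mc requires at least one parameter")
    # resolve the composed unit (and fraction normalisation) exactly as the
    # analytic envelope does
    envelope = interval_product(params)
    rng = np.random.default_rng(seed)
    prod = np.ones(n)
    for p in params:
        frac = p.as_fraction() if p.unit and dimension_of(p.unit) == FRACTION_DIMENSION else p
        prod *= rng.uniform(frac.low, frac.high, size=n)
    q05, q50, q95 = np.quantile(prod, [0.05, 0.50, 0.95])
    return SampleSummary(
        n=n,
        seed=seed,
        unit=envelope.unit,
        min=float(prod.min()),
        max=float(prod.max()),
        mean=float(prod.mean()),
        q05=float(q05),
        q50=float(q50),
        q95=float(q95),
        samples=prod if keep_samples else None,
    )
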