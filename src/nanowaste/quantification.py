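"""Step-1 quantification of nanowaste and contained ENM masses.

The market-product analysis estimates, for a nanoproduct type *p* assessed in
year *t*:

    X_t,p  = x_{t-rt,p} * F_pen,p * F_eol,p          (nanowaste mass, Mg/year)
    NM_t,p = X_t,p * C_NM,p * F_NM,p                 (contained ENM mass)

where ``x`` is the production put on the market ``rt`` (retention-time) years
earlier, ``F_pen`` the market penetration of the nano-enabled variant,
``F_eol`` the fraction of virgin product reaching end of life, ``C_NM`` the
ENM concentration in the product and ``F_NM`` the fraction of the initially
contained ENM still present at end of life (after use-phase losses such as
washing).  All parameters are interval envelopes; the chain is evaluated with
endpoint interval arithmetic and full precision is kept internally — rounding
happens only in the reporting layer.

Two production helpers mirror how market figures are assembled: compound
back-casting/forecasting of a production mass between calendar years, and
conversion of market unit counts (e.g. cosmetics bottles) into an annual mass.
Manufacturing by-product masses are estimated from published generation rates
(waste mass or volume per mass of ENM product).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .inventory import MatrixDescriptor
from .fate import TreatmentShares
from .units import (
    Quantity,
    UncertainInterval,
    UnitError,
    convert_unit,
    dimension_of,
    interval_mul,
)

__all__ = [
    "ProductionRecord",
    "NanoproductProfile",
    "QuantificationResult",
    "ByproductRate",
    "TraceStep",
    "backcast_production",
    "market_units_to_mass",
    "eol_nanowaste_mass",
    "enm_mass_in_nanowaste",
    "enm_used_in_manufacture",
    "byproduct_mass",
    "quantify",
    "load_byproduct_rates",
    "packaged_byproduct_rates",
]


def _check_fraction(name: str, iv: UncertainInterval) -> UncertainInterval:
    if iv.unit is not None:
        raise ValueError(f"{name} must be a dimensionless fraction interval")
    if iv.high > 1.0:
        raise ValueError(
            f"{name} must lie within [0, 1], got [{iv.low}, {iv.high}]"
        )
    return iv


@dataclass(frozen=True)
class ProductionRecord:
    """Market production input for one product, as mass or as unit counts."""

    product_id: str
    reference_year: int
    production_mass: UncertainInterval | None = None  # Mg/year
    market_units: UncertainInterval | None = None  # units/year
    unit_mass: Quantity | None = None  # mass of one unit
    sector_fraction: float = 1.0
    annual_growth: float = 0.0  # fractional growth per year

    def __post_init__(self) -> None:
        if (self.production_mass is None) == (self.market_units is None):
            raise ValueError(
                f"{self.product_id!r}: exactly one of production_mass / "
                "market_units must be populated"
            )
        if not 0.0 <= self.sector_fraction <= 1.0:
            raise ValueError(
                f"{self.product_id!r}: sector_fraction must lie in [0, 1], "
                f"got {self.sector_fraction}"
            )
        if self.annual_growth < -1.0:
            raise ValueError(
                f"{self.product_id!r}: annual_growth must be >= -1, "
                f"got {self.annual_growth}"
            )


@dataclass(frozen=True)
class NanoproductProfile:
    """Full Step-1 parameter set plus matrix and treatment descriptors."""

    product_id: str
    enm_type: str
    retention_time_years: int
    market_penetration: UncertainInterval  # F_pen
    eol_fraction: UncertainInterval  # F_eol
    enm_concentration: UncertainInterval  # C_NM, concentration unit
    enm_eol_fraction: UncertainInterval  # F_NM
    matrix: tuple[MatrixDescriptor, ...] = ()
    treatment_shares: TreatmentShares | None = None
    retention_time_range: tuple[int, int] | None = None  # documentation only
    exposure_factors: dict | None = None

    def __post_init__(self) -> None:
        if self.retention_time_years < 0:
            raise ValueError("retention_time_years must be >= 0")
        _check_fraction("market_penetration", self.market_penetration)
        _check_fraction("eol_fraction", self.eol_fraction)
        _check_fraction("enm_eol_fraction", self.enm_eol_fraction)
        if self.enm_concentration.unit is None:
            raise ValueError("enm_concentration must carry a concentration unit")
        if dimension_of(self.enm_concentration.unit) != "mass_fraction":
            raise ValueError(
                f"enm_concentration unit {self.enm_concentration.unit!r} is "
                "not a mass-per-mass concentration"
            )
        object.__setattr__(self, "matrix", tuple(self.matrix))


@dataclass(frozen=True)
class TraceStep:
    """One provenance record: operation, inputs, output."""

    operation: str
    inputs: dict
    output: UncertainInterval


@dataclass(frozen=True)
class QuantificationResult:
    """Nanowaste mass X_t,p and ENM mass NM_t,p with a provenance trace."""

    product_id: str
    assessment_year: int
    eol_mass: UncertainInterval  # X_t,p, Mg/year
    enm_mass: UncertainInterval  # NM_t,p, Mg/year
    trace: tuple[TraceStep, ...] = ()

    def __post_init__(self) -> None:
        if not self.trace:
            raise ValueError("trace must be non-empty")
        object.__setattr__(self, "trace", tuple(self.trace))


@dataclass(frozen=True)
class ByproductRate:
    """Published manufacturing-waste generation rate per mass of ENM product."""

    enm_type: str
    waste_name: str
    rate: UncertainInterval  # unit g/g or L/g
    process_note: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.rate.unit is None or dimension_of(self.rate.unit) not in (
            "mass_fraction",
            "volume_per_mass",
        ):
            raise ValueError(
                f"by-product rate unit must be mass- or volume-per-mass, "
                f"got {self.rate.unit!r}"
            )


def backcast_production(
    rec: ProductionRecord, target_year: int
) -> UncertainInterval:
    """Project a production mass to another calendar year by compound growth.

    ``mass * (1 + annual_growth) ** (target_year - reference_year)``; the
    exponent may be negative (back-casting an older figure forward is the
    common case, e.g. a 2004 polyester figure grown to 2005).
    """
    if rec.production_mass is None:
        raise ValueError(
            f"{rec.product_id!r} is a market-units record; convert with "
            "market_units_to_mass first"
        )
    factor = (1.0 + rec.annual_growth) ** (target_year - rec.reference_year)
    m = rec.production_mass
    return UncertainInterval(m.low * factor, m.high * factor, m.unit, m.sources)


def market_units_to_mass(rec: ProductionRecord) -> UncertainInterval:
    """Convert annual market unit counts to a mass flow in Mg/year.

    ``units * sector_fraction * unit_mass``, e.g. 547e6 cosmetics units of
    which 65.4 % are sun-protection items at 200 g each.
    """
    if rec.market_units is None:
        raise ValueError(f"{rec.product_id!r} has no market_units")
    if rec.unit_mass is None:
        raise ValueError(f"{rec.product_id!r}: unit_mass is required")
    per_unit_mg = convert_unit(rec.unit_mass, "Mg").value
    u = rec.market_units
    scale = rec.sector_fraction * per_unit_mg
    return UncertainInterval(
        u.low * scale, u.high * scale, "Mg/year", u.sources
    )


def eol_nanowaste_mass(
    profile: NanoproductProfile, production: UncertainInterval
) -> UncertainInterval:
    """Nanowaste mass: X = x * F_pen * F_eol (interval endpoints, Mg/year)."""
    return interval_mul(
        interval_mul(production, profile.market_penetration),
        profile.eol_fraction,
    )


def enm_mass_in_nanowaste(
    profile: NanoproductProfile, X: UncertainInterval
) -> UncertainInterval:
    """Contained ENM mass: NM = X * C_NM * F_NM (Mg/year).

    The concentration is normalised internally to a dimensionless mass
    fraction, so the result stays in the mass unit of ``X``.
    """
    return interval_mul(
        interval_mul(X, profile.enm_concentration.as_fraction()),
        profile.enm_eol_fraction,
    )


def enm_used_in_manufacture(
    production: UncertainInterval, enm_concentration: UncertainInterval
) -> UncertainInterval:
    """ENM mass entering manufacturing: production x concentration.

    No end-of-life factors apply; this is the upstream usage estimate
    (e.g. nanosilver consumed by textile production).
    """
    return interval_mul(production, enm_concentration.as_fraction())


def byproduct_mass(
    rate: ByproductRate, enm_production: Quantity
) -> UncertainInterval:
    """Manufacturing waste from an ENM production mass and a generation rate.

    A mass-per-mass rate yields waste mass in the production's own unit; a
    volume-per-mass rate (e.g. spent thiol solvent in L/g) yields litres.
    """
    dim = dimension_of(rate.rate.unit)
    if dim == "mass_fraction":
        r = rate.rate.to("g/g")
        return UncertainInterval(
            r.low * enm_production.value,
            r.high * enm_production.value,
            enm_production.unit,
            rate.rate.sources,
        )
    if dim == "volume_per_mass":
        grams = convert_unit(enm_production, "g").value
        r = rate.rate.to("L/g")
        return UncertainInterval(
            r.low * grams, r.high * grams, "L", rate.rate.sources
        )
    raise UnitError(f"incompatible by-product rate unit {rate.rate.unit!r}")


def load_byproduct_rates(path: str | Path) -> list[ByproductRate]:
    """Load a generation-rate table.

    Columns: ``waste_name, unit, rate_low, rate_high, enm_type, source,
    comment`` — one row per published manufacturing-waste generation rate.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"waste_name", "unit", "rate_low", "rate_high", "enm_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"by-product rate file {path} lacks columns {sorted(missing)}")
    rates = []
    for _, row in df.iterrows():
        rates.append(
            ByproductRate(
                enm_type=row["enm_type"].strip(),
                waste_name=row["waste_name"].strip(),
                rate=UncertainInterval(
                    float(row["rate_low"]),
                    float(row["rate_high"]),
                    row["unit"].strip(),
                    (str(row.get("source", "")).strip(),),
                ),
                process_note=str(row.get("comment", "")).strip(),
                source=str(row.get("source", "")).strip(),
            )
        )
    return rates


def packaged_byproduct_rates() -> list[ByproductRate]:
    """The manufacturing-waste generation rates shipped with the package."""
    with resources.as_file(
        resources.files("nanowaste.data") / "byproduct_rates.csv"
    ) as p:
        return load_byproduct_rates(p)


def quantify(
    profile: NanoproductProfile,
    production: UncertainInterval,
    assessment_year: int,
) -> QuantificationResult:
    """Run the full Step-1 chain and record a provenance trace."""
    X = eol_nanowaste_mass(profile, production)
    NM = enm_mass_in_nanowaste(profile, X)
    trace = (
        TraceStep(
            "eol_nanowaste_mass",
            {
                "production": production,
                "F_pen": profile.market_penetration,
                "F_eol": profile.eol_fraction,
            },
            X,
        ),
        TraceStep(
            "enm_mass_in_nanowaste",
            {
                "X": X,
                "C_NM": profile.enm_concentration,
                "F_NM": profile.enm_eol_fraction,
            },
            NM,
        ),
    )
    return QuantificationResult(
        product_id=profile.product_id,
        assessment_year=assessment_year,
        eol_mass=X,
        enm_mass=NM,
        trace=trace,
    )
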