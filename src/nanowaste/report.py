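"""Profile I/O, the end-to-end assessment pipeline and report rendering.

Profiles are YAML files whose keys mirror the framework's symbols
(``x_production``, ``retention_time_years``, ``F_pen``, ``F_eol``, ``C_NM``,
``F_NM``, ``treatment_shares``, ``exposure_factors``).  Every interval carries
its literature sources.  Validation errors name the offending field path and
value.

Internally the pipeline keeps full precision; display rounding (3 significant
figures by default, with an opt-in truncate-to-integer mode for matching
legacy truncated figures) happens only when rendering.  The machine-readable
report serialises losslessly to a plain dict and back.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import yaml

from . import __version__
from .exposure import ExposureFactors, ExposureLevel, ExposureRating, score_exposure
from .fate import (
    Compartment,
    ControlMeasure,
    FateRoute,
    FateRuleTables,
    RouteQualifier,
    TransformationProcess,
    TreatmentShares,
    TreatmentTechnology,
    allocate_to_treatments,
    packaged_rule_tables,
    release_routes,
)
from .inventory import MatrixDescriptor, NanostructureLocation
from .quantification import (
    NanoproductProfile,
    ProductionRecord,
    QuantificationResult,
    quantify,
)
from .units import Quantity, UncertainInterval, interval

__all__ = [
    "ProfileValidationError",
    "ProfileBundle",
    "AssessmentReport",
    "FixtureSpec",
    "load_profile",
    "bundle_from_dict",
    "packaged_profile",
    "packaged_profile_names",
    "assess",
    "report_from_dict",
    "render_report",
    "report_to_frame",
    "generate_fixtures",
    "round_sig",
    "truncate_int",
    "format_value",
    "format_interval",
]

PACKAGED_PROFILES = ("nanosilver_textile", "tio2_sunscreen", "cnt_racquet")


class ProfileValidationError(ValueError):
    """A profile field failed validation; carries the field path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_interval(
    node: Any, path: str, unit: str | None = None, fraction: bool = False
) -> UncertainInterval:
    """Accept a scalar, a [low, high] pair, or {value, unit, sources}."""
    sources: tuple[str, ...] = ()
    if isinstance(node, dict):
        extra = set(node) - {"value", "unit", "sources"}
        if extra:
            raise ProfileValidationError(path, f"unknown keys {sorted(extra)}")
        if "value" not in node:
            raise ProfileValidationError(path, "missing 'value'")
        sources = tuple(str(s) for s in node.get("sources", ()))
        unit = node.get("unit", unit)
        node = node["value"]
    try:
        iv = interval(node, unit=unit, sources=sources)
    except (TypeError, ValueError) as exc:
        raise ProfileValidationError(path, f"invalid interval {node!r}: {exc}") from exc
    if fraction:
        if iv.unit is not None:
            raise ProfileValidationError(path, "fractions must be dimensionless")
        if iv.high > 1.0:
            raise ProfileValidationError(
                path, f"fraction outside [0, 1]: [{iv.low}, {iv.high}]"
            )
    return iv


def _require(d: dict, key: str, path: str) -> Any:
    if key not in d:
        raise ProfileValidationError(f"{path}.{key}" if path else key, "missing field")
    return d[key]


@dataclass(frozen=True)
class ProfileBundle:
    """A fully validated profile plus its production record and controls."""

    profile: NanoproductProfile
    x_production: UncertainInterval  # Mg/year input to Eq. 1
    assessment_year: int
    production: ProductionRecord | None = None
    controls: dict[TreatmentTechnology, ControlMeasure] = field(default_factory=dict)
    manufacture_concentration: UncertainInterval | None = None
    config_hash: str = ""

    def to_dict(self) -> dict:
        return _bundle_to_dict(self)


def bundle_from_dict(d: dict, origin: str = "<dict>") -> ProfileBundle:
    """Validate a raw profile mapping into typed objects."""
    if not isinstance(d, dict) or not d:
        raise ProfileValidationError(origin, "profile must be a non-empty mapping")
    product_id = str(_require(d, "product_id", ""))
    enm_type = str(_require(d, "enm_type", ""))
    assessment_year = int(_require(d, "assessment_year", ""))

    x_production = _parse_interval(
        _require(d, "x_production", ""), "x_production", unit="Mg/year"
    )
    rt = int(_require(d, "retention_time_years", ""))
    f_pen = _parse_interval(_require(d, "F_pen", ""), "market_penetration", fraction=True)
    f_eol = _parse_interval(_require(d, "F_eol", ""), "F_eol", fraction=True)
    c_nm_node = _require(d, "C_NM", "")
    if not isinstance(c_nm_node, dict) or "unit" not in c_nm_node:
        raise ProfileValidationError("C_NM", "must be {value, unit, sources}")
    c_nm = _parse_interval(c_nm_node, "C_NM")
    f_nm = _parse_interval(_require(d, "F_NM", ""), "F_NM", fraction=True)

    matrix = []
    for i, m in enumerate(d.get("matrix", ())):
        p = f"matrix[{i}]"
        try:
            matrix.append(
                MatrixDescriptor(
                    material=str(_require(m, "material", p)),
                    state=_require(m, "state", p),
                    nanostructure_location=_require(m, "nanostructure", p),
                )
            )
        except ValueError as exc:
            raise ProfileValidationError(p, str(exc)) from exc

    shares_node = d.get("treatment_shares")
    try:
        shares = TreatmentShares(shares_node) if shares_node else None
    except ValueError as exc:
        raise ProfileValidationError("treatment_shares", str(exc)) from exc

    exposure_factors = d.get("exposure_factors")
    if exposure_factors is not None:
        try:
            ExposureFactors(**exposure_factors)
        except (TypeError, ValueError) as exc:
            raise ProfileValidationError("exposure_factors", str(exc)) from exc

    rt_range = d.get("retention_time_range")
    try:
        profile = NanoproductProfile(
            product_id=product_id,
            enm_type=enm_type,
            retention_time_years=rt,
            market_penetration=f_pen,
            eol_fraction=f_eol,
            enm_concentration=c_nm,
            enm_eol_fraction=f_nm,
            matrix=tuple(matrix),
            treatment_shares=shares,
            retention_time_range=tuple(rt_range) if rt_range else None,
            exposure_factors=exposure_factors,
        )
    except ValueError as exc:
        raise ProfileValidationError(product_id, str(exc)) from exc

    production = None
    if "production" in d:
        p = d["production"]
        basis = _require(p, "basis", "production")
        kwargs: dict[str, Any] = dict(
            product_id=product_id,
            reference_year=int(_require(p, "reference_year", "production")),
            annual_growth=float(p.get("annual_growth", 0.0)),
        )
        if basis == "production_mass":
            kwargs["production_mass"] = _parse_interval(
                {"value": _require(p, "value", "production"),
                 "sources": p.get("sources", ())},
                "production.value",
                unit=p.get("unit", "Mg/year"),
            )
        elif basis == "market_units":
            kwargs["market_units"] = _parse_interval(
                {"value": _require(p, "market_units", "production"),
                 "sources": p.get("sources", ())},
                "production.market_units",
                unit="units/year",
            )
            um = _require(p, "unit_mass", "production")
            kwargs["unit_mass"] = Quantity(float(um["value"]), um["unit"])
            kwargs["sector_fraction"] = float(p.get("sector_fraction", 1.0))
        else:
            raise ProfileValidationError(
                "production.basis", f"unknown basis {basis!r}"
            )
        try:
            production = ProductionRecord(**kwargs)
        except ValueError as exc:
            raise ProfileValidationError("production", str(exc)) from exc

    controls: dict[TreatmentTechnology, ControlMeasure] = {}
    for code, c in (d.get("controls") or {}).items():
        p = f"controls.{code}"
        try:
            controls[TreatmentTechnology(code)] = ControlMeasure(
                name=str(_require(c, "name", p)),
                effectiveness=_require(c, "effectiveness", p),
            )
        except ValueError as exc:
            raise ProfileValidationError(p, str(exc)) from exc

    manufacture = None
    if "C_NM_manufacture" in d:
        manufacture = _parse_interval(d["C_NM_manufacture"], "C_NM_manufacture")

    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return ProfileBundle(
        profile=profile,
        x_production=x_production,
        assessment_year=assessment_year,
        production=production,
        controls=controls,
        manufacture_concentration=manufacture,
        config_hash=hashlib.sha256(blob).hexdigest()[:16],
    )


def load_profile(path: str | Path) -> ProfileBundle:
    """Load and validate a YAML product profile."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ProfileValidationError(str(path), f"not valid YAML: {exc}") from exc
    if raw is None:
        raise ProfileValidationError(str(path), "file is empty")
    return bundle_from_dict(raw, origin=str(path))


def packaged_profile_names() -> tuple[str, ...]:
    return PACKAGED_PROFILES


def packaged_profile(name: str) -> ProfileBundle:
    """Load one of the packaged case-study profiles by name."""
    if name not in PACKAGED_PROFILES:
        raise KeyError(f"unknown packaged profile {name!r}; have {PACKAGED_PROFILES}")
    with resources.as_file(
        resources.files("nanowaste.data") / "profiles" / f"{name}.yaml"
    ) as p:
        return load_profile(p)


# ---------------------------------------------------------------------------
# display rounding


def round_sig(x: float, sigfigs: int = 3) -> float:
    """Round to ``sigfigs`` significant figures (half away from zero)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (sigfigs - 1 - exponent)
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)


def truncate_int(x: float) -> int:
    """Truncate toward zero (for matching legacy truncated table cells)."""
    return int(x)


def format_value(
    x: float, sigfigs: int = 3, truncate: bool = False
) -> str:
    """Human-readable value at ``sigfigs`` significant figures.

    Large/small magnitudes use engineering notation ("23.7 x 10^3"); values
    between 0.001 and 100,000 print plainly.  ``truncate=True`` drops the
    fractional part instead of rounding (flagged per cell, never global).
    """
    if truncate:
        return str(truncate_int(x))
    r = round_sig(x, sigfigs)
    if r == 0:
        return "0"
    exponent = math.floor(math.log10(abs(r)))
    if -3 <= exponent < 4:
        decimals = max(sigfigs - 1 - exponent, 0)
        return f"{r:.{decimals}f}"
    eng = 3 * math.floor(exponent / 3)
    mantissa = r / 10**eng
    decimals = max(sigfigs - 1 - (exponent - eng), 0)
    return f"{mantissa:.{decimals}f} × 10^{eng}"


def format_interval(
    iv: UncertainInterval, sigfigs: int = 3, truncate: bool = False
) -> str:
    unit = f" {iv.unit}" if iv.unit else ""
    if iv.is_point:
        return f"{format_value(iv.low, sigfigs, truncate)}{unit}"
    return (
        f"{format_value(iv.low, sigfigs, truncate)}-"
        f"{format_value(iv.high, sigfigs, truncate)}{unit}"
    )


# ---------------------------------------------------------------------------
# assessment pipeline


@dataclass(frozen=True)
class AssessmentReport:
    """Five-step assessment of one nanoproduct, full precision + display."""

    product_id: str
    enm_type: str
    assessment_year: int
    quantification: QuantificationResult
    allocation: dict[TreatmentTechnology, UncertainInterval]
    routes: dict[TreatmentTechnology, FateRoute]
    exposure: ExposureRating | None
    config_hash: str
    seed: int | None = None
    version: str = __version__

    def to_dict(self) -> dict:
        def iv(i: UncertainInterval) -> dict:
            return {
                "low": i.low,
                "high": i.high,
                "unit": i.unit,
                "sources": list(i.sources),
            }

        return {
            "product_id": self.product_id,
            "enm_type": self.enm_type,
            "assessment_year": self.assessment_year,
            "eol_mass": iv(self.quantification.eol_mass),
            "enm_mass": iv(self.quantification.enm_mass),
            "eol_mass_display": format_interval(self.quantification.eol_mass),
            "enm_mass_display": format_interval(self.quantification.enm_mass),
            "allocation": {t.value: iv(i) for t, i in self.allocation.items()},
            "routes": {
                t.value: {
                    "processes": sorted(p.value for p in r.processes),
                    "qualifiers": {
                        c.value: q.value for c, q in r.qualifiers.items()
                    },
                    "controls": (
                        {
                            "name": r.controls.name,
                            "effectiveness": r.controls.effectiveness.value,
                        }
                        if r.controls
                        else None
                    ),
                    "notes": list(r.notes),
                }
                for t, r in self.routes.items()
            },
            "exposure": (
                {
                    "level": self.exposure.level.value,
                    "mean_score": self.exposure.mean_score,
                    "rule": self.exposure.rule,
                    "factors": {
                        "amount_on_market": self.exposure.factors.amount_on_market.value,
                        "emission_magnitude": self.exposure.factors.emission_magnitude.value,
                        "receptor_proximity": self.exposure.factors.receptor_proximity.value,
                        "duration": self.exposure.factors.duration.value,
                        "notes": self.exposure.factors.notes,
                    },
                    "narrative": self.exposure.narrative,
                }
                if self.exposure
                else None
            ),
            "trace": [
                {
                    "operation": step.operation,
                    "inputs": {
                        k: iv(v) if isinstance(v, UncertainInterval) else v
                        for k, v in step.inputs.items()
                    },
                    "output": iv(step.output),
                }
                for step in self.quantification.trace
            ],
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
        }


def _iv_from_dict(d: dict) -> UncertainInterval:
    return UncertainInterval(
        d["low"], d["high"], d.get("unit"), tuple(d.get("sources", ()))
    )


def report_from_dict(d: dict) -> AssessmentReport:
    """Rebuild an :class:`AssessmentReport` from its serialised form."""
    from .quantification import TraceStep

    trace = tuple(
        TraceStep(
            operation=s["operation"],
            inputs={
                k: _iv_from_dict(v) if isinstance(v, dict) and "low" in v else v
                for k, v in s["inputs"].items()
            },
            output=_iv_from_dict(s["output"]),
        )
        for s in d["trace"]
    )
    quant = QuantificationResult(
        product_id=d["product_id"],
        assessment_year=d["assessment_year"],
        eol_mass=_iv_from_dict(d["eol_mass"]),
        enm_mass=_iv_from_dict(d["enm_mass"]),
        trace=trace,
    )
    routes = {}
    for code, r in d["routes"].items():
        t = TreatmentTechnology(code)
        controls = (
            ControlMeasure(r["controls"]["name"], r["controls"]["effectiveness"])
            if r.get("controls")
            else None
        )
        routes[t] = FateRoute(
            treatment=t,
            processes=frozenset(
                TransformationProcess(p) for p in r["processes"]
            ),
            qualifiers={
                Compartment(c): RouteQualifier(q)
                for c, q in r["qualifiers"].items()
            },
            controls=controls,
            notes=tuple(r.get("notes", ())),
        )
    exposure = None
    if d.get("exposure"):
        e = d["exposure"]
        factors = ExposureFactors(**e["factors"])
        exposure = ExposureRating(
            level=ExposureLevel(e["level"]),
            factors=factors,
            mean_score=e["mean_score"],
            rule=e["rule"],
            narrative=e.get("narrative", ""),
        )
    return AssessmentReport(
        product_id=d["product_id"],
        enm_type=d["enm_type"],
        assessment_year=d["assessment_year"],
        quantification=quant,
        allocation={
            TreatmentTechnology(t): _iv_from_dict(i)
            for t, i in d["allocation"].items()
        },
        routes=routes,
        exposure=exposure,
        config_hash=d["config_hash"],
        seed=d.get("seed"),
        version=d.get("version", __version__),
    )


def assess(
    bundle: ProfileBundle,
    tables: FateRuleTables | None = None,
    seed: int | None = None,
) -> AssessmentReport:
    """Run all five assessment steps on a validated profile.

    Quantifies X and NM (Step 1), allocates X across the treatment shares
    (Step 2), derives the release route per treatment from the dominant
    (first-listed) matrix component's nanostructure location and any declared
    control measures (Steps 3-4), and scores the packaged exposure factors
    (Step 5).
    """
    tables = tables or packaged_rule_tables()
    profile = bundle.profile
    result = quantify(profile, bundle.x_production, bundle.assessment_year)

    allocation: dict[TreatmentTechnology, UncertainInterval] = {}
    routes: dict[TreatmentTechnology, FateRoute] = {}
    if profile.treatment_shares is not None:
        allocation = allocate_to_treatments(result.eol_mass, profile.treatment_shares)
        location = (
            profile.matrix[0].nanostructure_location
            if profile.matrix
            else NanostructureLocation.SUSPENDED_IN_SOLID
        )
        for treatment in profile.treatment_shares.shares:
            routes[treatment] = release_routes(
                treatment,
                location,
                controls=bundle.controls.get(treatment),
                tables=tables,
            )

    rating = None
    if profile.exposure_factors:
        factors = ExposureFactors(**profile.exposure_factors)
        rating = score_exposure(factors, narrative=factors.notes)

    return AssessmentReport(
        product_id=profile.product_id,
        enm_type=profile.enm_type,
        assessment_year=bundle.assessment_year,
        quantification=result,
        allocation=allocation,
        routes=routes,
        exposure=rating,
        config_hash=bundle.config_hash,
        seed=seed,
    )


def render_report(report: AssessmentReport, sigfigs: int = 3) -> str:
    """Render a human-readable plain-text report."""
    lines = [
        f"Assessment of {report.product_id} ({report.enm_type}), "
        f"year {report.assessment_year}",
        f"  nanowaste mass X:  {format_interval(report.quantification.eol_mass, sigfigs)}",
        f"  contained ENM NM:  {format_interval(report.quantification.enm_mass, sigfigs)}",
    ]
    for t in sorted(report.allocation, key=lambda t: t.value):
        mass = report.allocation[t]
        route = report.routes[t]
        quals = ", ".join(
            f"{c.value}={route.qualifiers[c].value}"
            for c in sorted(route.qualifiers, key=lambda c: c.value)
        )
        procs = ", ".join(sorted(p.value for p in route.processes)) or "none"
        lines.append(
            f"  {t.value}: {format_interval(mass, sigfigs)}"
            f"  [processes: {procs}; release: {quals or 'none'}]"
        )
    if report.exposure:
        f = report.exposure.factors
        lines.append(
            f"  exposure: {report.exposure.level.value.upper()} "
            f"(mean {report.exposure.mean_score:.2f}; amount={f.amount_on_market.value}, "
            f"emission={f.emission_magnitude.value}, "
            f"proximity={f.receptor_proximity.value}, duration={f.duration.value})"
        )
    lines.append(f"  config {report.config_hash}, nanowaste {report.version}")
    return "\n".join(lines)


def report_to_frame(reports: Iterable[AssessmentReport]):
    """Tabulate reports as a pandas DataFrame (one row per product)."""
    import pandas as pd

    rows = []
    for r in reports:
        rows.append(
            {
                "product_id": r.product_id,
                "enm_type": r.enm_type,
                "assessment_year": r.assessment_year,
                "X_low_Mg": r.quantification.eol_mass.low,
                "X_high_Mg": r.quantification.eol_mass.high,
                "NM_low_Mg": r.quantification.enm_mass.low,
                "NM_high_Mg": r.quantification.enm_mass.high,
                "exposure_level": r.exposure.level.value if r.exposure else None,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic fixtures


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for generating synthetic, schema-valid product profiles."""

    n_profiles: int
    seed: int
    production_range_mg: tuple[float, float] = (1e2, 1e7)
    concentration_range_mg_per_kg: tuple[float, float] = (1.0, 1e5)
    max_retention_years: int = 10

    def __post_init__(self) -> None:
        if self.n_profiles < 1:
            raise ValueError("n_profiles must be >= 1")


def _random_sub_interval(rng: np.random.Generator, lo: float, hi: float) -> list[float]:
    a, b = sorted(rng.uniform(lo, hi, size=2).tolist())
    return [a, b]


def generate_fixtures(spec: FixtureSpec) -> list[dict]:
    """Deterministically generate random profile mappings.

    Every generated mapping passes :func:`bundle_from_dict` validation:
    fraction intervals stay inside [0, 1], treatment shares sum to one and
    enum fields draw from the closed vocabularies.
    """
    rng = np.random.default_rng(spec.seed)
    locations = [l.value for l in NanostructureLocation]
    levels = [l.value for l in ExposureLevel]
    treatments = [t.value for t in TreatmentTechnology if t.value != "COLLECTION"]
    out = []
    for i in range(spec.n_profiles):
        n_shares = int(rng.integers(1, 4))
        chosen = rng.choice(treatments, size=n_shares, replace=False)
        weights = rng.dirichlet(np.ones(n_shares))
        # repair the last share so the sum is exactly 1.0
        weights[-1] = max(0.0, 1.0 - float(weights[:-1].sum()))
        d = {
            "product_id": f"synthetic_{spec.seed}_{i}",
            "enm_type": str(rng.choice(["Ag", "TiO2", "CNT", "ZnO"])),
            "assessment_year": 2011,
            "x_production": {
                "value": round(float(rng.uniform(*spec.production_range_mg)), 3),
                "unit": "Mg/year",
                "sources": ["synthetic fixture"],
            },
            "retention_time_years": int(rng.integers(0, spec.max_retention_years + 1)),
            "F_pen": {"value": _random_sub_interval(rng, 0.0, 1.0)},
            "F_eol": {"value": _random_sub_interval(rng, 0.0, 1.0)},
            "C_NM": {
                "value": _random_sub_interval(
                    rng, *spec.concentration_range_mg_per_kg
                ),
                "unit": "mg/kg",
                "sources": ["synthetic fixture"],
            },
            "F_NM": {"value": _random_sub_interval(rng, 0.0, 1.0)},
            "matrix": [
                {
                    "material": "synthetic matrix",
                    "state": str(rng.choice(["solid", "liquid"])),
                    "nanostructure": str(rng.choice(locations)),
                }
            ],
            "treatment_shares": {
                str(t): float(w) for t, w in zip(chosen, weights)
            },
            "exposure_factors": {
                "amount_on_market": str(rng.choice(levels)),
                "emission_magnitude": str(rng.choice(levels)),
                "receptor_proximity": str(rng.choice(levels)),
                "duration": str(rng.choice(levels)),
            },
        }
        out.append(d)
    return out


def _bundle_to_dict(bundle: ProfileBundle) -> dict:
    """Serialise a bundle back to the profile-mapping form (lossy on layout,
    lossless on content)."""
    p = bundle.profile

    def iv(i: UncertainInterval) -> dict:
        d: dict[str, Any] = {"value": [i.low, i.high]}
        if i.unit:
            d["unit"] = i.unit
        if i.sources:
            d["sources"] = list(i.sources)
        return d

    d: dict[str, Any] = {
        "product_id": p.product_id,
        "enm_type": p.enm_type,
        "assessment_year": bundle.assessment_year,
        "x_production": iv(bundle.x_production),
        "retention_time_years": p.retention_time_years,
        "F_pen": iv(p.market_penetration),
        "F_eol": iv(p.eol_fraction),
        "C_NM": iv(p.enm_concentration),
        "F_NM": iv(p.enm_eol_fraction),
        "matrix": [
            {
                "material": m.material,
                "state": m.state.value,
                "nanostructure": m.nanostructure_location.value,
            }
            for m in p.matrix
        ],
    }
    if p.treatment_shares:
        d["treatment_shares"] = {
            t.value: s for t, s in p.treatment_shares.items()
        }
    if p.exposure_factors:
        d["exposure_factors"] = dict(p.exposure_factors)
    if bundle.controls:
        d["controls"] = {
            t.value: {"name": c.name, "effectiveness": c.effectiveness.value}
            for t, c in bundle.controls.items()
        }
    return d
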