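"""Treatment-specific transformation processes, release routes and allocation.

Step 4 of the framework.  Each waste-treatment technology exposes the waste
to a subset of the eight transformation processes that can alter or liberate
engineered nanomaterials (ENMs), and releases them into environmental
compartments (air, water, soil) with a qualitative weight: a *primary*
pathway, an *indirect* one (e.g. deposition of airborne particles onto soil
and water), a *residual stream* routed to further management (bottom ash,
leachate-treatment sludge, digestate) or a *negligible* one.

The default rule tables are shipped as CSV data and can be overridden per
scenario, since the actual routing depends on the local waste management
system.  Reuse maps to no transformation and no release: no reuse release
pathway is described in the waste-management literature this table encodes.
Photochemical transformation attaches only to the collection/storage stage
(and open dumps), where exposure to sunlight remains possible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .inventory import NanostructureLocation, release_prone
from .units import UncertainInterval

__all__ = [
    "TransformationProcess",
    "TreatmentTechnology",
    "Compartment",
    "RouteQualifier",
    "ControlEffectiveness",
    "ControlMeasure",
    "FateRoute",
    "TreatmentShares",
    "FateRuleTables",
    "transformations_for",
    "release_routes",
    "allocate_to_treatments",
    "packaged_rule_tables",
]


class TransformationProcess(str, enum.Enum):
    """The eight processes that can transform or liberate ENMs in waste."""

    PHOTOCHEMICAL_TRANSFORMATION = "photochemical_transformation"
    OXIDATION = "oxidation"
    REDUCTION = "reduction"
    DISSOLUTION_PRECIPITATION = "dissolution_precipitation"
    ADSORPTION_DESORPTION = "adsorption_desorption"
    COMBUSTION = "combustion"
    BIOTRANSFORMATION_BIODEGRADATION = "biotransformation_biodegradation"
    ABRASION_MECHANICAL_EROSION = "abrasion_mechanical_erosion"


class TreatmentTechnology(str, enum.Enum):
    RE = "RE"  # reuse
    RC = "RC"  # recycling
    BT = "BT"  # biotreatment
    UOL = "UOL"  # use on land
    IN = "IN"  # incineration
    LF = "LF"  # landfill
    COLLECTION = "COLLECTION"  # pre-treatment handling and storage


class Compartment(str, enum.Enum):
    AIR = "air"
    WATER = "water"
    SOIL = "soil"


class RouteQualifier(str, enum.Enum):
    PRIMARY = "primary"
    INDIRECT = "indirect"
    RESIDUAL_STREAM = "residual_stream"
    NEGLIGIBLE = "negligible"


#: ordering used only to verify that controls never increase severity
QUALIFIER_SEVERITY = {
    RouteQualifier.PRIMARY: 3,
    RouteQualifier.INDIRECT: 2,
    RouteQualifier.RESIDUAL_STREAM: 1,
    RouteQualifier.NEGLIGIBLE: 0,
}


class ControlEffectiveness(str, enum.Enum):
    NONE = "none"
    PARTIAL = "partial"
    HIGH = "high"


@dataclass(frozen=True)
class ControlMeasure:
    """An emission-control device, e.g. flue-gas cleaning or hall filtration."""

    name: str
    effectiveness: ControlEffectiveness

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "effectiveness", ControlEffectiveness(self.effectiveness)
        )


@dataclass(frozen=True)
class FateRoute:
    """Release routing of one treatment applied to one nanostructure."""

    treatment: TreatmentTechnology
    processes: frozenset[TransformationProcess]
    qualifiers: dict[Compartment, RouteQualifier]
    controls: ControlMeasure | None = None
    notes: tuple[str, ...] = ()

    @property
    def compartments(self) -> frozenset[Compartment]:
        """Compartments with a non-negligible release pathway."""
        return frozenset(
            c
            for c, q in self.qualifiers.items()
            if q is not RouteQualifier.NEGLIGIBLE
        )


@dataclass(frozen=True)
class TreatmentShares:
    """How a nanowaste stream splits across treatments (shares sum to 1)."""

    shares: dict[TreatmentTechnology, float]

    def __post_init__(self) -> None:
        shares = {
            TreatmentTechnology(t): float(s) for t, s in self.shares.items()
        }
        for t, s in shares.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"share for {t.value} is {s}, outside [0, 1]")
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"treatment shares sum to {total:.12g}, deficit "
                f"{1.0 - total:+.12g}; they must sum to 1"
            )
        object.__setattr__(self, "shares", shares)

    def items(self):
        return self.shares.items()


@dataclass(frozen=True)
class FateRuleTables:
    """Treatment -> processes and treatment -> (compartment, qualifier) rules."""

    processes: dict[TreatmentTechnology, frozenset[TransformationProcess]]
    routes: dict[TreatmentTechnology, dict[Compartment, RouteQualifier]]

    @classmethod
    def from_csv(
        cls, processes_path: str | Path, routes_path: str | Path
    ) -> "FateRuleTables":
        pdf = pd.read_csv(processes_path, dtype=str)
        processes: dict[TreatmentTechnology, set[TransformationProcess]] = {
            t: set() for t in TreatmentTechnology
        }
        for _, row in pdf.iterrows():
            processes[TreatmentTechnology(row["treatment"].strip())].add(
                TransformationProcess(row["process"].strip())
            )
        rdf = pd.read_csv(routes_path, dtype=str)
        routes: dict[TreatmentTechnology, dict[Compartment, RouteQualifier]] = {
            t: {} for t in TreatmentTechnology
        }
        for _, row in rdf.iterrows():
            routes[TreatmentTechnology(row["treatment"].strip())][
                Compartment(row["compartment"].strip())
            ] = RouteQualifier(row["qualifier"].strip())
        return cls(
            processes={t: frozenset(s) for t, s in processes.items()},
            routes=routes,
        )


def packaged_rule_tables() -> FateRuleTables:
    """The default rule tables shipped with the package."""
    data = resources.files("nanowaste.data")
    with resources.as_file(data / "treatment_processes.csv") as p_proc, \
            resources.as_file(data / "release_routes.csv") as p_routes:
        return FateRuleTables.from_csv(p_proc, p_routes)


def transformations_for(
    treatment: TreatmentTechnology, tables: FateRuleTables | None = None
) -> frozenset[TransformationProcess]:
    """Transformation processes a treatment technology can apply.

    Defaults: landfill exposes waste to reduction, dissolution/precipitation,
    adsorption/desorption and oxidation in the infiltrating water; incineration
    to combustion; biotreatment and use-on-land to bio-transformation;
    recycling (shredding, sorting) and collection (compaction) to mechanical
    abrasion, with sunlight-driven photochemistry possible during collection
    and storage.  Reuse asserts no transformation.
    """
    tables = tables or packaged_rule_tables()
    return tables.processes[TreatmentTechnology(treatment)]


def release_routes(
    treatment: TreatmentTechnology,
    location: NanostructureLocation,
    controls: ControlMeasure | None = None,
    tables: FateRuleTables | None = None,
) -> FateRoute:
    """Build the release route for one treatment x nanostructure pair.

    Starting from the treatment's default compartment qualifiers, two
    qualitative modifiers apply:

    * a nanostructure that is not release-prone (nanostructured in the bulk)
      downgrades every pathway to negligible — the ENM stays locked in the
      matrix during handling;
    * a high-effectiveness control measure (state-of-the-art flue-gas
      cleaning) downgrades the *primary* pathway to negligible; partial
      controls (ordinary ventilation/filtration, not fully effective against
      nanoscale particles) leave the qualifiers unchanged and are recorded in
      the route for the exposure step to weigh.
    """
    treatment = TreatmentTechnology(treatment)
    location = NanostructureLocation(location)
    tables = tables or packaged_rule_tables()
    qualifiers = dict(tables.routes[treatment])
    notes: list[str] = []
    if not release_prone(location):
        qualifiers = {c: RouteQualifier.NEGLIGIBLE for c in qualifiers}
        notes.append(
            f"nanostructure location {location.value} is not release-prone; "
            "all pathways downgraded to negligible"
        )
    elif controls is not None and controls.effectiveness is ControlEffectiveness.HIGH:
        qualifiers = {
            c: (RouteQualifier.NEGLIGIBLE if q is RouteQualifier.PRIMARY else q)
            for c, q in qualifiers.items()
        }
        notes.append(
            f"high-effectiveness control ({controls.name}) suppresses the "
            "primary release pathway"
        )
    elif controls is not None and controls.effectiveness is ControlEffectiveness.PARTIAL:
        notes.append(
            f"partial control ({controls.name}) reduces but does not stop the "
            "primary release"
        )
    return FateRoute(
        treatment=treatment,
        processes=tables.processes[treatment],
        qualifiers=qualifiers,
        controls=controls,
        notes=tuple(notes),
    )


def allocate_to_treatments(
    X: UncertainInterval, shares: TreatmentShares
) -> dict[TreatmentTechnology, UncertainInterval]:
    """Split a nanowaste mass envelope across treatment shares.

    Endpoint-wise mass conservation holds exactly: summing the allocated
    intervals recovers the input interval.
    """
    return {
        t: UncertainInterval(X.low * s, X.high * s, X.unit, X.sources)
        for t, s in shares.items()
    }
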