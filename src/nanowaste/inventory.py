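"""Nanowaste knowledge base: waste records, classification and nanostructure.

Covers the second and third assessment steps plus the definitional rule that
separates *nanowaste* (separately collected or collectable material that is or
contains engineered nanomaterials, ENMs) from *nanopollution* (ENMs released
directly to the environment, e.g. nanosilver washed from T-shirts into
wastewater) and from regular, ENM-free waste.

The packaged knowledge base (``data/waste_records.csv``) transcribes published
examples of end-of-life nanoproducts, the waste fraction they enter and the
treatment technologies likely to receive them.  It is shipped as data, not
code: users can extend it with their own products, and every file is schema
validated on load.  Products with a composite matrix (e.g. a sunscreen -
liquid lotion plus solid flacon) carry one matrix descriptor per component.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "NanostructureLocation",
    "MatrixState",
    "WasteCategory",
    "WasteOrigin",
    "MatrixDescriptor",
    "WasteItem",
    "WasteRecord",
    "classify_waste",
    "release_prone",
    "load_waste_records",
    "lookup_waste_record",
    "packaged_waste_records",
]


class MatrixState(str, enum.Enum):
    SOLID = "solid"
    LIQUID = "liquid"


class NanostructureLocation(str, enum.Enum):
    """Where the nanostructure sits in (or on) the host matrix."""

    SURFACE_NANOFILM = "surface_nanofilm"
    SURFACE_BOUND = "surface_bound"
    SUSPENDED_IN_LIQUID = "suspended_in_liquid"
    SUSPENDED_IN_SOLID = "suspended_in_solid"
    AIRBORNE_ENCLOSED = "airborne_enclosed"
    BULK_NANOSTRUCTURED = "bulk_nanostructured"


#: locations most prone to releasing ENMs during waste handling; material that
#: is nanostructured in the bulk (e.g. a battery anode) is not on the list.
RELEASE_PRONE_LOCATIONS = frozenset(
    {
        NanostructureLocation.SURFACE_NANOFILM,
        NanostructureLocation.SURFACE_BOUND,
        NanostructureLocation.SUSPENDED_IN_LIQUID,
        NanostructureLocation.SUSPENDED_IN_SOLID,
        NanostructureLocation.AIRBORNE_ENCLOSED,
    }
)


def release_prone(location: NanostructureLocation) -> bool:
    """Whether a nanostructure location is prone to ENM release."""
    return NanostructureLocation(location) in RELEASE_PRONE_LOCATIONS


class WasteCategory(str, enum.Enum):
    NANOWASTE = "nanowaste"
    NANOPOLLUTION = "nanopollution"
    REGULAR_WASTE = "regular_waste"


class WasteOrigin(str, enum.Enum):
    MANUFACTURING_BYPRODUCT = "manufacturing_byproduct"
    EOL_NANOPRODUCT = "eol_nanoproduct"
    CONTAMINATED_WASTE = "contaminated_waste"
    DIRECT_ENVIRONMENTAL_RELEASE = "direct_environmental_release"


@dataclass(frozen=True)
class MatrixDescriptor:
    """Host-matrix description for one component of a nanoproduct."""

    material: str
    state: MatrixState
    nanostructure_location: NanostructureLocation

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", MatrixState(self.state))
        object.__setattr__(
            self,
            "nanostructure_location",
            NanostructureLocation(self.nanostructure_location),
        )


@dataclass(frozen=True)
class WasteItem:
    """A candidate waste material to classify."""

    description: str
    contains_or_is_enm: bool
    separately_collected_or_collectable: bool
    origin: WasteOrigin

    def __post_init__(self) -> None:
        origin = WasteOrigin(self.origin)
        object.__setattr__(self, "origin", origin)
        if (
            origin is WasteOrigin.DIRECT_ENVIRONMENTAL_RELEASE
            and self.separately_collected_or_collectable
        ):
            raise ValueError(
                f"{self.description!r}: material released directly to the "
                "environment cannot be separately collectable"
            )


def classify_waste(item: WasteItem) -> WasteCategory:
    """Classify a waste item as nanowaste, nanopollution or regular waste.

    Nanowaste is material that is or contains ENMs *and* is separately
    collected or collectable (single-fraction manufacturing by-products,
    end-of-life nanoproducts, ENM-contaminated fractions such as wastewater
    sludge).  ENM-bearing material that cannot be collected is nanopollution;
    ENM-free material is regular waste regardless of collectability.
    """
    if not item.contains_or_is_enm:
        return WasteCategory.REGULAR_WASTE
    if item.separately_collected_or_collectable:
        return WasteCategory.NANOWASTE
    return WasteCategory.NANOPOLLUTION


# treatment technology codes used in the knowledge base; the full enum (with
# the collection stage) lives in nanowaste.fate
TREATMENT_CODES = frozenset({"RE", "RC", "BT", "UOL", "IN", "LF"})


@dataclass(frozen=True)
class WasteRecord:
    """One nanoproduct's waste-stream entry in the knowledge base."""

    nanoproduct: str
    enm_type: str
    matrix: tuple[MatrixDescriptor, ...]
    waste_fraction: str
    treatments: frozenset[str]
    secondary_stream: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", tuple(self.matrix))
        treatments = frozenset(self.treatments)
        if not treatments:
            raise ValueError(f"{self.nanoproduct!r}: treatments must be non-empty")
        unknown = treatments - TREATMENT_CODES
        if unknown:
            raise ValueError(
                f"{self.nanoproduct!r}: unknown treatment codes {sorted(unknown)}; "
                f"allowed: {sorted(TREATMENT_CODES)}"
            )
        object.__setattr__(self, "treatments", treatments)


_KB_COLUMNS = [
    "nanoproduct",
    "enm_type",
    "matrix_material",
    "matrix_state",
    "nanostructure",
    "waste_fraction",
    "treatments",
    "secondary_stream",
]


def load_waste_records(path: str | Path) -> list[WasteRecord]:
    """Load and validate a waste-record CSV.

    The file has one row per matrix component with columns
    ``nanoproduct, enm_type, matrix_material, matrix_state, nanostructure,
    waste_fraction, treatments, secondary_stream``; rows sharing a nanoproduct
    name merge into a single record with several matrix descriptors.
    Treatment codes are pipe-separated.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _KB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"waste-record file {path} lacks columns {missing}")
    records: dict[str, dict] = {}
    for i, row in df.iterrows():
        name = row["nanoproduct"].strip()
        if not name:
            raise ValueError(f"{path}, row {i}: empty nanoproduct name")
        descriptor = MatrixDescriptor(
            material=row["matrix_material"].strip(),
            state=row["matrix_state"].strip(),
            nanostructure_location=row["nanostructure"].strip(),
        )
        codes = {c.strip() for c in row["treatments"].split("|") if c.strip()}
        entry = records.setdefault(
            name,
            {
                "enm_type": row["enm_type"].strip(),
                "matrix": [],
                "waste_fraction": row["waste_fraction"].strip(),
                "treatments": set(),
                "secondary_stream": row["secondary_stream"].strip().lower()
                in ("true", "yes", "1"),
            },
        )
        entry["matrix"].append(descriptor)
        entry["treatments"] |= codes
    return [
        WasteRecord(
            nanoproduct=name,
            enm_type=e["enm_type"],
            matrix=tuple(e["matrix"]),
            waste_fraction=e["waste_fraction"],
            treatments=frozenset(e["treatments"]),
            secondary_stream=e["secondary_stream"],
        )
        for name, e in records.items()
    ]


def _normalise(name: str) -> str:
    return " ".join(name.split()).lower()


def lookup_waste_record(kb: list[WasteRecord], nanoproduct: str) -> WasteRecord:
    """Find a product in the knowledge base (case/whitespace-insensitive)."""
    wanted = _normalise(nanoproduct)
    for rec in kb:
        if _normalise(rec.nanoproduct) == wanted:
            return rec
    known = sorted(rec.nanoproduct for rec in kb)
    raise KeyError(f"no waste record for {nanoproduct!r}; known products: {known}")


def packaged_waste_records() -> list[WasteRecord]:
    """The knowledge base shipped with the package."""
    with resources.as_file(
        resources.files("nanowaste.data") / "waste_records.csv"
    ) as p:
        return load_waste_records(p)
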