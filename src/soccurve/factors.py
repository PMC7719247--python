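"""IPCC Tier 1 classification dimensions, stock-change factor tables and
reference SOC stocks.

The Tier 1 method estimates the equilibrium soil organic carbon stock of a
managed soil (0-30 cm) as the product of a reference stock under native
vegetation and three dimensionless stock-change factors::

    SOC = SOC_ref(climate, soil) * F_LU * F_MG * F_I

where ``F_LU`` captures land use, ``F_MG`` tillage-driven soil disturbance and
``F_I`` the level of carbon input to the soil.  All three factors depend on
the climate zone.  Factor values and reference stocks are configuration, not
code: this module loads them from CSV (a default fixture populated from the
2006 IPCC guideline tables ships with the package and is editable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import DomainError, FactorLookupError, IntegrityError, SchemaError

# --------------------------------------------------------------------------
# Enumerated dimensions
# --------------------------------------------------------------------------


class ClimateZone(str, Enum):
    """IPCC climate zones relevant to U.S. and generic Tier 1 cropland."""

    BOREAL_DRY = "boreal-dry"
    BOREAL_MOIST = "boreal-moist"
    COLD_TEMPERATE_DRY = "cold-temperate-dry"
    COLD_TEMPERATE_MOIST = "cold-temperate-moist"
    WARM_TEMPERATE_DRY = "warm-temperate-dry"
    WARM_TEMPERATE_MOIST = "warm-temperate-moist"
    TROPICAL_DRY = "tropical-dry"
    TROPICAL_MOIST = "tropical-moist"
    TROPICAL_WET = "tropical-wet"
    TROPICAL_MONTANE = "tropical-montane"


class SoilClass(str, Enum):
    """IPCC default soil classes (0-30 cm reference-stock dimension)."""

    HIGH_ACTIVITY_MINERAL = "high-activity-mineral"
    LOW_ACTIVITY_MINERAL = "low-activity-mineral"
    SANDY = "sandy"
    VOLCANIC = "volcanic"
    SPODIC = "spodic"
    WETLAND = "wetland"


class LandUse(str, Enum):
    LONG_TERM_CULTIVATED = "long-term-cultivated"
    SET_ASIDE = "set-aside"
    PERENNIAL = "perennial"


class Tillage(str, Enum):
    CT = "CT"  # conventional (full) tillage
    RT = "RT"  # reduced tillage
    NT = "NT"  # no-till
    NONE = "none"  # not tilled because not cropland


class InputLevel(str, Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    HIGH_WITH_AMENDMENT = "high-with-amendment"


class FactorKind(str, Enum):
    LU = "LU"  # land use
    MG = "MG"  # management (tillage)
    I = "I"  # input


NON_CROP_LAND_USES = frozenset({LandUse.SET_ASIDE, LandUse.PERENNIAL})

# Alias maps: the literature and survey files spell these many ways
# ("cold temperate, moist", "HAC", "no till", ...).  Keys are normalised
# (lower case, separators collapsed to single spaces).

_CLIMATE_ALIASES = {
    "ctd": ClimateZone.COLD_TEMPERATE_DRY,
    "ctm": ClimateZone.COLD_TEMPERATE_MOIST,
    "wtd": ClimateZone.WARM_TEMPERATE_DRY,
    "wtm": ClimateZone.WARM_TEMPERATE_MOIST,
    "cool temperate dry": ClimateZone.COLD_TEMPERATE_DRY,
    "cool temperate moist": ClimateZone.COLD_TEMPERATE_MOIST,
}

_SOIL_ALIASES = {
    "hac": SoilClass.HIGH_ACTIVITY_MINERAL,
    "lac": SoilClass.LOW_ACTIVITY_MINERAL,
    "high activity clay": SoilClass.HIGH_ACTIVITY_MINERAL,
    "low activity clay": SoilClass.LOW_ACTIVITY_MINERAL,
}

_LANDUSE_ALIASES = {
    "cropland": LandUse.LONG_TERM_CULTIVATED,
    "cultivated": LandUse.LONG_TERM_CULTIVATED,
    "crop": LandUse.LONG_TERM_CULTIVATED,
    "ltc": LandUse.LONG_TERM_CULTIVATED,
    "crp": LandUse.SET_ASIDE,
    "setaside": LandUse.SET_ASIDE,
    "nc": LandUse.PERENNIAL,
    "non crop": LandUse.PERENNIAL,
    "noncrop": LandUse.PERENNIAL,
    "hay": LandUse.PERENNIAL,
    "pasture": LandUse.PERENNIAL,
    "perennial non crop": LandUse.PERENNIAL,
}

_TILLAGE_ALIASES = {
    "full": Tillage.CT,
    "conventional": Tillage.CT,
    "reduced": Tillage.RT,
    "no till": Tillage.NT,
    "notill": Tillage.NT,
    "ct": Tillage.CT,
    "rt": Tillage.RT,
    "nt": Tillage.NT,
}

_INPUT_ALIASES = {
    "high with manure": InputLevel.HIGH_WITH_AMENDMENT,
    "high manure": InputLevel.HIGH_WITH_AMENDMENT,
    "med": InputLevel.MEDIUM,
}

_KIND_ALIASES = {
    "landuse": FactorKind.LU,
    "land use": FactorKind.LU,
    "tillage": FactorKind.MG,
    "management": FactorKind.MG,
    "input": FactorKind.I,
    "lu": FactorKind.LU,
    "mg": FactorKind.MG,
    "i": FactorKind.I,
}


def _norm(code: str) -> str:
    s = str(code).strip().lower()
    for ch in ("_", "-", ",", "/"):
        s = s.replace(ch, " ")
    return " ".join(s.split())


def _parse_enum(enum_cls, aliases: Mapping, code, what: str):
    """Resolve ``code`` to an ``enum_cls`` member via value match or alias map."""
    if isinstance(code, enum_cls):
        return code
    key = _norm(code)
    for member in enum_cls:
        if _norm(member.value) == key:
            return member
    if key in aliases:
        return aliases[key]
    valid = ", ".join(m.value for m in enum_cls)
    raise DomainError(f"unknown {what} {code!r}; expected one of: {valid}")


def parse_climate(code) -> ClimateZone:
    return _parse_enum(ClimateZone, _CLIMATE_ALIASES, code, "climate zone")


def parse_soil(code) -> SoilClass:
    return _parse_enum(SoilClass, _SOIL_ALIASES, code, "soil class")


def parse_land_use(code) -> LandUse:
    return _parse_enum(LandUse, _LANDUSE_ALIASES, code, "land use")


def parse_tillage(code) -> Tillage:
    return _parse_enum(Tillage, _TILLAGE_ALIASES, code, "tillage")


def parse_input_level(code) -> InputLevel:
    return _parse_enum(InputLevel, _INPUT_ALIASES, code, "input level")


def parse_factor_kind(code) -> FactorKind:
    return _parse_enum(FactorKind, _KIND_ALIASES, code, "factor kind")


_LEVEL_PARSERS = {
    FactorKind.LU: parse_land_use,
    FactorKind.MG: parse_tillage,
    FactorKind.I: parse_input_level,
}


# --------------------------------------------------------------------------
# Management state
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ManagementState:
    """Land use, tillage and carbon-input level of a land unit at one date.

    Non-crop land uses (set-aside, perennial) carry ``tillage = none``.
    """

    land_use: LandUse
    tillage: Tillage
    input_level: InputLevel

    def __post_init__(self):
        object.__setattr__(self, "land_use", parse_land_use(self.land_use))
        object.__setattr__(self, "tillage", parse_tillage(self.tillage))
        object.__setattr__(self, "input_level", parse_input_level(self.input_level))
        if self.land_use in NON_CROP_LAND_USES and self.tillage is not Tillage.NONE:
            raise DomainError(
                f"non-crop land use {self.land_use.value!r} must carry tillage "
                f"'none', got {self.tillage.value!r}"
            )
        if self.land_use is LandUse.LONG_TERM_CULTIVATED and self.tillage is Tillage.NONE:
            raise DomainError("cultivated land must carry a CT/RT/NT tillage state")

    def with_tillage(self, tillage: Tillage) -> "ManagementState":
        return ManagementState(self.land_use, tillage, self.input_level)


# --------------------------------------------------------------------------
# Factor table
# --------------------------------------------------------------------------

_FACTOR_COLUMNS = ["factor_kind", "level", "climate_zone", "value"]
_REF_COLUMNS = ["climate_zone", "soil_class", "soc_ref_mg_c_ha"]

FactorKey = tuple[FactorKind, str, ClimateZone]


@dataclass
class FactorTable:
    """Mapping (factor kind, level, climate zone) -> stock-change multiplier.

    ``uncertainty_pct`` holds an optional per-kind relative uncertainty (in
    percent); it is stored for the sensitivity sweep only and plays no role in
    the point estimates.
    """

    entries: dict[FactorKey, float]
    uncertainty_pct: dict[FactorKind, float] = field(default_factory=dict)

    def __post_init__(self):
        for key, value in self.entries.items():
            if not (value > 0):
                raise DomainError(f"factor multiplier for {key} must be > 0, got {value}")
        self._warn_tillage_ordering()

    def _warn_tillage_ordering(self):
        # Temperate-zone convention: less disturbance never lowers SOC, so
        # F_NT >= F_CT within a climate.  Violations are suspicious but legal.
        for climate in ClimateZone:
            nt = self.entries.get((FactorKind.MG, Tillage.NT.value, climate))
            ct = self.entries.get((FactorKind.MG, Tillage.CT.value, climate))
            if nt is not None and ct is not None and nt < ct:
                warnings.warn(
                    f"tillage factors inverted in {climate.value}: "
                    f"NT={nt} < CT={ct}",
                    stacklevel=3,
                )

    def lookup(self, kind, level, climate) -> float:
        kind = parse_factor_kind(kind)
        climate = parse_climate(climate)
        level_code = _LEVEL_PARSERS[kind](level).value
        try:
            return self.entries[(kind, level_code, climate)]
        except KeyError:
            raise FactorLookupError(
                f"no factor for kind={kind.value!r}, level={level_code!r}, "
                f"climate={climate.value!r}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor_kind": k.value,
                "level": lvl,
                "climate_zone": cz.value,
                "value": v,
                "uncertainty_pct": self.uncertainty_pct.get(k, float("nan")),
            }
            for (k, lvl, cz), v in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2].value)
            )
        ]
        return pd.DataFrame(rows, columns=_FACTOR_COLUMNS + ["uncertainty_pct"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def load_factor_table(path) -> FactorTable:
    """Load and validate a stock-change factor table from CSV.

    Required columns: factor_kind, level, climate_zone, value; an optional
    uncertainty_pct column gives the per-kind relative uncertainty.
    """
    df = _read_csv(path, _FACTOR_COLUMNS, "factor table")
    entries: dict[FactorKey, float] = {}
    uncertainty: dict[FactorKind, float] = {}
    for _, row in df.iterrows():
        kind = parse_factor_kind(row["factor_kind"])
        climate = parse_climate(row["climate_zone"])
        level = _LEVEL_PARSERS[kind](row["level"]).value
        value = _parse_number(row["value"], "value", path)
        if not (value > 0):
            raise DomainError(
                f"{path}: factor value must be > 0, got {value} for "
                f"({kind.value}, {level}, {climate.value})"
            )
        key = (kind, level, climate)
        if key in entries:
            raise IntegrityError(
                f"{path}: duplicate factor key "
                f"({kind.value}, {level}, {climate.value})"
            )
        entries[key] = value
        if "uncertainty_pct" in df.columns and pd.notna(row.get("uncertainty_pct")):
            pct = _parse_number(row["uncertainty_pct"], "uncertainty_pct", path)
            prev = uncertainty.setdefault(kind, pct)
            uncertainty[kind] = max(prev, pct)
    return FactorTable(entries=entries, uncertainty_pct=uncertainty)


# --------------------------------------------------------------------------
# Reference stocks
# --------------------------------------------------------------------------


@dataclass
class ReferenceStockTable:
    """Mapping (climate zone, soil class) -> SOC_ref, Mg C per ha, 0-30 cm."""

    entries: dict[tuple[ClimateZone, SoilClass], float]

    def __post_init__(self):
        for key, value in self.entries.items():
            if not (value > 0):
                raise DomainError(f"reference stock for {key} must be > 0, got {value}")

    def lookup(self, climate, soil) -> float:
        climate = parse_climate(climate)
        soil = parse_soil(soil)
        try:
            return self.entries[(climate, soil)]
        except KeyError:
            raise FactorLookupError(
                f"no reference stock for climate={climate.value!r}, soil={soil.value!r}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"climate_zone": cz.value, "soil_class": sc.value, "soc_ref_mg_c_ha": v}
            for (cz, sc), v in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
        ]
        return pd.DataFrame(rows, columns=_REF_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def load_ref_stock_table(path) -> ReferenceStockTable:
    df = _read_csv(path, _REF_COLUMNS, "reference stock table")
    entries: dict[tuple[ClimateZone, SoilClass], float] = {}
    for _, row in df.iterrows():
        climate = parse_climate(row["climate_zone"])
        soil = parse_soil(row["soil_class"])
        value = _parse_number(row["soc_ref_mg_c_ha"], "soc_ref_mg_c_ha", path)
        if not (value > 0):
            raise DomainError(f"{path}: SOC_ref must be > 0, got {value}")
        key = (climate, soil)
        if key in entries:
            raise IntegrityError(
                f"{path}: duplicate reference stock key "
                f"({climate.value}, {soil.value})"
            )
        entries[key] = value
    return ReferenceStockTable(entries=entries)


# --------------------------------------------------------------------------
# Packaged defaults and shared CSV helpers
# --------------------------------------------------------------------------


def default_factor_table() -> FactorTable:
    """Editable default factors shipped with the package (IPCC 2006 values)."""
    with resources.as_file(resources.files("soccurve.data") / "factors.csv") as p:
        return load_factor_table(p)


def default_reference_stocks() -> ReferenceStockTable:
    """Editable default 0-30 cm reference stocks shipped with the package."""
    with resources.as_file(resources.files("soccurve.data") / "ref_stocks.csv") as p:
        return load_ref_stock_table(p)


def _read_csv(path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{what} not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: could not parse {what}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {what} missing columns {missing}")
    return df


def _parse_number(raw, column: str, path) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise SchemaError(f"{path}: non-numeric {column} value {raw!r}") from None
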