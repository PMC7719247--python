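"""Tier 1 SOC stock-change model for tillage-intensity transitions.

A stratum is a homogeneous land unit (climate x soil x rotation x state x
tillage history x area) observed at three inventory dates (1982, 1997, 2017).
The scenario converts every convertible cropland stratum to no-till at the
final date; the SOC consequence follows the IPCC Tier 1 assumption that a
managed soil moves linearly to a new equilibrium stock over D = 20 years:

    rate (Mg C / ha / yr) = (SOC_eq(new management) - SOC_eq(old)) / D

Each inventory's end state is assumed fully equilibrated by the next
inventory date, so the conversion rate depends only on the 1997 state and the
no-till end state; the 1982 state enters only through sequence labelling and
stratum composition.  Land already under no-till in 1997, or not managed as
cropland in 1997 (set-aside / CRP, hay, pasture), contributes exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import CO2_PER_C
from .errors import ClassificationError, DomainError, EmptyInputError, SchemaError
from .factors import (
    ClimateZone,
    FactorKind,
    FactorTable,
    InputLevel,
    LandUse,
    ManagementState,
    ReferenceStockTable,
    SoilClass,
    Tillage,
    parse_climate,
    parse_input_level,
    parse_soil,
)

HA_PER_MHA = 1.0e6  # 1 Mha = 1e6 ha; 1 Tg = 1e6 Mg, so Mg/ha/yr * Mha = Tg/yr


class TillageSequence(str, Enum):
    """The nine soil-disturbance sequences over the 1982/1997/2017 inventories.

    The first two letters give the 1982 state (CT, RT, or NC for non-crop),
    the middle pair the 1997 tillage, and the final pair is always NT because
    the scenario converts all convertible cropland to no-till.
    """

    CTCTNT = "CTCTNT"
    CTRTNT = "CTRTNT"
    CTNTNT = "CTNTNT"
    RTCTNT = "RTCTNT"
    RTRTNT = "RTRTNT"
    RTNTNT = "RTNTNT"
    NCCTNT = "NCCTNT"
    NCRTNT = "NCRTNT"
    NCNTNT = "NCNTNT"


#: Sequences whose 1997 tillage is already NT: zero change by construction.
ZERO_CHANGE_SEQUENCES = frozenset(
    {TillageSequence.CTNTNT, TillageSequence.RTNTNT, TillageSequence.NCNTNT}
)


@dataclass(frozen=True)
class EquilibriumHorizon:
    """Years for SOC to reach its new equilibrium after a management change."""

    D: float = 20.0

    def __post_init__(self):
        if not self.D > 0:
            raise DomainError(f"equilibrium horizon must be > 0 years, got {self.D}")


DEFAULT_HORIZON = EquilibriumHorizon()


@dataclass(frozen=True)
class Stratum:
    """One homogeneous land unit with its dated management states."""

    stratum_id: str
    state: str  # two-letter postal code
    climate_zone: ClimateZone
    soil_class: SoilClass
    rotation: str
    input_level: InputLevel
    area_ha: float
    state_1982: ManagementState
    state_1997: ManagementState
    region: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "climate_zone", parse_climate(self.climate_zone))
        object.__setattr__(self, "soil_class", parse_soil(self.soil_class))
        object.__setattr__(self, "input_level", parse_input_level(self.input_level))
        if not self.area_ha > 0:
            raise DomainError(
                f"stratum {self.stratum_id}: area_ha must be > 0, got {self.area_ha}"
            )

    @property
    def eligible(self) -> bool:
        """Convertible to no-till: cropland in 1997 and not already NT."""
        return (
            self.state_1997.land_use is LandUse.LONG_TERM_CULTIVATED
            and self.state_1997.tillage in (Tillage.CT, Tillage.RT)
        )


@dataclass(frozen=True)
class SequestrationResult:
    """Per-stratum sequestration rates and totals under NT conversion.

    Units: rates in Mg per ha per yr; annual totals in Tg per yr; 20-year
    totals in Tg.  ``rate_co2 = rate_c * 44/12`` and
    ``annual_total = rate * area`` hold exactly (in Tg-vs-Mha units).
    """

    stratum_id: str
    state: str
    sequence: Optional[TillageSequence]
    area_ha: float
    rate_c: float
    rate_co2: float
    annual_total_c: float
    annual_total_co2: float
    total_20yr_c: float
    total_20yr_co2: float
    eligible: bool
    flags: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# Core Tier 1 arithmetic
# --------------------------------------------------------------------------


def equilibrium_stock(
    state: ManagementState,
    climate: ClimateZone,
    soil: SoilClass,
    factors: FactorTable,
    refs: ReferenceStockTable,
) -> float:
    """Equilibrium SOC stock (Mg C / ha, 0-30 cm): SOC_ref * F_LU * F_MG * F_I."""
    soc_ref = refs.lookup(climate, soil)
    f_lu = factors.lookup(FactorKind.LU, state.land_use, climate)
    f_mg = factors.lookup(FactorKind.MG, state.tillage, climate)
    f_i = factors.lookup(FactorKind.I, state.input_level, climate)
    return soc_ref * f_lu * f_mg * f_i


def annual_rate(
    state_from: ManagementState,
    state_to: ManagementState,
    climate: ClimateZone,
    soil: SoilClass,
    factors: FactorTable,
    refs: ReferenceStockTable,
    horizon: EquilibriumHorizon = DEFAULT_HORIZON,
) -> float:
    """Annual SOC stock-change rate (Mg C / ha / yr) between two states.

    Exactly zero when the states are identical (no management change means no
    net SOC change at equilibrium); negative when the new state stores less.
    """
    if state_from == state_to:
        return 0.0
    stock_from = equilibrium_stock(state_from, climate, soil, factors, refs)
    stock_to = equilibrium_stock(state_to, climate, soil, factors, refs)
    return (stock_to - stock_from) / horizon.D


def classify_sequence(stratum: Stratum) -> TillageSequence:
    """Map a stratum's dated states to one of the nine tillage sequences.

    The 1982 element is NC for non-crop land uses, otherwise the 1982 tillage
    (CT or RT; the tillage surveys report no NT cropland in 1982).  The 1997
    element is the 1997 cropland tillage; the 2017 element is NT by scenario.
    """
    s82, s97 = stratum.state_1982, stratum.state_1997
    if s97.land_use is not LandUse.LONG_TERM_CULTIVATED:
        raise ClassificationError(
            f"stratum {stratum.stratum_id}: 1997 land use "
            f"{s97.land_use.value!r} is not cropland; no tillage sequence"
        )
    if s82.land_use is LandUse.LONG_TERM_CULTIVATED:
        if s82.tillage is Tillage.CT:
            first = "CT"
        elif s82.tillage is Tillage.RT:
            first = "RT"
        else:
            raise ClassificationError(
                f"stratum {stratum.stratum_id}: 1982 cropland tillage "
                f"{s82.tillage.value!r} not in (CT, RT)"
            )
    else:
        first = "NC"
    if s97.tillage not in (Tillage.CT, Tillage.RT, Tillage.NT):
        raise ClassificationError(
            f"stratum {stratum.stratum_id}: 1997 tillage {s97.tillage.value!r} "
            "not in (CT, RT, NT)"
        )
    return TillageSequence(first + s97.tillage.value + "NT")


def sequence_rate(
    stratum: Stratum,
    factors: FactorTable,
    refs: ReferenceStockTable,
    horizon: EquilibriumHorizon = DEFAULT_HORIZON,
) -> SequestrationResult:
    """Classify a stratum and compute its NT-conversion sequestration result.

    Ineligible strata (non-crop in 1997) and already-NT strata return
    all-zero results, flagged accordingly; negative rates (possible only with
    factor tables outside the reduced-disturbance convention) are retained
    but flagged so the cost-curve stage can exclude them.
    """
    flags: list[str] = []
    if stratum.state_1997.land_use is not LandUse.LONG_TERM_CULTIVATED:
        return _zero_result(stratum, None, ("excluded:not-cropland-1997",))
    sequence = classify_sequence(stratum)
    if stratum.state_1997.tillage is Tillage.NT:
        return _zero_result(stratum, sequence, ("already-no-till",))
    end_state = stratum.state_1997.with_tillage(Tillage.NT)
    rate_c = annual_rate(
        stratum.state_1997,
        end_state,
        stratum.climate_zone,
        stratum.soil_class,
        factors,
        refs,
        horizon,
    )
    if rate_c < 0:
        flags.append("negative-rate")
    rate_co2 = rate_c * CO2_PER_C
    annual_c = rate_c * stratum.area_ha / HA_PER_MHA  # Tg C / yr
    annual_co2 = annual_c * CO2_PER_C
    return SequestrationResult(
        stratum_id=stratum.stratum_id,
        state=stratum.state,
        sequence=sequence,
        area_ha=stratum.area_ha,
        rate_c=rate_c,
        rate_co2=rate_co2,
        annual_total_c=annual_c,
        annual_total_co2=annual_co2,
        total_20yr_c=annual_c * horizon.D,
        total_20yr_co2=annual_co2 * horizon.D,
        eligible=True,
        flags=tuple(flags),
    )


def _zero_result(
    stratum: Stratum, sequence: Optional[TillageSequence], flags: tuple[str, ...]
) -> SequestrationResult:
    return SequestrationResult(
        stratum_id=stratum.stratum_id,
        state=stratum.state,
        sequence=sequence,
        area_ha=stratum.area_ha,
        rate_c=0.0,
        rate_co2=0.0,
        annual_total_c=0.0,
        annual_total_co2=0.0,
        total_20yr_c=0.0,
        total_20yr_co2=0.0,
        eligible=False,
        flags=flags,
    )


def compute_rates(
    strata: Sequence[Stratum],
    factors: FactorTable,
    refs: ReferenceStockTable,
    horizon: EquilibriumHorizon = DEFAULT_HORIZON,
) -> list[SequestrationResult]:
    """Run :func:`sequence_rate` over a collection of strata."""
    if len(strata) == 0:
        raise EmptyInputError("no strata to compute rates for")
    return [sequence_rate(s, factors, refs, horizon) for s in strata]


# --------------------------------------------------------------------------
# Aggregation
# --------------------------------------------------------------------------


def results_to_frame(results: Iterable[SequestrationResult]) -> pd.DataFrame:
    rows = [
        {
            "stratum_id": r.stratum_id,
            "state": r.state,
            "sequence": r.sequence.value if r.sequence else "",
            "area_ha": r.area_ha,
            "rate_c_mg_ha_yr": r.rate_c,
            "rate_co2_mg_ha_yr": r.rate_co2,
            "annual_tg_c": r.annual_total_c,
            "annual_tg_co2": r.annual_total_co2,
            "total_20yr_tg_c": r.total_20yr_c,
            "total_20yr_tg_co2": r.total_20yr_co2,
            "eligible": r.eligible,
            "flags": ";".join(r.flags),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def aggregate_by_sequence(results: Sequence[SequestrationResult]) -> pd.DataFrame:
    """Per-sequence area, annual and 20-year totals, shares and weighted rates.

    Mirrors the inventory's national summary: one row per tillage sequence
    present, plus a TOTAL row.  Shares are percentages of the grand totals;
    the weighted average rate is sum(rate_i * area_i) / sum(area_i).
    """
    classified = [r for r in results if r.sequence is not None]
    if not classified:
        raise EmptyInputError("no classified results to aggregate")
    df = results_to_frame(classified)
    total_area = df["area_ha"].sum()
    total_annual_c = df["annual_tg_c"].sum()

    def _one(group: pd.DataFrame) -> dict:
        area = group["area_ha"].sum()
        annual_c = group["annual_tg_c"].sum()
        return {
            "area_mha": area / HA_PER_MHA,
            "area_share_pct": 100.0 * area / total_area,
            "annual_tg_c": annual_c,
            "annual_tg_co2": group["annual_tg_co2"].sum(),
            "total_20yr_tg_c": group["total_20yr_tg_c"].sum(),
            "total_20yr_tg_co2": group["total_20yr_tg_co2"].sum(),
            "c_share_pct": (
                100.0 * annual_c / total_annual_c if total_annual_c != 0 else 0.0
            ),
            "wavg_rate_c": float(
                np.average(group["rate_c_mg_ha_yr"], weights=group["area_ha"])
            ),
            "wavg_rate_co2": float(
                np.average(group["rate_co2_mg_ha_yr"], weights=group["area_ha"])
            ),
        }

    rows = {}
    for seq in TillageSequence:
        group = df[df["sequence"] == seq.value]
        if len(group):
            rows[seq.value] = _one(group)
    rows["TOTAL"] = _one(df)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sequence"
    return out


def aggregate_by_region(
    results: Sequence[SequestrationResult], strata: Sequence[Stratum]
) -> pd.DataFrame:
    """Area-weighted mean C rate per (region, sequence), with margins.

    Rows are sequences plus an overall-average row; columns are regions plus
    an all-region average column.  Cells are NaN where a sequence does not
    occur in a region.
    """
    meta = {s.stratum_id: s for s in strata}
    records = []
    for r in results:
        if r.sequence is None:
            continue
        stratum = meta.get(r.stratum_id)
        region = stratum.region if stratum is not None else None
        if region is None:
            raise DomainError(
                f"stratum {r.stratum_id} has no region label; cannot aggregate by region"
            )
        records.append(
            {
                "sequence": r.sequence.value,
                "region": region,
                "rate_c": r.rate_c,
                "area_ha": r.area_ha,
            }
        )
    if not records:
        raise EmptyInputError("no classified results to aggregate by region")
    df = pd.DataFrame(records)
    df["rate_area"] = df["rate_c"] * df["area_ha"]
    regions = sorted(df["region"].unique())
    seqs = [s.value for s in TillageSequence if s.value in set(df["sequence"])]
    out = pd.DataFrame(index=seqs + ["Overall average"], columns=regions + ["Average"], dtype=float)
    for seq in seqs:
        sub = df[df["sequence"] == seq]
        for region in regions:
            cell = sub[sub["region"] == region]
            if len(cell):
                out.loc[seq, region] = cell["rate_area"].sum() / cell["area_ha"].sum()
        out.loc[seq, "Average"] = sub["rate_area"].sum() / sub["area_ha"].sum()
    for region in regions:
        sub = df[df["region"] == region]
        out.loc["Overall average", region] = sub["rate_area"].sum() / sub["area_ha"].sum()
    out.loc["Overall average", "Average"] = df["rate_area"].sum() / df["area_ha"].sum()
    out.index.name = "sequence"
    return out


# --------------------------------------------------------------------------
# Strata CSV I/O
# --------------------------------------------------------------------------

_STRATA_COLUMNS = [
    "stratum_id",
    "state",
    "region",
    "climate_zone",
    "soil_class",
    "rotation",
    "input_level",
    "area_ha",
    "landuse_1982",
    "tillage_1982",
    "landuse_1997",
    "tillage_1997",
]


def load_strata(path) -> list[Stratum]:
    """Read a strata table; an optional tillage_2017 column must equal NT."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"strata table not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _STRATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: strata table missing columns {missing}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: strata table has no rows")
    strata = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["stratum_id"])
        if sid in seen:
            raise SchemaError(f"{path}: duplicate stratum_id {sid!r}")
        seen.add(sid)
        if "tillage_2017" in df.columns and pd.notna(row["tillage_2017"]):
            if str(row["tillage_2017"]).strip().upper() != "NT":
                raise SchemaError(
                    f"{path}: stratum {sid}: tillage_2017 must be NT (scenario), "
                    f"got {row['tillage_2017']!r}"
                )
        input_level = row["input_level"]
        strata.append(
            Stratum(
                stratum_id=sid,
                state=str(row["state"]).strip().upper(),
                climate_zone=row["climate_zone"],
                soil_class=row["soil_class"],
                rotation=str(row["rotation"]),
                input_level=input_level,
                area_ha=float(row["area_ha"]),
                state_1982=ManagementState(
                    row["landuse_1982"], row["tillage_1982"], input_level
                ),
                state_1997=ManagementState(
                    row["landuse_1997"], row["tillage_1997"], input_level
                ),
                region=None if pd.isna(row["region"]) else str(row["region"]),
            )
        )
    return strata


def strata_to_frame(strata: Sequence[Stratum]) -> pd.DataFrame:
    rows = [
        {
            "stratum_id": s.stratum_id,
            "state": s.state,
            "region": s.region if s.region is not None else "",
            "climate_zone": s.climate_zone.value,
            "soil_class": s.soil_class.value,
            "rotation": s.rotation,
            "input_level": s.input_level.value,
            "area_ha": s.area_ha,
            "landuse_1982": s.state_1982.land_use.value,
            "tillage_1982": s.state_1982.tillage.value,
            "landuse_1997": s.state_1997.land_use.value,
            "tillage_1997": s.state_1997.tillage.value,
            "tillage_2017": "NT",
        }
        for s in strata
    ]
    return pd.DataFrame(rows, columns=_STRATA_COLUMNS + ["tillage_2017"])
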