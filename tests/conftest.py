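import pytest

from soccurve import (
    ClimateZone,
    FactorKind,
    FactorTable,
    ManagementState,
    ReferenceStockTable,
    SoilClass,
    Stratum,
)

CTM = ClimateZone.COLD_TEMPERATE_MOIST
HAC = SoilClass.HIGH_ACTIVITY_MINERAL


@pytest.fixture
def tiny_factors():
    """Hand-sized factor table: SOC stocks 40 (CT), 43.2 (RT), 46 (NT)."""
    entries = {
        (FactorKind.LU, "long-term-cultivated", CTM): 0.80,
        (FactorKind.LU, "set-aside", CTM): 0.82,
        (FactorKind.LU, "perennial", CTM): 1.00,
        (FactorKind.MG, "CT", CTM): 1.00,
        (FactorKind.MG, "RT", CTM): 1.08,
        (FactorKind.MG, "NT", CTM): 1.15,
        (FactorKind.MG, "none", CTM): 1.00,
        (FactorKind.I, "low", CTM): 0.92,
        (FactorKind.I, "medium", CTM): 1.00,
        (FactorKind.I, "high", CTM): 1.11,
    }
    return FactorTable(entries=entries)


@pytest.fixture
def tiny_refs():
    return ReferenceStockTable(entries={(CTM, HAC): 50.0})


def make_state(land_use="long-term-cultivated", tillage="CT", input_level="medium"):
    return ManagementState(land_use, tillage, input_level)


def make_stratum(
    stratum_id="s1",
    state="IA",
    till_1982="CT",
    till_1997="CT",
    landuse_1982="long-term-cultivated",
    landuse_1997="long-term-cultivated",
    input_level="medium",
    area_ha=1.0e6,
    region="HR",
    climate=CTM,
    soil=HAC,
):
    t82 = "none" if landuse_1982 != "long-term-cultivated" else till_1982
    t97 = "none" if landuse_1997 != "long-term-cultivated" else till_1997
    return Stratum(
        stratum_id=stratum_id,
        state=state,
        climate_zone=climate,
        soil_class=soil,
        rotation="continuous-row-crop",
        input_level=input_level,
        area_ha=area_ha,
        state_1982=ManagementState(landuse_1982, t82, input_level),
        state_1997=ManagementState(landuse_1997, t97, input_level),
        region=region,
    )
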