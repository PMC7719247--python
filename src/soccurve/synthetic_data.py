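"""Seeded synthetic strata, factor tables and payment schedules.

No public micro-data exist at the resolution the analysis needs (land-use
survey points crossed with tillage-survey adoption and state program
payments), so this module generates inputs with the same statistical
structure: strata assigned to the nine tillage sequences by configurable
area shares, long-tailed areas rescaled to an exact national total, factor
and reference-stock tables constructed so that every convertible stratum's
implied sequestration rate falls in a configured range, and state payments
drawn uniformly over a configured interval.

Rates are never written into strata directly: the generator builds factor and
reference tables and lets the SOC model derive the rates, so the real
pipeline is genuinely exercised.  One master seed drives all draws through a
fixed stream order (factors by climate, reference stocks by climate x soil,
payments by state, then per-stratum attributes), making every bundle
bit-reproducible from its recorded provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .economics import PaymentSchedule
from .errors import DomainError, GenerationError
from .factors import (
    ClimateZone,
    FactorKind,
    FactorTable,
    LandUse,
    ManagementState,
    ReferenceStockTable,
    SoilClass,
    Tillage,
    parse_climate,
    parse_soil,
)
from .soc_model import Stratum, TillageSequence, strata_to_frame

# Default area shares (% of total cropland) by tillage sequence, reflecting
# the 1997 national inventory composition: conventional tillage dominated,
# with modest reduced-till and no-till adoption and a non-crop fringe.
DEFAULT_SEQUENCE_SHARES = {
    "CTCTNT": 58.0,
    "CTRTNT": 23.2,
    "CTNTNT": 2.2,
    "RTCTNT": 0.0,
    "RTRTNT": 0.9,
    "RTNTNT": 4.8,
    "NCCTNT": 6.9,
    "NCRTNT": 3.1,
    "NCNTNT": 0.9,
}

DEFAULT_CLIMATES = (
    "cold-temperate-dry",
    "cold-temperate-moist",
    "warm-temperate-dry",
    "warm-temperate-moist",
)
DEFAULT_SOILS = ("high-activity-mineral", "low-activity-mineral", "sandy")
DEFAULT_ROTATIONS = (
    "continuous-row-crop",
    "row-crop-small-grain",
    "small-grain-fallow",
    "wheat-fallow",
    "hay-rotation",
)
DEFAULT_INPUT_LEVELS = ("low", "medium", "high")
DEFAULT_REGIONS = ("BRR", "EUR", "FRR", "HR", "MPR", "NCR", "NGPR", "PGR", "SSR")

CONTERMINOUS_STATES = (
    "AL AZ AR CA CO CT DE FL GA ID IL IN IA KS KY LA ME MD MA MI MN MS MO MT "
    "NE NV NH NJ NM NY NC ND OH OK OR PA RI SC SD TN TX UT VT VA WA WV WI WY"
).split()


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic bundle.

    Defaults mirror the study scenario: 124.7 Mha of 1997 cropland split
    across the nine tillage sequences by the national area shares,
    convertible-stratum sequestration rates spanning 0.12-0.47 Mg C/ha/yr,
    and 48 state payments spanning $18.29-$125.73 per ha per yr.
    """

    n_strata: int = 5000
    sequence_shares: dict = field(default_factory=lambda: dict(DEFAULT_SEQUENCE_SHARES))
    total_area_mha: float = 124.7
    rate_range_c: tuple[float, float] = (0.12, 0.47)
    payment_range: tuple[float, float] = (18.29, 125.73)
    n_states: int = 48
    climates: tuple = DEFAULT_CLIMATES
    soils: tuple = DEFAULT_SOILS
    rotations: tuple = DEFAULT_ROTATIONS
    input_levels: tuple = DEFAULT_INPUT_LEVELS
    regions: tuple = DEFAULT_REGIONS
    area_lognormal_sigma: float = 1.0
    horizon_years: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_strata < 1:
            raise DomainError(f"n_strata must be >= 1, got {self.n_strata}")
        unknown = set(self.sequence_shares) - {s.value for s in TillageSequence}
        if unknown:
            raise DomainError(f"unknown tillage sequences in shares: {sorted(unknown)}")
        if any(v < 0 for v in self.sequence_shares.values()):
            raise DomainError("sequence shares must be >= 0")
        total = sum(self.sequence_shares.values())
        if abs(total - 100.0) > 1e-9:
            raise DomainError(f"sequence shares must sum to 100, got {total}")
        lo, hi = self.rate_range_c
        if not (0 < lo < hi):
            raise DomainError(f"rate_range_c must be ordered positive, got {self.rate_range_c}")
        plo, phi = self.payment_range
        if not (0 < plo <= phi):
            raise DomainError(f"payment_range must be ordered positive, got {self.payment_range}")
        if not (1 <= self.n_states <= len(CONTERMINOUS_STATES)):
            raise DomainError(
                f"n_states must be in [1, {len(CONTERMINOUS_STATES)}], got {self.n_states}"
            )
        if not self.total_area_mha > 0:
            raise DomainError(f"total_area_mha must be > 0, got {self.total_area_mha}")
        if not self.horizon_years > 0:
            raise DomainError(f"horizon_years must be > 0, got {self.horizon_years}")


@dataclass
class SyntheticBundle:
    """A complete, reproducible set of pipeline inputs."""

    strata: list[Stratum]
    payments: PaymentSchedule
    factors: FactorTable
    ref_stocks: ReferenceStockTable
    provenance: dict

    def strata_frame(self) -> pd.DataFrame:
        return strata_to_frame(self.strata)

    def write(self, outdir) -> None:
        """Emit strata.csv, payments.csv, factors.csv, ref_stocks.csv and
        provenance.json (deterministic byte-for-byte for a fixed config)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.strata_frame().to_csv(
            outdir / "strata.csv", index=False, float_format="%.12g"
        )
        self.payments.to_csv(outdir / "payments.csv")
        self.factors.to_csv(outdir / "factors.csv")
        self.ref_stocks.to_csv(outdir / "ref_stocks.csv")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")


def generate_bundle(config: Optional[GeneratorConfig] = None) -> SyntheticBundle:
    """Generate a seeded synthetic bundle under ``config``.

    Raises :class:`GenerationError` when the configured rate range is not
    representable with positive factors for some climate (the range of
    input-level and tillage-gap combinations exceeds the rate range's span).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    climates = [parse_climate(c) for c in config.climates]
    soils = [parse_soil(s) for s in config.soils]
    D = config.horizon_years
    rate_lo, rate_hi = config.rate_range_c

    # --- stream 1: stock-change factors, per climate (sorted order) -------
    entries: dict = {}
    climate_params = {}
    for climate in sorted(climates, key=lambda c: c.value):
        f_nt = rng.uniform(1.10, 1.17)
        delta_ct = f_nt - 1.0
        # keep the CT-gap / RT-gap ratio <= 2.5 so one reference stock can
        # serve both CT->NT and RT->NT transitions within the rate range
        delta_rt = rng.uniform(0.40 * delta_ct, 0.60 * delta_ct)
        f_lu_cult = rng.uniform(0.69, 0.80)
        f_lu_setaside = rng.uniform(0.82, 0.93)
        f_i = {"low": rng.uniform(0.92, 0.95), "medium": 1.0, "high": rng.uniform(1.04, 1.11)}
        entries[(FactorKind.LU, LandUse.LONG_TERM_CULTIVATED.value, climate)] = f_lu_cult
        entries[(FactorKind.LU, LandUse.SET_ASIDE.value, climate)] = f_lu_setaside
        entries[(FactorKind.LU, LandUse.PERENNIAL.value, climate)] = 1.0
        entries[(FactorKind.MG, Tillage.CT.value, climate)] = 1.0
        entries[(FactorKind.MG, Tillage.RT.value, climate)] = f_nt - delta_rt
        entries[(FactorKind.MG, Tillage.NT.value, climate)] = f_nt
        entries[(FactorKind.MG, Tillage.NONE.value, climate)] = 1.0
        for level in config.input_levels:
            if level not in f_i:
                raise GenerationError(
                    f"no generator rule for input level {level!r}; "
                    "use low/medium/high or supply your own factor table"
                )
            entries[(FactorKind.I, level, climate)] = f_i[level]
        # feasible SOC_ref interval so every (tillage, input) combo lands in range
        gaps = {"CT": delta_ct, "RT": delta_rt}
        m = [f_i[lvl] * gaps[t] for lvl in config.input_levels for t in gaps]
        ref_lo = rate_lo * D / (f_lu_cult * min(m))
        ref_hi = rate_hi * D / (f_lu_cult * max(m))
        if ref_lo > ref_hi:
            raise GenerationError(
                f"rate range {config.rate_range_c} not representable in "
                f"{climate.value}: factor spread exceeds the range span"
            )
        climate_params[climate] = (ref_lo, ref_hi)
    factors = FactorTable(
        entries=entries,
        uncertainty_pct={FactorKind.LU: 12.0, FactorKind.MG: 10.0, FactorKind.I: 15.0},
    )

    # --- stream 2: reference stocks, per climate x soil --------------------
    ref_entries = {}
    for climate in sorted(climates, key=lambda c: c.value):
        ref_lo, ref_hi = climate_params[climate]
        for soil in sorted(soils, key=lambda s: s.value):
            ref_entries[(climate, soil)] = rng.uniform(ref_lo, ref_hi)
    ref_stocks = ReferenceStockTable(entries=ref_entries)

    # --- stream 3: state payments ------------------------------------------
    states = CONTERMINOUS_STATES[: config.n_states]
    plo, phi = config.payment_range
    payments = PaymentSchedule(
        entries={s: float(rng.uniform(plo, phi)) for s in states}
    )

    # --- stream 4: strata ---------------------------------------------------
    n = config.n_strata
    seq_codes = sorted(config.sequence_shares)
    probs = np.array([config.sequence_shares[c] for c in seq_codes]) / 100.0
    seq_draw = rng.choice(len(seq_codes), size=n, p=probs)
    climate_draw = rng.integers(0, len(climates), size=n)
    soil_draw = rng.integers(0, len(soils), size=n)
    rotation_draw = rng.integers(0, len(config.rotations), size=n)
    input_draw = rng.integers(0, len(config.input_levels), size=n)
    region_draw = rng.integers(0, len(config.regions), size=n)
    state_draw = rng.integers(0, len(states), size=n)
    raw_areas = rng.lognormal(mean=0.0, sigma=config.area_lognormal_sigma, size=n)
    areas = raw_areas * (config.total_area_mha * 1.0e6 / raw_areas.sum())

    width = len(str(n))
    strata = []
    for i in range(n):
        code = seq_codes[seq_draw[i]]
        first, mid = code[:2], code[2:4]
        level = config.input_levels[input_draw[i]]
        if first == "NC":
            state_1982 = ManagementState(LandUse.PERENNIAL, Tillage.NONE, level)
        else:
            state_1982 = ManagementState(
                LandUse.LONG_TERM_CULTIVATED, Tillage(first), level
            )
        state_1997 = ManagementState(LandUse.LONG_TERM_CULTIVATED, Tillage(mid), level)
        strata.append(
            Stratum(
                stratum_id=f"S{i:0{width}d}",
                state=states[state_draw[i]],
                climate_zone=climates[climate_draw[i]],
                soil_class=soils[soil_draw[i]],
                rotation=config.rotations[rotation_draw[i]],
                input_level=level,
                area_ha=float(areas[i]),
                state_1982=state_1982,
                state_1997=state_1997,
                region=config.regions[region_draw[i]],
            )
        )

    provenance = {"generator": "soccurve.synthetic_data.generate_bundle",
                  "config": _config_to_jsonable(config)}
    return SyntheticBundle(
        strata=strata,
        payments=payments,
        factors=factors,
        ref_stocks=ref_stocks,
        provenance=provenance,
    )


def expected_aggregates(config: Optional[GeneratorConfig] = None) -> pd.DataFrame:
    """Analytic recovery targets for the generated sequence area shares.

    The standard error of an area-weighted share under per-stratum multinomial
    assignment with i.i.d. lognormal areas is sqrt(p(1-p) * deff / n) with
    design effect deff = E[a^2]/E[a]^2 = exp(sigma^2); tolerances therefore
    scale as 1/sqrt(n_strata).
    """
    config = config or GeneratorConfig()
    deff = float(np.exp(config.area_lognormal_sigma**2))
    rows = []
    for code in sorted(config.sequence_shares):
        p = config.sequence_shares[code] / 100.0
        se = 100.0 * np.sqrt(p * (1.0 - p) * deff / config.n_strata)
        rows.append(
            {"sequence": code, "expected_share_pct": 100.0 * p, "se_share_pct": se}
        )
    df = pd.DataFrame(rows).set_index("sequence")
    df.attrs["total_area_mha"] = config.total_area_mha
    return df


def _config_to_jsonable(config: GeneratorConfig) -> dict:
    d = asdict(config)
    for key in ("climates", "soils", "rotations", "input_levels", "regions",
                "rate_range_c", "payment_range"):
        d[key] = list(d[key])
    return d
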