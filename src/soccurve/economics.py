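"""Mass-basis conversion and unit-cost economics for sequestered carbon.

The unit cost of sequestration ("carbon value") for a land unit is the annual
conservation-program payment per hectare divided by the annual CO2
sequestration rate per hectare::

    C_value ($ / Mg CO2) = payment ($ / ha / yr) / rate (Mg CO2 / ha / yr)

Carbon and CO2 mass bases are related by the molar-mass ratio 44/12, kept as
an exact binary ratio; rounding to the conventional 3.67 happens only in the
reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DomainError, IntegrityError, SchemaError, UndefinedCostError

#: Mass of CO2 per mass of C (molar-mass ratio).
CO2_PER_C: float = 44.0 / 12.0


def c_to_co2(x: float) -> float:
    """Convert a mass or rate on a carbon basis to a CO2 basis (x * 44/12)."""
    return x * CO2_PER_C


def co2_to_c(x: float) -> float:
    """Convert a mass or rate on a CO2 basis to a carbon basis (x * 12/44)."""
    return x / CO2_PER_C


@dataclass(frozen=True)
class CarbonValue:
    """Unit cost of sequestration on both mass bases.

    ``usd_per_mg_c = usd_per_mg_co2 * 44/12``: a tonne of carbon embodies
    44/12 tonnes of CO2, so the same dollar amount per tonne CO2 is a larger
    amount per tonne C.
    """

    usd_per_mg_co2: float

    @property
    def usd_per_mg_c(self) -> float:
        return self.usd_per_mg_co2 * CO2_PER_C


def carbon_value(payment: float, rate_co2: float) -> CarbonValue:
    """Price a stratum: annual payment per ha over annual CO2 rate per ha.

    Raises :class:`UndefinedCostError` for non-positive rates — a stratum
    sequestering nothing has no finite unit cost and must be excluded from
    cost curves rather than silently priced.
    """
    if not (payment > 0 and math.isfinite(payment)):
        raise DomainError(f"payment must be positive and finite, got {payment}")
    if not (rate_co2 > 0 and math.isfinite(rate_co2)):
        raise UndefinedCostError(
            f"unit cost undefined for CO2 rate {rate_co2} (must be > 0)"
        )
    return CarbonValue(usd_per_mg_co2=payment / rate_co2)


@dataclass(frozen=True)
class DollarDeflator:
    """Multiplier taking a dollar amount from source to target dollar year.

    The default is the exact ratio 36.36/30 implied by restating a $30
    geologic-storage cost from 2005 to 2014 dollars as $36.36.
    """

    factor: float = 36.36 / 30.0

    def __post_init__(self):
        if not (self.factor > 0 and math.isfinite(self.factor)):
            raise DomainError(f"deflator factor must be > 0, got {self.factor}")


def inflation_adjust(value: float, deflator: DollarDeflator = DollarDeflator()) -> float:
    """Restate ``value`` in the deflator's target dollar year."""
    return value * deflator.factor


@dataclass(frozen=True)
class ReserveFraction:
    """Fraction of credited sequestration withheld as reversal insurance.

    Exchanges have withheld on the order of 20 percent; the default is 0
    (no reserve pool).
    """

    fraction: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.fraction < 1.0):
            raise DomainError(f"reserve fraction must be in [0, 1), got {self.fraction}")


def apply_reserve(rate_co2: float, reserve: ReserveFraction = ReserveFraction()) -> float:
    """Discount a sequestration rate by the withheld reserve fraction."""
    if rate_co2 < 0:
        raise DomainError(f"rate must be >= 0 to apply a reserve, got {rate_co2}")
    return rate_co2 * (1.0 - reserve.fraction)


# --------------------------------------------------------------------------
# Payment schedule
# --------------------------------------------------------------------------

_PAYMENT_COLUMNS = ["state", "payment_usd_per_ha_yr"]


@dataclass
class PaymentSchedule:
    """Annual conservation-program payment for no-till adoption, by state.

    Payments vary across states but not within a state, so every stratum
    inherits its state's payment.
    """

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for state, value in self.entries.items():
            if not (value > 0 and math.isfinite(value)):
                raise DomainError(f"payment for {state!r} must be positive, got {value}")

    def __getitem__(self, state: str) -> float:
        return self.entries[state.strip().upper()]

    def __contains__(self, state: str) -> bool:
        return state.strip().upper() in self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"state": s, "payment_usd_per_ha_yr": v}
            for s, v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=_PAYMENT_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def load_payment_schedule(path) -> PaymentSchedule:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"payment schedule not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _PAYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: payment schedule missing columns {missing}")
    entries: dict[str, float] = {}
    for _, row in df.iterrows():
        state = str(row["state"]).strip().upper()
        try:
            value = float(row["payment_usd_per_ha_yr"])
        except ValueError:
            raise SchemaError(
                f"{path}: non-numeric payment {row['payment_usd_per_ha_yr']!r}"
            ) from None
        if state in entries:
            raise IntegrityError(f"{path}: duplicate payment row for state {state}")
        entries[state] = value
    return PaymentSchedule(entries=entries)
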