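"""Marginal cost curves for SOC sequestration and threshold queries.

Each convertible stratum is priced at payment / CO2 rate and the strata are
sorted by unit cost, giving the supply curve of sequestration: the cumulative
annual quantity available at or below any carbon price.  Threshold summaries
report, for each candidate price (by default the low and high geologic
CO2-storage cost estimates), the quantity supplied by each tillage sequence,
its share of the below-threshold quantity, and its share of the scenario's
total annual potential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .economics import (
    PaymentSchedule,
    ReserveFraction,
    apply_reserve,
    carbon_value,
)
from .errors import ConfigurationError, DomainError, EmptyInputError
from .factors import FactorKind, FactorTable, ReferenceStockTable
from .soc_model import (
    DEFAULT_HORIZON,
    EquilibriumHorizon,
    SequestrationResult,
    Stratum,
    TillageSequence,
    compute_rates,
)

#: Default cost thresholds: low/high geologic CO2 capture-and-storage cost
#: estimates ($30 and $71 per Mg CO2 in 2005 dollars, restated to 2014).
DEFAULT_THRESHOLDS = (36.36, 86.06)

#: Default per-kind relative factor uncertainty (percent) for the sweep:
#: land-use factors ~12 %, tillage factors under 10 %, input factors under 15 %.
DEFAULT_FACTOR_UNCERTAINTY_PCT = {
    FactorKind.LU: 12.0,
    FactorKind.MG: 10.0,
    FactorKind.I: 15.0,
}


@dataclass(frozen=True)
class CostPoint:
    stratum_id: str
    sequence: TillageSequence
    unit_cost: float  # $ / Mg CO2
    annual_qty: float  # Tg CO2 / yr
    cumulative_qty: float  # Tg CO2 / yr


@dataclass
class CostCurve:
    """Strata sorted by unit cost, plus the strata excluded from pricing."""

    points: list[CostPoint]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total_qty(self) -> float:
        return self.points[-1].cumulative_qty if self.points else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum_id": p.stratum_id,
                    "sequence": p.sequence.value,
                    "unit_cost_usd_per_mg_co2": p.unit_cost,
                    "annual_tg_co2": p.annual_qty,
                    "cumulative_tg_co2": p.cumulative_qty,
                }
                for p in self.points
            ],
            columns=[
                "stratum_id",
                "sequence",
                "unit_cost_usd_per_mg_co2",
                "annual_tg_co2",
                "cumulative_tg_co2",
            ],
        )


@dataclass(frozen=True)
class ThresholdSummary:
    """Quantities and shares below one cost threshold, by tillage sequence."""

    threshold: float
    qty_by_sequence: dict[str, float]
    total_qty: float
    shares_within_pct: dict[str, float]
    shares_of_total_pct: dict[str, float]
    total_share_of_potential_pct: float


def build_curve(
    results: Sequence[SequestrationResult],
    payments: PaymentSchedule,
    reserve: ReserveFraction = ReserveFraction(),
) -> CostCurve:
    """Price each positive-rate stratum and assemble the sorted cost curve.

    Zero-rate strata (already no-till, or not cropland in 1997) and
    negative-rate strata are routed to ``excluded`` with a reason instead of
    being priced.  Ties in unit cost are broken by stratum_id so the curve is
    identical across runs.  A non-zero reserve fraction discounts the
    creditable CO2 rate, raising every unit cost by 1/(1-f) and shrinking
    quantities by (1-f).
    """
    if len(results) == 0:
        raise EmptyInputError("no sequestration results to build a curve from")
    missing = sorted(
        {r.state for r in results if r.eligible and r.rate_co2 > 0 and r.state not in payments}
    )
    if missing:
        ids = [r.stratum_id for r in results if r.state in set(missing)]
        raise ConfigurationError(
            f"states {missing} have no payment; offending strata: {ids[:20]}"
        )
    priced = []
    excluded: list[tuple[str, str]] = []
    for r in results:
        if not r.eligible:
            reason = r.flags[0] if r.flags else "ineligible"
            excluded.append((r.stratum_id, reason))
        elif r.rate_co2 == 0:
            excluded.append((r.stratum_id, "zero-rate"))
        elif r.rate_co2 < 0:
            excluded.append((r.stratum_id, "negative-rate"))
        else:
            credit_rate = apply_reserve(r.rate_co2, reserve)
            cost = carbon_value(payments[r.state], credit_rate).usd_per_mg_co2
            qty = r.annual_total_co2 * (1.0 - reserve.fraction)
            priced.append((cost, r.stratum_id, r.sequence, qty))
    priced.sort(key=lambda t: (t[0], t[1]))
    points: list[CostPoint] = []
    cum = 0.0
    for cost, sid, seq, qty in priced:
        cum += qty
        points.append(CostPoint(sid, seq, cost, qty, cum))
    return CostCurve(points=points, excluded=excluded)


def quantity_below(curve: CostCurve, price: float) -> float:
    """Annual quantity (Tg CO2 / yr) available strictly below ``price``.

    A step function of price, non-decreasing, stepping exactly at the
    distinct unit costs; zero below the cheapest point and the curve total
    above the dearest.
    """
    if price < 0:
        raise DomainError(f"price must be >= 0, got {price}")
    return float(sum(p.annual_qty for p in curve.points if p.unit_cost < price))


def threshold_summary(
    curve: CostCurve,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    total_potential: Optional[float] = None,
) -> list[ThresholdSummary]:
    """Per-sequence quantities and shares below each cost threshold.

    ``total_potential`` is the scenario-wide annual potential (Tg CO2 / yr)
    used as the denominator of the share-of-total column; it defaults to the
    curve total but should normally include zero-rate (already-NT) land.
    """
    if total_potential is None:
        total_potential = curve.total_qty
    if not total_potential > 0:
        raise DomainError(f"total_potential must be > 0, got {total_potential}")
    summaries = []
    for threshold in thresholds:
        if not threshold > 0:
            raise DomainError(f"thresholds must be positive, got {threshold}")
        below = [p for p in curve.points if p.unit_cost < threshold]
        qty: dict[str, float] = {}
        for p in below:
            qty[p.sequence.value] = qty.get(p.sequence.value, 0.0) + p.annual_qty
        total = sum(qty.values())
        shares_within = {
            s: (100.0 * q / total if total > 0 else 0.0) for s, q in qty.items()
        }
        shares_total = {s: 100.0 * q / total_potential for s, q in qty.items()}
        summaries.append(
            ThresholdSummary(
                threshold=threshold,
                qty_by_sequence=qty,
                total_qty=total,
                shares_within_pct=shares_within,
                shares_of_total_pct=shares_total,
                total_share_of_potential_pct=100.0 * total / total_potential,
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[ThresholdSummary]) -> pd.DataFrame:
    """Tidy (threshold, sequence) table, with a TOTAL row per threshold."""
    rows = []
    for s in summaries:
        for seq in sorted(s.qty_by_sequence):
            rows.append(
                {
                    "threshold_usd_per_mg_co2": s.threshold,
                    "sequence": seq,
                    "annual_tg_co2": s.qty_by_sequence[seq],
                    "share_within_pct": s.shares_within_pct[seq],
                    "share_of_total_pct": s.shares_of_total_pct[seq],
                }
            )
        rows.append(
            {
                "threshold_usd_per_mg_co2": s.threshold,
                "sequence": "TOTAL",
                "annual_tg_co2": s.total_qty,
                "share_within_pct": 100.0 if s.total_qty > 0 else 0.0,
                "share_of_total_pct": s.total_share_of_potential_pct,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "threshold_usd_per_mg_co2",
            "sequence",
            "annual_tg_co2",
            "share_within_pct",
            "share_of_total_pct",
        ],
    )


# --------------------------------------------------------------------------
# Factor-uncertainty sensitivity sweep
# --------------------------------------------------------------------------


def sensitivity_sweep(
    strata: Sequence[Stratum],
    factors: FactorTable,
    refs: ReferenceStockTable,
    payments: PaymentSchedule,
    factor_uncertainty_pct: Optional[dict] = None,
    n_draws: int = 100,
    seed: int = 0,
    prices: Optional[Sequence[float]] = None,
    horizon: EquilibriumHorizon = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Quantity-below-price envelope under factor-level uncertainty.

    Each draw perturbs every factor multiplier independently with a relative
    Gaussian error at its kind's stated percentage, recomputes all rates
    through the SOC model, rebuilds the curve, and evaluates the quantity
    available below each price.  Returns a DataFrame indexed by price with
    the per-price min, 2.5 %, median, 97.5 % and max across draws.  Fully
    determined by ``seed``.
    """
    if n_draws < 1:
        raise DomainError(f"n_draws must be >= 1, got {n_draws}")
    if factor_uncertainty_pct is None:
        factor_uncertainty_pct = (
            dict(factors.uncertainty_pct)
            if factors.uncertainty_pct
            else dict(DEFAULT_FACTOR_UNCERTAINTY_PCT)
        )
    pct = {}
    for kind in FactorKind:
        p = float(factor_uncertainty_pct.get(kind, factor_uncertainty_pct.get(kind.value, 0.0)))
        if p < 0 or p >= 100:
            raise DomainError(f"uncertainty for {kind.value} must be in [0, 100), got {p}")
        pct[kind] = p
    if prices is None:
        base = build_curve(compute_rates(strata, factors, refs, horizon), payments)
        costs = [p.unit_cost for p in base.points]
        if not costs:
            raise EmptyInputError("base curve has no priced points")
        prices = np.linspace(min(costs), max(costs) * 1.01, 25)
    prices = np.asarray(sorted(prices), dtype=float)

    rng = np.random.default_rng(seed)
    keys = sorted(factors.entries, key=lambda k: (k[0].value, k[1], k[2].value))
    draws = np.empty((n_draws, len(prices)))
    for d in range(n_draws):
        perturbed = {}
        for key in keys:
            sigma = pct[key[0]] / 100.0
            mult = 1.0 + sigma * rng.standard_normal() if sigma > 0 else 1.0
            perturbed[key] = factors.entries[key] * max(mult, 1e-6)
        with warnings.catch_warnings():
            # perturbation can transiently invert NT/CT ordering; not actionable here
            warnings.simplefilter("ignore")
            ftab = FactorTable(entries=perturbed, uncertainty_pct=dict(factors.uncertainty_pct))
        curve = build_curve(compute_rates(strata, ftab, refs, horizon), payments)
        draws[d] = [quantity_below(curve, price) for price in prices]

    return pd.DataFrame(
        {
            "price_usd_per_mg_co2": prices,
            "qty_min": draws.min(axis=0),
            "qty_q025": np.quantile(draws, 0.025, axis=0),
            "qty_median": np.quantile(draws, 0.5, axis=0),
            "qty_q975": np.quantile(draws, 0.975, axis=0),
            "qty_max": draws.max(axis=0),
        }
    ).set_index("price_usd_per_mg_co2")
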