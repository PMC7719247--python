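import numpy as np
import pytest

from soccurve import (
    CO2_PER_C,
    GeneratorConfig,
    PaymentSchedule,
    ReserveFraction,
    SequestrationResult,
    TillageSequence,
    aggregate_by_sequence,
    build_curve,
    compute_rates,
    generate_bundle,
    quantity_below,
    sensitivity_sweep,
    threshold_summary,
)
from soccurve.cost_curve import DEFAULT_THRESHOLDS
from soccurve.errors import ConfigurationError, DomainError, EmptyInputError


def make_result(sid, rate_co2, area_ha=1.0e6, state="IA", seq=TillageSequence.CTCTNT,
                eligible=True, flags=()):
    rate_c = rate_co2 / CO2_PER_C
    annual_co2 = rate_co2 * area_ha / 1.0e6
    return SequestrationResult(
        stratum_id=sid,
        state=state,
        sequence=seq,
        area_ha=area_ha,
        rate_c=rate_c,
        rate_co2=rate_co2,
        annual_total_c=annual_co2 / CO2_PER_C,
        annual_total_co2=annual_co2,
        total_20yr_c=20 * annual_co2 / CO2_PER_C,
        total_20yr_co2=20 * annual_co2,
        eligible=eligible,
        flags=tuple(flags),
    )


PAY = PaymentSchedule(entries={"IA": 10.0, "TX": 20.0, "NH": 5.0})


def test_curve_sorted_with_cumulative_quantity():
    # unit costs 10/1=10, 10/2=5, 10/0.5=20; qty 1 Tg each on 1 Mha
    results = [make_result("a", 1.0), make_result("b", 2.0), make_result("c", 0.5)]
    curve = build_curve(results, PAY)
    assert [p.stratum_id for p in curve.points] == ["b", "a", "c"]
    assert [p.unit_cost for p in curve.points] == pytest.approx([5.0, 10.0, 20.0])
    assert [p.cumulative_qty for p in curve.points] == pytest.approx([2.0, 3.0, 1.0 + 2.0 + 0.5])
    assert curve.excluded == []


def test_zero_rate_stratum_routed_to_excluded():
    results = [
        make_result("a", 1.0),
        make_result("z", 0.0, seq=TillageSequence.CTNTNT, eligible=False,
                    flags=("already-no-till",)),
    ]
    curve = build_curve(results, PAY)
    assert [p.stratum_id for p in curve.points] == ["a"]
    assert curve.excluded == [("z", "already-no-till")]


def test_equal_cost_ties_broken_by_stratum_id():
    results = [make_result(sid, 1.0) for sid in ("s3", "s1", "s2")]
    first = build_curve(results, PAY)
    second = build_curve(list(reversed(results)), PAY)
    ids = [p.stratum_id for p in first.points]
    assert ids == ["s1", "s2", "s3"]
    assert ids == [p.stratum_id for p in second.points]
    assert first.to_frame().equals(second.to_frame())


def test_unresolvable_state_is_configuration_error():
    results = [make_result("a", 1.0, state="ZZ")]
    with pytest.raises(ConfigurationError, match="ZZ"):
        build_curve(results, PAY)
    with pytest.raises(EmptyInputError):
        build_curve([], PAY)


def test_quantity_below_strict_boundaries():
    curve = build_curve([make_result("a", 1.0), make_result("b", 2.0)], PAY)
    # costs are 10 and 5
    assert quantity_below(curve, 4.99) == 0.0
    assert quantity_below(curve, 5.0) == 0.0  # strictly below, boundary excluded
    assert quantity_below(curve, 5.01) == pytest.approx(2.0)
    assert quantity_below(curve, 1e9) == pytest.approx(curve.total_qty)
    with pytest.raises(DomainError):
        quantity_below(curve, -1.0)


def test_quantity_below_matches_brute_force_on_random_curves():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = rng.integers(1, 100)
        results = [
            make_result(f"s{i:03d}", rate_co2=float(rng.uniform(0.05, 3.0)),
                        area_ha=float(rng.uniform(1e4, 5e6)))
            for i in range(n)
        ]
        curve = build_curve(results, PAY)
        for price in rng.uniform(0, 250, size=10):
            brute = sum(p.annual_qty for p in curve.points if p.unit_cost < price)
            assert quantity_below(curve, float(price)) == pytest.approx(brute, rel=1e-12)


def test_quantity_below_steps_exactly_at_distinct_costs():
    results = [make_result("a", 1.0), make_result("b", 2.0), make_result("c", 1.0, state="TX")]
    curve = build_curve(results, PAY)
    costs = sorted({p.unit_cost for p in curve.points})
    eps = 1e-9
    prev_total = 0.0
    for c in costs:
        assert quantity_below(curve, c - eps) == quantity_below(curve, c)
        after = quantity_below(curve, c + eps)
        assert after > prev_total
        prev_total = after


def test_payment_doubling_doubles_costs_quantities_unchanged():
    bundle = generate_bundle(GeneratorConfig(n_strata=200, seed=9))
    results = compute_rates(bundle.strata, bundle.factors, bundle.ref_stocks)
    curve = build_curve(results, bundle.payments)
    doubled = PaymentSchedule(entries={s: 2 * v for s, v in bundle.payments.entries.items()})
    curve2 = build_curve(results, doubled)
    assert [p.stratum_id for p in curve2.points] == [p.stratum_id for p in curve.points]
    for a, b in zip(curve.points, curve2.points):
        assert b.unit_cost == pytest.approx(2 * a.unit_cost, rel=1e-12)
        assert b.annual_qty == a.annual_qty
        assert b.cumulative_qty == a.cumulative_qty


def test_curve_conservation_points_plus_excluded():
    bundle = generate_bundle(GeneratorConfig(n_strata=500, seed=13))
    results = compute_rates(bundle.strata, bundle.factors, bundle.ref_stocks)
    curve = build_curve(results, bundle.payments)
    total_potential = sum(r.annual_total_co2 for r in results)
    excluded_ids = {sid for sid, _ in curve.excluded}
    excluded_qty = sum(r.annual_total_co2 for r in results if r.stratum_id in excluded_ids)
    assert curve.total_qty + excluded_qty == pytest.approx(total_potential, rel=1e-9)
    assert len(curve.points) + len(curve.excluded) == len(results)


def test_reserve_fraction_scales_curve():
    results = [make_result("a", 1.0), make_result("b", 2.0)]
    base = build_curve(results, PAY)
    f = 0.2
    reserved = build_curve(results, PAY, ReserveFraction(f))
    for a, b in zip(base.points, reserved.points):
        assert b.unit_cost == pytest.approx(a.unit_cost / (1 - f), rel=1e-12)
        assert b.annual_qty == pytest.approx(a.annual_qty * (1 - f), rel=1e-12)


# --------------------------------------------------------------------------
# threshold summaries
# --------------------------------------------------------------------------


def test_default_thresholds_are_geologic_storage_costs():
    assert DEFAULT_THRESHOLDS == (36.36, 86.06)


def test_single_sequence_has_full_within_share():
    curve = build_curve([make_result("a", 1.0)], PAY)
    (summary,) = threshold_summary(curve, [50.0], total_potential=curve.total_qty)
    assert summary.shares_within_pct == {"CTCTNT": pytest.approx(100.0)}
    assert summary.total_share_of_potential_pct == pytest.approx(100.0)


def test_threshold_shares_and_share_of_total():
    # per-sequence quantities below the threshold: 75.1, 4.2, 0.1, 9.0, 0.7
    seq_qty = {
        TillageSequence.CTCTNT: 75.1,
        TillageSequence.CTRTNT: 4.2,
        TillageSequence.RTRTNT: 0.1,
        TillageSequence.NCCTNT: 9.0,
        TillageSequence.NCRTNT: 0.7,
    }
    results = [
        make_result(f"s{i}", 1.0, area_ha=q * 1e6, seq=seq)
        for i, (seq, q) in enumerate(seq_qty.items())
    ]
    curve = build_curve(results, PAY)  # all priced at $10, below the threshold
    (summary,) = threshold_summary(curve, [36.36], total_potential=140.1)
    assert summary.total_qty == pytest.approx(89.1, rel=1e-12)
    assert summary.shares_within_pct["CTCTNT"] == pytest.approx(84.3, abs=0.05)
    shares = sum(summary.shares_within_pct.values())
    assert shares == pytest.approx(100.0, rel=1e-12)
    assert summary.shares_of_total_pct["CTCTNT"] == pytest.approx(100 * 75.1 / 140.1, rel=1e-12)


def test_threshold_above_max_cost_reproduces_sequence_totals():
    bundle = generate_bundle(GeneratorConfig(n_strata=300, seed=21))
    results = compute_rates(bundle.strata, bundle.factors, bundle.ref_stocks)
    curve = build_curve(results, bundle.payments)
    table1 = aggregate_by_sequence(results)
    (summary,) = threshold_summary(
        curve, [1e9], total_potential=sum(r.annual_total_co2 for r in results)
    )
    for seq, qty in summary.qty_by_sequence.items():
        assert qty == pytest.approx(table1.loc[seq, "annual_tg_co2"], rel=1e-9)
    with pytest.raises(DomainError):
        threshold_summary(curve, [36.36], total_potential=0.0)
    with pytest.raises(DomainError):
        threshold_summary(curve, [-1.0], total_potential=1.0)


# --------------------------------------------------------------------------
# sensitivity sweep
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_bundle():
    return generate_bundle(GeneratorConfig(n_strata=60, seed=17))


def test_zero_uncertainty_collapses_to_point_curve(small_bundle):
    b = small_bundle
    results = compute_rates(b.strata, b.factors, b.ref_stocks)
    curve = build_curve(results, b.payments)
    prices = [p.unit_cost + 1e-9 for p in curve.points[::10]]
    env = sensitivity_sweep(
        b.strata, b.factors, b.ref_stocks, b.payments,
        factor_uncertainty_pct={"LU": 0.0, "MG": 0.0, "I": 0.0},
        n_draws=5, seed=1, prices=prices,
    )
    for price in prices:
        point = quantity_below(curve, price)
        row = env.loc[price]
        assert row["qty_min"] == pytest.approx(point, rel=1e-12)
        assert row["qty_max"] == pytest.approx(point, rel=1e-12)


def test_sweep_deterministic_and_median_within_extremes(small_bundle):
    b = small_bundle
    kwargs = dict(n_draws=20, seed=42, prices=[10.0, 40.0, 80.0, 200.0])
    env1 = sensitivity_sweep(b.strata, b.factors, b.ref_stocks, b.payments, **kwargs)
    env2 = sensitivity_sweep(b.strata, b.factors, b.ref_stocks, b.payments, **kwargs)
    assert env1.equals(env2)  # bit-identical under a fixed seed
    assert (env1["qty_min"] <= env1["qty_median"]).all()
    assert (env1["qty_median"] <= env1["qty_max"]).all()
    assert (env1["qty_min"] <= env1["qty_q025"]).all()
    assert (env1["qty_q975"] <= env1["qty_max"]).all()


def test_sweep_invalid_percentages_rejected(small_bundle):
    b = small_bundle
    with pytest.raises(DomainError):
        sensitivity_sweep(b.strata, b.factors, b.ref_stocks, b.payments,
                          factor_uncertainty_pct={"LU": -5.0}, n_draws=2, seed=0,
                          prices=[10.0])
    with pytest.raises(DomainError):
        sensitivity_sweep(b.strata, b.factors, b.ref_stocks, b.payments,
                          n_draws=0, seed=0, prices=[10.0])
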