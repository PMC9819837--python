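"""Markov cohort trace and outcome accumulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from markovcea import (
    Correction,
    DiscountTiming,
    ModelConfig,
    StrategyInputs,
    accumulate_outcomes,
    batch_outcomes,
    build_transition_matrix,
    run_cohort_trace,
    run_strategy,
)
from markovcea.errors import InvalidStrategyError

# random-but-valid strategies for the property tests
strategies_st = st.builds(
    StrategyInputs,
    name=st.just("x"),
    cost_pfs_month=st.floats(min_value=0, max_value=50_000),
    cost_pd_month=st.floats(min_value=0, max_value=50_000),
    utility_pfs=st.floats(min_value=0, max_value=1),
    utility_pd=st.floats(min_value=0, max_value=1),
    p_pfs_to_pd=st.floats(min_value=0, max_value=0.5),
    p_pfs_to_death=st.floats(min_value=0, max_value=0.5),
    p_pd_to_death=st.floats(min_value=0, max_value=1),
)


def test_transition_matrix_matches_published_palbociclib_row(palbociclib):
    m = build_transition_matrix(palbociclib)
    np.testing.assert_allclose(m[0], [0.9534376, 0.0459708, 0.0005916], atol=1e-12)
    np.testing.assert_allclose(m[1], [0.0, 1 - 0.0116347, 0.0116347], atol=1e-12)
    np.testing.assert_allclose(m[2], [0.0, 0.0, 1.0], atol=0)


def test_zero_probability_matrix_is_identity_with_absorbing_death():
    s = StrategyInputs("idle", 0, 0, 1, 1, 0, 0, 0)
    np.testing.assert_array_equal(build_transition_matrix(s), np.eye(3))


def test_probability_sum_above_one_rejected():
    with pytest.raises(InvalidStrategyError):
        StrategyInputs("bad", 0, 0, 1, 1, 0.9, 0.2, 0)


def test_first_cycle_occupancy_is_pfs_row(palbociclib, model):
    m = build_transition_matrix(palbociclib)
    trace = run_cohort_trace(m, model.config)
    np.testing.assert_allclose(trace.occupancy[1], m[0], atol=1e-15)


def test_death_absorbs_everything_eventually(palbociclib):
    cfg = ModelConfig(horizon_cycles=5000)
    trace = run_cohort_trace(build_transition_matrix(palbociclib), cfg)
    assert trace.occupancy[-1, 2] == pytest.approx(1.0, abs=1e-9)


@given(s=strategies_st)
def test_trace_conservation_and_death_monotonicity(s):
    cfg = ModelConfig(horizon_cycles=60)
    trace = run_cohort_trace(build_transition_matrix(s), cfg)
    np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
    assert (np.diff(trace.occupancy[:, 2]) >= -1e-12).all()
    assert (trace.occupancy >= -1e-12).all() and (trace.occupancy <= 1 + 1e-12).all()


def test_two_cycle_closed_form_oracle():
    """Hand-computed 2-cycle totals (independent arithmetic, no engine)."""
    p12, p13, p23 = 0.2, 0.1, 0.3
    c_pfs, c_pd, u_pfs, u_pd = 100.0, 50.0, 0.9, 0.5
    rate = 0.035
    s = StrategyInputs("toy", c_pfs, c_pd, u_pfs, u_pd, p12, p13, p23)
    cfg = ModelConfig(horizon_cycles=2, annual_discount_rate=rate)

    # occupancy: s0 = (1,0,0); s1 = (0.7, 0.2, 0.1)
    # s2 = (0.7*0.7, 0.7*0.2 + 0.2*0.7, 0.7*0.1 + 0.2*0.3 + 0.1)
    s1 = (0.7, 0.2, 0.1)
    s2 = (0.49, 0.28, 0.23)
    cred1 = ((1 + s1[0]) / 2, (0 + s1[1]) / 2)
    cred2 = ((s1[0] + s2[0]) / 2, (s1[1] + s2[1]) / 2)
    v1 = (1 + rate) ** (-0.5 / 12)
    v2 = (1 + rate) ** (-1.5 / 12)
    exp_cost = (cred1[0] * c_pfs + cred1[1] * c_pd) * v1 + (cred2[0] * c_pfs + cred2[1] * c_pd) * v2
    exp_ly = ((cred1[0] + cred1[1]) * v1 + (cred2[0] + cred2[1]) * v2) / 12
    exp_qaly = (
        (cred1[0] * u_pfs + cred1[1] * u_pd) * v1 + (cred2[0] * u_pfs + cred2[1] * u_pd) * v2
    ) / 12

    res = run_strategy(s, cfg)
    assert res.total_cost == pytest.approx(exp_cost, abs=1e-10)
    assert res.life_years == pytest.approx(exp_ly, abs=1e-10)
    assert res.qalys == pytest.approx(exp_qaly, abs=1e-10)


def test_stay_forever_in_pfs_degenerate_case():
    s = StrategyInputs("stay", 1000.0, 0.0, 1.0, 1.0, 0, 0, 0)
    cfg = ModelConfig(horizon_cycles=120, annual_discount_rate=0.0)
    res = run_strategy(s, cfg)
    assert res.life_years == pytest.approx(10.0, abs=1e-9)
    assert res.qalys == pytest.approx(10.0, abs=1e-9)
    assert res.total_cost == pytest.approx(120 * 1000.0, abs=1e-6)


@given(s=strategies_st)
def test_discounting_never_increases_totals(s):
    cfg0 = ModelConfig(horizon_cycles=24, annual_discount_rate=0.0)
    cfg1 = ModelConfig(horizon_cycles=24, annual_discount_rate=0.035)
    cfg2 = ModelConfig(horizon_cycles=24, annual_discount_rate=0.10)
    r0, r1, r2 = (run_strategy(s, c) for c in (cfg0, cfg1, cfg2))
    tol = 1e-9
    assert r1.total_cost <= r0.total_cost + tol and r2.total_cost <= r1.total_cost + tol
    assert r1.qalys <= r0.qalys + tol and r2.qalys <= r1.qalys + tol
    assert r1.life_years <= r0.life_years + tol and r2.life_years <= r1.life_years + tol


@given(s=strategies_st)
def test_trapezoidal_totals_lie_between_endpoint_variants(s):
    results = {}
    for corr in (Correction.START, Correction.WITHIN_CYCLE, Correction.NONE):
        cfg = ModelConfig(horizon_cycles=24, correction=corr)
        results[corr] = run_strategy(s, cfg)
    lo = min(results[Correction.START].total_cost, results[Correction.NONE].total_cost)
    hi = max(results[Correction.START].total_cost, results[Correction.NONE].total_cost)
    assert lo - 1e-9 <= results[Correction.WITHIN_CYCLE].total_cost <= hi + 1e-9
    lo = min(results[Correction.START].qalys, results[Correction.NONE].qalys)
    hi = max(results[Correction.START].qalys, results[Correction.NONE].qalys)
    assert lo - 1e-9 <= results[Correction.WITHIN_CYCLE].qalys <= hi + 1e-9


@given(s=strategies_st)
def test_qalys_never_exceed_life_years(s):
    res = run_strategy(s, ModelConfig(horizon_cycles=36))
    assert res.qalys <= res.life_years + 1e-12
    assert res.total_cost == pytest.approx(res.cost_pfs + res.cost_pd, abs=1e-6)


@pytest.mark.parametrize("timing", list(DiscountTiming))
def test_discount_timing_variants_are_ordered(palbociclib, timing):
    cfg = ModelConfig(horizon_cycles=120, discount_timing=timing)
    res = run_strategy(palbociclib, cfg)
    start = run_strategy(palbociclib, ModelConfig(discount_timing=DiscountTiming.CYCLE_START))
    end = run_strategy(palbociclib, ModelConfig(discount_timing=DiscountTiming.CYCLE_END))
    assert end.total_cost - 1e-9 <= res.total_cost <= start.total_cost + 1e-9


def test_mismatched_config_rejected(palbociclib):
    cfg_a = ModelConfig(horizon_cycles=12)
    cfg_b = ModelConfig(horizon_cycles=24)
    trace = run_cohort_trace(build_transition_matrix(palbociclib), cfg_a)
    with pytest.raises(ValueError):
        accumulate_outcomes(trace, palbociclib, cfg_b)


def test_batch_engine_matches_scalar_engine(palbociclib, ribociclib, model):
    """The vectorised PSA path and the scalar path are the same arithmetic."""
    cfg = model.config
    arms = [palbociclib, ribociclib]
    cost, ly, qaly = batch_outcomes(
        [a.p_pfs_to_pd for a in arms],
        [a.p_pfs_to_death for a in arms],
        [a.p_pd_to_death for a in arms],
        [a.cost_pfs_month for a in arms],
        [a.cost_pd_month for a in arms],
        [a.utility_pfs for a in arms],
        [a.utility_pd for a in arms],
        cfg,
    )
    for i, arm in enumerate(arms):
        res = run_strategy(arm, cfg)
        assert cost[i] == pytest.approx(res.total_cost, rel=1e-12)
        assert ly[i] == pytest.approx(res.life_years, rel=1e-12)
        assert qaly[i] == pytest.approx(res.qalys, rel=1e-12)


def test_trace_export_has_expected_columns(palbociclib, model):
    frame = run_cohort_trace(build_transition_matrix(palbociclib), model.config).to_frame()
    assert list(frame.columns) == [
        "cycle", "pfs", "pd", "death", "credited_pfs", "credited_pd", "discount_factor",
    ]
    assert len(frame) == model.config.horizon_cycles
    assert frame["cycle"].iloc[0] == 1
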