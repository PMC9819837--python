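"""One-way deterministic sensitivity analysis, tornado and thresholds."""

import pytest

from markovcea import Dominance, ParameterSpec, one_way, run_dsa, threshold_search, tornado
from markovcea.dsa import apply_parameter
from markovcea.errors import AmbiguousThresholdError, InvalidStrategyError


@pytest.fixture(scope="module")
def dsa_specs(base_config):
    return {s.id: s for s in base_config.dsa_specs()}


def test_degenerate_range_reproduces_base_case(model, base_result):
    spec = ParameterSpec(
        id="frozen", arm="comparator", field="cost_pfs_month",
        base_value=11_628.5, lower_bound=11_628.5, upper_bound=11_628.5,
    )
    lo, hi = one_way(spec, model)
    for row in (lo, hi):
        assert row.result.comparator.total_cost == base_result.comparator.total_cost
        assert row.result.intervention.qalys == base_result.intervention.qalys
        assert row.result.cea.delta_cost == base_result.cea.delta_cost


def test_one_way_perturbs_only_the_target_arm(model, dsa_specs, base_result):
    lo, hi = one_way(dsa_specs["cost_pfs_ribociclib"], model)
    for row in (lo, hi):
        # comparator untouched, bit-for-bit
        assert row.result.comparator.total_cost == base_result.comparator.total_cost
        assert row.result.intervention.qalys == base_result.intervention.qalys


def test_shared_parameter_moves_both_arms(model, dsa_specs, base_result):
    lo, _ = one_way(dsa_specs["cost_pd"], model)
    assert lo.result.comparator.total_cost < base_result.comparator.total_cost
    assert lo.result.intervention.total_cost < base_result.intervention.total_cost


def test_pd_cost_bounds_preserve_dominance(model, dsa_specs):
    lo, hi = one_way(dsa_specs["cost_pd"], model)
    assert lo.result.cea.dominance is Dominance.INTERVENTION_DOMINANT
    assert hi.result.cea.dominance is Dominance.INTERVENTION_DOMINANT


def test_monotone_response_to_costs_and_utilities(model, base_config):
    """Total cost is non-decreasing in any state-cost parameter and QALYs
    non-decreasing in any utility parameter, across all DSA runs."""
    for spec in base_config.dsa_specs():
        lo, hi = one_way(spec, model)
        for arm in ("intervention", "comparator"):
            lo_res = getattr(lo.result, arm)
            hi_res = getattr(hi.result, arm)
            if spec.field.startswith("cost"):
                assert lo_res.total_cost <= hi_res.total_cost + 1e-9
                assert lo_res.qalys == hi_res.qalys
            elif spec.field.startswith("utility"):
                assert lo_res.qalys <= hi_res.qalys + 1e-9
                assert lo_res.total_cost == hi_res.total_cost


def test_out_of_range_bound_raises(model):
    spec = ParameterSpec(
        id="bad_utility", arm="intervention", field="utility_pfs",
        base_value=0.7, lower_bound=0.7, upper_bound=1.2,
    )
    with pytest.raises(InvalidStrategyError):
        one_way(spec, model)


def test_discount_rate_is_addressable_as_config_parameter(model):
    spec = ParameterSpec(
        id="discount", arm="config", field="annual_discount_rate",
        base_value=0.035, lower_bound=0.015, upper_bound=0.035,
    )
    lo, hi = one_way(spec, model)
    # lower discounting inflates both arms' totals
    assert lo.result.comparator.total_cost > hi.result.comparator.total_cost


class TestTornado:
    def test_single_parameter_table(self, model, dsa_specs):
        table = tornado([one_way(dsa_specs["cost_pd"], model)], wtp=576_150.0)
        assert len(table) == 1
        assert table.loc[0, "parameter"] == "cost_pd"

    def test_zero_width_range_ranks_last(self, model, dsa_specs):
        frozen = ParameterSpec(
            id="frozen", arm="comparator", field="cost_pfs_month",
            base_value=11_628.5, lower_bound=11_628.5, upper_bound=11_628.5,
        )
        rows = run_dsa([dsa_specs["cost_pd"], frozen], model)
        table = tornado(rows, wtp=576_150.0)
        assert table.iloc[-1]["parameter"] == "frozen"
        assert table.iloc[-1]["spread"] == 0.0

    def test_full_set_is_ordered_by_nmb_spread(self, model, base_config):
        table = tornado(run_dsa(base_config.dsa_specs(), model), wtp=576_150.0)
        assert len(table) == 8
        assert (table["spread"].diff().dropna() <= 1e-9).all()
        # the wide ribociclib utility and progression ranges drive the model
        assert set(table.loc[:1, "parameter"]) == {
            "utility_pfs_ribociclib",
            "p_pfs_to_pd_ribociclib",
        }


class TestThresholdSearch:
    def _dominant(self, result):
        return result.cea.dominance is Dominance.INTERVENTION_DOMINANT

    def test_palbociclib_pfs_cost_dominance_threshold(self, model, dsa_specs):
        """Below some comparator PFS cost the intervention stops being
        cost-saving.  Independent oracle: total cost is linear in the
        monthly state cost, so the break-even point solves a linear
        equation in closed form."""
        spec = dsa_specs["cost_pfs_palbociclib"].__class__(
            id="cost_pfs_palbociclib", arm="comparator", field="cost_pfs_month",
            base_value=11_628.5, lower_bound=5_000.0, upper_bound=13_954.2,
        )
        found = threshold_search(spec, self._dominant, model)
        base = model.run()
        # linear oracle: comparator cost = pd_cost + unit_pfs_cost * slope
        slope = base.comparator.cost_pfs / model.comparator.cost_pfs_month
        oracle = (base.intervention.total_cost - base.comparator.cost_pd) / slope
        assert found == pytest.approx(oracle, rel=1e-3)
        # published neighbourhood: threshold reported near 9,612.9 QAR
        assert found == pytest.approx(9_612.9, rel=0.01)
        # plugging the threshold back puts the model at the flip point
        eps = 1e-3 * spec.base_value
        assert self._dominant(apply_parameter(model, spec, found + eps).run())
        assert not self._dominant(apply_parameter(model, spec, found - eps).run())

    def test_ribociclib_utility_dominance_threshold(self, model, dsa_specs):
        spec = dsa_specs["utility_pfs_ribociclib"]
        found = threshold_search(spec, self._dominant, model)
        # linear oracle: QALYs are linear in utility
        base = model.run()
        pfs_years = base.intervention.cost_pfs / (model.intervention.cost_pfs_month * 12)
        oracle = model.intervention.utility_pfs - (
            base.intervention.qalys - base.comparator.qalys
        ) / pfs_years
        assert found == pytest.approx(oracle, rel=1e-3)
        # published neighbourhood: dominance lost below about 0.622
        assert found == pytest.approx(0.622, rel=0.01)

    def test_ribociclib_progression_dominance_threshold(self, model, dsa_specs):
        spec = dsa_specs["p_pfs_to_pd_ribociclib"]
        found = threshold_search(spec, self._dominant, model)
        assert spec.lower_bound < found < spec.upper_bound
        eps = 5e-4 * spec.base_value
        assert self._dominant(apply_parameter(model, spec, found + eps).run())
        assert not self._dominant(apply_parameter(model, spec, found - eps).run())

    def test_constant_predicate_returns_none(self, model, dsa_specs):
        found = threshold_search(dsa_specs["cost_pd"], self._dominant, model)
        assert found is None

    def test_non_monotone_predicate_raises(self, model, dsa_specs):
        spec = dsa_specs["cost_pd"]
        calls = iter(range(10_000))

        def flappy(result):
            return next(calls) % 2 == 0

        with pytest.raises(AmbiguousThresholdError):
            threshold_search(spec, flappy, model)
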