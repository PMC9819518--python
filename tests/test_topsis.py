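"""Benchmark-anchored TOPSIS: panels, pooling, closeness, ranks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hisbench import (
    IndicatorSpec,
    aggregate_closeness,
    build_panel,
    deviations,
    evaluate_city,
    rank_results,
)
from hisbench.topsis import ClosenessResult


def brute_force(city, pi, ni, weight, orientation):
    """Plain transliteration of the pipeline in extended precision."""
    import decimal

    d = decimal.Decimal
    decimal.getcontext().prec = 50
    x = [d(repr(city)), d(repr(pi)), d(repr(ni))]
    norm = sum(t * t for t in x).sqrt()
    v = [d(repr(weight)) * t / norm for t in x]
    best = max(v) if orientation == "MAX" else min(v)
    worst = min(v) if orientation == "MAX" else max(v)
    return float((v[0] - best) ** 2), float((v[0] - worst) ** 2)


def spec_for(orientation, pi, ni, code="X"):
    return IndicatorSpec(code=code, orientation=orientation,
                         positive_ideal=pi, negative_ideal=ni)


class TestBuildPanel:
    def test_fully_specified_max_indicator(self):
        # life expectancy: city between its two published standards
        p = build_panel(spec_for("MAX", 85.29, 73.2), 75.20, 0.48)
        assert round(p.a_plus, 2) == 0.30
        assert round(p.a_minus, 2) == 0.26
        assert round(p.dev_plus_sq, 3) == 0.001
        assert round(p.dev_minus_sq, 3) == 0.000

    def test_one_sided_standard_with_zero_substitute(self):
        # forest-area rate: only the target is published
        p = build_panel(spec_for("MAX", 40, None), 11.23, 0.48)
        assert round(p.a_plus, 2) == 0.46
        assert p.a_minus == 0.0
        assert round(p.dev_plus_sq, 3) == 0.110
        assert round(p.dev_minus_sq, 3) == 0.017

    def test_min_indicator_city_beyond_negative_ideal(self):
        # diabetes mortality above the world-average ceiling: the city
        # itself becomes the anti-ideal
        spec = IndicatorSpec(code="X", orientation="MIN",
                             negative_ideal=18.5, substitute_pi=1)
        p = build_panel(spec, 30.52, 0.33)
        assert round(p.dev_plus_sq, 3) == 0.074
        assert p.dev_minus_sq == 0.0
        assert p.a_minus == p.v_city

    def test_city_outperforming_defines_its_own_ideal(self):
        # ambulances: city 8.80 beats the PI 3.3
        p = build_panel(spec_for("MAX", 3.3, 1), 8.80, 0.04)
        assert p.a_plus == p.v_city
        assert p.dev_plus_sq == 0.0

    def test_degenerate_equal_column(self):
        p = build_panel(spec_for("MAX", 7, 7), 7.0, 0.5)
        assert np.allclose(p.normalized, 1 / math.sqrt(3))
        assert p.a_plus == p.a_minus == p.v_city
        assert p.dev_plus_sq == p.dev_minus_sq == 0.0

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            build_panel(spec_for("MAX", 0, 0), 0.0, 0.5)

    def test_weight_out_of_range(self):
        with pytest.raises(ValueError, match="weight"):
            build_panel(spec_for("MAX", 1, 0), 0.5, 0.0)

    def test_deviation_accessor(self):
        p = build_panel(spec_for("MIN", 5, 20), 6.28, 0.13)
        assert deviations(p) == (p.dev_plus_sq, p.dev_minus_sq)
        # independent recomputation of both squared deviations
        assert deviations(p) == pytest.approx(
            brute_force(6.28, 5, 20, 0.13, "MIN"), abs=1e-15)


class TestAggregation:
    def test_health_status_element(self, evaluation):
        r = evaluation.element("HS")
        assert round(r.s_plus, 2) == 0.13
        assert round(r.closeness, 2) == 0.47

    def test_health_promotion_element(self, evaluation):
        assert round(evaluation.element("HP").closeness, 2) == 0.76

    def test_city_on_negative_ideal_scores_zero(self):
        specs = [spec_for("MAX", 10, 2, f"c{i}") for i in range(3)]
        panels = [build_panel(s, 2.0, 0.3) for s in specs]
        r = aggregate_closeness(panels, scope="E")
        assert r.closeness == 0.0 and r.s_minus == 0.0

    def test_degenerate_double_zero_defined_as_one(self, caplog):
        panels = [build_panel(spec_for("MAX", 5, 5), 5.0, 0.5)]
        with caplog.at_level("WARNING"):
            r = aggregate_closeness(panels, scope="E")
        assert r.closeness == 1.0
        assert "E" in caplog.text

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_closeness([], scope="E")


class TestRanking:
    def test_fixture_dimension_ranking(self, evaluation):
        order = [(r.scope, r.rank) for r in evaluation.dimension_results]
        assert order == [("ECDm", 1), ("SODm", 2), ("HEDm", 3), ("ENDm", 4)]

    def test_single_result(self):
        r = ClosenessResult("only", "element", ("a",), 1.0, 1.0, 0.5)
        assert rank_results([r])[0].rank == 1

    def test_ties_break_by_scope_code(self):
        a = ClosenessResult("B", "element", ("x",), 1, 1, 0.5)
        b = ClosenessResult("A", "element", ("y",), 1, 1, 0.5)
        ranked = rank_results([a, b])
        assert [(r.scope, r.rank) for r in ranked] == [("A", 1), ("B", 2)]


class TestEvaluateCity:
    def test_environment_is_the_weak_dimension(self, evaluation):
        r = evaluation.dimension("ENDm")
        assert round(r.closeness, 2) == 0.28
        assert r.rank == 4

    def test_household_debt_element_scores_zero(self, evaluation):
        assert round(evaluation.element("HHD").closeness, 2) == 0.00

    def test_city_on_every_positive_ideal_scores_one(self, bundle,
                                                     printed_weights):
        from hisbench import CityObservation

        fw = bundle.framework
        values = {c: fw.indicator_map[c].resolve_ideals("zero")[0]
                  for c in fw.indicator_codes}
        obs = CityObservation(city_id="ideal", year=None, values=values)
        res = evaluate_city(fw, obs, printed_weights)
        for r in (*res.element_results, *res.dimension_results):
            assert r.closeness == pytest.approx(1.0, abs=1e-12)

    def test_missing_weight_rejected(self, bundle, printed_weights):
        w = dict(printed_weights)
        del w["VR07"]
        with pytest.raises(ValueError, match="VR07"):
            evaluate_city(bundle.framework, bundle.observation, w)


# ---------------------------------------------------------------------
# Properties

panel_strategy = st.tuples(
    st.floats(0.01, 1e4), st.floats(0.01, 1e4), st.floats(0.01, 1e4),
    st.floats(0.01, 1.0), st.sampled_from(["MAX", "MIN"]),
)


def _ordered(city, a, b, orientation):
    pi, ni = (max(a, b), min(a, b)) if orientation == "MAX" else (min(a, b), max(a, b))
    return city, pi, ni


@settings(deadline=None, max_examples=300, derandomize=True)
@given(panel_strategy)
def test_panel_matches_brute_force_oracle(args):
    city, a, b, w, orientation = args
    city, pi, ni = _ordered(city, a, b, orientation)
    p = build_panel(spec_for(orientation, pi, ni), city, w)
    dp, dm = brute_force(city, pi, ni, w, orientation)
    assert p.dev_plus_sq == pytest.approx(dp, abs=1e-12, rel=1e-9)
    assert p.dev_minus_sq == pytest.approx(dm, abs=1e-12, rel=1e-9)
    assert all(0.0 <= r <= 1.0 for r in p.normalized)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(panel_strategy, st.floats(1e-3, 1e3))
def test_scale_invariance(args, k):
    """Multiplying (city, PI, NI) by k > 0 changes nothing downstream."""
    city, a, b, w, orientation = args
    city, pi, ni = _ordered(city, a, b, orientation)
    p1 = build_panel(spec_for(orientation, pi, ni), city, w)
    p2 = build_panel(spec_for(orientation, pi * k, ni * k), city * k, w)
    assert np.allclose(p1.normalized, p2.normalized, atol=1e-12)
    assert p1.dev_plus_sq == pytest.approx(p2.dev_plus_sq, abs=1e-12, rel=1e-9)
    assert p1.dev_minus_sq == pytest.approx(p2.dev_minus_sq, abs=1e-12, rel=1e-9)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.floats(1.0, 99.0), st.floats(0.0, 1.0), st.floats(0.01, 1.0))
def test_moving_toward_ideal_never_increases_deviation(city, step, w):
    """For a MAX indicator, nudging the city toward PI (re-normalizing)
    cannot increase its squared deviation from the ideal."""
    pi, ni = 100.0, 1.0
    closer = city + step * (pi - city)
    p0 = build_panel(spec_for("MAX", pi, ni), city, w)
    p1 = build_panel(spec_for("MAX", pi, ni), closer, w)
    assert p1.dev_plus_sq <= p0.dev_plus_sq + 1e-15


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(panel_strategy, min_size=1, max_size=6))
def test_closeness_bounded(panel_args):
    panels = []
    for i, (city, a, b, w, orientation) in enumerate(panel_args):
        city, pi, ni = _ordered(city, a, b, orientation)
        panels.append(build_panel(spec_for(orientation, pi, ni, f"c{i}"), city, w))
    r = aggregate_closeness(panels, scope="G")
    assert 0.0 <= r.closeness <= 1.0
    assert r.s_plus >= 0.0 and r.s_minus >= 0.0
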