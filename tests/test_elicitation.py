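"""Prospect valuation, lottery-choice simulation and switch-point inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obesipath import elicitation as el
from obesipath.errors import (
    InconsistencyError,
    InvalidParameterError,
    InvalidProbabilityError,
    MultipleSwitchError,
)


class TestProspectValue:
    def test_reduces_to_expected_value(self):
        assert el.prospect_value(el.Prospect(10, 0, 0.5),
                                 el.PTParams(1, 1, 1)) == pytest.approx(5.0)

    def test_concave_value_function(self):
        v = el.prospect_value(el.Prospect(10, 0, 0.5), el.PTParams(0.5, 1, 1))
        assert v == pytest.approx(np.sqrt(10) / 2)

    def test_certain_loss_scaled_by_lambda(self):
        v = el.prospect_value(el.Prospect(-4, 0, 1.0), el.PTParams(1, 2.25, 1))
        assert v == pytest.approx(-9.0)

    def test_invalid_probability_and_parameters(self):
        with pytest.raises(InvalidProbabilityError):
            el.Prospect(10, 0, 1.2)
        with pytest.raises(InvalidParameterError):
            el.PTParams(-0.1, 1, 1)
        with pytest.raises(InvalidParameterError):
            el.PTParams(1, 1, 0)

    @given(st.floats(1, 50), st.floats(1, 50), st.floats(0.4, 1.6),
           st.floats(1, 5), st.floats(0.3, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_increasing_in_x(self, x, dx, sigma, lam, gamma):
        p = el.PTParams(sigma, lam, gamma)
        lo = el.prospect_value(el.Prospect(x, 0.5, 0.4), p)
        hi = el.prospect_value(el.Prospect(x + dx, 0.5, 0.4), p)
        assert hi > lo

    @given(st.floats(0.4, 1.6), st.floats(1, 5), st.floats(0.5, 5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_losses_decrease_with_lambda(self, sigma, lam, dlam):
        pr = el.Prospect(5, -3, 0.5)
        v1 = el.prospect_value(pr, el.PTParams(sigma, lam, 0.7))
        v2 = el.prospect_value(pr, el.PTParams(sigma, lam + dlam, 0.7))
        assert v2 < v1


class TestSimulateChoices:
    def test_ev_dominant_row_chooses_b(self, design):
        params = el.PTParams(1, 1, 1)
        cv = el.simulate_choices(design, params)
        # last series-1 row: Plan B pays 170 with p=0.1, EV 17.45 vs 1.9
        assert cv.choices[13] == 1

    def test_tie_breaks_to_plan_a(self):
        row = el.LotteryRow(el.Prospect(5, 1, 0.5), el.Prospect(5, 1, 0.5))
        design = el.LotteryDesign([row] * 14, [row] * 14, [row] * 7)
        cv = el.simulate_choices(design, el.PTParams(0.8, 2, 0.7))
        assert all(c == 0 for c in cv.choices)

    def test_matches_row_by_row_brute_force(self, design):
        params = el.PTParams(0.6, 3.0, 0.7)
        cv = el.simulate_choices(design, params, noise=0)
        k = 0
        for series in design.series:
            for row in series:
                va = el.prospect_value(row.plan_a, params)
                vb = el.prospect_value(row.plan_b, params)
                assert cv.choices[k] == (1 if vb > va else 0)
                k += 1

    def test_noise_reproducible_under_seed(self, design):
        params = el.PTParams(0.8, 2, 0.7)
        a = el.simulate_choices(design, params, noise=0.5, seed=11)
        b = el.simulate_choices(design, params, noise=0.5, seed=11)
        assert a == b

    @given(st.floats(0.1, 1.9), st.floats(0.1, 10), st.floats(0.3, 1.4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_deterministic_choices_are_monotone(self, sigma, lam, gamma):
        design = el.default_design()
        cv = el.simulate_choices(design, el.PTParams(sigma, lam, gamma))
        el.infer_switchpoints(cv, design)  # raises on any switch-back

    @given(st.floats(0.2, 1.6), st.floats(0.2, 8),
           st.floats(0.35, 1.0), st.floats(0.35, 1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_series3_ordering_invariant_to_gamma(self, sigma, lam, g1, g2):
        """At 50/50 odds the Prelec weights cancel: gamma cannot matter."""
        design = el.default_design()
        c1 = el.simulate_choices(design, el.PTParams(sigma, lam, g1))
        c2 = el.simulate_choices(design, el.PTParams(sigma, lam, g2))
        assert c1.choices[28:] == c2.choices[28:]


class TestSwitchpoints:
    def test_never_switch_sentinels(self, design):
        cv = el.ChoiceVector(tuple([0] * 35))
        assert el.infer_switchpoints(cv, design) == (15, 15, 8)

    def test_first_b_row(self, design):
        choices = [0] * 5 + [1] * 9 + [0] * 14 + [0] * 7
        assert el.infer_switchpoints(el.ChoiceVector(tuple(choices)),
                                     design) == (6, 15, 8)

    def test_switch_back_rejected(self, design):
        choices = [0] * 14 + [0, 1, 0] + [0] * 11 + [0] * 7
        with pytest.raises(MultipleSwitchError):
            el.infer_switchpoints(el.ChoiceVector(tuple(choices)), design)


class TestEstimation:
    def test_risk_neutral_round_trip(self, design):
        cv = el.simulate_choices(design, el.PTParams(1, 1, 1))
        est = el.estimate_from_choices(cv, design)
        assert est.risk_category == "risk_neutral"
        assert est.loss_category == "not_loss_averse"
        assert est.sigma_interval[0] <= 1 <= est.sigma_interval[1]
        assert est.gamma_interval[0] <= 1 <= est.gamma_interval[1]
        assert est.lam_interval[0] <= 1 <= est.lam_interval[1]

    def test_interior_grid_recovery(self, design):
        """Noiseless simulate -> infer -> estimate brackets the truth."""
        for sigma in (0.35, 0.62, 0.95, 1.25):
            for gamma in (0.45, 0.72, 0.95):
                for lam in (0.6, 2.0, 5.0):
                    p = el.PTParams(sigma, lam, gamma)
                    est = el.estimate_params(
                        el.infer_switchpoints(el.simulate_choices(design, p),
                                              design),
                        design,
                    )
                    assert est.sigma_interval[0] <= sigma <= est.sigma_interval[1]
                    assert est.gamma_interval[0] <= gamma <= est.gamma_interval[1]
                    assert est.lam_interval[0] <= lam <= est.lam_interval[1]

    def test_series3_never_switch_censors_lambda_above(self, design):
        sp = el.infer_switchpoints(
            el.simulate_choices(design, el.PTParams(0.7, 11.0, 0.7)), design
        )
        assert sp[2] == 8
        est = el.estimate_params(sp, design)
        # lower bound must exceed the largest finite cell boundary at some
        # sigma in the interval
        bounds = el._lambda_bounds(design, est.params.sigma)
        assert est.lam_interval[0] <= bounds[-1]
        assert est.lam_interval[1] == el.LAMBDA_BOUNDS[1]
        assert est.censored

    def test_out_of_range_switchpoints_rejected(self, design):
        with pytest.raises(InconsistencyError):
            el.estimate_params((0, 3, 3), design)


class TestCategorize:
    @pytest.mark.parametrize("sigma,expected", [
        (0.58, "risk_averse"), (1.0, "risk_neutral"), (1.2, "risk_loving"),
    ])
    def test_risk_threshold_at_one(self, sigma, expected):
        assert el.categorize(el.PTParams(sigma, 1, 1))[0] == expected

    @pytest.mark.parametrize("lam,expected", [
        (3.67, "loss_averse"), (1.0, "loss_averse"), (0.9, "not_loss_averse"),
    ])
    def test_loss_threshold_at_one(self, lam, expected):
        assert el.categorize(el.PTParams(1, lam, 1))[1] == expected


class TestDesignIO:
    def test_yaml_round_trip(self, design, tmp_path):
        path = tmp_path / "design.yaml"
        design.save(path)
        loaded = el.LotteryDesign.load(path)
        assert loaded.to_dict() == design.to_dict()

    def test_design_invariants(self, design):
        for row in design.series1 + design.series2:
            assert row.plan_a.x >= 0 and row.plan_b.x >= 0
        for row in design.series3:
            assert row.plan_a.p == 0.5 and row.plan_b.p == 0.5
            assert row.plan_a.y < 0 < row.plan_a.x
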