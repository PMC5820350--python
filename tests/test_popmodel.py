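"""Deterministic two-state model: closed forms, benchmark-value anchors,
numerical-integration oracle, and structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from escapewatch.popmodel import (
    NEVER,
    ModelParams,
    closed_form_counts,
    half_life,
    nonproducer_ratio,
    producer_fraction,
    relative_production,
    scale_annotation,
    trajectory,
)


class TestClosedFormCounts:
    @pytest.mark.parametrize("c", [0.0, 0.1, 0.3, 0.5])
    @pytest.mark.parametrize("k", [1e-9, 1e-7, 1e-5])
    def test_matches_ode_integration(self, c, k):
        """Closed forms agree with adaptive numerical integration of the
        ODE pair to relative error < 1e-8 over g in [0, 200].

        Integrated in growth-discounted variables (P, N scaled by
        e^{-mu g}) so the comparison stays in floating range out to g=200;
        the scaling is exact and common to both sides."""
        params = ModelParams(c, k)
        grid = np.linspace(0.0, 200.0, 9)
        sol = solve_ivp(
            lambda t, y: [(-c - k) * y[0], k * y[0]],
            (0.0, 200.0),
            [1.0, 0.0],
            t_eval=grid,
            rtol=1e-13,
            atol=[0.0, 1e-60],
            method="DOP853",
        )
        P, N = closed_form_counts(params, grid)
        discount = np.exp(-grid)  # mu = 1
        np.testing.assert_allclose(P * discount, sol.y[0], rtol=1e-8)
        np.testing.assert_allclose((N * discount)[1:], sol.y[1][1:], rtol=1e-8)

    def test_no_escape_means_no_nonproducers(self):
        P, N = closed_form_counts(ModelParams(0.3, 0.0), np.array([0.0, 10.0, 60.0]))
        assert np.all(N == 0.0)
        np.testing.assert_allclose(P, np.exp(0.7 * np.array([0.0, 10.0, 60.0])))

    def test_initial_condition(self):
        P, N = closed_form_counts(ModelParams(0.2, 1e-7), 0.0, p0=5.0)
        assert (P, N) == (5.0, 0.0)

    def test_negative_generations_rejected(self):
        with pytest.raises(ValueError):
            closed_form_counts(ModelParams(0.3, 1e-7), -1.0)


class TestNonproducerRatio:
    def test_96_percent_takeover_at_reactor_scale(self):
        """Load 0.30, escape 1e-7: 96% non-producers after 60 generations."""
        rho = nonproducer_ratio(ModelParams(0.30, 1e-7), 60.0)
        assert rho == pytest.approx(21.8868, abs=1e-3)
        assert 100.0 * rho / (1.0 + rho) == pytest.approx(95.63, abs=0.01)

    def test_zero_escape_is_identically_zero(self):
        assert nonproducer_ratio(ModelParams(0.4, 0.0), 123.0) == 0.0
        assert nonproducer_ratio(ModelParams(0.0, 0.0), 50.0) == 0.0

    def test_zero_load_exact_form(self):
        rho = nonproducer_ratio(ModelParams(0.0, 2.1e-7), 1e6)
        assert rho == pytest.approx(math.expm1(0.21), rel=1e-12)

    def test_cross_check_ode_at_example_point(self):
        # growth-discounted variables: the N/P ratio is unchanged
        c, k = 0.3, 1e-7
        sol = solve_ivp(
            lambda t, y: [(-c - k) * y[0], k * y[0]],
            (0.0, 60.0),
            [1.0, 0.0],
            rtol=1e-13,
            atol=[0.0, 1e-40],
            method="DOP853",
        )
        assert sol.y[1][-1] / sol.y[0][-1] == pytest.approx(
            nonproducer_ratio(ModelParams(c, k), 60.0), rel=1e-7
        )


class TestProducerFraction:
    def test_under_3_percent_at_lab_scale(self):
        f = producer_fraction(ModelParams(0.30, 1e-7), 37.0)
        assert 1.0 - f < 0.03
        assert f == pytest.approx(0.9784, abs=1e-3)

    def test_takeover_fraction_at_60_generations(self):
        assert producer_fraction(ModelParams(0.30, 1e-7), 60.0) == pytest.approx(
            0.0437, abs=2e-4
        )

    def test_overflow_safe_at_large_exponent(self):
        # (c+k) g = 600: rho overflows but f underflows gracefully
        with np.errstate(over="raise"):
            f = producer_fraction(ModelParams(0.5, 1e-3), 1200.0)
        assert 0.0 <= f < 1e-200

    @given(
        st.floats(0.0, 0.9),
        st.floats(1e-9, 1e-3),
        st.floats(0.0, 300.0),
    )
    def test_bounded_and_complementary(self, c, k, g):
        params = ModelParams(c, k)
        f = producer_fraction(params, g)
        assert 0.0 <= f <= 1.0
        P, N = closed_form_counts(params, g)
        if math.isfinite(P + N) and P + N > 0:
            assert f + N / (P + N) == pytest.approx(1.0, abs=1e-9)

    def test_zero_load_reduces_to_pure_exponential(self):
        g = np.linspace(0, 100, 11)
        np.testing.assert_allclose(
            producer_fraction(ModelParams(0.0, 1e-5), g), np.exp(-1e-5 * g), rtol=1e-12
        )

    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0 * math.log(2.0)])
    def test_mu_independence(self, mu):
        f = producer_fraction(ModelParams(0.3, 1e-7, ref_growth=mu), 60.0)
        assert f == pytest.approx(producer_fraction(ModelParams(0.3, 1e-7), 60.0), abs=1e-12)

    def test_strictly_decreasing_with_escape(self):
        g = np.linspace(0.0, 120.0, 50)
        f = producer_fraction(ModelParams(0.3, 1e-4), g)
        assert np.all(np.diff(f) < 0)
        assert f[0] == 1.0


class TestHalfLife:
    @pytest.mark.parametrize(
        "load,expected",
        [(0.30, 47.24), (0.22, 63.01), (0.21, 65.79)],
    )
    def test_benchmark_half_lives(self, load, expected):
        assert half_life(ModelParams(load, 2.1e-7)) == pytest.approx(expected, abs=0.01)

    def test_neutral_limit(self):
        assert half_life(ModelParams(0.0, 2.1e-7)) == pytest.approx(
            math.log(2.0) / 2.1e-7, rel=1e-4
        )

    def test_no_escape_never_declines(self):
        assert half_life(ModelParams(0.3, 0.0)) == NEVER

    def test_consistency_with_fraction(self):
        params = ModelParams(0.28, 3e-8)
        assert producer_fraction(params, half_life(params)) == pytest.approx(0.5, rel=1e-9)

    def test_monotone_decreasing_in_both_parameters(self):
        loads = [0.05, 0.15, 0.25, 0.35]
        ks = [1e-8, 1e-7, 1e-6, 1e-5]
        for k in ks:
            hl = [half_life(ModelParams(c, k)) for c in loads]
            assert all(a > b for a, b in zip(hl, hl[1:]))
        for c in loads:
            hl = [half_life(ModelParams(c, k)) for k in ks]
            assert all(a > b for a, b in zip(hl, hl[1:]))


class TestRelativeProduction:
    def test_reference_point_is_one(self):
        assert relative_production(ModelParams(0.3, 1e-7), 14.0, 14.0) == 1.0

    def test_pure_start_equals_producer_fraction(self):
        params = ModelParams(0.3, 1e-7)
        assert relative_production(params, 60.0, 0.0) == pytest.approx(0.0437, abs=2e-4)

    def test_monotone_decline(self):
        params = ModelParams(0.3, 1e-7)
        g = np.linspace(10.0, 90.0, 9)
        r = relative_production(params, g, 10.0)
        assert np.all(np.diff(r) < 0)


class TestTrajectory:
    def test_fraction_and_ratio_views(self):
        tr = trajectory(ModelParams(0.3, 1e-5), np.linspace(0, 80, 9))
        assert tr.producer_fraction[0] == 1.0
        assert np.all(np.diff(tr.nonproducer_ratio) >= 0)
        assert np.all((tr.producer_fraction >= 0) & (tr.producer_fraction <= 1))


class TestScaleAnnotation:
    def test_default_anchor(self):
        assert scale_annotation(60.0) == "2 m³"

    def test_unmapped_far_from_anchor(self):
        assert scale_annotation(5.0) == "unmapped"

    def test_nearest_anchor_wins(self):
        table = {60.0: "2 m³", 80.0: "200 m³"}
        assert scale_annotation(60.4, table) == "2 m³"

    def test_empty_table(self):
        assert scale_annotation(60.0, {}) == "unmapped"


class TestModelParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"load": 1.0, "escape_rate": 1e-7},
            {"load": -0.1, "escape_rate": 1e-7},
            {"load": 0.3, "escape_rate": -1e-9},
            {"load": 0.3, "escape_rate": 1e-7, "ref_growth": 0.0},
            {"load": float("nan"), "escape_rate": 1e-7},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
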