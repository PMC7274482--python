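"""Closed-form theory: reparametrization, classification, boundaries, averaging."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lvdilution import (
    CommunityParams,
    DegenerateBoundaryError,
    DilutionSchedule,
    NoCrossingError,
    NoInteriorEquilibriumError,
    OutcomeLabel,
    SimulationConfig,
    WashoutError,
    classify_outcome,
    critical_delta,
    delta_to_df,
    df_to_delta,
    integrate_continuous,
    interior_fixed_point,
    reparametrize,
    schedule_equivalent_df,
)
from lvdilution.model import reparametrized_params, rescaling_factors


def pair(r_i, r_j, a_ij, a_ji):
    return CommunityParams(("i", "j"), np.array([r_i, r_j]),
                           np.array([[1.0, a_ij], [a_ji, 1.0]]))


class TestReparametrize:
    @pytest.mark.parametrize(
        "a, ri, rj, delta, expected",
        [
            (0.8, 1.0, 2.0, 0.0, 0.8),          # no mortality: identity
            (1.5, 1.0, 0.5, 0.25, 1.0),         # 1.5 * (1 - 0.5) / (1 - 0.25)
            (0.8, 0.7, 0.4, 0.2, 0.56),         # 0.8 * 0.5 / (5/7)
        ],
    )
    def test_closed_form(self, a, ri, rj, delta, expected):
        assert reparametrize(a, ri, rj, delta) == pytest.approx(expected, abs=1e-12)

    def test_washout_names_the_failing_species(self):
        with pytest.raises(WashoutError) as exc:
            reparametrize(0.8, 1.0, 0.4, 0.5)
        assert exc.value.species == "j"
        assert exc.value.r == 0.4

    @given(
        ri=st.floats(2.0, 30.0),
        gap=st.floats(0.5, 10.0),
        a_ij=st.floats(0.2, 2.5),
        a_ji=st.floats(0.2, 2.5),
    )
    def test_mortality_favors_the_fast_grower(self, ri, gap, a_ij, a_ji):
        """With i the faster grower, raising delta weakens the pressure on i
        (alpha_tilde_ij non-increasing) and strengthens it on j."""
        rj = ri - gap
        if rj <= 0.2:
            return
        deltas = np.linspace(0.0, 0.95 * rj, 20)
        at_ij = [reparametrize(a_ij, ri, rj, d) for d in deltas]
        at_ji = [reparametrize(a_ji, rj, ri, d) for d in deltas]
        assert np.all(np.diff(at_ij) <= 1e-12)
        assert np.all(np.diff(at_ji) >= -1e-12)


class TestRescalingEquivalence:
    def test_trajectories_coincide_after_variable_scaling(self, rng):
        """Integrating the mortality model directly and integrating its
        mortality-free reparametrization give the same trajectory once the
        rescaled abundances are mapped back."""
        cfg = SimulationConfig(rtol=1e-10, atol=1e-13)
        for _ in range(5):
            r = rng.uniform(3.0, 25.0, 2)
            a = rng.uniform(0.2, 2.0, 2)
            params = pair(r[0], r[1], a[0], a[1])
            delta = rng.uniform(0.0, 0.7 * r.min())
            y0 = rng.uniform(0.01, 0.8, 2)
            scale = rescaling_factors(params, delta)
            direct = integrate_continuous(y0, params, delta, days=2.0, config=cfg)
            tilde = integrate_continuous(
                y0 / scale, reparametrized_params(params, delta), 0.0, days=2.0,
                config=cfg,
            )
            np.testing.assert_allclose(direct, tilde * scale, atol=1e-6)


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "at_ij, at_ji, label",
        [
            (0.5, 0.7, OutcomeLabel.COEXISTENCE),
            (1.5, 2.0, OutcomeLabel.BISTABILITY),
            (1.5, 0.5, OutcomeLabel.EXCLUSION_J_WINS),
            (0.5, 1.5, OutcomeLabel.EXCLUSION_I_WINS),
        ],
    )
    def test_quadrants(self, at_ij, at_ji, label):
        assert classify_outcome(at_ij, at_ji).label == label

    def test_coexistence_interior_state(self):
        out = classify_outcome(0.5, 0.7)
        ni = (1 - 0.5) / (1 - 0.35)
        nj = (1 - 0.7) / (1 - 0.35)
        assert out.stable_states == (pytest.approx(ni / (ni + nj)),)

    def test_bistability_reports_unstable_interior(self):
        out = classify_outcome(1.5, 2.0)
        assert out.stable_states == (0.0, 1.0)
        assert len(out.unstable_states) == 1
        assert 0 < out.unstable_states[0] < 1

    @pytest.mark.parametrize("at", [1.0, 1.0 + 1e-10, 1.0 - 1e-10])
    def test_boundary_is_degenerate(self, at):
        with pytest.raises(DegenerateBoundaryError):
            classify_outcome(at, 0.5)


class TestInteriorFixedPoint:
    def test_symmetric_coexistence(self):
        eq = interior_fixed_point(pair(10.0, 10.0, 0.5, 0.5), 0.0)
        assert eq.abundances == (pytest.approx(2 / 3), pytest.approx(2 / 3))
        assert eq.stable

    def test_symmetric_bistable_interior_is_unstable(self):
        eq = interior_fixed_point(pair(10.0, 10.0, 1.5, 1.5), 0.0)
        assert eq.abundances == (pytest.approx(0.4), pytest.approx(0.4))
        assert not eq.stable

    def test_nullcline_residuals_vanish(self, rng):
        """The returned point satisfies both per-capita growth nullclines."""
        checked = 0
        while checked < 20:
            r = rng.uniform(3.0, 25.0, 2)
            a = rng.uniform(0.2, 0.9, 2)
            params = pair(r[0], r[1], a[0], a[1])
            delta = rng.uniform(0.0, 0.6 * r.min())
            try:
                eq = interior_fixed_point(params, delta)
            except NoInteriorEquilibriumError:
                continue  # mortality pushed an effective coefficient past 1
            checked += 1
            N = np.asarray(eq.abundances)
            residual = params.r * (1.0 - params.alpha @ N) - delta
            assert np.max(np.abs(residual)) < 1e-10

    def test_negative_component_signals_no_interior(self):
        with pytest.raises(NoInteriorEquilibriumError):
            interior_fixed_point(pair(10.0, 10.0, 1.5, 0.5), 0.0)


class TestCriticalDelta:
    def test_worked_example(self):
        assert critical_delta(1.5, 1.0, 0.5) == pytest.approx(0.25)

    def test_alpha_one_crosses_at_zero(self):
        assert critical_delta(1.0, 3.0, 7.0) == 0.0

    def test_no_crossing_detected_by_sign(self):
        # delta* = (1 - 1.5) / (1/0.5 - 1.5/1.0) = -1 < 0
        with pytest.raises(NoCrossingError):
            critical_delta(1.5, 0.5, 1.0)

    def test_round_trip_alpha_tilde_is_one(self, rng):
        found = 0
        while found < 25:
            ri, rj = rng.uniform(3.0, 30.0, 2)
            a = rng.uniform(0.3, 2.5)
            try:
                d = critical_delta(a, ri, rj)
            except NoCrossingError:
                continue
            found += 1
            assert abs(reparametrize(a, ri, rj, d) - 1.0) < 1e-10


class TestDilutionMortalityMap:
    def test_no_dilution_no_mortality(self):
        assert df_to_delta(1.0, 24.0) == 0.0

    def test_thousandfold_daily(self):
        assert df_to_delta(1e3, 24.0) == pytest.approx(3 * math.log(10))

    @pytest.mark.parametrize("df", [10.0**k for k in range(1, 7)])
    def test_round_trip(self, df):
        assert delta_to_df(df_to_delta(df)) == pytest.approx(df, rel=1e-12)

    def test_cycle_duration_scales_the_rate(self):
        assert df_to_delta(100.0, 12.0) == pytest.approx(2 * df_to_delta(100.0, 24.0))


class TestScheduleAveraging:
    @pytest.mark.parametrize(
        "dfs, expected",
        [((10.0, 1e5), 1e3), ((1e2, 1e4), 1e3), ((1e2, 1e2, 1e2), 1e2)],
    )
    def test_geometric_mean(self, dfs, expected):
        assert schedule_equivalent_df(DilutionSchedule(dfs)) == pytest.approx(
            expected, rel=1e-12
        )

    @given(st.lists(st.floats(1.0, 1e6), min_size=1, max_size=8), st.randoms())
    def test_permutation_invariance(self, dfs, pyrandom):
        """Timing independence: the equivalent constant DF ignores order."""
        shuffled = list(dfs)
        pyrandom.shuffle(shuffled)
        a = schedule_equivalent_df(DilutionSchedule(tuple(dfs)))
        b = schedule_equivalent_df(DilutionSchedule(tuple(shuffled)))
        assert a == pytest.approx(b, rel=1e-12)
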