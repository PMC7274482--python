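"""Serial growth-dilution simulator: cycles, schedules, basins, diagrams."""

import math
import warnings

import numpy as np
import pytest

from lvdilution import (
    CommunityParams,
    DilutionSchedule,
    NoSeparatrixError,
    OutcomeLabel,
    SimulationConfig,
    apply_dilution,
    bifurcation_diagram,
    classify_final_states,
    day0_density,
    df_to_delta,
    find_separatrix,
    grow_cycle,
    integrate_continuous,
    pair_outcome,
    run_schedule,
)
from lvdilution.model import classify_outcome, reparametrize_pair
from lvdilution.simulate import endpoints, integrate_batch

SYMMETRIC_BISTABLE = CommunityParams(
    ("a", "b"), np.array([12.0, 12.0]), np.array([[1.0, 1.6], [1.6, 1.0]])
)
SYMMETRIC_COEXIST = CommunityParams(
    ("a", "b"), np.array([12.0, 12.0]), np.array([[1.0, 0.6], [0.6, 1.0]])
)


class TestGrowCycle:
    def test_monoculture_carrying_capacity_is_fixed(self):
        params = CommunityParams(("a",), np.array([10.0]), np.eye(1))
        assert grow_cycle(np.array([1.0]), params)[0] == pytest.approx(1.0, abs=1e-9)

    def test_empty_culture_stays_empty(self, bistable_pair):
        out = grow_cycle(np.zeros(2), bistable_pair)
        assert np.all(out == 0.0)

    def test_absent_species_does_not_spontaneously_appear(self, bistable_pair):
        out = grow_cycle(np.array([0.0, 0.02]), bistable_pair)
        assert out[0] == 0.0 and out[1] > 0.02

    def test_logistic_closed_form(self):
        params = CommunityParams(("a",), np.array([1.0]), np.eye(1))
        n0 = 0.01
        expected = n0 * math.e / (1 + n0 * (math.e - 1))
        assert grow_cycle(np.array([n0]), params)[0] == pytest.approx(expected, rel=1e-7)


class TestApplyDilution:
    def test_divides_by_the_factor(self):
        out = apply_dilution(np.array([0.5]), 10.0)
        assert out[0] == pytest.approx(0.05)

    def test_extinction_threshold_zeroes_small_populations(self):
        cfg = SimulationConfig(extinction_threshold=1e-8)
        out = apply_dilution(np.array([1e-7, 0.5]), 1e4, cfg)
        assert out[0] == 0.0 and out[1] == pytest.approx(0.5 / 1e4)

    def test_never_increases_abundance(self, rng):
        for _ in range(20):
            n = rng.uniform(0, 1, 3)
            df = rng.uniform(1, 1e5)
            assert np.all(apply_dilution(n, df) <= n + 1e-15)

    def test_stochastic_extinction_matches_binomial_oracle(self):
        """With < 1 expected survivor, the extinction frequency follows the
        binomial zero-class probability."""
        cfg = SimulationConfig(stochastic_dilution=True, cells_per_unit=1e4)
        n, df = 0.02, 1e3  # 200 cells, transfer prob 1e-3 -> 0.2 expected
        rng = np.random.default_rng(7)
        draws = np.array(
            [apply_dilution(np.array([n]), df, cfg, rng=rng)[0] for _ in range(4000)]
        )
        p_extinct = (1 - 1 / df) ** round(n * cfg.cells_per_unit)
        assert np.mean(draws == 0.0) == pytest.approx(p_extinct, abs=0.03)


class TestRunSchedule:
    def test_symmetric_pair_keeps_even_fractions(self):
        traj = run_schedule(
            [0.5, 0.5], 0.01, SYMMETRIC_COEXIST, DilutionSchedule.constant(100.0),
            SimulationConfig(max_cycles=20, convergence_tol=0.0),
        )
        np.testing.assert_allclose(traj.fractions[:, 0], 0.5, atol=1e-6)

    @pytest.mark.parametrize("df, survives", [(1e4, True), (1e6, False)])
    def test_monoculture_persistence_depends_on_net_cycle_growth(self, df, survives):
        # r = 12/day: growth e^12 ~ 1.6e5 per cycle at low density
        params = CommunityParams(("a",), np.array([12.0]), np.eye(1))
        traj = run_schedule(
            [1.0], 1e-4, params, DilutionSchedule.constant(df),
            SimulationConfig(max_cycles=60),
        )
        assert (traj.final_abundances[0] > 0) == survives

    def test_bistable_pair_splits_by_initial_fraction(self, bistable_pair):
        sched = DilutionSchedule.constant(10**2.5)
        finals, _ = endpoints(np.array([0.05, 0.95]), bistable_pair, sched)
        fr = finals[:, 0] / finals.sum(axis=1)
        assert fr[0] < 0.01 and fr[1] > 0.99

    def test_unconverged_run_is_flagged_not_raised(self, bistable_pair):
        traj = run_schedule(
            [0.5, 0.5], 0.01, bistable_pair, DilutionSchedule.constant(100.0),
            SimulationConfig(max_cycles=2),
        )
        assert not traj.converged and traj.n_cycles == 2

    def test_extinct_species_never_revives(self, bistable_pair):
        traj = run_schedule(
            [0.05, 0.95], day0_density(10**2.5), bistable_pair,
            DilutionSchedule.constant(10**2.5), SimulationConfig(max_cycles=100),
        )
        gone = np.flatnonzero(traj.abundances[:, 0] == 0.0)
        if gone.size:
            assert np.all(traj.abundances[gone.min():, 0] == 0.0)


class TestSeparatrix:
    def test_symmetric_pair_splits_at_one_half(self):
        sep = find_separatrix(SYMMETRIC_BISTABLE, 100.0)
        assert sep == pytest.approx(0.5, abs=1e-3)

    def test_brackets_divide_the_basins(self, bistable_pair):
        sep = find_separatrix(bistable_pair, 10**2.5)
        sched = DilutionSchedule.constant(10**2.5)
        finals, _ = endpoints(
            np.array([max(sep - 0.02, 1e-3), min(sep + 0.02, 1 - 1e-3)]),
            bistable_pair, sched,
        )
        fr = finals[:, 0] / finals.sum(axis=1)
        assert fr[0] < 0.01 and fr[1] > 0.99

    def test_higher_dilution_favors_the_fast_grower(self, bistable_pair):
        """Within the bistable window the separatrix moves toward the slow
        grower's corner as dilution rises: less of the fast grower is needed
        to reach its winning state."""
        assert find_separatrix(bistable_pair, 10**3.0) < find_separatrix(
            bistable_pair, 10**2.0
        )

    def test_not_bistable_raises(self, coexist_pair):
        with pytest.raises(NoSeparatrixError):
            find_separatrix(coexist_pair, 1e3)


class TestBifurcationDiagram:
    def test_coexisting_pair_has_single_interior_branch(self):
        params = CommunityParams(
            ("a", "b"), np.array([13.0, 12.0]), np.array([[1.0, 0.5], [0.5, 1.0]])
        )
        diag = bifurcation_diagram(params, df_grid=[10.0, 100.0, 1000.0],
                                   initial_fraction_grid=[0.1, 0.5, 0.9])
        for stable, unstable in zip(diag.stable, diag.unstable):
            assert len(stable) == 1 and not unstable
            assert 0.02 < stable[0] < 0.98

    def test_bistable_window_between_exclusion_regimes(self, bistable_pair):
        diag = bifurcation_diagram(
            bistable_pair, df_grid=[10.0, 10**2.5, 10**4.5],
            initial_fraction_grid=[0.05, 0.5, 0.95],
        )
        assert len(diag.stable[0]) == 1 and diag.stable[0][0] < 0.02  # slow wins
        assert len(diag.stable[1]) == 2 and len(diag.unstable[1]) == 1
        assert len(diag.stable[2]) == 1 and diag.stable[2][0] > 0.98  # fast wins

    def test_matches_analytic_classification_at_matched_mortality(self, bistable_pair):
        """Endpoint clustering at each DF agrees with the phase-diagram label
        at the equivalent continuous mortality (away from boundaries)."""
        for df in (10.0, 10**2.5, 10**4.5):
            rp = reparametrize_pair(bistable_pair, df_to_delta(df))
            want = classify_outcome(rp.alpha_tilde_ij, rp.alpha_tilde_ji).label
            got = pair_outcome(bistable_pair, DilutionSchedule.constant(df))
            assert got.label == want


class TestClassifyFinalStates:
    def _traj(self, species, rows, converged=True):
        rows = np.asarray(rows, dtype=float)
        return type(
            "T", (), {
                "species_names": species,
                "abundances": rows,
                "final_fractions": rows[-1] / rows[-1].sum(),
                "converged": converged,
            },
        )()

    def test_opposite_endpoints_mean_bistability(self):
        trajs = [
            self._traj(("a", "b"), [[0.5, 0.5], [0.0, 1.0]]),
            self._traj(("a", "b"), [[0.5, 0.5], [1.0, 0.0]]),
        ]
        out = classify_final_states(trajs)
        assert out.label == OutcomeLabel.BISTABILITY

    def test_unconverged_runs_are_flagged(self):
        trajs = [self._traj(("a", "b"), [[0.5, 0.5], [0.2, 0.8]], converged=False)]
        with pytest.warns(UserWarning, match="without converging"):
            classify_final_states(trajs)

    def test_trio_states_grouped_by_surviving_set(self):
        trajs = [
            self._traj(("x", "y", "z"), [[1, 1, 1], [0.4, 0.0, 0.6]]),
            self._traj(("x", "y", "z"), [[1, 1, 1], [0.0, 0.7, 0.3]]),
            self._traj(("x", "y", "z"), [[1, 1, 1], [0.41, 0.0, 0.59]]),
        ]
        states = classify_final_states(trajs)
        labels = {s.label: s.n_trajectories for s in states}
        assert labels == {"x+z": 2, "y+z": 1}

    def test_order_invariance(self):
        trajs = [
            self._traj(("x", "y", "z"), [[1, 1, 1], [0.4, 0.0, 0.6]]),
            self._traj(("x", "y", "z"), [[1, 1, 1], [0.0, 0.7, 0.3]]),
        ]
        a = {s.label for s in classify_final_states(trajs)}
        b = {s.label for s in classify_final_states(trajs[::-1])}
        assert a == b


class TestTrioTimeAveraging:
    def test_constant_and_fluctuating_regimes_reach_identical_states(self, trio_params):
        """Four starting mixes map to the same surviving pair under constant
        DF 10^3, alternating 10/10^5, and alternating 10^2/10^4 — and the
        split (three to one state, one to the other) matches the bistable
        three-species phase portrait."""
        inits = [(0.8, 0.1, 0.1), (0.1, 0.1, 0.8), (0.45, 0.1, 0.45), (0.05, 0.9, 0.05)]
        cfg = SimulationConfig(max_cycles=200)
        outcomes = {}
        for dfs in ((1e3,), (10.0, 1e5), (1e2, 1e4)):
            sched = DilutionSchedule(dfs)
            labels = []
            for f in inits:
                t = run_schedule(f, day0_density(dfs[0]), trio_params, sched, cfg)
                labels.append(
                    "+".join(
                        n for n, x in zip(trio_params.species_names, t.final_fractions)
                        if x > 1e-3
                    )
                )
            outcomes[dfs] = labels
        assert len(set(map(tuple, outcomes.values()))) == 1
        assert sorted(outcomes[(1e3,)]) == ["Pp+Ea", "Pp+Ea", "Pp+Ea", "Pv+Ea"]


class TestDiscreteContinuousConsistency:
    def test_subdividing_the_cycle_converges_to_the_continuous_flow(self, bistable_pair):
        """Splitting one 24 h cycle at DF D into m cycles at DF D^(1/m)
        approaches the constant-mortality flow monotonically in m."""
        D = 1e3
        y0 = np.array([[0.3, 0.4]])
        cont = integrate_continuous(y0, bistable_pair, math.log(D), 1.0)
        errs = []
        for m in (1, 2, 4, 8):
            y = y0.copy()
            for _ in range(m):
                y = integrate_batch(y, bistable_pair, 1.0 / m) / D ** (1.0 / m)
            errs.append(float(np.max(np.abs(y - cont))))
        assert all(a > b for a, b in zip(errs, errs[1:]))
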