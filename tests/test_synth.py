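"""Synthetic-data generators: regimes, OD curves, counts, bundles."""

import math

import numpy as np
import pytest

from lvdilution import (
    DilutionSchedule,
    OutcomeLabel,
    RegimeInfeasibleError,
    classify_outcome,
    critical_delta,
    estimate_growth_rate,
    sample_params,
)
from lvdilution.errors import NoCrossingError, ValidationError
from lvdilution.model import reparametrize_pair
from lvdilution.params import HOURS_PER_DAY
from lvdilution.synth import (
    ExperimentDesign,
    generate_bundle,
    generate_count_tables,
    generate_od_curves,
    resample_counts,
)

WINDOW = (math.log(10.0), math.log(1e4))


def small_design(**kw):
    defaults = dict(
        initial_fractions=((0.2, 0.8), (0.8, 0.2)),
        schedules=(DilutionSchedule.constant(100.0),),
        days=3,
        od_replicates=4,
        od_duration_h=40.0,
    )
    defaults.update(kw)
    return ExperimentDesign(**defaults)


class TestSampleParams:
    def test_coexist_regime_places_both_alphas_below_one(self):
        p = sample_params(2, "coexist", seed=1)
        assert p.alpha[0, 1] < 1 and p.alpha[1, 0] < 1
        assert classify_outcome(p.alpha[0, 1], p.alpha[1, 0]).label == OutcomeLabel.COEXISTENCE

    def test_bistable_window_has_reachable_boundaries(self):
        p = sample_params(2, "bistable", seed=2, delta_window=WINDOW)
        # both effective coefficients cross one below the slow grower's washout
        for a, ri, rj in ((p.alpha[0, 1], p.r[0], p.r[1]), (p.alpha[1, 0], p.r[1], p.r[0])):
            d = critical_delta(a, ri, rj)
            assert WINDOW[0] < d < WINDOW[1] < min(p.r)

    def test_windowed_pair_walks_slow_to_fast(self):
        p = sample_params(2, "coexist", seed=3, delta_window=WINDOW)
        labels = []
        for d in (WINDOW[0], 0.5 * sum(WINDOW), WINDOW[1]):
            rp = reparametrize_pair(p, d)
            labels.append(classify_outcome(rp.alpha_tilde_ij, rp.alpha_tilde_ji).label)
        assert labels == [
            OutcomeLabel.EXCLUSION_J_WINS,
            OutcomeLabel.COEXISTENCE,
            OutcomeLabel.EXCLUSION_I_WINS,
        ]

    def test_rates_within_stated_range_fast_first(self):
        p = sample_params(2, "random", seed=4)
        assert p.r[0] >= p.r[1]
        assert np.all(p.r >= 0.2 * HOURS_PER_DAY) and np.all(p.r <= 1.5 * HOURS_PER_DAY)

    def test_same_seed_reproduces_identical_params(self):
        a = sample_params(2, "bistable", seed=9, delta_window=WINDOW)
        b = sample_params(2, "bistable", seed=9, delta_window=WINDOW)
        np.testing.assert_array_equal(a.r, b.r)
        np.testing.assert_array_equal(a.alpha, b.alpha)

    def test_infeasible_window_raises(self):
        with pytest.raises(RegimeInfeasibleError):
            sample_params(2, "bistable", seed=0, delta_window=(0.0, 60.0), max_tries=40)

    def test_trio_supports_random_regime_only(self):
        p = sample_params(3, "random", seed=5)
        assert p.n_species == 3
        with pytest.raises(ValidationError):
            sample_params(3, "bistable", seed=5)


class TestGenerateODCurves:
    def test_noiseless_curves_recover_the_rate(self, bistable_pair):
        design = small_design(od_noise_sd=0.0)
        curves = generate_od_curves(bistable_pair, design, seed=0)
        for c in curves:
            r_true = bistable_pair.r[list(bistable_pair.species_names).index(c.species)]
            assert estimate_growth_rate(c) * HOURS_PER_DAY == pytest.approx(r_true, rel=0.02)

    def test_initial_od_is_equalized_over_dilution(self, bistable_pair):
        design = small_design(od_noise_sd=0.0)
        for c in generate_od_curves(bistable_pair, design, seed=0):
            assert c.od[0] == pytest.approx(design.equalized_od / c.inoculum_dilution)

    def test_more_noise_cannot_improve_the_estimate(self, bistable_pair):
        """Median |r_hat - r| over seeds is non-decreasing in OD noise."""
        errs = {}
        for sd in (0.005, 0.02):
            design = small_design(od_noise_sd=sd, od_replicates=2)
            per_seed = []
            for seed in range(60):
                curves = generate_od_curves(bistable_pair, design, seed=seed)
                c = curves[0]
                r_true = bistable_pair.r[0]
                per_seed.append(abs(estimate_growth_rate(c) * HOURS_PER_DAY - r_true))
            errs[sd] = float(np.median(per_seed))
        assert errs[0.02] >= errs[0.005]

    def test_lag_is_dead_time(self, bistable_pair):
        quiet = small_design(od_noise_sd=0.0, lag_hours_mean=3.0)
        curves = generate_od_curves(bistable_pair, quiet, seed=0)
        c = curves[0]
        within_lag = c.times_h <= 3.0
        np.testing.assert_allclose(c.od[within_lag], c.od[0], rtol=1e-12)


class FakeTraj:
    def __init__(self, fractions, names=("a", "b")):
        self.species_names = names
        self._fr = np.asarray(fractions, dtype=float)

    @property
    def fractions(self):
        return self._fr

    @property
    def n_cycles(self):
        return self._fr.shape[0] - 1


class TestGenerateCountTables:
    def test_pure_culture_yields_single_species_colonies(self):
        traj = FakeTraj([[1.0, 0.0], [1.0, 0.0]])
        counts = generate_count_tables(traj, small_design(days=1), seed=0)
        assert counts[counts.species == "b"].colonies.sum() == 0
        assert counts[counts.species == "a"].colonies.sum() > 0

    def test_even_mixture_unbiased_at_scale(self):
        """10^4 platings of a 50:50 community average to fraction 0.5
        (binomial oracle)."""
        traj = FakeTraj([[0.5, 0.5]])
        design = small_design(days=0, platings_per_condition=10_000)
        counts = generate_count_tables(traj, design, seed=1)
        wide = counts.pivot_table(index="replicate", columns="species",
                                  values="colonies", aggfunc="sum")
        frac = wide["a"] / (wide["a"] + wide["b"])
        assert 0.49 < frac.mean() < 0.51

    def test_plating_sd_matches_beta_formula_scale(self):
        from lvdilution import CountObservation, fraction_sd

        traj = FakeTraj([[0.5, 0.5]])
        design = small_design(days=0, platings_per_condition=500)
        counts = generate_count_tables(traj, design, seed=2)
        wide = counts.pivot_table(index="replicate", columns="species",
                                  values="colonies", aggfunc="sum")
        frac = wide["a"] / (wide["a"] + wide["b"])
        typical_sd = fraction_sd(CountObservation((24, 25)))
        assert frac.std() == pytest.approx(typical_sd, rel=0.25)


class TestGenerateBundle:
    def test_fixed_seed_reproduces_the_bundle(self, bistable_pair):
        design = small_design()
        a = generate_bundle(design, seed=7, params=bistable_pair)
        b = generate_bundle(design, seed=7, params=bistable_pair)
        assert a.counts.equals(b.counts)
        for ca, cb in zip(a.od_curves, b.od_curves):
            np.testing.assert_array_equal(ca.od, cb.od)
        for cid in a.trajectories:
            np.testing.assert_array_equal(
                a.trajectories[cid].abundances, b.trajectories[cid].abundances
            )

    def test_day_zero_design_observes_initial_fractions(self, bistable_pair):
        design = small_design(days=0, platings_per_condition=400,
                              target_colonies=100)
        bundle = generate_bundle(design, seed=3, params=bistable_pair)
        counts = bundle.counts
        for cond in bundle.conditions:
            sub = counts[counts.condition == cond.condition_id]
            assert sub.day.max() == 0
            wide = sub.pivot_table(index="replicate", columns="species",
                                   values="colonies", aggfunc="sum")
            observed = wide.sum()
            frac_a = observed[bundle.params.species_names[0]] / observed.sum()
            assert frac_a == pytest.approx(cond.initial_fractions[0], abs=0.02)

    def test_resample_counts_keeps_trajectories_fixed(self, bistable_pair):
        design = small_design()
        bundle = generate_bundle(design, seed=7, params=bistable_pair)
        re1 = resample_counts(bundle, seed=8, platings_per_condition=3)
        assert re1.trajectories is bundle.trajectories
        assert re1.design.platings_per_condition == 3
        assert not re1.counts.equals(bundle.counts)
        re2 = resample_counts(bundle, seed=8, platings_per_condition=3)
        assert re1.counts.equals(re2.counts)
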