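"""Synthetic experiments with known ground truth.

Everything the analysis pipeline consumes can be generated here: community
parameter sets placed in a chosen outcome regime, monoculture OD growth
curves (logistic shape, optional dead-time lag, additive plate-reader
noise), and multi-day coculture experiments observed through daily colony
counts (Poisson plate totals, multinomially split on the true fractions).

The defaults mirror the experimental design being emulated: 24-hour cycles,
about 49 colonies per plating, OD sampled every 15 minutes for ~40 hours
from inocula spread over decades of starting density, and day-0 mixtures
pre-diluted by their daily dilution factor (with the deepest dilutions
started one decade higher).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import RegimeInfeasibleError, ValidationError
from .infer import ODCurve
from .model import classify_outcome, reparametrize_pair
from .params import (
    HOURS_PER_DAY,
    CommunityParams,
    DilutionSchedule,
    OutcomeLabel,
    SimulationConfig,
)
from .simulate import Trajectory, day0_density, run_schedule

REGIMES = ("coexist", "bistable", "dominance", "random")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _loguniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


def sample_params(
    n_species: int,
    regime: str = "random",
    seed=None,
    delta_window: tuple[float, float] | None = None,
    r_range_per_hour: tuple[float, float] = (0.2, 1.5),
    K_range: tuple[float, float] = (0.8, 1.5),
    max_tries: int = 2000,
) -> CommunityParams:
    """Draw a community in a requested outcome regime (ground truth known).

    Growth rates are log-uniform on ``r_range_per_hour`` (converted to 1/day;
    pairs are ordered fast grower first).  For pairs, ``regime`` names the
    effective-coefficient region: with ``delta_window=None`` the region holds
    at delta = 0; with a window ``(d_lo, d_hi)`` (1/day) the pair follows the
    canonical mortality trajectory — slow-grower exclusion below the window,
    the requested regime strictly inside it, fast-grower exclusion above —
    placed by choosing the two boundary mortalities inside the window and
    inverting the boundary condition.  Returned parameters are always
    verified with classify_outcome.
    """
    rng = _rng(seed)
    if n_species not in (1, 2, 3):
        raise ValidationError("n_species must be 1, 2, or 3")
    if regime not in REGIMES:
        raise ValidationError(f"regime must be one of {REGIMES}")
    r_lo, r_hi = r_range_per_hour

    def draw_r(n):
        r = np.sort(_loguniform(rng, r_lo, r_hi, n))[::-1] * HOURS_PER_DAY
        return r

    K = _loguniform(rng, *K_range, size=n_species)
    if n_species == 1:
        return CommunityParams(("sp1",), draw_r(1), np.ones((1, 1)), K=K)
    if n_species == 3:
        if regime != "random":
            raise ValidationError(
                "regime placement is pairwise; three-species sampling supports 'random'"
            )
        r = draw_r(3)
        alpha = _loguniform(rng, 0.15, 2.5, (3, 3))
        np.fill_diagonal(alpha, 1.0)
        return CommunityParams(("sp1", "sp2", "sp3"), r, alpha, K=K)

    names = ("fast", "slow")
    if delta_window is None or delta_window == (0.0, 0.0):
        for _ in range(max_tries):
            r = draw_r(2)
            if regime == "coexist":
                a_ij, a_ji = rng.uniform(0.2, 0.9, 2)
            elif regime == "bistable":
                a_ij, a_ji = rng.uniform(1.1, 2.2, 2)
            elif regime == "dominance":
                a_ij, a_ji = rng.uniform(1.1, 2.2), rng.uniform(0.2, 0.9)
                if rng.random() < 0.5:
                    a_ij, a_ji = a_ji, a_ij
            else:
                a_ij, a_ji = _loguniform(rng, 0.15, 2.5, 2)
                if abs(a_ij - 1) < 0.02 or abs(a_ji - 1) < 0.02:
                    continue
            params = CommunityParams(
                names, r, np.array([[1.0, a_ij], [a_ji, 1.0]]), K=K
            )
            if _regime_matches(classify_outcome(a_ij, a_ji).label, regime):
                return params
        raise RegimeInfeasibleError(regime, max_tries)

    d_lo, d_hi = map(float, delta_window)
    if not (0 <= d_lo < d_hi):
        raise ValidationError("delta_window must satisfy 0 <= d_lo < d_hi")
    if regime in ("coexist", "bistable"):
        for _ in range(max_tries):
            r = draw_r(2)
            if r[1] <= d_hi / 0.9:  # keep the slow grower clear of washout
                continue
            r_i, r_j = r  # i fast, j slow
            mid = 0.5 * (d_lo + d_hi)
            m = 0.1 * (d_hi - d_lo)
            d_a = rng.uniform(d_lo + m, mid - 0.5 * m)
            d_b = rng.uniform(mid + 0.5 * m, d_hi - m)
            if regime == "bistable":
                # alpha_tilde_ji rises through 1 at d_a, alpha_tilde_ij falls at d_b
                a_ji = (1 - d_a / r_j) / (1 - d_a / r_i)
                a_ij = (1 - d_b / r_i) / (1 - d_b / r_j)
            else:
                a_ij = (1 - d_a / r_i) / (1 - d_a / r_j)
                a_ji = (1 - d_b / r_j) / (1 - d_b / r_i)
            params = CommunityParams(
                names, r, np.array([[1.0, a_ij], [a_ji, 1.0]]), K=K
            )
            if _window_pattern_ok(params, d_lo, d_hi, regime):
                return params
        raise RegimeInfeasibleError(regime, max_tries)
    # dominance / random over a window: plain rejection at the window midpoint
    mid = 0.5 * (d_lo + d_hi)
    for _ in range(max_tries):
        r = draw_r(2)
        if r[1] <= d_hi / 0.9:
            continue
        a_ij, a_ji = _loguniform(rng, 0.15, 2.5, 2)
        rp = reparametrize_pair(
            CommunityParams(names, r, np.array([[1.0, a_ij], [a_ji, 1.0]])), mid
        )
        if abs(rp.alpha_tilde_ij - 1) < 0.02 or abs(rp.alpha_tilde_ji - 1) < 0.02:
            continue
        label = classify_outcome(rp.alpha_tilde_ij, rp.alpha_tilde_ji).label
        if _regime_matches(label, regime):
            return CommunityParams(names, r, np.array([[1.0, a_ij], [a_ji, 1.0]]), K=K)
    raise RegimeInfeasibleError(regime, max_tries)


def _regime_matches(label: OutcomeLabel, regime: str) -> bool:
    if regime == "coexist":
        return label == OutcomeLabel.COEXISTENCE
    if regime == "bistable":
        return label == OutcomeLabel.BISTABILITY
    if regime == "dominance":
        return label in (OutcomeLabel.EXCLUSION_I_WINS, OutcomeLabel.EXCLUSION_J_WINS)
    return True


def _window_pattern_ok(params, d_lo, d_hi, regime) -> bool:
    mid = 0.5 * (d_lo + d_hi)
    want_mid = OutcomeLabel.BISTABILITY if regime == "bistable" else OutcomeLabel.COEXISTENCE
    for delta, want in (
        (d_lo, OutcomeLabel.EXCLUSION_J_WINS),  # slow grower (j) wins at low mortality
        (mid, want_mid),
        (d_hi, OutcomeLabel.EXCLUSION_I_WINS),
    ):
        rp = reparametrize_pair(params, delta)
        if classify_outcome(rp.alpha_tilde_ij, rp.alpha_tilde_ji).label != want:
            return False
    return True


def example_community() -> CommunityParams:
    """Three soil-bacteria-like species used by the analysis scripts.

    A slow grower and two fast growers whose pairwise boundary dilution
    factors were placed so that, at daily DF 10^3, the slow-fast pair is
    bistable and both pairs involving the third species coexist — the
    configuration that yields two alternative three-species states.
    Coefficients were obtained by inverting the pairwise boundary condition
    at the chosen boundary DFs (the same construction the inference module
    uses on data).  Growth-rate gaps are kept moderate (0.50-0.62/h, the
    regime the species' measured rates occupy): larger gaps make the
    basin boundary in initial-fraction space drift strongly with the
    schedule's phase, taking the system outside the regime where
    time-averaging holds quantitatively.
    """
    r = np.array([0.62, 0.50, 0.56]) * HOURS_PER_DAY  # Pp-like, Pv-like, Ea-like
    names = ("Pp", "Pv", "Ea")

    def boundary_alpha(d, ri, rj):
        return (1 - d / ri) / (1 - d / rj)

    d = {15: math.log(10**1.5), 35: math.log(10**3.5), 40: math.log(10**4)}
    alpha = np.ones((3, 3))
    alpha[0, 1] = boundary_alpha(d[35], r[0], r[1])  # Pp-Pv: bistable DF 10^1.5..10^3.5
    alpha[1, 0] = boundary_alpha(d[15], r[1], r[0])
    alpha[2, 1] = boundary_alpha(d[15], r[2], r[1])  # Ea-Pv: coexist DF 10^1.5..10^4
    alpha[1, 2] = boundary_alpha(d[40], r[1], r[2])
    alpha[2, 0] = 0.70  # Ea-Pp: coexist across the window
    alpha[0, 2] = 0.80
    return CommunityParams(names, r, alpha, K=np.array([1.2, 1.0, 1.1]))


# ---------------------------------------------------------------------------
# experiment designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """What to generate: schedules, sampling, plating and OD-noise levels."""

    initial_fractions: tuple[tuple[float, ...], ...]
    schedules: tuple[DilutionSchedule, ...]
    days: int = 7
    platings_per_condition: int = 1
    target_colonies: float = 49.0
    od_replicates: int = 16
    od_interval_min: float = 15.0
    od_duration_h: float = 40.0
    od_dilutions: tuple[float, ...] = (1e3, 1e4, 1e5, 1e6, 1e7)  # fold dilutions
    equalized_od: float = 0.1
    od_noise_sd: float = 0.003
    lag_hours_mean: float = 0.0
    lag_hours_sd: float = 0.0
    run_to_convergence: bool = False

    def __post_init__(self):
        if self.days < 0:
            raise ValidationError("days must be >= 0")
        if self.platings_per_condition < 1 or self.target_colonies <= 0:
            raise ValidationError("invalid plating design")
        for f in self.initial_fractions:
            s = sum(f)
            if any(x < 0 for x in f) or abs(s - 1) > 1e-8:
                raise ValidationError(f"initial fractions {f} must be >= 0 and sum to 1")

    @property
    def n_species(self) -> int:
        return len(self.initial_fractions[0])


def standard_pairwise_design(days: int = 7) -> ExperimentDesign:
    """Pairwise design: constant DFs 10..10^6 plus an alternating 10/10^5 regime."""
    schedules = tuple(
        DilutionSchedule.constant(10.0**k) for k in range(1, 7)
    ) + (DilutionSchedule((10.0, 1e5)),)
    inits = tuple((x, 1 - x) for x in (0.05, 0.2, 0.35, 0.5, 0.65, 0.8, 0.95))
    return ExperimentDesign(initial_fractions=inits, schedules=schedules, days=days)


def recovery_design(
    spacing_decades: float = 0.25,
    df_min_exp: float = 0.5,
    df_max_exp: float = 5.0,
    days: int = 60,
    noiseless_od: bool = True,
) -> ExperimentDesign:
    """Dense constant-DF grid for boundary-based coefficient recovery."""
    exps = np.arange(df_min_exp, df_max_exp + 1e-9, spacing_decades)
    schedules = tuple(DilutionSchedule.constant(10.0**e) for e in exps)
    # extreme starting fractions keep bistability visible right up to the
    # boundary DFs, where the separatrix approaches an absorbing state
    inits = tuple((x, 1 - x) for x in (0.01, 0.05, 0.275, 0.5, 0.725, 0.95, 0.99))
    return ExperimentDesign(
        initial_fractions=inits,
        schedules=schedules,
        days=days,
        od_noise_sd=0.0 if noiseless_od else 0.003,
        run_to_convergence=True,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_od_curves(
    params: CommunityParams, design: ExperimentDesign, seed=None
) -> list[ODCurve]:
    """Monoculture logistic OD curves on the design's sampling grid.

    Per species, ``od_replicates`` curves whose inoculum dilutions cycle
    through ``design.od_dilutions`` (so starting ODs span decades).  Lag is
    dead time: the culture sits at its initial OD for a lag drawn from a
    truncated normal, then grows logistically at rate r toward K (OD units).
    Additive Gaussian noise is clipped at zero.
    """
    rng = _rng(seed)
    times = np.arange(0.0, design.od_duration_h + 1e-9, design.od_interval_min / 60.0)
    K = params.K if params.K is not None else np.ones(params.n_species)
    curves = []
    for s, name in enumerate(params.species_names):
        r_h = params.r[s] / HOURS_PER_DAY
        for rep in range(design.od_replicates):
            dilution = design.od_dilutions[rep % len(design.od_dilutions)]
            od0 = design.equalized_od / dilution
            lag = max(0.0, rng.normal(design.lag_hours_mean, design.lag_hours_sd)) \
                if design.lag_hours_sd > 0 else design.lag_hours_mean
            t_eff = np.maximum(times - lag, 0.0)
            od = K[s] * od0 * np.exp(r_h * t_eff) / (K[s] + od0 * (np.exp(r_h * t_eff) - 1.0))
            if design.od_noise_sd > 0:
                od = np.maximum(od + rng.normal(0, design.od_noise_sd, od.shape), 0.0)
            curves.append(
                ODCurve(
                    times_h=times,
                    od=od,
                    equalized_od=design.equalized_od,
                    inoculum_dilution=dilution,
                    species=name,
                    replicate=f"{name}_rep{rep}",
                )
            )
    return curves


def generate_count_tables(
    trajectory: Trajectory,
    design: ExperimentDesign,
    seed=None,
    condition: str = "cond0",
) -> pd.DataFrame:
    """Daily colony-count observations of one coculture trajectory.

    For every sampled day each plating draws its total colony count from
    Poisson(target_colonies) and splits it multinomially on the day's true
    fractions (binomial for a pair).  Long format: day, condition,
    replicate, species, colonies.
    """
    rng = _rng(seed)
    days = min(design.days, trajectory.n_cycles)
    fr = trajectory.fractions[: days + 1]
    n_days, n_sp = fr.shape
    reps = design.platings_per_condition
    totals = rng.poisson(design.target_colonies, size=(n_days, reps))
    counts = np.zeros((n_days, reps, n_sp), dtype=np.int64)
    for d in range(n_days):
        if fr[d].sum() > 0:
            counts[d] = rng.multinomial(totals[d], fr[d])
    day_idx = np.repeat(np.arange(n_days), reps * n_sp)
    rep_idx = np.tile(np.repeat(np.arange(reps), n_sp), n_days)
    sp_idx = np.tile(np.arange(n_sp), n_days * reps)
    return pd.DataFrame(
        {
            "day": day_idx,
            "condition": condition,
            "replicate": rep_idx,
            "species": np.asarray(trajectory.species_names)[sp_idx],
            "colonies": counts.ravel(),
        }
    )


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a schedule applied to one starting mix."""

    condition_id: str
    schedule: DilutionSchedule
    initial_fractions: tuple[float, ...]
    day0_total_density: float


@dataclass
class SyntheticBundle:
    """A full synthetic experiment plus its ground truth.

    Observation tables (``counts``, ``od_curves``) follow the same schemas
    the readers ingest from disk; the generating parameters and the true
    trajectories ride alongside as the sidecar ground truth.
    """

    params: CommunityParams
    design: ExperimentDesign
    seed: int | None
    conditions: list[Condition]
    trajectories: dict[str, Trajectory]
    counts: pd.DataFrame
    od_curves: list[ODCurve]

    def final_day_counts(self, condition_id: str) -> np.ndarray:
        """Summed per-species colony counts on the last sampled day."""
        return self.final_day_counts_all()[condition_id]

    def final_day_counts_all(self) -> dict[str, np.ndarray]:
        """Last-day per-species colony counts for every condition, one pass."""
        cached = getattr(self, "_final_day_cache", None)
        if cached is not None and cached[0] is self.counts:
            return cached[1]
        names = list(self.params.species_names)
        last = self.counts.groupby("condition")["day"].transform("max")
        finals = self.counts[self.counts.day == last]
        table = finals.pivot_table(index="condition", columns="species",
                                   values="colonies", aggfunc="sum", fill_value=0)
        table = table.reindex(columns=names, fill_value=0)
        out = {cid: row.to_numpy(dtype=np.int64) for cid, row in table.iterrows()}
        object.__setattr__(self, "_final_day_cache", (self.counts, out))
        return out


def _schedule_label(schedule: DilutionSchedule) -> str:
    if schedule.period == 1:
        return f"df{schedule.dfs[0]:g}"
    return "alt" + "_".join(f"{d:g}" for d in schedule.dfs)


def generate_bundle(
    design: ExperimentDesign,
    seed=None,
    params: CommunityParams | None = None,
    regime: str = "bistable",
    delta_window: tuple[float, float] | None = None,
    config: SimulationConfig | None = None,
) -> SyntheticBundle:
    """Compose a reproducible synthetic experiment.

    Samples parameters unless given, runs every (schedule x initial mix)
    condition with the day-0 pre-dilution convention, and observes each
    trajectory through OD curves and daily colony counts.  Identical
    (design, seed, params) inputs give byte-identical bundles.
    """
    rng = _rng(seed)
    if params is None:
        params = sample_params(
            design.n_species, regime=regime, seed=rng, delta_window=delta_window
        )
    if params.n_species != design.n_species:
        raise ValidationError(
            f"design has {design.n_species}-species mixes but params have {params.n_species}"
        )
    if config is None:
        config = SimulationConfig(
            max_cycles=max(design.days, 1),
            convergence_tol=1e-9 if design.run_to_convergence else 0.0,
        )
    conditions, trajectories = [], {}
    count_frames = []
    for schedule in design.schedules:
        for k, fr in enumerate(design.initial_fractions):
            cid = f"{_schedule_label(schedule)}|init{k}"
            dens = day0_density(schedule.dfs[0])
            traj = run_schedule(fr, dens, params, schedule, config)
            conditions.append(
                Condition(
                    condition_id=cid,
                    schedule=schedule,
                    initial_fractions=tuple(float(x) for x in fr),
                    day0_total_density=dens,
                )
            )
            trajectories[cid] = traj
            count_frames.append(
                generate_count_tables(traj, design, seed=rng, condition=cid)
            )
    od_curves = generate_od_curves(params, design, seed=rng)
    return SyntheticBundle(
        params=params,
        design=design,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        conditions=conditions,
        trajectories=trajectories,
        counts=pd.concat(count_frames, ignore_index=True),
        od_curves=od_curves,
    )


def resample_counts(
    bundle: SyntheticBundle,
    seed=None,
    platings_per_condition: int | None = None,
) -> SyntheticBundle:
    """Redraw the plating observations of a bundle without re-simulating.

    The underlying trajectories are deterministic given (design, params);
    only the counting noise is resampled, optionally at a different plating
    depth.  Useful for Monte-Carlo studies of observation noise.
    """
    rng = _rng(seed)
    design = bundle.design
    if platings_per_condition is not None:
        design = replace(design, platings_per_condition=platings_per_condition)
    frames = [
        generate_count_tables(bundle.trajectories[c.condition_id], design, seed=rng,
                              condition=c.condition_id)
        for c in bundle.conditions
    ]
    return replace(bundle, design=design, counts=pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# randomized study-condition samplers for the headline property checks
# ---------------------------------------------------------------------------

def sample_time_averaging_case(
    rng: np.random.Generator,
    n_dfs: int = 4,
    df_exp_range: tuple[float, float] = (0.25, 2.5),
    margin: float = 0.05,
    max_tries: int = 500,
):
    """A random pair plus a random DF multiset for the time-averaging check.

    Conditions match where the linear-averaging argument applies: the
    effective mortality sits strictly inside an outcome region
    (|alpha_tilde - 1| > margin at the equivalent constant mortality), away
    from washout (delta_eff < 0.8 min r), and away from basin boundaries —
    when the outcome is coexistence the interior state must not be
    degenerate (both equilibrium fractions above 5%), and when it is
    bistability the unstable interior fraction must be interior (10-90%); all
    draws have bounded growth-rate disparity (r_fast/r_slow <= 2.5).  The cap
    keeps the basin boundary in starting-fraction space from being displaced
    past the probe fractions by a single cycle's free-growth transient
    (displacement scales like df^(delta_r / mean r)); outside that regime
    the qualitative outcome itself becomes an initial-density question and
    the averaging claim no longer applies to fixed starting fractions.

    Returns (params, schedule, expected_label).
    """
    from .model import interior_fixed_point, schedule_equivalent_delta

    for _ in range(max_tries):
        dfs = 10.0 ** rng.uniform(*df_exp_range, size=n_dfs)
        schedule = DilutionSchedule(tuple(dfs))
        delta_eff = schedule_equivalent_delta(schedule)
        params = sample_params(2, regime="random", seed=rng)
        if delta_eff >= 0.8 * params.r.min():
            continue
        rp = reparametrize_pair(params, delta_eff)
        if abs(rp.alpha_tilde_ij - 1) <= margin or abs(rp.alpha_tilde_ji - 1) <= margin:
            continue
        if params.r[0] > 2.5 * params.r[1]:
            continue
        label = classify_outcome(rp.alpha_tilde_ij, rp.alpha_tilde_ji).label
        if label in (OutcomeLabel.COEXISTENCE, OutcomeLabel.BISTABILITY):
            eq = interior_fixed_point(params, delta_eff)
            f = eq.abundances[0] / sum(eq.abundances)
            lo = 0.10 if label == OutcomeLabel.BISTABILITY else 0.05
            if not (lo < f < 1.0 - lo):
                continue
        return params, schedule, label
    raise RegimeInfeasibleError("time-averaging case", max_tries)


def sample_classification_case(
    rng: np.random.Generator,
    margin: float = 0.05,
    max_tries: int = 500,
):
    """A random (params, delta) pair suitable for the brute-force oracle check.

    Same guards as sample_time_averaging_case, against a continuous
    mortality drawn uniformly below 0.8 min r.
    """
    from .model import interior_fixed_point

    for _ in range(max_tries):
        params = sample_params(2, regime="random", seed=rng)
        delta = rng.uniform(0.0, 0.8 * params.r.min())
        rp = reparametrize_pair(params, delta)
        if abs(rp.alpha_tilde_ij - 1) <= margin or abs(rp.alpha_tilde_ji - 1) <= margin:
            continue
        label = classify_outcome(rp.alpha_tilde_ij, rp.alpha_tilde_ji).label
        if label == OutcomeLabel.COEXISTENCE:
            eq = interior_fixed_point(params, delta)
            f = eq.abundances[0] / sum(eq.abundances)
            if not (0.05 < f < 0.95):
                continue
        return params, delta, label
    raise RegimeInfeasibleError("classification case", max_tries)
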