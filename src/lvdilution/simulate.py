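"""Serial growth-dilution simulator for Lotka-Volterra communities.

The experiment being emulated: a coculture grows for ``cycle_hours`` (24 h by
default) following mortality-free LV dynamics, then is instantaneously diluted
``df``-fold into fresh medium, and the cycle repeats.  The continuous
approximation — LV dynamics with a constant death rate
``delta = ln(df)/cycle_time`` — is provided as a separate, clearly labeled
integration mode used for theory checks; the serial map is what the
experiments (and the default simulations here) actually do.

All heavy loops are batched: a stack of replicate cultures is integrated as a
single flattened ODE system, which is what makes bifurcation diagrams and
Monte-Carlo property checks affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import NoSeparatrixError, SimulationError, ValidationError
from .params import (
    HOURS_PER_DAY,
    CommunityParams,
    DilutionSchedule,
    OutcomeClass,
    OutcomeLabel,
    SimulationConfig,
    as_fractions,
    check_fractions,
    validate_dilution_factor,
)

DEFAULT_CONFIG = SimulationConfig()


# ---------------------------------------------------------------------------
# core integration
# ---------------------------------------------------------------------------

def _lv_rhs(t, y, r, alpha_T, delta, m, s):
    Y = y.reshape(m, s)
    dY = Y * (r * (1.0 - Y @ alpha_T) - delta)
    return dY.ravel()


def integrate_batch(
    Y0: np.ndarray,
    params: CommunityParams,
    days: float,
    config: SimulationConfig = DEFAULT_CONFIG,
    delta: float = 0.0,
    cycle: int | None = None,
) -> np.ndarray:
    """Integrate m replicate communities for ``days``; returns final states.

    ``Y0`` has shape (m, n_species).  Species at exactly zero stay at zero
    (the flow has no spontaneous generation); small negative excursions from
    the integrator are clipped back to zero.
    """
    Y0 = np.asarray(Y0, dtype=float)
    squeeze = Y0.ndim == 1
    if squeeze:
        Y0 = Y0[np.newaxis, :]
    m, s = Y0.shape
    if s != params.n_species:
        raise ValidationError(f"state has {s} species, params have {params.n_species}")
    if np.any(Y0 < 0):
        raise ValidationError("abundances must be non-negative")
    if days <= 0 or not np.any(Y0 > 0):
        return Y0[0].copy() if squeeze else Y0.copy()
    sol = solve_ivp(
        _lv_rhs,
        (0.0, float(days)),
        Y0.ravel(),
        method=config.method,
        rtol=config.rtol,
        atol=config.atol,
        args=(params.r, params.alpha.T, delta, m, s),
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}", cycle=cycle)
    Y = np.maximum(sol.y[:, -1].reshape(m, s), 0.0)
    Y[Y0 == 0.0] = 0.0
    return Y[0] if squeeze else Y


def grow_cycle(
    abundances,
    params: CommunityParams,
    cycle_hours: float = 24.0,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """One mortality-free growth phase of ``cycle_hours``."""
    return integrate_batch(
        np.asarray(abundances, dtype=float), params, cycle_hours / HOURS_PER_DAY, config
    )


def integrate_continuous(
    abundances,
    params: CommunityParams,
    delta: float,
    days: float,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """LV flow with constant continuous mortality delta (theory-check mode)."""
    return integrate_batch(np.asarray(abundances, dtype=float), params, days, config, delta=delta)


def steady_state_continuous(
    Y0: np.ndarray,
    params: CommunityParams,
    delta: float,
    config: SimulationConfig = DEFAULT_CONFIG,
    chunk_days: float = 50.0,
    max_days: float = 5000.0,
    tol: float = 1e-9,
) -> np.ndarray:
    """Integrate the continuous-mortality flow until the state stops moving."""
    Y = np.atleast_2d(np.asarray(Y0, dtype=float)).copy()
    elapsed = 0.0
    while elapsed < max_days:
        Y_next = integrate_batch(Y, params, chunk_days, config, delta=delta)
        elapsed += chunk_days
        if np.max(np.abs(Y_next - Y)) < tol:
            return Y_next
        Y = Y_next
    return Y


def apply_dilution(
    abundances,
    df: float,
    config: SimulationConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Instantaneous df-fold dilution.

    Deterministic mode divides by df and zeroes anything below the extinction
    threshold.  Stochastic mode (config.stochastic_dilution) converts to cell
    counts at ``config.cells_per_unit`` cells per unit abundance and draws
    binomial survivors with transfer probability 1/df, which reproduces
    demographic extinction at strong dilutions.
    """
    df = validate_dilution_factor(df)
    N = np.asarray(abundances, dtype=float)
    if config.stochastic_dilution:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        cells = np.round(N * config.cells_per_unit).astype(np.int64)
        survivors = rng.binomial(cells, min(1.0, 1.0 / df))
        out = survivors / config.cells_per_unit
    else:
        out = N / df
        out = np.where(out < config.extinction_threshold, 0.0, out)
    return out


def day0_density(df: float, cap_df: float = 1e5) -> float:
    """Day-0 total density when mixtures are pre-diluted by their daily DF.

    Mixtures start from saturated cultures (total normalized density ~1)
    diluted by the factor they will see daily, except that extreme factors
    are capped (the deepest-dilution cultures were started one decade higher
    to avoid stochastic extinction on day 0).
    """
    return 1.0 / min(validate_dilution_factor(df), cap_df)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Record of one serial-dilution run.

    ``abundances[c]`` is the state at the end of the growth phase of cycle
    ``c`` (1-based); row 0 is the initial, pre-growth state.  ``dfs_applied[c-1]``
    is the dilution executed after cycle ``c``'s growth.
    """

    species_names: tuple[str, ...]
    abundances: np.ndarray  # (n_cycles + 1, n_species)
    dfs_applied: np.ndarray  # (n_cycles,)
    schedule: DilutionSchedule
    converged: bool

    @property
    def n_cycles(self) -> int:
        return self.abundances.shape[0] - 1

    @property
    def fractions(self) -> np.ndarray:
        return as_fractions(self.abundances)

    @property
    def final_abundances(self) -> np.ndarray:
        return self.abundances[-1]

    @property
    def final_fractions(self) -> np.ndarray:
        return self.fractions[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle records: cycle, species, abundance, fraction, df_applied."""
        rows = []
        fr = self.fractions
        for c in range(self.abundances.shape[0]):
            # dilution executed after this cycle's growth (none after the last)
            df_applied = self.dfs_applied[c - 1] if 1 <= c <= len(self.dfs_applied) else np.nan
            for k, sp in enumerate(self.species_names):
                rows.append(
                    {
                        "cycle": c,
                        "species": sp,
                        "abundance": self.abundances[c, k],
                        "fraction": fr[c, k],
                        "df_applied": df_applied,
                    }
                )
        return pd.DataFrame(rows)


def run_schedule(
    initial_fractions,
    total_density: float,
    params: CommunityParams,
    schedule: DilutionSchedule,
    config: SimulationConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Alternate growth and dilution cycles, repeating the schedule cyclically.

    Stops early once the end-of-growth fractions change by less than
    ``config.convergence_tol`` across one full schedule period for
    ``config.convergence_window`` consecutive cycles; otherwise runs to
    ``config.max_cycles`` and returns with ``converged=False``.
    """
    f0 = check_fractions(initial_fractions, params.n_species)
    if total_density <= 0:
        raise ValidationError("total_density must be positive")
    states, dfs, converged = _run_batch(
        (f0 * total_density)[np.newaxis, :], params, schedule, config, rng=rng, record=True
    )
    return Trajectory(
        species_names=params.species_names,
        abundances=states[:, 0, :],
        dfs_applied=dfs,
        schedule=schedule,
        converged=bool(converged[0]),
    )


def _run_batch(
    Y0: np.ndarray,
    params: CommunityParams,
    schedule: DilutionSchedule,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    record: bool = False,
):
    """Run m replicate cultures through the schedule in lock step.

    Returns (states, dfs_applied, converged_mask) where states is
    (n_cycles+1, m, s) when record=True, else just the final (m, s) block in
    a length-1 leading axis.  The batch stops once every replicate has
    converged (a converged replicate keeps integrating; it sits at its
    attractor, so the extra cycles are inert).
    """
    Y = np.asarray(Y0, dtype=float).copy()
    m, s = Y.shape
    T_days = schedule.cycle_hours / HOURS_PER_DAY
    period = schedule.period
    history = [Y.copy()]
    frac_hist = [as_fractions(Y)]
    dfs_applied = []
    streak = np.zeros(m, dtype=int)
    converged = np.zeros(m, dtype=bool)
    for cycle in range(1, config.max_cycles + 1):
        Y = integrate_batch(Y, params, T_days, config, cycle=cycle)
        if record:
            history.append(Y.copy())
        f = as_fractions(Y)
        frac_hist.append(f)
        if len(frac_hist) > period:
            drift = np.max(np.abs(f - frac_hist[-1 - period]), axis=1)
            streak = np.where(drift < config.convergence_tol, streak + 1, 0)
            converged = streak >= config.convergence_window
        if len(frac_hist) > period + 1:
            frac_hist.pop(0)
        # stop only at full schedule periods so fluctuating-schedule endpoints
        # are phase-consistent (fractions oscillate within a period)
        if (converged.all() and cycle % period == 0) or cycle == config.max_cycles:
            break
        df = schedule.df_for_cycle(cycle - 1)
        Y = apply_dilution(Y, df, config, rng=rng)
        dfs_applied.append(df)
    if record:
        n = len(history)
        states = np.stack(history, axis=0)
        return states, np.asarray(dfs_applied[: n - 1], dtype=float), converged
    return Y[np.newaxis, ...], np.asarray(dfs_applied, dtype=float), converged


def endpoints(
    initial_fraction_grid,
    params: CommunityParams,
    schedule: DilutionSchedule,
    config: SimulationConfig = DEFAULT_CONFIG,
    total_density: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Final abundances from a grid of initial compositions (batched).

    ``initial_fraction_grid`` is (m, n_species) or, for pairs, a 1-D array of
    species-i fractions.  ``total_density`` defaults to the day-0 convention
    for the schedule's first dilution factor.  Returns (final_abundances,
    converged_mask).
    """
    grid = np.asarray(initial_fraction_grid, dtype=float)
    if grid.ndim == 1:
        if params.n_species != 2:
            raise ValidationError("1-D fraction grids are only defined for pairs")
        grid = np.stack([grid, 1.0 - grid], axis=1)
    if total_density is None:
        total_density = day0_density(schedule.dfs[0])
    Y0 = grid * total_density
    states, _, converged = _run_batch(Y0, params, schedule, config, record=False)
    return states[-1], converged


# ---------------------------------------------------------------------------
# endpoint clustering and outcome classification
# ---------------------------------------------------------------------------

def cluster_1d(values: np.ndarray, tol: float) -> list[tuple[float, np.ndarray]]:
    """Greedy 1-D clustering: sort and split at gaps larger than tol.

    Returns a list of (cluster mean, member indices) ordered by mean.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values)
    clusters: list[list[int]] = [[order[0]]]
    for idx in order[1:]:
        if values[idx] - values[clusters[-1][-1]] <= tol:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    return [(float(values[c].mean()), np.asarray(c)) for c in clusters]


@dataclass(frozen=True)
class TrioState:
    """One final community state, labeled by its surviving-species subset."""

    label: str
    survivors: tuple[str, ...]
    composition: tuple[float, ...]  # mean final fractions over member runs
    n_trajectories: int
    member_indices: tuple[int, ...]


def classify_endpoint_fractions(
    fractions_i: np.ndarray,
    cluster_tol: float = 0.02,
    boundary_tol: float = 0.02,
) -> OutcomeClass:
    clusters = cluster_1d(fractions_i, cluster_tol)
    means = [m for m, _ in clusters]

    def kind(mean):
        if mean >= 1.0 - boundary_tol:
            return 1.0
        if mean <= boundary_tol:
            return 0.0
        return mean

    states = [kind(m) for m in means]
    if len(states) == 1:
        st = states[0]
        if st == 1.0:
            return OutcomeClass(OutcomeLabel.EXCLUSION_I_WINS, (1.0,))
        if st == 0.0:
            return OutcomeClass(OutcomeLabel.EXCLUSION_J_WINS, (0.0,))
        return OutcomeClass(OutcomeLabel.COEXISTENCE, (float(st),))
    return OutcomeClass(OutcomeLabel.BISTABILITY, tuple(float(s) for s in states))


def classify_final_states(
    trajectories: list[Trajectory],
    survival_threshold: float = 1e-3,
    cluster_tol: float = 0.05,
    pair_cluster_tol: float = 0.02,
    boundary_tol: float = 0.02,
):
    """Group converged runs into final community states.

    Two-species input returns an OutcomeClass from endpoint clustering of the
    species-i fraction.  Three or more species returns a list of TrioState,
    grouped first by which species survive (final fraction above
    ``survival_threshold``) and then by composition within
    ``cluster_tol``.  Unconverged trajectories are included but flagged with
    a warning, never dropped silently.
    """
    if not trajectories:
        raise ValidationError("no trajectories to classify")
    unconverged = [k for k, t in enumerate(trajectories) if not t.converged]
    if unconverged:
        warnings.warn(
            f"trajectories {unconverged} hit max_cycles without converging; "
            "classification may reflect transient states",
            stacklevel=2,
        )
    n = len(trajectories[0].species_names)
    finals = np.stack([t.final_fractions for t in trajectories])
    if n == 2:
        return classify_endpoint_fractions(
            finals[:, 0], cluster_tol=pair_cluster_tol, boundary_tol=boundary_tol
        )
    names = trajectories[0].species_names
    groups: dict[tuple[int, ...], list[int]] = {}
    for k, f in enumerate(finals):
        key = tuple(int(i) for i in np.flatnonzero(f > survival_threshold))
        groups.setdefault(key, []).append(k)
    states: list[TrioState] = []
    for key in sorted(groups):
        members = groups[key]
        comps = finals[members]
        # split a surviving set into sub-states if compositions disagree
        remaining = list(range(len(members)))
        while remaining:
            seedi = remaining[0]
            close = [
                k for k in remaining if np.max(np.abs(comps[k] - comps[seedi])) <= cluster_tol
            ]
            remaining = [k for k in remaining if k not in close]
            idx = tuple(members[k] for k in close)
            comp = comps[list(close)].mean(axis=0)
            survivors = tuple(names[i] for i in key)
            states.append(
                TrioState(
                    label="+".join(survivors) if survivors else "extinct",
                    survivors=survivors,
                    composition=tuple(float(x) for x in comp),
                    n_trajectories=len(idx),
                    member_indices=idx,
                )
            )
    return states


def pair_outcome(
    params: CommunityParams,
    schedule: DilutionSchedule,
    initial_fractions=(0.05, 0.275, 0.5, 0.725, 0.95),
    config: SimulationConfig = DEFAULT_CONFIG,
    total_density: float | None = None,
    boundary_tol: float = 0.02,
) -> OutcomeClass:
    """Brute-force outcome of a pair under a schedule, from endpoint clustering."""
    finals, _ = endpoints(
        np.asarray(initial_fractions, dtype=float), params, schedule, config, total_density
    )
    fr = as_fractions(finals)[:, 0]
    # a species is extinct-bound if its absolute abundance has collapsed even
    # when slow asymptotics leave its fraction slightly off the boundary
    ab = finals
    fr = fr.copy()
    fr[(ab[:, 1] < 1e-4) & (ab[:, 0] > 1e-4)] = 1.0
    fr[(ab[:, 0] < 1e-4) & (ab[:, 1] > 1e-4)] = 0.0
    return classify_endpoint_fractions(fr, boundary_tol=boundary_tol)


def brute_force_outcome_continuous(
    params: CommunityParams,
    delta: float,
    config: SimulationConfig = DEFAULT_CONFIG,
    initial_fractions=(0.01, 0.1, 0.25, 0.4, 0.5, 0.6, 0.75, 0.9, 0.99),
    total_density: float = 1.0,
    survival_abundance: float = 1e-4,
) -> OutcomeLabel | None:
    """Outcome of a pair by integrating the continuous-mortality flow to rest.

    Independent of the reparametrization: integrates the mortality-augmented
    LV equations from a grid of initial fractions until the state stops
    moving, then reads which species persist (abundance above
    ``survival_abundance``) from each start.  Starts are placed at
    carrying-capacity-scale density so the fraction grid actually slices
    through the basin structure around the equilibria (a very dilute start
    lets the faster grower race through a transient that belongs to the
    washed-out part of state space, not to the basins being probed).
    Returns None when the endpoint pattern fits no clean outcome.
    """
    grid = np.asarray(initial_fractions, dtype=float)
    Y0 = np.stack([grid, 1.0 - grid], axis=1) * total_density
    Y = steady_state_continuous(Y0, params, delta, config)
    patterns = {tuple(Y[k] > survival_abundance) for k in range(Y.shape[0])}
    if patterns == {(True, True)}:
        return OutcomeLabel.COEXISTENCE
    if patterns == {(True, False)}:
        return OutcomeLabel.EXCLUSION_I_WINS
    if patterns == {(False, True)}:
        return OutcomeLabel.EXCLUSION_J_WINS
    if patterns == {(True, False), (False, True)}:
        return OutcomeLabel.BISTABILITY
    return None


def bracket_outcome(
    params: CommunityParams,
    schedule: DilutionSchedule,
    config: SimulationConfig = DEFAULT_CONFIG,
    bracket: tuple[float, float] = (0.001, 0.999),
    persistence_fraction: float = 1e-3,
    total_density: float | None = None,
) -> OutcomeLabel:
    """Outcome of a pair from basin probing at the bracket's two ends.

    Designed for the idealized model (extinction_threshold = 0), where
    exclusion is an asymptotic decay rather than a hard zero: runs start from
    the two bracket fractions plus 50:50, and a species counts as persisting
    when its fraction at a schedule-period boundary stays above
    ``persistence_fraction`` after convergence (a converged, period-locked
    interior state can legitimately sit at a small fraction, while a loser's
    fraction decays geometrically far below it).  Differing endpoints from
    the two bracket ends mean bistability.
    """
    grid = np.array([bracket[0], 0.5, bracket[1]])
    finals, _ = endpoints(grid, params, schedule, config, total_density)
    fr = as_fractions(finals)[:, 0]
    kinds = np.where(fr < persistence_fraction, 0.0, np.where(fr > 1 - persistence_fraction, 1.0, 0.5))
    if kinds[0] != kinds[2]:
        return OutcomeLabel.BISTABILITY
    mid = kinds[1]
    if mid == 1.0:
        return OutcomeLabel.EXCLUSION_I_WINS
    if mid == 0.0:
        return OutcomeLabel.EXCLUSION_J_WINS
    return OutcomeLabel.COEXISTENCE


# ---------------------------------------------------------------------------
# separatrix and bifurcation diagram
# ---------------------------------------------------------------------------

def find_separatrix(
    params: CommunityParams,
    df_or_schedule,
    config: SimulationConfig = DEFAULT_CONFIG,
    bracket: tuple[float, float] = (0.01, 0.99),
    xtol: float = 1e-4,
    total_density: float | None = None,
) -> float:
    """Unstable initial fraction dividing the two basins of a bistable pair.

    Bisection on the initial fraction of species i until the bracket is
    narrower than ``xtol``; raises NoSeparatrixError when runs from the two
    bracket ends reach the same final state.
    """
    if params.n_species != 2:
        raise ValidationError("find_separatrix is defined for pairs")
    schedule = (
        df_or_schedule
        if isinstance(df_or_schedule, DilutionSchedule)
        else DilutionSchedule.constant(df_or_schedule)
    )

    def final_fraction(x):
        finals, _ = endpoints(np.asarray([x]), params, schedule, config, total_density)
        return as_fractions(finals)[0, 0]

    lo, hi = bracket
    f_lo, f_hi = final_fraction(lo), final_fraction(hi)
    if abs(f_hi - f_lo) < 0.5:
        raise NoSeparatrixError(
            f"endpoints from initial fractions {lo} and {hi} agree "
            f"({f_lo:.3f} vs {f_hi:.3f}); the pair is not bistable here"
        )
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        f_mid = final_fraction(mid)
        if abs(f_mid - f_lo) <= abs(f_mid - f_hi):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class BifurcationDiagram:
    """Stable/unstable branches over a dilution-factor grid for one pair."""

    species_names: tuple[str, ...]
    dfs: np.ndarray
    stable: list[list[float]]  # per DF: stable final fractions of species i
    unstable: list[list[float]]  # per DF: separatrix fractions (may be empty)
    endpoint_map: list[np.ndarray]  # per DF: (m, 2) array [initial, final] fraction of i
    cycle_hours: float = 24.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, df in enumerate(self.dfs):
            for f in self.stable[k]:
                rows.append({"df": df, "branch_type": "stable", "fraction": f})
            for f in self.unstable[k]:
                rows.append({"df": df, "branch_type": "unstable", "fraction": f})
        return pd.DataFrame(rows)

    def endpoint_frame(self) -> pd.DataFrame:
        rows = []
        for k, df in enumerate(self.dfs):
            for x0, x1 in self.endpoint_map[k]:
                rows.append({"df": df, "initial_fraction": x0, "final_fraction": x1})
        return pd.DataFrame(rows)


def bifurcation_diagram(
    params: CommunityParams,
    df_grid,
    initial_fraction_grid=(0.05, 0.275, 0.5, 0.725, 0.95),
    config: SimulationConfig = DEFAULT_CONFIG,
    cycle_hours: float = 24.0,
    cluster_tol: float = 0.02,
) -> BifurcationDiagram:
    """Endpoint map, stable branches, and separatrices over a DF grid."""
    df_grid = np.asarray(df_grid, dtype=float)
    init = np.asarray(initial_fraction_grid, dtype=float)
    if df_grid.size == 0 or init.size == 0:
        raise ValidationError("df and initial-fraction grids must be non-empty")
    stable, unstable, endpoint_map = [], [], []
    for df in df_grid:
        schedule = DilutionSchedule.constant(df, cycle_hours=cycle_hours)
        try:
            finals, _ = endpoints(init, params, schedule, config)
        except SimulationError as exc:
            raise SimulationError(f"DF {df:g}: {exc}") from exc
        fr = as_fractions(finals)[:, 0]
        clusters = cluster_1d(fr, cluster_tol)
        stable.append([m for m, _ in clusters])
        endpoint_map.append(np.stack([init, fr], axis=1))
        if len(clusters) >= 2:
            try:
                sep = find_separatrix(params, schedule, config)
                unstable.append([sep])
            except NoSeparatrixError:
                unstable.append([])
        else:
            unstable.append([])
    return BifurcationDiagram(
        species_names=params.species_names,
        dfs=df_grid,
        stable=stable,
        unstable=unstable,
        endpoint_map=endpoint_map,
        cycle_hours=cycle_hours,
    )
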