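"""Lotka-Volterra competition with added mortality: closed-form theory.

The model for n species with a community-wide death rate ``delta`` is::

    dN_i/dt = N_i * [ r_i * (1 - sum_j alpha_ij N_j) - delta ],   alpha_ii = 1

with abundances normalized by carrying capacity.  For a pair, rescaling
``N_tilde_i = N_i / (1 - delta/r_i)`` eliminates the death rate and yields an
ordinary LV model with effective parameters::

    r_tilde_i     = r_i - delta
    alpha_tilde_ij = alpha_ij * (1 - delta/r_j) / (1 - delta/r_i)

so the qualitative outcome is read off the effective coefficients exactly as
in the classic model: both below one -> stable coexistence, both above one ->
bistability (alternative stable states), exactly one above one -> competitive
exclusion.  Because delta enters the per-capita growth linearly, a fluctuating
mortality can be replaced by its time average; for daily fold dilutions the
equivalent continuous rate is ``delta = ln(df) / cycle_time``, which makes the
equivalent constant dilution factor the *geometric* mean of a fluctuating
schedule.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import (
    DegenerateBoundaryError,
    NoCrossingError,
    NoInteriorEquilibriumError,
    ValidationError,
    WashoutError,
)
from .params import (
    HOURS_PER_DAY,
    CommunityParams,
    DilutionSchedule,
    Equilibrium,
    OutcomeClass,
    OutcomeLabel,
    ReparametrizedPair,
    validate_dilution_factor,
)

#: |alpha_tilde - 1| below this is treated as sitting on the classification
#: boundary, where the outcome is discontinuous.
BOUNDARY_TOL = 1e-9


def check_washout(r, delta: float, species_names=None):
    """Raise WashoutError naming the first species with r - delta <= 0."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if delta < 0:
        raise ValidationError(f"mortality rate must be non-negative, got {delta}")
    for k, rk in enumerate(r):
        if delta >= rk:
            name = species_names[k] if species_names is not None else k
            raise WashoutError(name, rk, delta)


def reparametrize(alpha_ij: float, r_i: float, r_j: float, delta: float) -> float:
    """Effective competition coefficient alpha_tilde_ij at mortality delta.

    alpha_tilde_ij = alpha_ij * (1 - delta/r_j) / (1 - delta/r_i); exact
    identity at delta = 0.  Defined only for 0 <= delta < min(r_i, r_j);
    outside that range one species is washed out and the reduction to a
    mortality-free model breaks down.
    """
    check_washout([r_i, r_j], delta, species_names=("i", "j"))
    return alpha_ij * (1.0 - delta / r_j) / (1.0 - delta / r_i)


def reparametrize_pair(params: CommunityParams, delta: float, i: int = 0, j: int = 1) -> ReparametrizedPair:
    """Both effective coefficients and growth rates for a pair at delta."""
    r_i, r_j = float(params.r[i]), float(params.r[j])
    check_washout(
        [r_i, r_j], delta, species_names=(params.species_names[i], params.species_names[j])
    )
    return ReparametrizedPair(
        alpha_tilde_ij=reparametrize(params.alpha[i, j], r_i, r_j, delta),
        alpha_tilde_ji=reparametrize(params.alpha[j, i], r_j, r_i, delta),
        r_tilde_i=r_i - delta,
        r_tilde_j=r_j - delta,
    )


def reparametrized_params(params: CommunityParams, delta: float) -> CommunityParams:
    """Mortality-free community equivalent to ``params`` under delta.

    Rescaled abundances relate to the originals by
    ``N_tilde_i = N_i / (1 - delta/r_i)``.  n-species generalization of the
    pairwise formula (the derivation is per-row and does not use n = 2).
    """
    check_washout(params.r, delta, params.species_names)
    scale = 1.0 - delta / params.r  # N = scale * N_tilde
    alpha_t = params.alpha * scale[np.newaxis, :] / scale[:, np.newaxis]
    np.fill_diagonal(alpha_t, 1.0)
    return CommunityParams(
        species_names=params.species_names,
        r=params.r - delta,
        alpha=alpha_t,
        K=params.K,
    )


def rescaling_factors(params: CommunityParams, delta: float) -> np.ndarray:
    """Per-species factors s_i = 1 - delta/r_i with N_i = s_i * N_tilde_i."""
    check_washout(params.r, delta, params.species_names)
    return 1.0 - delta / params.r


def _interior_tilde(at_ij: float, at_ji: float) -> tuple[float, float]:
    det = 1.0 - at_ij * at_ji
    if det == 0:
        raise NoInteriorEquilibriumError("alpha_tilde_ij * alpha_tilde_ji == 1: nullclines parallel")
    return (1.0 - at_ij) / det, (1.0 - at_ji) / det


def classify_outcome(alpha_tilde_ij: float, alpha_tilde_ji: float) -> OutcomeClass:
    """Qualitative competition outcome from the effective coefficient pair.

    Both coefficients below one give coexistence at a single interior stable
    state; both above one give bistability with an unstable interior fraction
    (the separatrix); one above and one below give exclusion of the species
    whose coefficient exceeds one.
    """
    at_ij, at_ji = float(alpha_tilde_ij), float(alpha_tilde_ji)
    for v in (at_ij, at_ji):
        if not (math.isfinite(v) and v > 0):
            raise ValidationError(f"effective coefficients must be finite and positive, got {v}")
        if abs(v - 1.0) < BOUNDARY_TOL:
            raise DegenerateBoundaryError(
                f"alpha_tilde = {v!r} lies on the classification boundary (=1); "
                "perturb the parameters or report the boundary explicitly"
            )
    if at_ij < 1.0 and at_ji < 1.0:
        ni, nj = _interior_tilde(at_ij, at_ji)
        return OutcomeClass(
            label=OutcomeLabel.COEXISTENCE,
            stable_states=(ni / (ni + nj),),
        )
    if at_ij > 1.0 and at_ji > 1.0:
        ni, nj = _interior_tilde(at_ij, at_ji)
        return OutcomeClass(
            label=OutcomeLabel.BISTABILITY,
            stable_states=(0.0, 1.0),
            unstable_states=(ni / (ni + nj),),
        )
    if at_ij > 1.0:  # j suppresses i
        return OutcomeClass(label=OutcomeLabel.EXCLUSION_J_WINS, stable_states=(0.0,))
    return OutcomeClass(label=OutcomeLabel.EXCLUSION_I_WINS, stable_states=(1.0,))


def interior_fixed_point(params: CommunityParams, delta: float) -> Equilibrium:
    """Interior equilibrium of a two-species pair at mortality delta.

    Solved in reparametrized coordinates and mapped back to original
    normalized abundances (multiply by 1 - delta/r_i); stability from the
    eigenvalues of the 2x2 Jacobian of the original flow at the point.
    """
    if params.n_species != 2:
        raise ValidationError("interior_fixed_point is defined for two-species communities")
    rp = reparametrize_pair(params, delta)
    nt_i, nt_j = _interior_tilde(rp.alpha_tilde_ij, rp.alpha_tilde_ji)
    if nt_i < 0 or nt_j < 0:
        raise NoInteriorEquilibriumError(
            f"interior point ({nt_i:.6g}, {nt_j:.6g}) has a negative component"
        )
    scale = rescaling_factors(params, delta)
    N = np.array([nt_i, nt_j]) * scale
    J = jacobian(N, params, delta)
    eig = np.linalg.eigvals(J)
    return Equilibrium(
        abundances=(float(N[0]), float(N[1])),
        stable=bool(np.max(eig.real) < 0),
        eigenvalues=tuple(complex(e) for e in eig),
    )


def jacobian(N, params: CommunityParams, delta: float = 0.0) -> np.ndarray:
    """Community (Jacobian) matrix of the mortality-augmented LV flow at N."""
    N = np.asarray(N, dtype=float)
    r, A = params.r, params.alpha
    growth = r * (1.0 - A @ N) - delta
    return np.diag(growth) - (N * r)[:, np.newaxis] * A


def critical_delta(alpha_ij: float, r_i: float, r_j: float) -> float:
    """Mortality at which alpha_tilde_ij crosses 1 (the outcome boundary).

    delta* = (1 - alpha_ij) / (1/r_i - alpha_ij/r_j).  Raises NoCrossingError
    when the crossing does not lie in [0, min(r_i, r_j)).
    """
    if alpha_ij == 1.0:
        return 0.0
    denom = 1.0 / r_i - alpha_ij / r_j
    if denom == 0.0:
        raise NoCrossingError(
            f"alpha_tilde is constant in delta (alpha_ij = r_j/r_i = {alpha_ij}); no crossing"
        )
    delta_star = (1.0 - alpha_ij) / denom
    if not (0.0 <= delta_star < min(r_i, r_j)):
        raise NoCrossingError(
            f"alpha_tilde_ij = 1 solves at delta = {delta_star:.6g}, outside "
            f"[0, {min(r_i, r_j):.6g})"
        )
    return delta_star


def df_to_delta(df: float, cycle_hours: float = 24.0) -> float:
    """Continuous mortality (1/day) equivalent to a per-cycle fold dilution.

    delta = ln(df) / cycle_time: over one cycle the dilution removes the
    same logarithmic amount of biomass as the continuous death rate.
    """
    df = validate_dilution_factor(df)
    if cycle_hours <= 0:
        raise ValidationError("cycle_hours must be positive")
    return math.log(df) / (cycle_hours / HOURS_PER_DAY)


def delta_to_df(delta: float, cycle_hours: float = 24.0) -> float:
    """Inverse of df_to_delta."""
    if delta < 0:
        raise ValidationError("mortality rate must be non-negative")
    return math.exp(delta * cycle_hours / HOURS_PER_DAY)


def schedule_equivalent_df(schedule: DilutionSchedule) -> float:
    """Constant dilution factor equivalent to a fluctuating schedule.

    The geometric mean of the per-cycle factors — equivalently exp of the
    arithmetic mean of the per-cycle delta*T — because mortality enters the
    per-capita growth linearly and can be time-averaged.
    """
    logs = np.log(np.asarray(schedule.dfs, dtype=float))
    return float(np.exp(logs.mean()))


def schedule_equivalent_delta(schedule: DilutionSchedule) -> float:
    """Time-averaged continuous mortality (1/day) of a schedule."""
    return df_to_delta(schedule_equivalent_df(schedule), schedule.cycle_hours)
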