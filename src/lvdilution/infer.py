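"""Parameter estimation: growth rates from OD curves, competition
coefficients from outcome boundaries on dilution-factor grids.

Growth rates use the time-to-threshold method: assume exponential growth
from the known initial OD to a fixed threshold (OD 0.1) and divide the log
ratio by the first crossing time.  Lag is deliberately not corrected for —
a longer lag simply reads as a lower effective rate, which is the rate that
matters for daily-dilution competition.

Competition coefficients are read off the dilution factor at which the
qualitative pairwise outcome changes: there, one effective coefficient
equals one, so alpha_ij = (1 - delta*/r_i) / (1 - delta*/r_j) with
delta* = ln(DF*)/cycle_time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidCurveError,
    NoGrowthError,
    UninformativeDesignError,
    ValidationError,
    WashoutError,
)
from .model import df_to_delta
from .params import HOURS_PER_DAY, OutcomeLabel
from .simulate import classify_endpoint_fractions
from .stats import CountObservation, fraction_raw, fraction_sd


@dataclass(frozen=True)
class ODCurve:
    """One background-subtracted monoculture growth curve.

    ``times_h`` in hours, strictly increasing.  The known initial OD is the
    equalized inoculum OD divided by the (fold) dilution at which the culture
    was seeded; negative background-subtracted readings are clipped to zero
    with a warning.
    """

    times_h: np.ndarray
    od: np.ndarray
    equalized_od: float
    inoculum_dilution: float
    species: str | None = None
    replicate: str | None = None

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if t.ndim != 1 or t.shape != od.shape or t.size < 2:
            raise ValidationError("times and OD must be matching 1-D arrays with >= 2 points")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.equalized_od <= 0 or self.inoculum_dilution < 1:
            raise ValidationError("equalized OD must be positive and dilution >= 1 (fold)")
        if np.any(od < 0):
            warnings.warn(
                "negative background-subtracted OD values clipped to 0", stacklevel=2
            )
            od = np.maximum(od, 0.0)
        t.setflags(write=False)
        od.setflags(write=False)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "od", od)

    @property
    def initial_od(self) -> float:
        return self.equalized_od / self.inoculum_dilution


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Aggregated time-to-threshold growth rate for one species (1/hour)."""

    rate: float
    sem: float
    per_replicate: tuple[float, ...]
    threshold: float
    n: int


@dataclass(frozen=True)
class BoundaryObservation:
    """A dilution factor at which the pairwise outcome changes.

    ``coefficient`` names which effective coefficient crosses one there:
    'ij' (effect of j on i) or 'ji'.  ``df_bracket`` is the pair of grid DFs
    bracketing the change; ``df`` is their geometric midpoint.
    """

    pair: tuple[str, str]
    df: float
    coefficient: str
    cycle_hours: float = 24.0
    df_bracket: tuple[float, float] | None = None

    def __post_init__(self):
        if self.df < 1:
            raise ValidationError("boundary DF must be >= 1")
        if self.coefficient not in ("ij", "ji"):
            raise ValidationError("coefficient must be 'ij' or 'ji'")


def estimate_growth_rate(curve: ODCurve, threshold: float = 0.1) -> float:
    """Time-to-threshold growth rate of one curve, in 1/hour.

    r = ln(threshold / OD0) / t_cross with t_cross the first
    linearly-interpolated crossing of the threshold.
    """
    if curve.initial_od >= threshold or curve.od[0] >= threshold:
        raise InvalidCurveError(
            f"curve starts at or above the threshold OD {threshold}"
        )
    above = np.flatnonzero(curve.od >= threshold)
    if above.size == 0:
        raise NoGrowthError(
            f"curve never crosses OD {threshold} within {curve.times_h[-1]:.1f} h"
        )
    k = int(above[0])
    t0, t1 = curve.times_h[k - 1], curve.times_h[k]
    y0, y1 = curve.od[k - 1], curve.od[k]
    t_cross = t0 + (threshold - y0) / (y1 - y0) * (t1 - t0)
    return math.log(threshold / curve.initial_od) / t_cross


def aggregate_growth_rates(
    estimates, threshold: float = 0.1
) -> GrowthRateEstimate:
    """Mean and SEM (SD/sqrt(n)) across per-replicate rate estimates."""
    est = [float(e) for e in estimates]
    if not est:
        raise ValidationError("need at least one growth-rate estimate")
    arr = np.asarray(est)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return GrowthRateEstimate(
        rate=float(arr.mean()),
        sem=sem,
        per_replicate=tuple(est),
        threshold=threshold,
        n=arr.size,
    )


def estimate_alpha_from_boundary(
    obs: BoundaryObservation, r_i: float, r_j: float
) -> float:
    """Invert the boundary condition alpha_tilde(delta*) = 1 for alpha.

    With ``obs.coefficient == 'ij'`` this returns
    alpha_ij = (1 - delta*/r_i) / (1 - delta*/r_j); 'ji' swaps the roles.
    Rates are in 1/day.  Raises WashoutError if delta* reaches either rate —
    there the boundary reflects washout, not a coefficient crossing.
    """
    delta_star = df_to_delta(obs.df, obs.cycle_hours)
    for name, r in zip(obs.pair, (r_i, r_j)):
        if delta_star >= r:
            raise WashoutError(name, r, delta_star)
    if obs.coefficient == "ij":
        return (1.0 - delta_star / r_i) / (1.0 - delta_star / r_j)
    return (1.0 - delta_star / r_j) / (1.0 - delta_star / r_i)


def alpha_grid_bound(
    df_bracket: tuple[float, float], r_i: float, r_j: float, cycle_hours: float = 24.0
) -> float:
    """Worst-case |Delta ln alpha| from placing the boundary at the bracket midpoint.

    The true boundary lies somewhere in the bracket and the estimate sits at
    its geometric midpoint, so the delta error is at most half the bracket
    width; propagate through d ln(alpha)/d delta = 1/(r_j - delta) - 1/(r_i - delta),
    maximized over the bracket.
    """
    d_lo = df_to_delta(df_bracket[0], cycle_hours)
    d_hi = df_to_delta(df_bracket[1], cycle_hours)
    half = 0.5 * (d_hi - d_lo)
    grid = np.linspace(d_lo, min(d_hi, 0.999 * min(r_i, r_j)), 64)
    slope = np.abs(1.0 / (r_j - grid) - 1.0 / (r_i - grid))
    return float(slope.max() * half)


# transition (label at lower DF, label at higher DF) -> coefficient crossing 1
_TRANSITION_COEFF = {
    (OutcomeLabel.EXCLUSION_J_WINS, OutcomeLabel.BISTABILITY): "ji",
    (OutcomeLabel.BISTABILITY, OutcomeLabel.EXCLUSION_I_WINS): "ij",
    (OutcomeLabel.EXCLUSION_J_WINS, OutcomeLabel.COEXISTENCE): "ij",
    (OutcomeLabel.COEXISTENCE, OutcomeLabel.EXCLUSION_I_WINS): "ji",
    (OutcomeLabel.EXCLUSION_I_WINS, OutcomeLabel.BISTABILITY): "ij",
    (OutcomeLabel.BISTABILITY, OutcomeLabel.EXCLUSION_J_WINS): "ji",
    (OutcomeLabel.EXCLUSION_I_WINS, OutcomeLabel.COEXISTENCE): "ji",
    (OutcomeLabel.COEXISTENCE, OutcomeLabel.EXCLUSION_J_WINS): "ij",
}


def boundaries_from_labels(
    dfs: np.ndarray,
    labels: list[OutcomeLabel],
    pair: tuple[str, str],
    cycle_hours: float = 24.0,
) -> list[BoundaryObservation]:
    """Boundary observations from the outcome label along a DF grid.

    Each adjacent label change yields one observation at the geometric
    midpoint of the bracketing grid DFs.  A direct exclusion-to-exclusion
    flip means both coefficients cross inside one bracket; both observations
    are emitted with the same (wide) bracket.  When a coefficient appears to
    cross more than once (count noise), the first crossing is kept.
    """
    obs: list[BoundaryObservation] = []
    seen: set[str] = set()
    for k in range(len(labels) - 1):
        lo, hi = labels[k], labels[k + 1]
        if lo == hi:
            continue
        mid = math.sqrt(dfs[k] * dfs[k + 1])
        bracket = (float(dfs[k]), float(dfs[k + 1]))
        key = (lo, hi)
        if key in _TRANSITION_COEFF:
            coeffs = [_TRANSITION_COEFF[key]]
        else:  # both coefficients cross within one grid step
            coeffs = ["ji", "ij"] if lo == OutcomeLabel.EXCLUSION_J_WINS else ["ij", "ji"]
        for c in coeffs:
            if c not in seen:
                seen.add(c)
                obs.append(
                    BoundaryObservation(
                        pair=pair, df=mid, coefficient=c,
                        cycle_hours=cycle_hours, df_bracket=bracket,
                    )
                )
    return obs


@dataclass
class RecoveryReport:
    """Ground-truth comparison for a synth-then-fit round trip."""

    species: tuple[str, str]
    r_estimates: dict[str, GrowthRateEstimate]  # 1/hour
    r_hat_per_day: dict[str, float]
    r_true_per_day: dict[str, float]
    r_rel_err: dict[str, float]
    labels_by_df: dict[float, str]
    boundaries: list[BoundaryObservation]
    alpha_hat: dict[str, float | None]  # 'ij', 'ji'
    alpha_true: dict[str, float]
    alpha_abs_log_err: dict[str, float | None]
    alpha_grid_bound: dict[str, float | None]
    alpha_total_bound: dict[str, float | None]  # grid bound + propagated r error
    used_true_fractions: bool

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "r_hat_per_day": self.r_hat_per_day,
            "r_true_per_day": self.r_true_per_day,
            "r_rel_err": self.r_rel_err,
            "r_sem_per_hour": {s: e.sem for s, e in self.r_estimates.items()},
            "labels_by_df": {f"{df:g}": lab for df, lab in self.labels_by_df.items()},
            "boundaries": [
                {
                    "df": b.df,
                    "coefficient": b.coefficient,
                    "bracket": list(b.df_bracket) if b.df_bracket else None,
                }
                for b in self.boundaries
            ],
            "alpha_hat": self.alpha_hat,
            "alpha_true": self.alpha_true,
            "alpha_abs_log_err": self.alpha_abs_log_err,
            "alpha_grid_bound": self.alpha_grid_bound,
            "alpha_total_bound": self.alpha_total_bound,
            "used_true_fractions": self.used_true_fractions,
        }


def recover_parameters(bundle, use_true_fractions: bool = False) -> RecoveryReport:
    """Fit growth rates and competition coefficients from a synthetic bundle.

    Growth rates come from the bundle's OD curves (time-to-threshold,
    averaged across replicates).  Competition coefficients come from the
    outcome boundaries on the bundle's constant-DF grid: per DF the run
    endpoints are classified by clustering final fractions (count-based
    estimates, or the true simulated fractions when
    ``use_true_fractions=True``), and each label change is inverted for the
    coefficient that crosses one there.
    """
    params = bundle.params
    if params.n_species != 2:
        raise ValidationError("recover_parameters handles two-species bundles")
    names = params.species_names

    # --- growth rates ---------------------------------------------------
    per_species: dict[str, list[float]] = {s: [] for s in names}
    for curve in bundle.od_curves:
        try:
            per_species[curve.species].append(estimate_growth_rate(curve))
        except NoGrowthError:
            warnings.warn(
                f"OD curve {curve.species}/{curve.replicate} never crossed the "
                "threshold; excluded from the growth-rate average",
                stacklevel=2,
            )
    r_estimates = {s: aggregate_growth_rates(v) for s, v in per_species.items() if v}
    if set(r_estimates) != set(names):
        missing = set(names) - set(r_estimates)
        raise ValidationError(f"no usable OD curves for species {sorted(missing)}")
    r_hat = {s: r_estimates[s].rate * HOURS_PER_DAY for s in names}

    # --- outcome labels along the constant-DF grid ----------------------
    constant = [c for c in bundle.conditions if c.schedule.period == 1]
    if not constant:
        raise ValidationError("bundle contains no constant-DF conditions")
    by_df: dict[float, list] = {}
    for cond in constant:
        by_df.setdefault(cond.schedule.dfs[0], []).append(cond)
    dfs = np.array(sorted(by_df))
    cycle_hours = constant[0].schedule.cycle_hours

    labels: list[OutcomeLabel] = []
    usable = []
    for df in dfs:
        fracs, sigmas = [], []
        for cond in by_df[df]:
            if use_true_fractions:
                total = bundle.trajectories[cond.condition_id].final_abundances.sum()
                if total <= 0:
                    fracs.append(math.nan)
                    continue
                fracs.append(bundle.trajectories[cond.condition_id].final_fractions[0])
                sigmas.append(0.0)
            else:
                counts = bundle.final_day_counts(cond.condition_id)
                obs = CountObservation(counts=tuple(int(c) for c in counts))
                fracs.append(fraction_raw(obs))
                sigmas.append(fraction_sd(obs))
        if np.any(np.isnan(fracs)):
            # the whole community died out (washout-regime DF): no outcome to
            # read, and no boundary information either
            warnings.warn(
                f"DF {df:g}: community extinct in at least one run; "
                "condition excluded from the outcome grid",
                stacklevel=2,
            )
            continue
        sig = float(np.mean(sigmas)) if sigmas else 0.0
        outcome = classify_endpoint_fractions(
            np.asarray(fracs),
            cluster_tol=max(0.02, 4.0 * sig),
            boundary_tol=max(0.02, 3.0 * sig),
        )
        usable.append(df)
        labels.append(outcome.label)

    if len(set(labels)) <= 1:
        raise UninformativeDesignError(labels[0].value if labels else "extinct")

    dfs = np.asarray(usable)
    boundaries = boundaries_from_labels(dfs, labels, (names[0], names[1]), cycle_hours)

    # --- invert boundaries for the coefficients -------------------------
    alpha_hat: dict[str, float | None] = {"ij": None, "ji": None}
    bound: dict[str, float | None] = {"ij": None, "ji": None}
    total_bound: dict[str, float | None] = {"ij": None, "ji": None}
    r_true = {s: float(params.r[k]) for k, s in enumerate(names)}
    for b in boundaries:
        try:
            alpha_hat[b.coefficient] = estimate_alpha_from_boundary(
                b, r_hat[names[0]], r_hat[names[1]]
            )
        except WashoutError:
            warnings.warn(
                f"boundary at DF {b.df:g} lies in the washout regime; skipped",
                stacklevel=2,
            )
            continue
        if b.df_bracket is not None:
            bound[b.coefficient] = alpha_grid_bound(
                b.df_bracket, r_hat[names[0]], r_hat[names[1]], cycle_hours
            )
            # propagate the growth-rate estimation error through the inversion:
            # d ln(alpha)/d r = -delta* / (r (r - delta*)) for each rate
            d_star = df_to_delta(b.df, b.cycle_hours)
            r_term = sum(
                d_star * abs(r_hat[s] - r_true[s]) / (r_true[s] * (r_true[s] - d_star))
                for s in names
                if r_true[s] > d_star
            )
            total_bound[b.coefficient] = bound[b.coefficient] + r_term

    alpha_true = {"ij": float(params.alpha[0, 1]), "ji": float(params.alpha[1, 0])}
    log_err = {
        k: (abs(math.log(alpha_hat[k] / alpha_true[k])) if alpha_hat[k] else None)
        for k in ("ij", "ji")
    }
    return RecoveryReport(
        species=(names[0], names[1]),
        r_estimates=r_estimates,
        r_hat_per_day=r_hat,
        r_true_per_day={s: float(params.r[k]) for k, s in enumerate(names)},
        r_rel_err={
            s: abs(r_hat[s] - params.r[k]) / params.r[k] for k, s in enumerate(names)
        },
        labels_by_df={float(df): lab.value for df, lab in zip(dfs, labels)},
        boundaries=boundaries,
        alpha_hat=alpha_hat,
        alpha_true=alpha_true,
        alpha_abs_log_err=log_err,
        alpha_grid_bound=bound,
        alpha_total_bound=total_bound,
        used_true_fractions=use_true_fractions,
    )
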