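"""Domain types shared across the package.

Conventions
-----------
* Abundances are carrying-capacity-normalized: ``N_i = density / K_i`` so a
  monoculture equilibrates at ``N_i = 1``.  ``K`` (OD units) is carried only
  to convert to/from OD-scale observations.
* The canonical time unit is days.  Growth rates supplied in 1/hour are
  converted on ingest and the original unit recorded.
* Dilution factors are fold dilutions, ``df >= 1``; a transfer written as
  10^-3 (fraction kept) is the same event as ``df = 10^3``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidDilutionError, ValidationError

HOURS_PER_DAY = 24.0

_RATE_TO_PER_DAY = {
    "1/day": 1.0,
    "per_day": 1.0,
    "1/hour": HOURS_PER_DAY,
    "per_hour": HOURS_PER_DAY,
    "1/h": HOURS_PER_DAY,
}


def rate_to_per_day(value: float, unit: str) -> float:
    """Convert a growth/death rate to the canonical 1/day unit."""
    try:
        return float(value) * _RATE_TO_PER_DAY[unit]
    except KeyError:
        raise ValidationError(
            f"unknown rate unit {unit!r}; expected one of {sorted(_RATE_TO_PER_DAY)}"
        ) from None


@dataclass(frozen=True)
class CommunityParams:
    """Per-species growth rates and the pairwise competition matrix.

    Parameters
    ----------
    species_names
        Identifiers, one per species.
    r
        Maximum per-capita growth rates in 1/day.
    alpha
        Square matrix of dimensionless competition coefficients; ``alpha[i, j]``
        is the inhibitory effect of species ``j`` on species ``i`` relative to
        i's self-inhibition.  The diagonal is exactly 1.
    K
        Optional per-species carrying capacities in OD units, used only to
        denormalize abundances for OD-scale synthetic data.
    rate_unit
        Unit the rates were originally supplied in (record-keeping only;
        ``r`` is always stored in 1/day).
    """

    species_names: tuple[str, ...]
    r: np.ndarray
    alpha: np.ndarray
    K: np.ndarray | None = None
    rate_unit: str = "1/day"

    def __post_init__(self):
        names = tuple(str(s) for s in self.species_names)
        r = np.asarray(self.r, dtype=float)
        alpha = np.asarray(self.alpha, dtype=float)
        n = len(names)
        if r.shape != (n,):
            raise ValidationError(f"r must have shape ({n},), got {r.shape}")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValidationError("all growth rates must be finite and strictly positive")
        if alpha.shape != (n, n):
            raise ValidationError(
                f"alpha must be a square {n}x{n} matrix, got shape {alpha.shape}"
            )
        if not np.all(np.isfinite(alpha)) or np.any(alpha < 0):
            raise ValidationError("alpha entries must be finite and non-negative")
        if not np.allclose(np.diag(alpha), 1.0, rtol=0, atol=1e-12):
            raise ValidationError("diagonal of alpha must be exactly 1 (self-inhibition)")
        alpha = alpha.copy()
        np.fill_diagonal(alpha, 1.0)
        K = self.K
        if K is not None:
            K = np.asarray(K, dtype=float)
            if K.shape != (n,):
                raise ValidationError(f"K must have shape ({n},), got {K.shape}")
            if np.any(K <= 0) or not np.all(np.isfinite(K)):
                raise ValidationError("carrying capacities must be finite and positive")
            K.setflags(write=False)
        r.setflags(write=False)
        alpha.setflags(write=False)
        object.__setattr__(self, "species_names", names)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "K", K)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def pair(self, i: int = 0, j: int = 1) -> "CommunityParams":
        """Extract the two-species subcommunity (i, j)."""
        idx = [i, j]
        return CommunityParams(
            species_names=tuple(self.species_names[k] for k in idx),
            r=self.r[idx],
            alpha=self.alpha[np.ix_(idx, idx)],
            K=None if self.K is None else self.K[idx],
            rate_unit=self.rate_unit,
        )


def validate_dilution_factor(df: float) -> float:
    df = float(df)
    if not math.isfinite(df) or df < 1.0:
        raise InvalidDilutionError(
            f"dilution factor must be >= 1 (fold dilution), got {df!r}; "
            "a 'fraction kept' of 10^-k should be supplied as df = 10^k"
        )
    return df


def normalize_dilution_factor(df: float) -> float:
    """Accept either fold-dilution (>= 1) or fraction-kept (< 1) notation.

    Values in (0, 1) are read as the fraction of culture transferred and
    inverted; values >= 1 are taken as-is.
    """
    df = float(df)
    if not math.isfinite(df) or df <= 0:
        raise InvalidDilutionError(f"dilution factor must be positive, got {df!r}")
    return 1.0 / df if df < 1.0 else df


@dataclass(frozen=True)
class DilutionSchedule:
    """Ordered per-cycle dilution factors plus the growth-cycle duration.

    A schedule shorter than a run is repeated cyclically, so
    ``DilutionSchedule([10, 1e5])`` means "alternate 10x and 10^5x daily".
    """

    dfs: tuple[float, ...]
    cycle_hours: float = 24.0

    def __post_init__(self):
        if len(self.dfs) == 0:
            raise ValidationError("schedule must contain at least one dilution factor")
        dfs = tuple(validate_dilution_factor(d) for d in self.dfs)
        if not (math.isfinite(self.cycle_hours) and self.cycle_hours > 0):
            raise ValidationError("cycle_hours must be positive")
        object.__setattr__(self, "dfs", dfs)
        object.__setattr__(self, "cycle_hours", float(self.cycle_hours))

    def df_for_cycle(self, cycle: int) -> float:
        return self.dfs[cycle % len(self.dfs)]

    @property
    def period(self) -> int:
        return len(self.dfs)

    @classmethod
    def constant(cls, df: float, cycle_hours: float = 24.0) -> "DilutionSchedule":
        return cls(dfs=(df,), cycle_hours=cycle_hours)


class OutcomeLabel(str, enum.Enum):
    """Qualitative result of a two-species competition."""

    EXCLUSION_I_WINS = "exclusion_i_wins"
    EXCLUSION_J_WINS = "exclusion_j_wins"
    COEXISTENCE = "coexistence"
    BISTABILITY = "bistability"


@dataclass(frozen=True)
class OutcomeClass:
    """Categorical competition outcome plus its stable/unstable states.

    ``stable_states`` are equilibrium *fractions* of species i (first
    species).  Coexistence has exactly one interior stable fraction;
    bistability has the two boundary states {0, 1} plus one unstable
    interior fraction (the separatrix location in fraction space);
    exclusion has a single boundary state.
    """

    label: OutcomeLabel
    stable_states: tuple[float, ...]
    unstable_states: tuple[float, ...] = ()

    def __post_init__(self):
        for f in self.stable_states + self.unstable_states:
            if not (-1e-9 <= f <= 1 + 1e-9):
                raise ValidationError(f"state fraction {f} outside [0, 1]")


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the two-species flow in original (unscaled) coordinates."""

    abundances: tuple[float, ...]
    stable: bool
    eigenvalues: tuple[complex, ...] = ()


@dataclass(frozen=True)
class ReparametrizedPair:
    """Effective pairwise parameters after absorbing mortality delta."""

    alpha_tilde_ij: float
    alpha_tilde_ji: float
    r_tilde_i: float
    r_tilde_j: float


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical knobs for the growth-dilution simulator.

    extinction_threshold models finite population size: any normalized
    abundance driven below it by a dilution event is set to zero.  Set it
    to 0 to recover the idealized infinite-population model (required for
    exact time-averaging behavior).
    """

    rtol: float = 1e-8
    atol: float = 1e-11
    extinction_threshold: float = 1e-8
    max_cycles: int = 300
    convergence_tol: float = 1e-7
    convergence_window: int = 5
    seed: int | None = None  # used only by the stochastic dilution mode
    method: str = "LSODA"
    stochastic_dilution: bool = False
    cells_per_unit: float = 1e9  # cells at normalized abundance 1 (stochastic mode)

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValidationError("integration tolerances must be positive")
        if not (0 <= self.extinction_threshold < 1):
            raise ValidationError("extinction_threshold must lie in [0, 1)")
        if self.max_cycles < 1:
            raise ValidationError("max_cycles must be >= 1")
        if self.convergence_tol < 0 or self.convergence_window < 1:
            raise ValidationError("invalid convergence criterion")


def as_fractions(abundances: np.ndarray) -> np.ndarray:
    """Row-normalize abundances to fractions; all-zero rows become 0."""
    abundances = np.asarray(abundances, dtype=float)
    total = abundances.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, abundances / np.where(total > 0, total, 1.0), 0.0)
    return frac


def check_fractions(fractions: Sequence[float], n: int) -> np.ndarray:
    f = np.asarray(fractions, dtype=float)
    if f.shape != (n,):
        raise ValidationError(f"expected {n} initial fractions, got shape {f.shape}")
    if np.any(f < 0) or not np.isclose(f.sum(), 1.0, rtol=0, atol=1e-8):
        raise ValidationError("initial fractions must be non-negative and sum to 1")
    return f / f.sum()
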