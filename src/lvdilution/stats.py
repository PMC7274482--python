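"""Colony-count fraction estimates and their beta-distribution error bars.

Relative abundances are measured by counting colonies of each species on a
plate.  With ``a`` colonies of one species and ``b`` of the other, the
posterior over the true fraction under a uniform (Bayes') prior is
Beta(a + 1, b + 1); the error bar used throughout is the standard deviation
of that posterior,

    sigma = sqrt[ (a+1)(b+1) / ((a+b+2)^2 (a+b+3)) ],

which stays finite and honest at 0 or few counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class CountObservation:
    """Colony counts per species from one plating condition.

    ``counts`` is ordered like the community's species list; two entries for
    a pair, three for a trio.  A zero total is allowed (flagged
    uninformative by the estimators via the prior).
    """

    counts: tuple[int, ...]

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts)
        if any(c < 0 for c in counts) or any(c != float(o) for c, o in zip(counts, self.counts)):
            raise ValidationError(f"colony counts must be non-negative integers, got {self.counts}")
        if len(counts) < 2:
            raise ValidationError("a plating must count at least two species")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def marginal(self, species: int = 0) -> tuple[int, int]:
        """(species, rest) counts — the pair that the beta posterior sees."""
        a = self.counts[species]
        return a, self.total - a


def fraction_estimate(obs: CountObservation, species: int = 0) -> float:
    """Posterior-mean fraction (a+1)/(a+b+2) of ``species`` under Beta(a+1, b+1).

    For three or more species the marginal (species vs rest) posterior is
    used.  With no colonies at all this is the prior mean, 1/2.
    """
    a, b = obs.marginal(species)
    return (a + 1) / (a + b + 2)


def fraction_raw(obs: CountObservation, species: int = 0) -> float:
    """Plain count ratio a/(a+b); NaN when the plate is empty."""
    a, b = obs.marginal(species)
    return a / (a + b) if a + b > 0 else math.nan


def fraction_sd(obs: CountObservation, species: int = 0) -> float:
    """SD of the Beta(a+1, b+1) posterior over the species' true fraction.

    Symmetric in (a, b) and strictly decreasing in the total count at fixed
    fraction; equals 1/sqrt(12) with no data (the uniform prior's SD).
    """
    a, b = obs.marginal(species)
    return math.sqrt((a + 1) * (b + 1) / ((a + b + 2) ** 2 * (a + b + 3)))


def annotate_counts(frame, species_cols: list[str]):
    """Add fraction, fraction_posterior and sigma columns to a count table.

    ``frame`` has one row per plating with integer colony counts in
    ``species_cols``; the added columns describe the first species in
    ``species_cols`` versus the rest (one extra trio of columns per species
    for multi-species platings).
    """
    frame = frame.copy()
    counts = frame[species_cols].to_numpy()
    total = counts.sum(axis=1)
    for k, col in enumerate(species_cols):
        a = counts[:, k]
        b = total - a
        with np.errstate(invalid="ignore", divide="ignore"):
            frame[f"fraction_{col}"] = np.where(total > 0, a / np.maximum(total, 1), np.nan)
        frame[f"fraction_posterior_{col}"] = (a + 1) / (total + 2)
        frame[f"sigma_{col}"] = np.sqrt(
            (a + 1) * (b + 1) / ((total + 2) ** 2 * (total + 3))
        )
    return frame
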