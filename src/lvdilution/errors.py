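"""Exception hierarchy.

Every failure mode that callers are expected to branch on gets its own
class; anything else surfaces as ``LVDilutionError``.
"""


class LVDilutionError(Exception):
    """Base class for all package errors."""


class ValidationError(LVDilutionError, ValueError):
    """Invalid parameter values, malformed files, or broken invariants."""


class WashoutError(LVDilutionError):
    """Mortality meets or exceeds a species' growth rate (r - delta <= 0).

    The reparametrization is undefined in this regime: the named species
    cannot sustain itself even without competitors.
    """

    def __init__(self, species, r, delta):
        self.species = species
        self.r = r
        self.delta = delta
        super().__init__(
            f"washout: species {species!r} has net growth r - delta = "
            f"{r - delta:.6g} <= 0 (r={r:.6g}, delta={delta:.6g})"
        )


class DegenerateBoundaryError(LVDilutionError):
    """An effective competition coefficient sits numerically on 1.

    The outcome classification is discontinuous there; the caller must
    perturb the parameters or report the boundary explicitly.
    """


class NoCrossingError(LVDilutionError):
    """alpha_tilde(delta) = 1 has no solution in [0, min r)."""


class NoInteriorEquilibriumError(LVDilutionError):
    """The interior fixed point has a negative component."""


class InvalidDilutionError(ValidationError):
    """Dilution factor below 1 (cultures are never concentrated)."""


class SimulationError(LVDilutionError):
    """ODE integration failed; carries the cycle index for context."""

    def __init__(self, message, cycle=None):
        self.cycle = cycle
        super().__init__(message if cycle is None else f"cycle {cycle}: {message}")


class RegimeInfeasibleError(LVDilutionError):
    """Rejection sampling could not place a pair in the requested regime."""

    def __init__(self, regime, tries):
        self.regime = regime
        self.tries = tries
        super().__init__(
            f"could not sample parameters in regime {regime!r} after {tries} tries"
        )


class NoSeparatrixError(LVDilutionError):
    """The pair is not bistable at the requested dilution factor."""


class NoGrowthError(LVDilutionError):
    """An OD curve never crosses the threshold."""


class InvalidCurveError(ValidationError):
    """An OD curve starts at or above the threshold."""


class UninformativeDesignError(LVDilutionError):
    """No outcome change anywhere on the dilution-factor grid.

    Carries the single observed outcome so the caller can report it.
    """

    def __init__(self, observed_label):
        self.observed_label = observed_label
        super().__init__(
            "no outcome change on the dilution-factor grid; observed "
            f"{observed_label} everywhere, so no boundary constrains alpha"
        )
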