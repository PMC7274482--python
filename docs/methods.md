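# Methods

## Model

The package implements Lotka–Volterra (LV) competition with a community-wide
added mortality,

    dN_i/dt = N_i [ r_i (1 − Σ_j α_ij N_j) − δ ],     α_ii = 1,

where N_i is abundance normalized by species i's carrying capacity (so a
monoculture equilibrates at N_i = 1), r_i is the maximum per-capita growth
rate, α_ij ≥ 0 the per-capita inhibition of i by j relative to i's
self-inhibition, and δ ≥ 0 a global death rate.  The model is
phenomenological: resources are implicit, growth is logistic, and
interactions are linear in abundances.

**Reparametrization.**  For δ < min r, the substitution
Ñ_i = N_i / (1 − δ/r_i) gives a mortality-free LV model with
r̃_i = r_i − δ and α̃_ij = α_ij (1 − δ/r_j)/(1 − δ/r_i).  (The n-species
generalization is per-row and implemented as such.)  The pairwise outcome is
read from (α̃_ij, α̃_ji) relative to 1: both below → one stable interior
point (coexistence); both above → two stable boundary states separated by an
unstable interior point (bistability); exactly one above → exclusion of the
suppressed species.  Points within 1e−9 of 1 raise a degenerate-boundary
error rather than being silently classified, because the classification is
discontinuous there.  When δ ≥ r_i the species cannot sustain itself even
alone; the package reports washout before computing any α̃.

**Serial dilution.**  The experiment alternates 24-h growth phases
(mortality-free LV flow) with instantaneous fold dilutions.  A per-cycle
dilution factor D is equivalent to the continuous rate δ = ln(D)/T, and for
a fluctuating schedule the equivalent constant factor is the geometric mean
of the factors (equivalently, exp of the mean per-cycle δ·T).  Two exact
facts anchor this equivalence in the discrete system: (i) rescaling
invariance of the continuous flow (checked numerically to integrator
tolerance), and (ii) the invasion boundary of the discrete cycle map —
whether a rare species can grow over one full cycle against a resident
monoculture on its periodic orbit — coincides exactly with α̃_ij(δ) = 1, a
short calculation using the resident's per-cycle biomass balance
∫ r_j N_j dt = r_j T − ln D.  Boundary dilution factors estimated from
serial-dilution outcome grids are therefore interpretable through the
continuous-δ formulas without a discretization correction.

## Simulator

Growth phases integrate the LV flow with scipy's LSODA (rtol 1e−8, atol
1e−11 by default); a batch of replicate cultures (different starting
compositions, DF grid points, or Monte-Carlo draws) is stacked into one
flattened ODE system, which keeps bifurcation diagrams and 200-draw property
checks to seconds.  Species at exactly zero stay zero; tiny negative
integrator excursions are clipped.

Dilution divides abundances by D; values driven below an extinction
threshold (default 1e−8 normalized units, modeling finite populations) are
zeroed.  Setting the threshold to zero recovers the idealized
infinite-population model, which is the regime where time-averaging holds
exactly and is used by the property checks.  An optional stochastic mode
draws binomial survivor counts at a configurable cells-per-unit-abundance
scale; it is off by default because the model's predictions are
deterministic.

Runs stop early when end-of-growth fractions change by less than 1e−7
across one full schedule period for 5 consecutive cycles, and only at
period boundaries, so fluctuating-schedule endpoints are phase-consistent;
otherwise they stop at max_cycles with an explicit `converged=False` flag.
Day-0 mixtures follow the experimental convention of pre-diluting by the
daily DF, with factors above 10⁵ capped (the deepest-dilution cultures are
started a decade higher to avoid day-0 extinction).

Endpoint clustering uses a 0.02 fraction tolerance for pairs and 0.05 for
trios (values chosen to separate the observed states comfortably; they are
configuration, not theory).  Separatrices are located by bisection on the
initial fraction to a 1e−4 bracket.  For outcome classification in the
idealized (threshold-zero) model, where exclusion is an asymptotic decay, a
species counts as persisting when its period-boundary fraction stays above
1e−3 after convergence — a converged interior state can legitimately sit at
a small fraction, while a loser's fraction decays far below it.

## Inference

Growth rates use the time-to-threshold method: assuming exponential growth
from the known initial OD (equalized OD over the inoculum fold dilution) to
OD 0.1, r = ln(0.1/OD₀)/t*, with t* the first linearly-interpolated
crossing.  Lag is deliberately uncorrected — it reads as a lower effective
rate.  The estimator carries a deterministic downward bias from incipient
saturation; with carrying capacities around OD 1 and inocula spread over
10⁻⁷–10⁻³ of the equalized OD it is ~0.5–1.5%, which is why the recovery
bound below includes a propagated rate-error term.  Replicates are averaged
with SEM = SD/√n.

Competition coefficients come from boundary dilution factors: at the DF
where the outcome changes, one effective coefficient equals 1, so
α_ij = (1 − δ*/r_i)/(1 − δ*/r_j) with δ* = ln(DF*)/T.  On a discrete DF
grid the boundary is placed at the geometric midpoint of the bracketing
grid points; which coefficient crosses is determined by the label
transition (e.g. slow-wins → bistability assigns the crossing to the
coefficient acting on the slow grower's competitor).  The **documented
recovery bound** per coefficient is the half-bracket width in δ propagated
through d ln α/dδ = 1/(r_j−δ) − 1/(r_i−δ) (maximized over the bracket),
plus the propagated growth-rate estimation error δ*·|Δr|/(r(r−δ*)) per
rate.  Grid conditions where the whole community went extinct (washout
DFs) are excluded from the outcome grid with a warning.

## Synthetic data

The generator emulates the experimental design: 24-h cycles; daily platings
with Poisson-distributed totals (mean 49 colonies) split multinomially on
the true fractions; OD curves sampled every 15 min for ~40 h, logistic with
optional dead-time lag and additive Gaussian noise clipped at zero; day-0
pre-dilution as above.  Everything is reproducible from (design, seed), and
ground truth travels separately from the observation tables.

`sample_params` draws growth rates log-uniform on 0.2–1.5 per hour
(converted to the canonical 1/day) and places a pair's effective
coefficients in a requested region: at δ = 0 by rejection, or across a
mortality window constructively, by choosing the two α̃ = 1 crossing
mortalities inside the window and inverting the boundary formula — the pair
then walks slow-grower exclusion → coexistence/bistability → fast-grower
exclusion as dilution rises.

`example_community` is a three-species replica (one slow, two fast growers,
rates 0.50–0.62/h) whose pairwise boundary DFs were placed at 10^1.5/10^3.5
(bistable pair) and 10^1.5/10^4 (coexisting pair), with the third pair
coexisting throughout; at DF 10³ this yields two alternative three-species
states, each a coexisting pair.

## Validity limits of time-averaging, and the study conditions

Outcome-level time-averaging (the fluctuating schedule reaches the same
qualitative outcome as its geometric-mean constant schedule) holds robustly
across random communities, but not unconditionally.  The randomized check
draws 200 pairs with: |α̃ − 1| > 0.05 at the effective mortality (away from
outcome boundaries), δ_eff < 0.8·min r (away from washout), interior states
away from the absorbing boundaries (equilibrium fraction in 5–95%, 10–90%
for the bistable unstable point), growth-rate disparity r_fast/r_slow ≤ 2.5,
and identical day-0 states for the compared regimes.  The disparity cap
matters because a single cycle's free-growth transient displaces the basin
boundary in starting-fraction space by roughly DF^(Δr/r̄); with large enough
disparity the slow grower's basin retreats below any experimentally
realizable starting fraction, and which outcome is *observed* becomes an
initial-density question that no averaging argument addresses.  For the
same reason, *quantitative* agreement of coexisting fractions between
fluctuating and averaged regimes (within 0.05) is checked on the replica
pair with moderate rates, where within-period oscillations are small; at
disparities of 6+/day the period-mean fraction can differ from the constant
regime's by 0.1 while the outcome type still agrees.

Passing these checks shows the model behaves as the theory says under the
emulated design; it does not show that real communities are LV, that real
plating noise is exactly Poisson-multinomial, or that real growth curves
are logistic with dead-time lag.

## Numerical choices

* Integrator LSODA; rtol 1e−8/atol 1e−11 (1e−10/1e−13 for the rescaling
  identity checks, asserted at 1e−6).
* Brute-force outcome oracle: integrate the continuous-mortality flow from
  nine starting fractions at carrying-capacity-scale density (a dilute
  start probes the washed-out transient, not the basins), in 50-day chunks
  until the state moves < 1e−9, survivors at abundance > 1e−4.
* Boundary tolerance on α̃ classification: 1e−9 (degenerate error).
* Bisection bracket for separatrices: (0.01, 0.99), width 1e−4.
* Problem sizes in the shipped analyses: 200 draws for time-averaging, 100
  for oracle agreement, quarter-decade DF grids from 10^0.5 to 10^5 with
  up to 100 cycles per run, 50 count redraws per plating depth.

## Known limitations

* Regime placement (`sample_params`) is pairwise; three-species sampling is
  unconstrained ('random'), and trio analyses use communities built from
  pairwise boundary placement.
* The boundary-inversion estimator inherits the visibility limit above:
  near a boundary the separatrix hugs an absorbing state, so the last grid
  point inside a bistable window can classify as exclusion; the recovery
  design counters this with extreme starting fractions (0.01/0.99), which
  is also why plating noise can occasionally *shift the detected bracket
  toward the truth* — median noisy error is therefore compared against the
  documented bound, not assumed unbiased.
* No resource-explicit (Monod-type) growth, no temperature or
  coefficient fluctuations, no spatial structure.
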