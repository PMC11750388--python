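# Methods

## Model structure and assumptions

The package couples a deterministic two-host-type SI epidemic with
demographic turnover to Price-equation dynamics of the parasite's
mean within-host growth rate (ε̄H, ε̄L — one mean per host type). Key
structural assumptions:

- **Two extreme host types.** "High-yield" hosts combine high
  transmission set point and shallow virulence slope; "low-yield"
  hosts the converse. Intermediate host types, contact structure and
  recovery to an immune class are outside the model: recovered hosts
  simply leave the system (γ removes infecteds, λ replenishes
  susceptibles).
- **Trade-off shape.** Transmission is β̄j(ε) = ρ(cj + ε^x) with
  0 < x ≤ 1 (linear at x = 1, concave below it); virulence is
  ᾱj(ε) = yj ε. With cj > 0 the transmission rate is positive even at
  ε = 0; this is immaterial in practice because every analysis starts
  from ε > 0 and selection never drives ε to 0 in the interior
  scenarios.
- **Price approximation.** cov(ε, r) ≈ var_j(ε) · dr/dε, mutation
  ignored, and the phenotypic variances varH, varL held constant in
  time. The variances are exogenous inputs, not dynamical variables;
  they set the speed of adaptation, not its direction.
- **Trait flow between types.** The cross-type terms are weighted by
  the infected-density ratios iL/iH and iH/iL. When the denominator
  class is (numerically) absent — below a floor of 1e-10 density
  units — the corresponding term is set to zero: there are no
  infections of that type to import trait values from.

## Parameters

Flat config keys, with the package defaults (the baseline
heterogeneous scenario):

| key | meaning | default | units |
|-----|---------|---------|-------|
| cH, cL | transmission set points | 1.0, 0.1 | dimensionless |
| yH, yL | virulence slopes | 0.1, 1.0 | per trait per time |
| x | transmission concavity | 0.5 | dimensionless, (0, 1] |
| rho | transmission scaling | 1e-2 | per density per time |
| lam | susceptible influx | 50 | density per time |
| p | low-yield share of influx | 0.5 | dimensionless, [0, 1] |
| delta | background mortality | 0.02 | per time |
| gamma | recovery (removal) rate | 0.6 | per time |
| varH, varL | trait variances | 1.0, 1.0 | trait² |

Densities and time are in the arbitrary "model units" implied by λ/δ
(the demographic cap is λ/δ = 2500). The default initial condition
puts susceptibles at the disease-free equilibrium with a seed of 0.1
infected hosts of each type, and both trait means at ε = 0.25;
initial conditions are configurable everywhere.

## Dispersion metrics

vmr(Re) = var(Re)/Re with var(Re) the infection-weighted second
moment of the per-type reproduction numbers about Re. Two conventions
for the per-type value Re_j are implemented: the default **expanded**
form β̄j(sH+sL)/(δ+γ+ᾱj) (each infection measured against the whole
susceptible pool) and a **compact** form β̄j·sj/(δ+γ+ᾱj)
(`form="compact"`). The expanded form is the default because it is
the fully written-out expression; note its var(Re) is a second moment
about Re, which is the central variance of the two-point distribution
only when Re coincides with that distribution's weighted mean (equal
pools and equal infected densities). vmr is reported as 0 with an
explicit `infections_present=False` flag when iH+iL falls below
1e-10, so trajectory annotation never aborts; vmr tends to 0
continuously as one host *type* (susceptibles and infecteds together)
vanishes, which is the limit the composition extremes realize.

## Numerical choices

- **Integration.** `scipy.integrate.solve_ivp` with LSODA,
  rtol = 1e-8, atol = 1e-10 (exposed). Negative undershoot above
  −1e-7 is clipped to zero with a logged warning; anything more
  negative raises.
- **Trait positivity floor.** ε^(x−1) is singular at 0 for x < 1. A
  mean trait crossing 1e-6 raises `TraitFloorError` (detected by a
  terminal solver event) rather than being clamped: in the interior
  scenarios selection never approaches the floor, so reaching it
  signals a misconfigured run — e.g. evolving a host type that has no
  susceptibles to infect.
- **Equilibria.** Root-finding (hybr) warm-started by integrating
  until the RHS norm falls below 1e-9 (chunks of 500 time units, cap
  2e5); accepted only if the residual is < 1e-8 and cross-checked
  against long integration in the tests (< 1e-4 relative). When the
  disease-free Re ≤ 1 the disease-free state is returned with a flag.
- **Composition boundaries.** At p = 0 or p = 1 the full coupled
  system would drag the absent host type's (meaningless) trait mean
  linearly to the floor, so `evo_equilibrium` solves the reduced
  single-type 3-dimensional system there; the absent type's densities
  are 0 and its trait is reported at the initial guess.
- **Default horizons.** Scenarios integrate to t = 2000 with 2001
  output points; the baseline settles (RHS < 1e-9) well before that.
  The variance scan resolves the early dispersion peak on a dense
  grid over the first 30 time units because the initial trait surge
  is an order of magnitude faster than the epidemic's relaxation.

## The multi-strain oracle

The strain-resolved model integrates N strains with fixed traits; the
default grid discretizes a normal distribution (cell-integrated
weights on 41 equally spaced cells over mean ± 3 sd, truncated to
> 1e-3). Truncation makes the grid's *empirical* mean and variance
differ from the nominal ones; comparisons against the Price model
always match moments at t = 0 using the empirical values. Because the
Price model holds variance constant while the oracle's variance
evolves, agreement is only expected — and only asserted — over the
horizon where the oracle's empirical variances stay within 20% of
their initial values (under strong early selection this window is
short, a fraction of a time unit). Within it the mean-trait
trajectories agree to a few percent at x = 0.5 and tighten as the
trade-off approaches linearity (x = 1), where cov(ε, r) = var·dr/dε
is exact; the zero-variance and single-strain reductions agree to
machine precision. The tolerances (5% relative over the stable
window, 1% refinement stability when doubling N) are engineering
choices, not claims inherited from theory.

What the oracle does *not* do: it has no mutation kernel and makes no
attempt to track variance dynamics beyond reporting them, so passing
the comparison shows the Price mean-trait equations are a faithful
summary of the strain-resolved model's *early* selection response —
not that constant variance is realistic over a whole epidemic.

## Design choices where the design was open

- **Quality-gap scan axis.** The Δvmr = vmr(evolved) − vmr(fixed)
  surface takes the varying quality axis as an explicit argument
  rather than hard-coding one. Along the virulence axis (raising yL)
  Δvmr grows with both the gap and the low-yield share p, as
  expected; along the transmission axis (raising cH) the evolved vmr
  grows but the fixed-trait vmr grows faster, so Δvmr *shrinks* — the
  monotone-gap regression therefore uses the virulence axis.
- **Composition axis.** The "% low-yield susceptibles" axis is
  produced by varying p and reporting equilibrium sL/(sH+sL); because
  infection pressure on susceptibles is type-independent, this
  equilibrium fraction equals p exactly.
- **Allowed x range.** Restricted to (0, 1] (all reference scenarios
  use 0.5); convex trade-offs (x > 1) would change the selection
  analysis qualitatively and are out of scope.

## Known limitations

- Strong virulence gaps can destabilize the endemic equilibrium into
  slow eco-evolutionary oscillations (observed at yL ≳ 2 with the
  baseline's other parameters); equilibrium-based scans raise a
  per-cell error there rather than reporting a spurious fixed point.
- The constant-variance Price approximation overstates late-epidemic
  adaptation speed whenever selection has eroded the standing
  variance; only the multi-strain oracle reflects that erosion.
- All dynamics are deterministic ODEs: no demographic stochasticity,
  so "dispersion" here is a between-type variance ratio, not a fitted
  negative-binomial k over realized offspring counts.
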