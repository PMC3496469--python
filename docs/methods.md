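# Methods

## Model

`nnlif` implements the population-density description of a large network of
noisy leaky integrate-and-fire neurons.  The state is the probability
density p(v, t) of membrane potentials v ∈ (−∞, V_F], evolving under the
Fokker–Planck equation with a reset source

    ∂_t p + ∂_v[(b N(t) − v) p] − a(N) ∂_vv p = N(t) δ(v − V_R),
    p(V_F, t) = 0,   p(−∞, t) = 0,   a(N) = a0 + a1 N,

where the mean firing rate N(t) is the probability flux through the
threshold, defined implicitly by N = −a(N) ∂_v p(V_F, t).  All quantities
are in the reduced (dimensionless) voltage/time variables in which the leak
reversal has been translated away; the biophysical parameterization (mV,
ms, capacitance, synaptic counts) is deliberately out of scope.  Throughout
the shipped experiments V_R = 1 and V_F = 2.

Parameters and units:

| parameter | meaning | default |
|---|---|---|
| b  | mean connectivity (voltage units); b>0 excitatory-average | required |
| a0 | baseline diffusion (voltage²/time), a0 > 0 | 1 |
| a1 | firing-rate diffusion gain (voltage²), a1 ≥ 0 | 0 |
| V_R, V_F | reset / threshold voltage, V_R < V_F | 1, 2 |

The solution conserves unit mass: every neuron that fires reappears at the
reset potential.

## Stationary states

Stationary solutions have constant rate N solving N·I(N) = 1 with

    I(N) = ∫₀^∞ e^{−s²/2} (e^{s·w_F} − e^{s·w_R}) / s ds,
    w_F = (V_F − bN)/√a(N),  w_R = (V_R − bN)/√a(N).

`I_of_N` evaluates this by adaptive Gauss–Kronrod quadrature on
[0, max(w_F, 0) + 10] (beyond which the log-integrand is ≥ 40 below its
peak), substituting the removable-singularity limit w_F − w_R for
s < 10⁻¹² and fusing the two exponentials into single exponents so nothing
overflows before the value itself would; past that point (only reachable
when scanning strongly inhibitory networks at large N) the value saturates
to +inf, which the root scanner treats as "no sign change here".
`find_steady_states` scans N·I(N) − 1 on 400 log-spaced points over
(10⁻⁴, N_max] with N_max = max(50, 20(V_F−V_R)/b) for b > 0 (past the
settling of the limit N·I(N) → (V_F−V_R)/b) and 50 otherwise, brackets
sign changes and polishes them with Brent's method to |N·I(N) − 1| < 10⁻⁹.
Near-tangent maxima of the scan within 10⁻⁶ of zero are reported as
flagged possible double roots rather than silently dropped, since the
uniqueness of the maximum of N·I(N) is an open question.

For the constant-noise model the sufficient conditions implemented in
`classify_regime` are, for b > 0:

* existence: 0 < b < V_F − V_R, or 2 a0 b < (V_F−V_R)² V_R;
* refined existence (one more series term of the integrand):
  2 a0 b < V_R (V_F−V_R)(√(2π a0) + V_F − V_R).  The refined condition is
  reported as a flag but never upgrades the classification: its printed
  form in the source material is typographically ambiguous about the
  placement of the square root, and we implement the version that follows
  from re-deriving the expansion (∫ e^{−s²/2} ds = √(π/2) carries the
  √a0 into the first term);
* two states: the noise condition together with b > V_F − V_R;
* nonexistence: b > max(2(V_F−V_R), 2 V_F / I(0)), with I(0) computed by
  quadrature rather than through its closed-form upper bound, which can be
  off by orders of magnitude.

For b < 0 (and a1 = 0) the steady state is unique.  These conditions are
sufficient only: the bistable window b = 1.5 satisfies none of the base
conditions yet has two numerically verified roots, and the report says
"inconclusive" there by design.

The stationary profile (`stationary_density`) is evaluated node-wise by
quadrature of the Gaussian-weighted incomplete integral with the same
exponent fusion; at a root it integrates to one on its own, and the
returned state is normalized exactly so it can seed the solver.  In the
linear case b = 0 the normalizing rate is N_∞ = 1/I(0) (Dawson-form
equilibrium).

### A note on the reference value of the high steady state

For b = 1.5, a ≡ 1 the bistable window's high firing rate is quoted in the
source material as 2.31901.  Four independent evaluations of the stationary
condition (the single-integral form, brute-force nested quadrature of the
double-integral form, quadrature in the original voltage variables, and a
scaled-complementary-error-function reduction, mutually consistent to
10⁻⁹ and confirmed with 30-digit arithmetic) place the root at
**2.2891257**.  The quoted value is evidently the output of the original
finite-resolution computation, 1.3% high.  The package reports the
recomputed root; the experiment that starts "at the high steady state"
(`fig4_bl`, `fig5`) therefore initializes from the root computed at run
time — starting from a profile built with the quoted rate would place the
initial condition 1.3% up the unstable direction and test a different
(blow-up) scenario than the original experiment.

## Time-dependent solver

Both spatial discretizations live on a uniform node-centred grid on
[V_min, V_F] with V_R and V_F exactly on nodes (the grid constructor snaps
the spacing to divide V_F − V_R and extends the domain downward if
needed).  Node centring makes the Dirichlet condition p(V_F) = 0 exact and
all integrals trapezoidal.  The default lower cut-off is eight standard
deviations (8√a0, and 8σ of a Gaussian initial datum) below the reset
potential, placing the truncated tail far below every tolerance in use; a
guard aborts the run (`status='vmin_leak'`) if the density near V_min ever
exceeds 10⁻⁶.

The semi-discretization is written in interface-flux form
Φ_{i+1/2} = (h p)_{i+1/2} − a (∂_v p)_{i+1/2}:

* `upwind1`: first-order upwinding of h p by the sign of the interface
  drift, centred diffusion;
* `weno5`: fifth-order WENO reconstruction of the advective flux with
  stencil-local Lax–Friedrichs splitting (ghost densities are zero on both
  sides: the density is negligible at V_min and identically zero above
  threshold), centred diffusion;
* `chang_cooper`: the Maxwellian flux form with exponential-fitting
  interface weights δ(w) = 1/w − 1/(eʷ − 1), w the cell Péclet number of
  the drift toward the local Maxwellian M = exp(−(v−bN)²/2a).  With the
  interface drift taken at the cell midpoint the discrete flux vanishes
  identically on M, so the scheme is positivity-preserving and second-order
  accurate near equilibria.

Mass bookkeeping is exact by construction: the flux through the lowest
interface is zero (a reflecting wall in a region where the density is
required to be negligible — pinning the boundary value to zero while
letting diffusion drain through it would leak mass at the level of the
boundary density, which is avoidable for free), and the flux through the
interface below V_F is re-deposited, in the same stage, onto the reset
node as the source N dt/dv.  Total mass is then conserved to rounding
(~10⁻¹³ over 10⁶ steps) for every scheme; the only deliberate violation is
the clipping of transient WENO undershoots below zero, which is logged and
accounted (it stays below 10⁻⁸ in all shipped experiments).  The firing
rate reported in traces, and used in the drift/diffusion coefficients, is
the second-order one-sided boundary derivative N = a0 q/(1 − a1 q),
q = (4 p_{J−1} − p_{J−2})/(2 dv); it agrees with the deposited interface
flux to truncation order.  Single-node deposition at V_R is intentional:
the stationary profile has a genuine derivative jump N/a there, which a
smeared source would wash out.

Time stepping is explicit SSP(TVD) Runge–Kutta (order 2 by default, 3
available) with the firing rate re-evaluated from the stage density at
every stage, and the step recomputed every step as
dt = cfl · min(dv/max|h|, dv²/2a) with cfl = 0.5.  That choice makes the
Euler stages convex combinations of node values for the upwind and
Chang–Cooper fluxes, hence positivity-preserving without limiters.

### Termination statuses

* `steady`: the L¹ change per unit time, sampled every 0.05 time units,
  fell below `steady_tol` (default 10⁻⁶).
* `blowup`: the firing rate crossed the blow-up threshold, or dt collapsed
  below 10⁻¹² t_end.  The default threshold is grid-aware rather than a
  fixed number: the stationary threshold boundary layer has width
  a/(bN − V_F), so once bN − V_F > a/dv the layer is thinner than one cell
  and the discrete firing rate is saturating at a grid ceiling
  (≈ 2a·m/dv² for mass m in the last cells) instead of diverging.
  Terminating at N* = (a0/dv + V_F)/b marks exactly the point where the
  computation leaves the resolvable regime; in every certified-blow-up
  experiment N crosses N* decisively (by factors of 2–8 at dv = 0.01),
  while the relaxing experiments stay two orders of magnitude below it.
  A fixed absolute threshold (say 10³) is not attainable at dv = 0.01:
  runs that provably lose global existence saturate below it and would be
  misreported as steady.
* `cc_breakdown`: with a1 > 0 the implicit firing-rate relation
  N = (a0 + a1 N) q loses its non-negative solution once a1 q ≥ 1; this is
  the rate-dependent-noise blow-up scenario and terminates the run.
* `vmin_leak`: see above.

### Scheme selection in the shipped experiments

The presets assign schemes by validity regime, mirroring the original
study's use of two different methods:

* relaxation runs (`fig3`, `fig4_tl`, `fig4_br`) use `chang_cooper` — near
  equilibrium it is second order and essentially exact (stationary-profile
  drift 2·10⁻⁶ per unit time at dv = 0.01, improving 4.0× under halving);
* blow-up runs (`fig4_tr`, `fig6`, `fig7`, `fig8`) use `weno5` — the
  concentration cascade needs low-dissipation shock capturing, and
  Chang–Cooper with constant diffusion is unsuitable at large N (the
  Maxwellian drift nearly vanishes on the domain; the solver warns);
* the bistable-drift runs (`fig4_bl`, `fig5`) use `upwind1`: they start on
  an unstable steady state, and the first-order truncation provides the
  same small symmetry-breaking perturbation that the original
  computation's discretization did.  (Chang–Cooper is accurate enough that
  the run would sit on the discrete fixed point and report `steady` at the
  unstable state.)  First-order upwinding alone is too dissipative to be
  the general default: its numerical diffusion grows with |h| = |bN − v|,
  which caps the firing rate below the blow-up threshold in the cascade
  runs and biases steady rates by O(dv·|h|/a).

Default resolution for the experiments is dv = 0.01 (so J between 900 and
1100 depending on V_min); the entropy-rate grid-stability check compares
dv = 0.02 against 0.01, and the fixed-point refinement compares dv = 0.01
against 0.005.  These problem sizes resolve every feature of the shipped
experiments (the narrowest initial Gaussian has σ ≈ 0.055 ≈ 5.5 cells) and
keep each experiment in the seconds-to-a-minute range.

## Blow-up certificates

For b > 0 the exponential-moment argument gives a checkable sufficient
condition: if for some μ > max(V_F/a_m, 1/b) (a_m = a0, the infimum of
a(N)) the initial moment M_μ(0) = ∫ e^{μv} p₀ dv reaches
λ = (e^{μV_F} − e^{μV_R})/(bμ), no global weak solution exists.
`blowup_certificate` scans 64 log-spaced μ in
[max(V_F/a0, 1/b)·(1+10⁻⁶), 50/(V_F−V_R)]; larger μ is numerically futile
because both sides ride on e^{μV_F} and double precision runs out of
relative resolution.  The moment is computed with non-positive working
exponents (relative to e^{μV_F}).  The certificate is one-sided by design:
`certified=False` never claims global existence — of the shipped blow-up
runs, `fig7` and `fig8` are certified while `fig4_tr` blows up without a
certificate (its mechanism is nonexistence of steady states at high
connectivity, not initial concentration).

## Moment bounds and relative entropy

`moment_bounds_report` re-checks the a-priori estimates along a recorded
trace (first moment ∫(V_F−v)p dv bounded below/above depending on whether
b exceeds V_F − V_R, time-integrated firing rate growing at most linearly,
second moment linear in t) and reports the worst margin of each applicable
bound; it is a post-hoc consistency check, not an assumption of the solver.

For the linear case the solver can record
H(t) = ∫ p_∞ (p/p_∞ − 1)² dv at every step against the closed-form
equilibrium.  The equilibrium is floored at 10⁻³⁰ and nodes below the
floor contribute nothing (they carry < 10⁻²⁰ of the integral; the
threshold node, where the ratio tends to N/N_∞ by l'Hôpital, has zero
weight p_∞(V_F) = 0 either way).  The decay rate is the least-squares
slope of log H on the window H ∈ [10⁻⁸, 10⁻²], i.e. after the initial
transient and before the discrete-equilibrium floor.  The theory
guarantees a rate of at least twice a0 times a weighted Poincaré constant
whose value is not computable from anything printed; accordingly only
positivity, monotonicity (dH ≤ 10⁻¹⁰ per step) and grid stability of the
fitted rate are asserted, never its value.  Measured with the shipped
defaults (Gaussian start v0 = 0, σ² = 0.25, a0 = 1) the fitted rate is
≈ 2.40 and moves by < 0.1% under grid halving.

## What the experiments do and do not show

All inputs are generated internally (Gaussian or stationary profiles);
there is no randomness anywhere, so every run is bit-reproducible.  The
experiments demonstrate the qualitative phase diagram — unique/two/no
steady states, local stability of the low state, instability of the high
state, certified finite-time blow-up, exponential relaxation in the linear
case — in the reduced variables of the model.  They do not validate the
diffusion approximation itself, say anything about finite-size network
fluctuations, or attach biophysical units to the rates; and numerical
"blow-up" is, necessarily, the certified departure of the discrete
solution from the resolvable regime rather than an observed infinity.

## Known limitations

* Explicit time stepping: the diffusion CFL makes runs at dv ≤ 0.005
  minutes-long; an implicit or semi-implicit variant is out of scope.
* No continuation past blow-up; the model itself leaves the nature of the
  singularity open.
* WENO5's Lax–Friedrichs dissipation biases stationary firing rates by
  O(1%) at dv = 0.01; use Chang–Cooper near equilibria.
* `classify_regime` implements sufficient conditions only; the numerical
  root scan is the authority on actual counts, up to its bracketing
  resolution (near-tangent double roots are flagged, not resolved).
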