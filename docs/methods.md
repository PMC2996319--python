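# Methods

## Model

Two immune cell populations interact through the extracellular
concentrations of two cytokines.  Population 1 secretes cytokine A and
is inhibited by cytokine B; population 2 secretes B when activated by
A.  The state is the concentration pair $(A, B)$, nonnegative and, in
all shipped configurations, dimensionless (normalized units of order
0.01–100).  The governing equations are

    dA/dt = prod_A(B) − uptake_A(A) − λ_A·A      [− protease term, optional]
    dB/dt = prod_B(A) − uptake_B(B) − λ_B·B

with

    prod(c…) = basal + q_max · Π_i [a_i/(K_i+a_i)]^h · Π_j [K_j/(K_j+c_j)]^h

A Hill exponent `h` exists on `ProductionParams` for
forward-compatibility but defaults to 1 and is 1 in every shipped
configuration: the model's regimes arise from the uptake nonlinearity,
not from production cooperativity.  An optional `self_activation_A`
flag adds A as an activator of its own production (off by default; the
default reading is pure inhibition of A-production by B).

### Receptor-mediated uptake

Receptors are conserved between a surface pool and an internalized
pool.  With bound fraction `b = c/(Kd+c)`, surface receptors
internalize at `ki_eff = ki_free·(1−b) + ki_bound·b` and recover at
`kr`, giving the steady-state surface fraction

    φ(c) = kr / (kr + ki_eff(c))  ∈ [0, 1].

The uptake flux couples the bound surface receptors to the surface
pool once more (an encounter between a bound receptor and the surface
internalization machinery), with one receptor-count factor folded into
the normalization:

    uptake(c) = u0 · R · b(c) · φ(c)².

This form is non-monotone exactly when `ki_bound > kr + 2·ki_free`
(peak at `b* = (kr+ki_free)/(ki_bound−ki_free)`, declining to
`u0·R·(kr/(kr+ki_bound))²`).  A flux linear in φ is provably monotone
in `c` for every parameter choice, so the squared form is the minimal
one consistent with the concentration-dependent uptake collapse the
model's multistability requires.

### Clearance and normalization

Capillary exchange and protease degradation are folded into one linear
clearance per cytokine; `normalize_parameters` maps a dimensional
tissue description (cell counts, surface areas, capillary
permeability, protease Vmax/Km, blood concentration) onto the
normalized vector by scaling production and uptake with the geometric
factors `S·N/V`, adding `S_cap·P_cap/V` plus the protease term
linearized at `c ≪ Km` to the clearance, and adding the blood
back-flux to the basal rate.  The full saturating protease term stays
available via the optional `protease_A/B` fields.  Linear clearance
must be strictly positive for the dissipative bounding box
`[0, (basal+q_max)/λ]` to exist; uptake saturates and cannot bound
production alone.

## Numerical methods

**Integration.**  `scipy.integrate.solve_ivp` with LSODA, default
rtol 1e-8 / atol 1e-10, output on fixed uniform grids so identical
inputs give bitwise-identical trajectories.  Pulse protocols are square
additive source terms; integration restarts at the pulse edges so the
discontinuity is never smeared (an instantaneous-jump mode is provided
as an option).  "Settled" at an equilibrium means within 1e-4
(normalized units) continuously over the final 10% of the settling
horizon.

**Equilibria.**  Because A-production is strictly monotone in its
single inhibitor, the A-nullcline is single-valued in closed form:
`B(A) = K·(1−x)/x` with `x = ((removal_A(A)−basal)/q_eff)^{1/h}`,
defined where `0 < x ≤ 1`.  All equilibria lie on this curve, so root
finding reduces to sign changes of `dB/dt` along it.  The scan grid is
uniform plus log-spaced (equilibria span decades), densified
geometrically around every domain edge (where the curve dives to
`B = 0`, equilibria cluster near folds), and locally refined (257-point
subgrids) around every sign change, |dB/dt| local minimum and domain
segment end — close saddle/node pairs hidden inside one grid interval
are the main failure mode of naive scanning.  Each bracket is solved by
Brent's method, every candidate polished by a 2-D `scipy.optimize.root`
(hybr) solve, verified to `|rhs| < 1e-9`, deduplicated within a 1e-5
merge radius and sorted by `conc_A`.  Defaults: 400 scan points,
analysis window 3× the dissipative box.

**Stability.**  Jacobian by central finite differences (step
`1e-6·(1+|state|)`, forward-shifted on the axes to stay in the
admissible quadrant) rather than symbolic derivatives, so user-supplied
rate-law variants remain analyzable.  Eigenvalue real parts within
±1e-7 of zero give `center-marginal` (never a forced call); otherwise
stable/unstable node/focus and saddle by the usual sign pattern.

**Limit cycles.**  Peak-train statistics rather than Poincaré
shooting: a cheap probe integration (rtol 1e-7) from a 1e-3 offset off
the unstable equilibrium rides out the transient, with the horizon
extended adaptively (up to 4 rounds, using the emerging inter-peak
interval) for slowly growing or slow relaxation oscillations; a
refined integration (rtol 1e-9) then resolves ~10 estimated periods.
A cycle is accepted when the last 6 peak heights of `conc_A` and the 5
inter-peak intervals each agree to 1% relative, with peak times and
heights interpolated parabolically to sub-sample precision (without
interpolation, sampling-grid quantization alone can exceed the 1%
interval tolerance).  The returned orbit is the final period; an
enclosure test (ray casting) verifies the cycle surrounds its seed
equilibrium.

**Regime labels.**  `monostable-homeostasis`: exactly one stable
equilibrium, no cycle (extra unstable equilibria allowed — the system
is then excitable but still monostable).  `bistable-trigger`: two
stable plus ≥1 unstable, no cycle.  `oscillatory-coexisting` /
`oscillatory-pure`: a detected cycle with / without a stable
equilibrium.  Cycle detection is run only around unstable non-saddle
equilibria (a planar cycle must enclose net index +1, which a lone
saddle cannot supply).  Any marginal eigenvalue yields
`unclassified-near-bifurcation`.

**Sweeps.**  `scipy.stats.qmc.LatinHypercube` in log10 space, one
seed, 14 axes: per cytokine the production scale and affinity, uptake
capacity (`u0·R` combined; receptor count fixed at 1), `Kd`,
`ki_bound`, `kr`, and clearance.  Free-receptor internalization is
fixed at 0.01 and basal secretion at 1e-4 of `q_max` (a small positive
basal keeps the origin from becoming a spurious absorbing state).
Bounds default to three decades centered on 1 for rates and
affinities, and `[0.01, 3.16]` for clearances (slower clearance keeps
removal from being clearance-dominated, which would linearize the
dynamics); these defaults were chosen, once, so that a 5000-sample
sweep reliably contains monostable, trigger and oscillatory samples.
Exemplars are ranked "mid-regime" by the stability margin (minimum
over equilibria of |Re of the leading eigenvalue|).

## Shipped exemplars

Five YAML configs under `cytodyn/exemplars/`, each documenting its
provenance in a header: `healthy`, `trigger` and `oscillatory_pure`
come directly from `search_regimes(n=5000, seed=0)` (the trigger pick
is the largest-margin hit whose stable states are ordered low/low vs
high/high in both cytokines); `healthy_excitable` and
`oscillatory_coexisting` are continuations of search hits along a
channel time scale — multiplying one cytokine's `q_max`, uptake
capacity and clearance by a common factor leaves every equilibrium
fixed while moving the Hopf point, which is how the coexisting regime's
narrow window was reached deliberately rather than by chance.

A structural note on coexistence: with A-production inhibited by B and
B-production activated by A, a stable point coexisting with a limit
cycle necessarily sits at the high-concentration end of the phase
plane.  A stable point on the low-concentration branch of the
A-nullcline always captures the would-be relaxation orbit (the slow
drift along that branch points toward the equilibrium from both
sides), which is also why escape from the oscillation is driven by
cytokine-A pulses: raising the inhibitor B pushes the state away from
the stable basin in every geometry this rate structure admits.
Escape is phase-dependent and thresholded; in the shipped exemplar an
A-pulse of amplitude 0.1 (≈16% of the A production scale) for 5 time
units escapes at all phases, while 0.02 never does.

## Synthetic dose-response generator

`generate_dose_response_fixture` samples a composite steady-state
output curve at log-spaced doses with multiplicative lognormal noise of
a given CV, writing the ground truth alongside.  The composite curve is
built from the package's own primitives: production activated by the
input dose and, for the non-monotone shape, inhibited by the input's
receptor-uptake flux — as dose rises the uptake signal first grows
(suppressing output) and then collapses with the surface receptor pool
(releasing it), giving the plateau–dip–rise shape seen in measured
IL-17-versus-IL-23 style tables; the shipped truth parameters are tuned
so the curve reads ≈120 at dose 0.25 and ≈180 at dose 10 (pg/ml-like
output units against ng/ml-like doses).  The generator emulates the
shape and noise character of such assays, not their biology: no
plate/batch effects, no heteroscedastic floor, no cell-count drift — so
recovery tests certify the fitting machinery, not field performance on
real assay data.  Fitting is box-constrained least squares in log
parameter space with multi-start (8 seeded starts plus the baseline),
ties broken by lower cost then smaller parameter norm; non-convergence
is reported in the result object, never silently.

## Problem sizes and tolerances

The test suite and acceptance script use: 5000-sample sweeps (≈1–2 min
on one CPU), 400×400 log-spaced grids for the brute-force equilibrium
oracle, 100-replicate recovery studies at 12 doses, settling horizons
of 300–600 time units and cycle-detection probes up to a few thousand
time units.  Perturbation cross-validation of stability uses 1e-3
relative offsets and horizons scaled by the leading eigenvalue.

## Limitations

Spatially lumped (no diffusion PDE); two cytokines only; no explicit
cell-population dynamics (proliferation/apoptosis enter only through
rate constants); receptor synthesis/degradation beyond the
conservation law is not modeled; deterministic ODEs only (no Langevin/
Gillespie); no numerical continuation of bifurcation surfaces — regime
boundaries are located by classification along parameter scans, and
the at-most-two-stable-levels statement is a falsification result over
seeded sweeps, not a proof.
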