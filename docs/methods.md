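# Methods

## The model

`feastfamine` studies a minimal cross-feeding community of two *E. coli*
ecotypes under feast–famine cycling: an **overproducer** `X1` that grows on a
primary resource `R1` (glucose-like) and releases a secondary resource `R2`
(secreted byproducts plus necromass), and an **auxotroph** `X2` that depends
on `R2` and may also draw on `R1`.  Between transfers the community follows
Monod-type consumer-resource ODEs:

```
dX1/dt = [mu1 R1/(K1+R1) − d1] X1
dX2/dt = [mu21 R1/(K21+R1) + mu22 R2/(K22+R2) − d2] X2
dR1/dt = −(1/Y1) mu1 R1/(K1+R1) X1 − (1/Y21) mu21 R1/(K21+R1) X2
dR2/dt = p X1 + q d1 X1 − (1/Y22) mu22 R2/(K22+R2) X2
```

The auxotroph's two carbon channels act additively; `R2` is sourced both by
secretion from live overproducers (rate `p`) and by recycling a fraction `q`
of dead overproducer biomass (necromass).  `R1` is never produced, so it is
monotone non-increasing within a batch.  The right-hand side lives in one
isolated function (`model.cr_rhs` / `model._rhs`) so an alternative
functional form (e.g. multiplicative co-limitation of the auxotroph) can be
swapped in without touching the rest of the machinery.

Every `dt_dilution` days an instantaneous transfer keeps a fraction
`D = 0.1` of the culture (1 mL into 9 mL of fresh medium) and replenishes
the primary resource:

```
X1' = D X1;  X2' = D X2;  R1' = D R1 + (1−D) S;  R2' = D R2
```

Byproducts and necromass carry over at fraction `D` — the same carryover
that makes aged-culture transfers qualitatively different from transfers of
young cultures.  The state immediately after each transfer defines a
discrete-time (stroboscopic) map; all long-term statements — exclusion,
coexistence, periodic orbits, chaos — are statements about this map's
attractors, with the dilution interval Δt as the natural bifurcation
parameter.

Units: time in days; biomass and resources in arbitrary consistent units
(the synthetic-data layer converts biomass to CFU/mL at a fixed
`1e8 CFU/mL` per biomass unit).  Rates are nominal day-scale values for a
feast–famine experiment: the feast phase (hours) and famine phase (days)
coexist in one batch, which is why a stiffness-capable integrator is the
default.

## Numerics

Batches are integrated with SciPy's LSODA at `rtol 1e-8`, `atol 1e-10`.
Adaptive solvers undershoot resource depletion by about `rtol × scale`
(observed ≈ 1e-7 on a supply scale of 10), so solution components in
`(neg_clamp, 0)` with `neg_clamp = −1e-6` are clamped to exactly 0 and
anything more negative raises an error — the clamp width is a
`SolverConfig` field, sized to the solver's own error, not a hidden fudge.
Inside the right-hand side, negative inputs are treated as 0 so Monod terms
never amplify transient undershoot.

Two further structural protections matter for the discrete map:

* **Extinction absorption.**  `{X_i = 0}` is an invariant manifold of the
  flow, but implicit solvers leak ~1e-25 of phantom biomass across it, and a
  famine-phase boom can amplify that to order 1e-2 within a few cycles.  The
  integrators therefore zero a species' output whenever its batch initial
  value is exactly 0.
* **Boundary snapping (gLV).**  Fractions within 1e-15 of 0 or 1 snap to
  the boundary, which is absorbing under resampling.

## Chaos diagnostics

The largest Lyapunov exponent is estimated with the Benettin two-trajectory
scheme: co-iterate the map from `x` and from `x + delta0·u`, accumulate
`ln(separation/delta0)` each step, and renormalise the companion to distance
`delta0` along the current separation direction.  Defaults: 200 transient
iterations, 1000 accumulation iterations, `delta0 = 1e-8`.  The
two-trajectory form treats the map as a black box, which is what lets one
estimator serve both the ODE-composed serial-dilution map (4-dimensional
state) and the one-dimensional gLV fraction map.  The `converged` flag
reports whether the running mean drifted less than `conv_tol` over its last
quarter; on maps with closed-form exponents (logistic r=4, tent, linear
contraction) the estimator is accurate to well under 0.01 nats at the
iteration counts the tests use.  A caveat: at the default 1000 iterations
the logistic-map estimate carries ~0.03 statistical error, so oracle tests
use longer runs (2×10⁵ iterations, still sub-second).

Period detection reports the smallest `p ≤ max_period` (default 32) with
`|x[n+p] − x[n]| < tol` (default 1e-6) across the whole post-transient tail;
period 1 is a fixed point, no such `p` means aperiodic at that tolerance.

Bifurcation diagrams iterate from a fixed initial state at every scan value
(independent columns, the form used for the Δt diagram), discarding 200
iterates and keeping 100.  A continuation mode (seed each scan value with
the previous attractor) exists for hysteresis exploration but is off by
default.  `interpolate_params` supports the second diagram style: a linear
path in parameter space from a stable set to a chaotic set at fixed Δt.

## The shipped calibrated parameter set

The package ships one reference parameter set
(`data/default_cr_params.json`) whose serial-dilution map reproduces the
target regime sequence as Δt grows, verified from the shipped file with the
default solver: auxotroph exclusion for Δt ≤ 3 days (famine too short for
the secondary-resource economy to sustain the auxotroph through the
bottleneck), a stable fixed point at intermediate intervals (two-species
coexistence near the transition at Δt ≈ 3.5, auxotroph-dominated at longer
intervals), a 3-period limit cycle at Δt = 9, its doubling to a 6-cycle at
Δt ≈ 9.5, and chaos from Δt ≈ 10 (Benettin λ = +0.079 nats/iteration at
Δt = 10).

Construction: a sequence of guided coordinate-ascent searches — first for
short-interval exclusion together with large-amplitude interior chaos at
long intervals, then for a strong 1:3-resonance (Neimark-Sacker-type)
instability of the intermediate fixed point, which is what produces the
wide, robust 3-period orbit and its doubling route into chaos — finished by
two exact symmetry transformations that cost nothing dynamically: a time
rescaling (all first-order rates × c maps the Δt axis to Δt/c), used to
place the 3-cycle at Δt = 9 with chaos at Δt = 10, and an R1-unit rescaling
(K1, K21, S × c; Y1, Y21 ÷ c), used to normalise the supply concentration
to S = 10.  The destabilising mechanism is delayed negative feedback
through the necromass channel: a high auxotroph fraction suppresses the
overproducer's feast-phase share of R1, which starves the next cycles'
necromass pool, which crashes the auxotroph.

Two properties of this set deserve explicit flags:

* **Bistability and basin structure.**  Near Δt = 9 the 3-cycle coexists
  with an auxotroph-takeover fixed point, and which attractor captures a
  trajectory depends sensitively (at the third decimal of Δt, or on the
  inoculum ratio) on initial conditions — the hallmark of a fractal basin
  boundary.  All shipped regime claims are therefore tied to the standard
  initial state; they are exactly reproducible, but not homogeneous across
  initial conditions.
* **The auxotroph's primary-resource channel.**  With these coefficients
  the auxotroph's R1 growth alone can sustain it at intermediate Δt, where
  it excludes the overproducer — additive co-limitation permits growth
  without the secondary resource.  An obligately cross-feeding auxotroph
  would need multiplicative co-limitation; `cr_rhs` is isolated precisely
  so that variant can be swapped in and recalibrated.

Two companion sets, `cr_stable_params.json` and `cr_chaotic_params.json`,
are frozen endpoints for the parameter-interpolation diagram: the chaotic
endpoint is the default set itself; the stable endpoint is the default with
every rate scaled by 0.2, whose Δt = 10 dynamics equal the default's at
Δt = 2 by the time-rescale symmetry — the stable, convergent
auxotroph-exclusion orbit.  Every convex combination of the two is a valid
parameter set.

Initial states: map and attractor analyses start from equal small inocula,
`(X1, X2, R1, R2) = (0.05, 0.05, 10, 0)` (`STANDARD_STATE0`).  The
co-culture generator's default inoculum is overproducer-majority
(`DEFAULT_COCULTURE_STATE0`, 9:1), emulating the early viable-cell
composition of a freshly assembled co-culture; under it the shipped set
shows the observed early overproducer dominance followed by delayed
auxotroph recovery.  With equal inocula the calibrated auxotroph takes an
early lead through its R1 channel — a known limitation of this parameter
set, consequence of the same R1 competition that generates chaos.

## The gLV resampling map

The generalized Lotka-Volterra variant replaces resource mediation with
direct pairwise interaction: `dx_i/dt = x_i (r_i + Σ_j a_ij x_j)` for one
batch of duration `T`, then resampling to fixed total biomass `B0` at the
batch-end proportions.  For two species this composition reduces exactly to
a one-dimensional map on the species-2 fraction; the reduction is checked
against the full 2-D pipeline to 1e-8 on random draws.  The shipped presets
use a predator-prey-type pair (`r = (1, −1)`, `a12 = −5`, `a11 = a22 = 0`,
`B0 = 1`, `T = 5` days) with the predation coefficient `a21` as the natural
scan parameter: `a21 = 5` (stable fixed point), `10` (2-cycle), `17`
(chaotic, λ ≈ +0.39), with the clean period-doubling cascade
1 → 2 (a21 ≈ 7.5) → 4 (a21 ≈ 14) → chaos (a21 ≈ 16) along the scan.  The
presets are synthetic reference sets found by grid search; window values
(e.g. a 10-cycle at a21 = 17.5) were avoided when freezing the chaotic
preset.

## Calibration

The fitting procedure is nested: each stage fixes what the previous stage
learned.

1. **Monoculture** — `mu1, K1, Y1, d1` against an overproducer growth
   curve, wide absolute bounds (no usable prior exists at this stage).
2. **Auxotroph** — auxotroph parameters against co-culture trajectories
   with `mu21` forced to 0 (no competition for the primary resource);
   overproducer parameters carried over bit-identically.
3. **Global** — competition introduced; seeded differential evolution
   within bounds centred on the prior, then Gauss-Newton polish
   (`scipy.optimize.least_squares`) on the log-residual vector.
4. **Dilution** — a seeded uniform sample (default 200 draws) in a ±50%
   multiplicative box around the fitted parameters, scored by squared error
   of per-cycle auxotroph frequencies under the serial-dilution map at the
   experiment's Δt, with the prior always included as draw 0 and the argmin
   polished locally.

Objectives: log-scale SSE for trajectory stages (CFU data span ~6 decades,
so linear SSE would fit only the peaks) and plain SSE on relative
frequencies for the dilution stage.  Failed simulations inside optimizer
loops return a large finite penalty (1e12) instead of raising.  All stages
are deterministic given (data, config, seed).

**Identifiability is a design constraint, not an afterthought.**  Two exact
degeneracies shape the shipped recovery fixture:

* `p` and `q` enter the R2 source only as `(p + q·d1)·X1` — they are never
  separately identifiable from trajectories.  Configs therefore fit `p` and
  hold `q` fixed (or fix both, below).
* `R2` is never observed, so its unit is a gauge freedom: scaling
  `K22 → cK22`, `Y22 → Y22/c` and the source by `c` leaves every observable
  trajectory unchanged.  A fit that floats source and consumption jointly
  can reach zero loss at wildly wrong values.

The recovery fixture (`synth.recovery_theta`) therefore fixes the gauge by
treating `p = 0` and `q = 0.6` as known constants, and realises the stage-2
assumption exactly (`mu21 = 0` in truth, so `K21, Y21` are structurally
inert and excluded from the free sets).  On noiseless data the pipeline
then recovers every free kinetic parameter essentially exactly (≪ 10%
relative error), which is what the recovery tests assert; `mu21`, freed in
the global stage, returns ≈ 0 and is checked in absolute terms.  The
dilution-stage fixture runs at Δt = 4 (stable coexistence): the study
system is bistable at long Δt, where a transient can hop basins under
1e-5 parameter changes and the frequency objective becomes discontinuous —
real-data calibration at chaotic Δt inherits that roughness, which the
sample-then-polish design (rather than pure gradient descent) is meant to
survive.

## Synthetic data

The generator emulates three instrument channels with known ground truth:
plate-reader OD600 logistic growth curves (additive Gaussian noise,
default σ = 0.005 OD, floored at the blank level 1e-4), co-culture CFU
trajectories (multiplicative lognormal noise, default σ_log = 0.2), and
serial-dilution spot-plate count tables.  Plating is simulated mechanically:
the noisy CFU value is pushed onto a ten-fold dilution ladder and reported
at the lowest dilution giving ≤ 300 colonies per spot; below 3 colonies at
every dilution the spot is flagged *uncountable* — an explicit flag, not a
zero, because the rule it feeds (impute 0.1 at the lowest countable parallel
dilution) is about detection limits, not true absences.  Default plated
volume is 5 µL.  Seeds split into per-artifact streams by a counter scheme
(`SeedSequence(seed, spawn_key=(stream,))`), so generating one artifact
never perturbs another.

What the generator does *not* emulate: OD-to-CFU nonlinearity, plate-reader
drift, well-position effects, demographic (birth-death) noise, and any
evolutionary change across the experiment.  Passing recovery tests
therefore show the *procedure* is correctly implemented and identifiable
under the stated noise, not that real cultures satisfy the model.

## Empirical statistics

`selection_rate` is the per-day difference in natural-log fold change of
two competitors' CFU counts — antisymmetric under swapping competitors and
invariant to rescaling either competitor's counts.  `cfu_per_ml` is the
standard spot-plate conversion `count × dilution × (1000/volume_µL)`.
`fit_logistic_growth` fits `N(t) = K / (1 + ((K−N0)/N0) e^{−rt})` by
bounded least squares with initial guesses `K = max(od)`, `N0 = od[0]`, and
`r` from the early-phase log-linear slope; a series with no positive-growth
solution (e.g. monotone decreasing) raises rather than returning a
boundary fit.  `periodic_growth_rate` is the per-interval percent CFU/mL
change per day.

## Problem sizes

Desk-scale defaults keep every standard run cheap: bifurcation diagrams use
a 27-point Δt grid with 200 transient + 100 kept iterates; Lyapunov
profiles use 300-iteration estimates on a coarser grid, with the full
1000-iteration estimate reserved for the three regime reports (Δt = 2, 9,
10); calibration tests cap optimizer budgets at a few thousand evaluations.
These sizes are the package's reporting defaults; all of them are config
fields.

## Known limitations

* The canonical equations are one defensible reading of the community's
  interaction structure (additive co-limitation, carryover of R2 at
  fraction D); `cr_rhs` is isolated precisely so variants can be compared.
* The calibrated parameter set is a *reference* object reproducing the
  qualitative regime sequence, not a fit to any real dataset; its rate
  constants are nominal day-scale values.
* Chaotic orbits push biomasses through many decades within a cycle, and at
  long Δt the attractor approaches the auxotroph-takeover boundary
  (fractions near 1, overproducer densities of order 1e-6 of its peak);
  below ~1e-300 the dynamics would underflow.  The exact-zero extinction
  rule above keeps true extinctions from being confused with these deep
  excursions.
* The Benettin estimator reports one exponent; degenerate leading
  directions (near-symmetric maps) converge slowly and are flagged by
  `converged=False` rather than resolved.
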