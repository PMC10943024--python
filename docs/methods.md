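# Methods

## Model overview and assumptions

`pondscape` simulates multitrophic metacommunities on explicitly spatial,
time-varying landscapes. Three assumptions shape everything else:

1. **Separation of time scales.** Local biomass dynamics are assumed much
   faster than dispersal and than the yearly activation cycle, so local
   communities are always at the Lotka–Volterra equilibrium of their current
   survivor set. The simulator never integrates the ODEs; equilibria are
   linear solves. (Numerical integration exists only in the test suite, as an
   independent oracle tying the algebraic shortcut to the dynamical model.)
2. **A permanent mainland.** One site is always active and always holds the
   entire regional pool at the regional equilibrium. It is the sole ultimate
   source of colonists and is treated as a boundary condition: it never
   changes, and all diversity/biomass metrics exclude it (including it would
   pin regional persistence at 1 and inflate regional biomass).
3. **Memoryless dispersal.** Dispersal is a continuous-time Markov chain over
   (species, edge) candidates; the first-reaction method with full redraws
   after every event is statistically exact by memorylessness.

## Landscape generator

Parameters: `n_P` sites, `n_E = 2 n_P` edges, `n_C = 5` modules, excess
factor `F ≥ 1`, distance exponent `x ≥ 0` (defaults follow the study design;
coordinates are dimensionless positions on the unit square, times are in
years).

* **Module placement.** Module centers are uniform on the square; sites are
  assigned to modules in balanced counts and placed at
  `center + (raw − center)/F` with `raw` uniform on the square. This choice —
  rather than, say, uniform discs of radius `∝ 1/F` around the centers — makes
  `F = 1` *exactly* uniform placement (no discernible clustering, matching the
  stated semantics of the excess factor) while dispersion still shrinks like
  `1/F`; a disc construction clipped to the square is measurably non-uniform
  at `F = 1`.
* **Edges.** The Euclidean MST guarantees connectivity; the remaining
  `n_E − (n_P − 1)` edges are a weighted sample without replacement of
  non-tree pairs with probability ∝ `d^−x`, implemented with exponential-race
  keys in log space (numerically safe for large `x`). `x = 0` is uniform.
* **Mainland.** A uniformly chosen module, then a uniformly chosen site in it.
* **Activation schedules.** `w_p ~ U(0.2, 0.3)` years; year-`k` interval
  `[max(0, k + z), …+ w_p]`, `z ~ U(−A, A)`; overlapping intervals are merged.
  Intervals are **closed**; activation/deactivation events fire exactly at
  their endpoints. Negative starts are clipped to 0 (affects only year 0 when
  `A > 0`). Paired low/high-asynchrony schedules share the `w_p` draws.

## Food-web generator

A generalized preferential-preying construction. Species `0..n_B−1` are basal
(basal fraction fixed at 20%); each consumer takes a uniformly random first
prey among earlier species, inheriting a provisional level `s_prey + 1`; the
remaining budget (link count `n_L` is hit exactly) is a single global weighted
sample without replacement over all remaining non-cannibal (prey, consumer)
pairs with weight `exp(−(s_c − s_p − 1)² / (2 max(T, 1e-6)²))`. The `1e-6`
temperature floor makes `T = 0` degenerate cleanly to gap-1 links only; if too
few coherent slots exist for the budget the attempt restarts with fresh
randomness (bounded retries, then an error the caller may catch and reseed).
Trophic levels for all statistics are recomputed from the final adjacency by a
dense linear solve (`s = 1` for basal, `s_j = 1 + mean prey level`);
incoherence `q` is the population standard deviation of link-level gaps
(sample-std variant switchable).

Connectance uses `C = n_L / (n_S (n_S − n_B − 1) + n_B)` — realized links over
the maximum for a web with `n_B` basal species and no cannibals.

## Community parameterization

Interaction strengths are lognormal with **mean 1 and standard deviation 0.25
of the variate itself** (underlying normal solved accordingly); a
`moments="log"` switch instead puts `ln X ~ N(0, 0.25²)` for users who read
the moments as those of the log. Self-limitation `λ` is stored positive
(`M_ii = −λ`); the study grid spans diagonal values −1…−1/3, i.e.
`λ ∈ [1/3, 1]`. Predator gain is 0.4 per unit prey loss.

The growth-rate LP (HiGHS, default tolerances ~1e-9) maximizes the smallest
equilibrium abundance `y*`; `y*` within solver tolerance of 0 is accepted
(the constraint is `y* ≥ 0`). Growth rates are reported as `r = −M x*`, so the
equilibrium identity holds to floating point exactly. Stability is the strict
Lyapunov test on `J = diag(x*) M`.

**Extinction cascades.** `local_equilibrium` first prunes consumers with no
present prey (structural, avoids sign tests on ill-posed systems), then solves
the subsystem and removes *all* species below the 0.001 threshold at once —
deterministic, order-independent, and terminating in at most `|present|`
rounds. Singular subsystems are non-generic with `λ > 0`; if a solve fails the
invading species (when known) is declared extinct and the solve retried,
otherwise the offending set fails that round's threshold test.

## Simulator

State: occupancy and biomass matrices plus per-site activity. Events are
deactivations/activations (deterministic, from the schedule) and dispersal
arrivals (stochastic). Tie-breaking at equal times: deactivate < activate <
dispersal, then site index. An arrival recomputes the destination equilibrium;
if the arriving species itself is cascade-removed the destination is left
unchanged (failed invasion) and only the failure is logged.

**Null-event elision.** Given the destination's composition, a failed invasion
is deterministic, so repeating it is a self-loop of the Markov chain that
cannot alter the state trajectory's law. After one observed failure the (site,
species) pair is blocked until the site's composition changes (arrival,
cascade, deactivation, reactivation). This is an exact optimization — removing
null events from a CTMC leaves the embedded state process unchanged — but the
event log consequently records each failed invasion once per composition, not
the raw (unbounded) number of attempts.

Dispersal rates use raw unit-square distances: with `a ∈ [30, 3000]` rates are
large relative to a year, i.e. dispersal is fast on the seasonal time scale;
the 0.1 cutoff `a/d < 0.1 → 0` is applied to the raw ratio. The linkage of
square coordinates to physical distance units is a declared convention of the
package, exposed implicitly through `a`.

## Responses and sensitivities

Per inter-event interval: alpha persistence averages site richness over
*active* non-mainland sites (undefined when none is active), gamma persistence
is the union richness over non-mainland sites (always defined; an empty
landscape scores 0), regional biomass sums non-mainland site biomasses, and
beta biomass is the population-CV of site biomass over active non-mainland
sites (undefined with < 2 active sites or zero mean). Scalars are continuous
power means with exponent `p = 1` (time averages) over the non-missing
measure; `count_empty_as_zero` flips the missing-interval policy, `p` is
exposed (|p| < 1e-9 routes to the geometric-mean limit to avoid `v^p`
cancellation). Beta persistence is the ratio of the time-averaged gamma and
alpha persistences, so `P_gamma = P_alpha · P_beta` holds identically.

Sensitivities use the referential contrast `A_L = 0`, `A_H = 0.5`. Within a
replicate the community, landscape, nominal active lengths, and (across
dispersal abilities) all of the above are shared, so the contrast isolates
asynchrony; only the jitters and event randomness differ. Pairing is a
variance-reduction choice of this package.

**Effect sizes.** The three mains are z-scored (population sd) before products
and squares are formed; OLS (statsmodels) supplies coefficients and standard
errors; all 512 subsets of the nine terms (intercept always included, no
hierarchy constraint) are ranked by
`AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1)`. RSS is floored at `1e-12 n`
so that numerically exact fits are compared by the parameter penalty alone
(the minimal true subset wins among zero-RSS supersets); candidates with
`n − k − 1 ≤ 0` are skipped with a warning. One regression row per replicate
(cell means are a caller-side aggregation if preferred).

## Single-site assembly experiment

`assembly_persistence` measures the stability surface of local assembly: one
permanently active site is colonized from the mainland (two-site star
landscape, `a = 3000`, 6 years) and persistence is the time-averaged site
richness over the pool size. Sequential invasions, establishment failures and
secondary extinctions leave incoherent (high `T`) or weakly self-limited
(low `λ`) webs stuck below full richness; if no feasible & stable
parameterization exists within `max_tries`, assembly fails and persistence
is 0. An `mode="equilibrium"` shortcut instead scores the survivor fraction of
the full pool dropped at equilibrium at once; note that this shortcut is blind
to invasion resistance and saturates at 1 for small, easily stabilized pools,
which is why the simulated assembly is the default.

## What the generators emulate — and what they do not

All inputs are synthetic by design (the system is a theoretical model): the
generators produce the study conditions themselves — modular random
landscapes, yearly stochastic activation, coherence-controlled webs,
lognormal interaction strengths. They do **not** emulate features of real pond
systems such as site-quality heterogeneity, species-specific or asymmetric
dispersal, dormancy/resting stages, within-season landscape change, or
empirically calibrated distances and rates. Passing tests therefore
demonstrate internal correctness of the model and the qualitative mechanisms
(dispersal limitation, rescue effects, invasion resistance), not quantitative
predictions for any real landscape.

## Problem sizes and determinism

Default experiment sizes used by the test suite and `scripts/acceptance.py`:
communities up to `n_S = 30` at `C = 0.2`, landscapes up to `n_P = 100` (25
for full simulations), 6 simulated years, 20 paired replicates per contrast,
50 webs per temperature level, and a 4×4 (T, λ) grid with 20 replicates for
the assembly surface. These desk-scale sizes preserve the qualitative
structure of the full factorial design while keeping single-CPU runtimes in
minutes. Every stochastic component draws from `numpy` `SeedSequence`-spawned
child streams of one root seed; sweeps replay bit-for-bit.

## Known limitations

* Equilibrium-only local dynamics ignore transients; systems with slow local
  relaxation may respond differently to activation/deactivation cycles.
* The event loop re-enumerates candidates after every event (clarity over
  speed); very large `n_P × n_S` problems would want an incremental queue.
* The LP picks one extreme parameterization (max-min abundance); it is a
  modeling convention, not an estimate of natural growth rates.
* The assembly experiment fixes one colonization order distribution (uniform
  arrival races); alternative propagule-pressure models are out of scope.
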