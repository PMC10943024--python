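# pondscape

Multitrophic metacommunity dynamics on stochastic **dynamic landscapes** of
temporary habitat sites — think networks of temporary ponds that flood and dry
every year, connected to one permanent "mainland" lake that holds the whole
regional species pool.

The package is for theoretical ecologists studying how **local stabilizing
factors** (food-web trophic coherence, self-limitation) and **regional
stabilizing factors** (dispersal ability) jointly determine the sensitivity of
metacommunity diversity and biomass to **asynchrony in habitat availability**.

## The model

**Landscape.** Sites live on the unit square, grouped into `n_C` spatial
modules whose tightness grows with the excess factor `F`; the graph is the
Euclidean minimum spanning tree plus extra edges sampled with probability
∝ `d^-x`. Each temporary site `p` activates every year `k` at
`start = k + z`, `z ~ U(-A, +A)`, for a nominal length `w_p ~ U(0.2, 0.3)`
years; `A` is the landscape asynchrony. The mainland is always active.

**Local communities.** The regional pool is a food web generated with a
preferential-preying scheme whose temperature `T` controls trophic coherence
(incoherence `q` = std of trophic-level gaps over links). Local dynamics are
generalized Lotka–Volterra,

```
dx_i/dt = (r_i + Σ_j M_ij x_j) x_i ,
```

with `M_ii = -λ` and, per link, `M_prey,pred = -X`, `M_pred,prey = 0.4 X`,
`X` lognormal (mean 1, sd 0.25). Growth rates solve the linear program
`max y*` s.t. `r + M x* = 0`, `x*_i ≥ y* ≥ 0`, `r ≤ ρ = 1` (basal),
`r ≤ -μ = -0.01` (consumers); infeasible or Lyapunov-unstable webs are
discarded. Local dynamics are assumed fast: sites always sit at the
equilibrium of their survivor set, with species below the 0.001 threshold
removed and secondary extinctions cascaded to a fixed point.

**Dispersal.** A continuous-time Markov chain simulated by the first-reaction
method: species `s` moves along edge (p, q) at rate `a / d(p, q)` (zero below
0.1) when both sites are active, `s` is present in `p`, absent from `q`, and
is basal or has prey present in `q`.

**Responses.** Time-averaged (continuous power mean) persistence
`P_alpha`, `P_gamma`, `P_beta = P_gamma / P_alpha` and biomass `B_gamma`,
`B_beta` (CV across sites), and their asynchrony sensitivities
`S[x] = (x_H − x_L)/(A_H − A_L)` for the referential contrast
`A_L = 0`, `A_H = 0.5`. Standardized effect sizes of `T`, `λ` and
`â = log10(a)` (plus quadratic terms) on `S[x]` come from OLS on z-scored
predictors with all-subsets AICc model comparison.

## Worked example

```python
import pondscape as ps

web, dyn = ps.generate_stable_regional_community(
    n_S=30, n_B=6, n_L=139, T=0.2, lam=0.47, seed=7
)
L = ps.generate_landscape(n_P=25, n_E=50, n_C=5, F=50, x=2, seed=1)
lo, hi = ps.paired_schedules(L, 0.0, 0.5, years=6, seed=3)
for name, sched, seed in [("A = 0.0", lo, 5), ("A = 0.5", hi, 6)]:
    traj = ps.simulate_run(L, sched, web, dyn, a=3000.0, horizon=6.0, seed=seed)
    r = ps.summarize_run(traj)
    print(f"{name}: P_alpha = {r.P_alpha:.3f}, P_gamma = {r.P_gamma:.3f}, "
          f"P_beta = {r.P_beta:.3f}, B_gamma = {r.B_gamma:.2f}, B_beta = {r.B_beta:.3f}")
```

prints

```
A = 0.0: P_alpha = 0.999, P_gamma = 0.291, P_beta = 0.291, B_gamma = 31.30, B_beta = 0.001
A = 0.5: P_alpha = 0.276, P_gamma = 0.672, P_beta = 2.434, B_gamma = 8.36, B_beta = 1.460
```

Reading: with synchronous sites (`A = 0`) dispersal is fast enough that every
active site carries essentially the whole pool (`P_alpha ≈ 1`), but all sites
are dry ~75% of the year, so the time-averaged regional persistence is ~0.29
and local communities are spatially homogeneous (`B_beta ≈ 0`). Raising
asynchrony to 0.5 desynchronizes the active windows: local persistence and
regional biomass collapse, while regional persistence and among-site
heterogeneity rise — active sites now exist through most of the year but each
holds a different fragment of the pool.

A `pondscape` console command exposes the same pipeline
(`generate-landscape`, `generate-web`, `build-community`, `simulate`,
`sweep`, `effects`); see `pondscape --help`.

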