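# Methods

## Model

`coopamr` simulates a well-mixed microbial co-culture of an
antimicrobial-resistant strain R and a drug-sensitive strain S under a
constant biostatic drug. R cells constitutively produce a drug-inactivating
enzyme at metabolic cost `s`, so their fitness is `f_R = 1 - s`. The enzyme
is a thresholded public good: once the resistant abundance reaches the
cooperation threshold `Nth` cells, the drug is inactivated for the whole
community and `f_S = 1`; below the threshold only R is protected and
`f_S = 1 - a` with `s < a < 1`. The step is sharp, with the convention that
cooperation is already active at `NR = Nth` exactly (`theta[0] = 0`); no
smoothing is applied.

Birth rates are fitnesses normalised by the population mean fitness
`fbar = (f_R NR + f_S NS)/N` and deaths are logistic:

    T+_alpha = (f_alpha/fbar) N_alpha,    T-_alpha = (N/K) N_alpha.

Two exact identities follow and are asserted in the tests: the total birth
rate is `N` and the total death rate `N^2/K`, for every state. Time is
measured in units of the baseline division time; abundances are integers in
the stochastic model and continuous in the deterministic one.

The environment is a binary carrying capacity `K(t) in {K-, K+}` driven by
dichotomous Markov (telegraph) noise `xi(t)` flipping at rate
`(1 - delta*xi) nu`. `nu` is the mean switching rate (half the inverse
correlation time) and `delta in (-1, 1)` the bias towards the mild state.
Ensembles start the environment from its stationary law
`P(xi = +/-1) = (1 +/- delta)/2`, overridable per run. The degenerate case
`K+ = K-` is allowed and gives a static environment; it is how all
constant-capacity experiments are run.

## Stochastic simulation

The composite process — four demographic channels plus the environment flip
— has rates constant between events, so a standard Gillespie loop samples
the joint master equation exactly; the environmental flip is simply a fifth
reaction channel. The loop is JIT-compiled with numba (pure-Python
fallback, same code and random stream). One seeded Mersenne-Twister stream
per replicate makes trajectories bit-reproducible; per-replicate seeds are
spawned from the ensemble base seed via `numpy.random.SeedSequence`.

Only the composition is absorbing: after fixation the population size keeps
fluctuating with `K(t)`. By default a replicate stops at compositional
absorption; runs that sample population-size statistics continue to the
horizon. Total extinction (`N = 0`) is its own outcome label and is never
folded into fixation counts. An event-count guard (default 2e8) raises an
explicit error rather than truncating silently.

Outcome classification at a finite horizon `T`: coexistence iff both
strains are present at `T`; the default horizon is `2<K>` with
`<K> = ((1+delta)K+ + (1-delta)K-)/2`. The stationary mean population
satisfies `<N> <= <K>`, so this is a computable, slightly conservative
stand-in for a `2<N>` rule; it is exposed as configuration. The default
ensemble start is the coexistence equilibrium: `xi0` stationary,
`N0 = K(xi0)`, `NR0 = min(Nth, N0 - 1)`.

Trajectory storage keeps the full event log by default; a record-interval
option thins it to all switching events plus a uniform time grid plus the
absorption event.

## Static-environment theory (effective Moran chain)

At constant `K0` the size relaxes on a O(1) time scale while the
composition evolves on the slower `1/s` (or `1/(a-s)`) scale, so the R
count is modelled as a birth-death chain on {0..K0} with effective rates
`T~R+- = T_R+- T_S-+ / N`. The hop ratio `gamma(n) = f_S(n)/f_R` is
piecewise constant — `(1-a)/(1-s)` below the threshold, `1/(1-s)` at and
above it — which the tests verify algebraically from the rate definitions.

Fixation probabilities use the standard absorption formula with cumulative
products of `gamma` accumulated in log space (stable to `K0 ~ 1e5`). The
mean coexistence time (unconditional mean absorption time) is obtained by
exact forward telescoping of the first-step equations in O(K0); it is
evaluated in the linear domain and raises an informative overflow error
once the cumulative products exceed double precision (around `K0` of a few
thousand at the default selection strengths — beyond every regime the
package targets). Both quantities are validated against an independent
first-step-analysis solve; notably, a float64 tridiagonal solve of that
system is ill-conditioned at strong selection (relative error ~1% at
`K0 = 200`, `s = 0.2`, `a = 0.5`), so the test oracle uses exact rational
arithmetic.

The closed-form approximation for a start at the coexistence equilibrium,

    phi ~= 1/(1 + (1-s)^-(K0 - K0*)),
    K0* = Nth ln(1-a)/ln(1-s) - ln(s(1-a)/(a-s))/ln(1-s),

gives the equiprobability size `K0*` (about `3 Nth` for `s=0.1, a=0.25`)
and is exact at `K0 = K0*` by construction.

## Deterministic and piecewise-deterministic dynamics

The infinite-population limit couples logistic growth of `N` towards
`K(t)` with selection on the composition. The threshold makes the vector
field discontinuous at `NR = Nth`, and near carrying capacity both branches
point towards the surface: the coexistence equilibrium is a *sliding*
equilibrium in the Filippov sense. The integrator therefore runs a small
hybrid automaton: free flow in the active branch with a terminal event at
the threshold crossing, and an explicit sliding mode (NR pinned at `Nth`,
`N` logistic) with events on the one-sided fields to detect when sliding
breaks — as it does after a `K+ -> K-` bottleneck, launching the transient
dip. Naive branch-switching would chatter at the surface; the sliding mode
avoids that. Segments use `scipy.integrate.solve_ivp` (RK45, default
`rtol = 1e-8`); paths are sampled on a uniform grid (default step 0.01)
plus event times. PDMP trajectories concatenate such segments between
environmental switches, either from a supplied switch-time path (fully
deterministic) or from a seeded telegraph sample.

Dip analytics are closed forms derived under `K+ >> K- >> 1` with
`NR(0) = Nth`:

    t_dip  = ln[(1-s)/(a-s) (1 - K-/K+)]
    NR_dip = Nth (K-/K+) ((1-s)/(1-a)) ((1-s)/(a-s))^((a-s)/(1-a))

with `NR_dip >= Nth K-/K+` and total population `K-(1-s)/(1-a)` at the
bottom. These are approximations: against the numeric PDMP at the reference
parameters (`s=0.1, a=0.25, K-=120, K+=1000`) they agree to ~6% (depth) and
~7% (timing); the tests allow 15% and 10% respectively, our choice in the
absence of a stated accuracy. For shallow contrasts (`K+/K-` below ~5) the
closed form can exceed `Nth` and the "dip" loses meaning; the invalid
regime (including a non-positive log argument) raises an explicit error.

Eradication feasibility operationalises "`NR_dip` of order one" as
`NR_dip <= 10` (configurable), and the optimal-region criterion bounds the
per-state switching rates:

    s/(2 ln(K+/K-)) <= nu(1-delta) <= s
    (a-s)/(2 ln(K+/K-)) <= nu(1+delta) <= 1/t_dip.

The large-population transferability check reports `Nth K-/K+` and whether
it is at most 10.

## Phase analysis

Grid scans run one ensemble per `(nu, delta)` point (defaults: log-spaced
`nu` in [1e-4, 1e2], linear `delta` in [-0.9, 0.9], 500 replicates — a desk
scale chosen so a full scan stays in CPU-minutes; estimates carry Wilson
95% intervals so the Monte-Carlo resolution is explicit). Abundance
distributions sample each replicate's state at the quasi-stationary time
`2<K>` (running through fixation), histogram it per cell count, and smooth
with a Gaussian of width sigma = 10 cells truncated at 4 sigma and
edge-renormalised so mass is preserved; modality counts peaks above a
configurable prominence (default 10% of the maximum), with an edge maximum
at zero counted as a mode (an absorbed strain piles mass at 0). Mean
abundances average final states over replicates, including post-fixation
runs. Coexistence composition averages `x = NR/N` only over replicates
still coexisting at the horizon; points with none are flagged, never
interpolated.

## What the simulator does and does not emulate

All inputs are model parameters; there is no external data. The generator
reproduces the model's own assumptions — sharp threshold, biostatic drug,
binary stationary environment, constant drug influx, well-mixed culture.
Passing tests therefore validate the mathematics and the sampling, not the
biological realism of those assumptions: quorum-regulated enzyme
production, concentration-based (fixed-fraction) thresholds, biocidal drug
action, periodic switching and spatial structure are all outside scope.
Reported probabilities are finite-horizon, finite-replicate estimates; at
500 replicates a probability near 0.5 carries a ~±0.045 (95%) interval.

## Numerical choices

- Gillespie waiting times via inverse-transform on `1 - U` to avoid log(0).
- Wilson intervals (`scipy.stats.binomtest`) for all binomial estimates.
- Log-space cumulative products (`logsumexp`) for fixation probabilities.
- Event tolerance for the sliding surface: `1e-9 * max(1, Nth)`.
- Ensemble seeds: `SeedSequence(seed_base)` children; all seeds logged.
- Degenerate inputs: empty populations return all-zero rates and classify
  as extinct; `K+ = K-` collapses both effective capacities to `K0`.

## Known limitations

- The MCT evaluation overflows (with an explicit error) for `K0` beyond a
  few thousand at default selection; fixation probabilities do not.
- The SSA-vs-Moran agreement is asymptotic in `K0`: at `K0 <= ~60` the
  finite-size deviation of the fixed-N reduction is comparable to a few
  binomial standard errors at desk replicate counts.
- Full phase diagrams at publication replicate counts (1e3-1e4 per point
  over dense grids) are CPU-hours; defaults are sized for CPU-minutes.
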