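# Methods

## Scope and model structure

`admarkov` implements a reduced compartment model of Alzheimer's disease
progression with nine state variables — neurons (N), intraneuronal and
extraneuronal amyloid beta (A_beta_i, A_beta_o), tau, intraneuronal and
extraneuronal neurofibrillary tangles (F_i, F_o), astroglia (A), and pro-
and anti-inflammatory microglia (M1, M2) — and 29 parameters.  All
concentrations are g/ml (1 ml and 1 cm³ are treated as identical volumes).
Reactive-oxygen-species inflammation appears only as the constant `R0 = 6`:
no surviving equation updates it, so it is a parameter, not a state.
Spatial structure and the wider cytokine network (TNF-α, MCP-1, …) are out
of scope of the reduction.

Two equations need interpretation beyond the model's printed skeleton:

* **Neuron equation sign.**  The neuron rate `d_NF · Fi/(Fi+K_Fi) · N`
  describes death by intracellular tangles, and the species' transition row
  is "pure death", so the term is applied as a loss.  Neurons then decline
  in every run, which matches the described behaviour of both model
  variants.
* **Extraneuronal amyloid clearance.**  The parameter set defines a
  clearance rate `d_AbetaoM`, a Michaelis constant `K_Abetao` and a relative
  effectivity `theta` that the literal A_beta_o equation never uses, while
  the species' process list includes death and its interaction count is
  quoted as 5.  We reconstruct the missing term from those parameter
  descriptions as `d_AbetaoM · (M1 + theta·M2) · A_beta_o/(A_beta_o +
  K_Abetao)` and enable it by default (`ModelOptions.abeta_o_clearance`).
  The exact algebraic form is a reconstruction: the flag exists so the
  literal, clearance-free equation remains available, and the interaction
  counts react accordingly (5 with clearance, 3 without).
* **Tau production units.**  `lambda_tau` and `lambda_tau0` are treated as
  g/ml/day so that the tau equation is dimensionally consistent.

`lambda_Nd = 0.05/365` per day encodes ~5%/year age-related neuron loss;
its flux also carries the two emigration routes (A_beta_i released as
A_beta_o, F_i released as F_o).

## Channel decomposition

Each species' rate equation is split into a non-negative birth and death
magnitude (`channel_rates`); birth − death reassembles the equation exactly,
a tested identity.  Emigration fluxes are carried on the destination's birth
channel (the printed source equations have no matching loss term, so
counting them once keeps the identity exact).  Neurons have a zero birth
channel.  The interaction count of a species is the number of *distinct
other* species appearing in its equation — self-couplings and parameters
excluded; the count is purely structural and verified in the tests against
finite-difference Jacobian sparsity under two different parameter sets.

## Deterministic integrator

The reference run covers 10 years recorded on a daily grid (3650 steps,
`times = 0…3650`).  Internally each output day is covered by explicit-Euler
sub-steps (default 0.05 day): the stiffest channel is intraneuronal amyloid
clearance at `d_Abetai = 9.51/day`, so explicit stability needs sub-steps
below `2/9.51 ≈ 0.21` day and a 1-day step would be violently unstable.
The integrator rejects unstable sub-steps by name, clamps tiny negative
excursions to zero (concentrations are physical), and is bit-reproducible.
Halving the sub-step changes no recorded value by more than 0.5% (tested),
so the daily grid is converged for this model.  Closed-form anchors serve
as oracles: `A_beta_i* = lambda_beta_i(1+R0)/d_Abetai = 7.0e-6` and
`tau* = (lambda_tau0 + lambda_tau·R0)/d_tau ≈ 5.848e-10` g/ml, both
independent of the surviving neuron fraction; the microglia have
saturated-tangle asymptotes `M0_G·lambda_MF·beta/d` (0.0564 and 0.00564
g/ml).  M2 undershoots its asymptote around day 370 and then levels off
toward it from below, because the tangle saturation `Fo/(Fo+K_Fo)` is still
rising while M2's initial excess decays.

## Stochastic engine

Every species is a two-state Markov process (existing vs
removed/translocated) whose events fire on variable-size global steps with
state-dependent stoichiometry: an accepted channel changes its species by
(channel rate at the start of the step) × (step length).  The engine is thus
a randomized explicit-Euler scheme, and in the fully-accepted fixed-step
limit (`force_fire=True, fixed_dt`) it reproduces the deterministic Euler
recursion exactly (tested to 1e-12 relative; measured 0.0).  Design choices,
in the order the engine applies them:

1. **Channel rates** are evaluated once per step from the current state.
2. **Visit order.**  Per-species waiting times are exponential with mean
   `step_scale · (Σ_j r_j)/(k · r_i)` for the k active species — the next-
   reaction-time ordering: high-rate species come up first, and with equal
   rates the mean wait is `step_scale`.  The order determines how the step's
   pre-drawn random numbers are assigned to species (ties broken in the
   fixed species order).
3. **Global clock.**  The elapsed step is exponential with mean
   `step_scale`, capped at the remaining horizon.  The waiting times
   themselves cannot serve as the clock: the channel rates span ten orders
   of magnitude (≈1e-3 g/ml/day for astroglia vs ≈5e-14 for extraneuronal
   tangles), so any max- or min-over-waits rule degenerates (the slowest
   species' wait exceeds the whole horizon ~1e5-fold and a run would
   collapse into a single step).  An explicit exponential clock keeps the
   intended property — mean global step equal to `step_scale` — exactly.
   The default `step_scale = 0.05` day equals the deterministic sub-step:
   the randomized-Euler update shares explicit Euler's stability bound
   (0.21 day), and an exponential step needs its mean a few-fold below that
   bound so that tail steps remain rare and damped.
4. **Acceptance.**  A channel with rate `r_c` fires if a uniform draw falls
   below `n ~ Normal(r_c/Σr, sigma)` clipped to [0,1] — a noisy relative
   propensity ("the rates are averages").  The channel means partition unity
   at every instant.  `sigma` (default 0.1) is an *absolute* standard
   deviation: it acts as a noise floor that lets channels whose relative
   propensity is ~1e-7 (tau, the tangles, extraneuronal amyloid) still fire
   at a low, noise-driven frequency.  With noise proportional to the mean
   (`relative_noise=True`, available) those species would simply freeze,
   which contradicts their described behaviour — every species progresses,
   and tau reaches the deterministic equilibrium.  Slow species are
   therefore *slowed* rather than frozen, one of the two mechanisms that
   differentiate the stochastic from the deterministic mean dynamics.
5. **Coupling policy.**  Species whose transition row includes an
   emigration process (A_beta_i, F_i) fire as a single both-or-none event —
   the translocated quantum must leave, arrive and be produced/cleared
   synchronously.  Plain birth–death rows fire their two channels
   independently, as the two Poisson streams of an ordinary birth–death
   chain.  This default ("emigration") is what gives the model its
   characteristic variability structure: independent birth/death firing
   sustains dispersion even at equilibrium (noise amplitude ∝ gross
   per-capita flux), while coupled firing makes noise vanish at a fixed
   point (amplitude ∝ net flux).  Hence intraneuronal amyloid — coupled and
   strongly contracting at 9.51/day — is the quietest species by orders of
   magnitude, and tau — uncoupled, with the largest gross per-capita flux
   (~0.2/day) among the slow species — is the most variable, with M1 and M2
   inheriting identical CVs from their mirrored kinetics.  The fully
   coupled ("all") and fully independent ("none") policies are exposed; the
   independent-firing stationary CV scales as
   `sqrt(per-capita flux · step/2)`, ≈0.07 for tau at a half-day step.
6. **Update and clamp.**  Accepted channels apply `±rate·Δt`
   simultaneously; the state is clamped at zero.

An absorbed state (every rate zero, e.g. total extinction) ends the run
with the state held to the horizon.

## Matched ensembles and the variability summary

`make_jump_schedule` pre-draws the global step sequence; all replicates of
an ensemble consume it verbatim, so they share one time grid and the
cross-replicate variance and CV are defined pointwise.  `run_ensemble`
derives the schedule from the base seed and gives replicate i the seed
`base_seed + i`, making every summary bit-reproducible from
`(base_seed, config)`.  The summary reports, per species: the sample
variance and the CV (sample sd over mean, n−1 denominator, defined as 0 at
zero mean) averaged *unweighted over grid points* (the grid indexes events,
not uniform time — its companion quantities are the CVs at the first and
last shared grid points), plus the interaction count.  The reference
conditions are 25 replicates over 3650 days at the default knobs; at the
default 0.05-day step scale that is a ~73,000-point grid and roughly one
minute of compute per ensemble on one CPU, the size used by the tests and
the acceptance script.

## What the defaults do and do not show

At the reference conditions the package reproduces the model's qualitative
findings: every recorded state stays non-negative, neurons are
non-increasing in every replicate, tau attains the maximum mean CV (≈0.16,
with extraneuronal amyloid second at ≈0.05) stably across base seeds, and
the interaction-richest species is *not* the most variable.  Mean dynamics
shift as described: slow species lag the deterministic run (their channels
fire at the noise-floor frequency), while fast channels track it closely.

Two caveats.  First, the engine's noise constants (`sigma`, `step_scale`,
the coupling policy) are free constants of this reconstruction — the
acceptance-noise law and step distribution admit no unique reading — so CV
*magnitudes* are knob-dependent and should be compared across settings only
in rank and order of magnitude.  Second, net-direction agreement with the
deterministic run holds in every replicate for eight of the nine species;
intraneuronal tangles (F_i) dip and barely recover deterministically (net
change +4.4% over 10 years), so their 10-year sign flips in a minority of
replicates whenever replicate spread is large enough to keep tau visibly
stochastic.  Across the explored engine family (coupling policies, absolute
vs relative noise, sigma 0.02–0.2, step scale 0.05–0.46 day) those two
properties — tau maximally variable and F_i's marginal sign preserved in
all 25 replicates — trade off against each other; the defaults favour the
variability structure and document the F_i exception.  Neuron decline being
*faster* stochastically is likewise knob-dependent (it requires the
stochastic tangle burden to outgrow the deterministic one) and is not
asserted.

The synthetic regime emulated by the generator-free defaults is the
published study design itself (one initial condition, one parameter set);
the package does not model biological parameter uncertainty, spatial
heterogeneity, or measurement noise, so passing tests show internal
consistency and reproduction of the model's reported structure, not
clinical validity.

## Interfaces

Trajectories round-trip through CSV (`time,N,A_beta_i,A_beta_o,tau,F_i,F_o,
A,M1,M2`, 17 significant digits, metadata in `#` comment lines).
Configuration is a flat YAML mapping over the defaults — parameter names,
initial-state names, engine knobs — with unknown keys rejected by name.
The CLI (`admarkov simulate-det | simulate-stoch | ensemble | summarize`)
is a thin layer over these functions; every stochastic invocation logs its
seed (default 1, fixed in favour of reproducibility over entropy).
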