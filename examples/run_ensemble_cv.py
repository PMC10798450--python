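"""Matched-replicate ensemble and the variability table.

Runs 25 stochastic replicates forced onto one shared sequence of time jumps,
then reports each species' cross-replicate variance and coefficient of
variation (CV = sd/mean) averaged over the shared grid, plus the CV at the
first and last grid points and the number of other species in its equation.
"""

from admarkov import run_ensemble, summarize

ens = run_ensemble(n_runs=25, base_seed=1)  # ~1 minute
summary = summarize(ens)

print(f"{ens.n_runs} replicates on a shared grid of {len(ens.times)} points "
      f"(mean step {ens.times[-1] / (len(ens.times) - 1):.3f} day)\n")
print(summary)
print(
    f"\nmost variable species: {summary.most_variable()} — tau's production "
    "and degradation fire as independent events, so its dispersion persists "
    "even at equilibrium, although its equation touches only one other "
    "species.  The interaction-rich extraneuronal amyloid is less variable: "
    "interaction count does not set variability."
)
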