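"""How variable is the estimand fit across simulated studies?

Runs the logged-DGM scenario grid (2000 iterations per cell, log base 10,
true slope 1, exposure median 8, residual SD 1) and reports the 5th/95th
percentiles of the per-iteration slope of outcome on untransformed exposure,
as percent deviation from their mean.
"""

from reexpress import variability_grid

grid = variability_grid(n_obs_values=(162, 8474), sigmas=(0.25, 0.45, 0.65, 0.85),
                        space="logged", noise_sd=1.0, n_sims=2000, seed=1)
print(grid.round(4).to_string(index=False))
print()
print("Reading: the estimand fit is a random variable.  At n=162 its 5th/95th")
print("percentiles sit tens of percent away from its own mean, and even at")
print("n=8474 several percent.  A quantity this variable cannot serve as the")
print("target of a Monte Carlo evaluation; the target must be a constant.")
print("(Residual noise SD is set to 1.0 here; the magnitudes scale with it.)")
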