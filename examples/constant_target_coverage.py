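"""The constant-target redesign: valid coverage vs the random-target pathology.

Unlogged DGM (outcome proportional to exposure): the true slope beta_DGM is
the estimand of the untransformed fit, so its 95% CI should cover beta_DGM
95% of the time.  Logged DGM: the untransformed-fit estimand is not beta_DGM,
and its sampling SD does not shrink however many Monte Carlo iterations are
run — only the MC error of its mean does.
"""

from reexpress import DGMConfig, coverage_vs_constant, mc_stability, run_mc

config = DGMConfig(n_obs=162, sigma=0.45, space="unlogged", noise_sd=1.0,
                   n_sims=2000, seed=1)
cov = coverage_vs_constant(run_mc(config), scale="estimand")
print(f"unlogged DGM, constant target beta_DGM = {cov.target}:")
print(f"  coverage of the 95% CI = {cov.coverage:.3f} (MC se {cov.mc_se:.4f})\n")

stab = mc_stability(
    DGMConfig(n_obs=162, sigma=0.25, space="logged", noise_sd=1.0,
              n_sims=2000, seed=1),
    [500, 2000],
)
print("logged DGM, estimand fit as would-be target:")
print(stab.round(6).to_string(index=False))
print()
print("Reading: coverage is nominal when the target is the constant built")
print("into the DGM.  Under the logged DGM, sd_hat barely moves from 500 to")
print("2000 iterations (it is a property of one simulated study, not of the")
print("Monte Carlo), while se_of_mean halves as 1/sqrt(n_sims).")
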