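"""Re-express one reported log10-exposure coefficient onto the raw scale.

A study reports a slope of 1.2 outcome units per unit log10 exposure
(SE 0.3), with exposure median 8 and log10-scale SD 0.45.  We convert it to
outcome units per exposure unit under the three factor conventions, with both
CI-propagation modes.
"""

from reexpress import ReportedLoggedEstimate, reexpress

reported = ReportedLoggedEstimate(
    beta_log=1.2, se_log=0.3, log_base=10, geo_median=8.0, sigma_log=0.45,
    sigma_log_se=0.05,
)

print(f"reported: beta_log = {reported.beta_log} +- {reported.se_log} "
      f"per unit log10 exposure\n")
for method in ("RB", "Dz", "Alt"):
    mult = reexpress(reported, method, propagation="multiplicative")
    pmc = reexpress(reported, method, propagation="parametric-mc",
                    n_draws=50_000, seed=1)
    print(f"{method}: factor {mult.factor:.5f}")
    print(f"   multiplicative: {mult.beta:.4f} "
          f"({mult.ci.lower:.4f}, {mult.ci.upper:.4f})")
    print(f"   parametric-mc : {pmc.beta:.4f} "
          f"({pmc.ci.lower:.4f}, {pmc.ci.upper:.4f})")

print()
print("The three factors anchor the log->linear conversion at different")
print("points of the lognormal exposure distribution, so they differ more as")
print("sigma grows.  Parametric MC also propagates uncertainty in sigma,")
print("which widens and skews the interval slightly.")
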