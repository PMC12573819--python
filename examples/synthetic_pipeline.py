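"""End-to-end synthetic pipeline: generate studies, re-express, screen.

Generates 120 synthetic studies with a known true untransformed slope
(beta_true = 1), re-expresses each study's log-exposure fit with the three
default methods, and runs the membership screen.  Because the methods are
only approximately correct, failures should concentrate in the large studies.
The exposure spread is kept moderate (sigma 0.1-0.3 in log10 units): with
very wide spreads the log-exposure fit is so attenuated that studies of every
size fail the screen and the size gradient disappears.
"""

import numpy as np

from reexpress import SyntheticStudySpec, generate_study_table, membership_table

spec = SyntheticStudySpec(n_studies=120, beta_true=1.0, noise_sd=2.0,
                          n_obs_range=(200, 50_000), sigma_range=(0.1, 0.3),
                          median_range=(4.0, 16.0), seed=1)
records, truths = generate_study_table(spec)
rows = membership_table(records)

betas = np.array([r.beta_observed for r in records])
print(f"{len(records)} synthetic studies, true slope {truths[0]}")
print(f"mean observed slope = {betas.mean():.4f} "
      f"(MC se {betas.std(ddof=1)/np.sqrt(len(betas)):.4f})\n")

for cls in ("small_moderate", "very_large"):
    sub = [r for r in rows if r.size_class == cls]
    rate = np.mean([r.n_failures / 3 for r in sub])
    print(f"{cls:<15}: {len(sub):>3} studies, "
          f"membership-failure rate {rate:.2f}")

print()
print("Reading: the observed slopes center on the known truth, and the")
print("screen's failure rate is higher for n > 5000 — precision exposes the")
print("approximation error of re-expression, mirroring the empirical table.")
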