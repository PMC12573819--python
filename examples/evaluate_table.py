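"""Consistency screen on the packaged 15-study evaluation table.

For each study we ask whether the observed (untransformed-exposure) estimate
lies inside the 95% CI of each of the three re-expressed estimates, then
stratify by study size at n = 5,000.
"""

from reexpress import load_fixture, membership_table, summarize_consistency

records = load_fixture()
rows = membership_table(records, size_threshold=5000)

print(f"{'study':<16} {'n_obs':>6}  RB Dz Alt  size class")
for row in rows:
    flags = " ".join("Y" if f else "N" for f in (row.in_rb, row.in_dz, row.in_alt))
    print(f"{row.study_id:<16} {row.n_obs:>6}  {flags:>8}  {row.size_class}")

summary = summarize_consistency(rows)
print()
print(f"{summary.n_studies} studies; {summary.n_very_large} with n > 5000, "
      f"of which {summary.n_very_large_all_consistent} consistent with all "
      f"three re-expressed CIs.")
print(f"Among the {summary.n_small_moderate} small/moderate studies, "
      f"{summary.n_small_moderate_exception_cells} study-method cell(s) fail "
      f"the screen.")
print()
print("Reading: membership failures concentrate in the very large studies —")
print("a precise observed estimate exposes re-expression approximation error,")
print("while for small-to-moderate studies re-expression is statistically")
print("indistinguishable from the observed estimate.")
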