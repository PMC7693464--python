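"""Conventional per-channel analysis: paired t-tests over the cohort.

For each channel, the clench-minute mean minus the rest-minute mean is
computed per subject; a two-sided paired t-test across the 15 subjects
tests the change, and the Bonferroni column is the raw p times 22,
deliberately uncapped.
"""

from nirsclench import CohortConfig, channel_changes, generate_cohort

cohort = generate_cohort(CohortConfig(seed=3))
tables = channel_changes(cohort)

for sp in ("oxy", "deoxy"):
    frame = tables[sp].frame
    sig = frame[frame["p_adj"] < 0.05]
    print(f"\n{sp}-Hb: significant channels after Bonferroni (p_adj < 0.05):")
    cols = ["channel", "change_mean", "change_sd", "p_adj", "region"]
    print(sig[cols].to_string(index=False) if len(sig) else "  none")
print("\nadjusted p-values above 1 (uncapped x22):",
      int((tables['oxy'].frame['p_adj'] > 1).sum()), "of 22 oxy channels")
# With the default effect profile the large-change channels (e.g. Ch19
# oxy, +0.305) come out significant, small-change channels do not.
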