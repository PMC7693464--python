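"""Identification-rate arithmetic and the Ryan multiple-proportion test.

Shows the evaluation toolbox on a toy confusion table and on the pooled
correct/total counts of three networks: the five metric formulas, the
macro mean +/- SD over folds, and the stepwise Ryan comparison of
proportions (pairs spanning m ranks tested at alpha' = 2*alpha/(k*m)).
"""

from nirsclench import (ConfusionCounts, aggregate_folds, compute_metrics,
                        ryan_compare)

counts = ConfusionCounts(tn=8, fp=2, fn=1, tp=9)
m = compute_metrics(counts)
print("toy confusion (TN=8 FP=2 FN=1 TP=9):", m.as_percent_row())

folds = [compute_metrics(c) for c in (
    ConfusionCounts(90, 10, 12, 88), ConfusionCounts(80, 20, 15, 85),
    ConfusionCounts(95, 5, 8, 92), ConfusionCounts(85, 15, 10, 90),
    ConfusionCounts(88, 12, 9, 91))]
mean, sd = aggregate_folds(folds)["accuracy"]
print(f"macro accuracy over 5 folds: {100 * mean:.1f} +/- {100 * sd:.1f} %")

# pooled test-image counts of three trained networks
networks = {"oxy": (11170, 12878), "deoxy": (8052, 10602), "od": (8502, 9442)}
print("\nRyan stepwise comparison of network accuracies:")
for d in ryan_compare(networks):
    verdict = "significant" if d.significant else "n.s."
    print(f"  {d.name_a} vs {d.name_b}: p = {d.p_raw:.3g} "
          f"(alpha' = {d.alpha_adjusted:.4f}, span {d.span}) -> {verdict}")
# The mixed-OD network's accuracy is significantly higher than both
# single-species networks at p < 0.001.
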