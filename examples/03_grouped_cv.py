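"""Subject-grouped five-fold cross-validation with the tiny CNN preset.

Runs the full pipeline (simulate -> preprocess -> encode -> balance ->
grouped CV -> evaluate) on a 15-subject cohort carrying the default
per-channel effect profile, for the oxy and mixed-OD modalities, and
prints the per-group identification-rate table plus the pooled AUC.
Takes about half a minute on one CPU core.
"""

from nirsclench import PipelineConfig, TrainConfig, run_pipeline
from nirsclench.synth import CohortConfig

config = PipelineConfig(
    cohort=CohortConfig(seed=7),
    frame_stride=20,            # every 2 s instead of every 0.1 s
    preset="tiny",              # 64-px input, reduced filters
    train=TrainConfig(epochs=10, batch_size=32),
    modalities=("oxy", "od"),
    seed=7,
)
manifest = run_pipeline(config)

for m, result in manifest["results"].items():
    print(f"\n=== {m} network ===")
    print(result.report.to_string(index=False))
    roc = result.roc
    print(f"pooled AUC {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f}), "
          f"n = {roc.n_pos}+{roc.n_neg} test frames")
# Accuracy near 100% reflects the cleanly separable synthetic effect
# profile; rows mirror the conventional per-group report layout.
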