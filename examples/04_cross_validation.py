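"""Leakage-controlled five-fold cross validation, end to end.

Generates the planted-block world, then for every fold removes the
test-fold miRNA-disease edges from the network *before* embedding, trains
the fused-feature CNN on the training fold, and reports the standard
metric panel.  Scaled down (small world, few epochs) so it runs in about a
minute; the package defaults reproduce the full protocol.
"""

from mdlink import (
    CnnConfig,
    CompressConfig,
    CvConfig,
    FixtureSpec,
    PipelineConfig,
    SdneConfig,
    run_pipeline,
)

config = PipelineConfig(
    fixture=FixtureSpec(
        n_mirna=30, n_disease=20, n_protein=20, n_lncrna=10, n_drug=10,
        n_blocks=2, p_in=0.4, p_out=0.03,
    ),
    cv=CvConfig(
        sdne=SdneConfig(epochs=40, layer_dims=(64, 128)),
        compress=CompressConfig(epochs=50),
        cnn=CnnConfig(epochs=15),
    ),
)
report = run_pipeline(config, seed=7)

print(f"known pairs: {report['n_positives']}")
print(f"leakage audit passed on all folds: "
      f"{all(all(a.values()) for a in report['leakage_audit'])}")
print("\nper-fold AUC:", [round(m["auc"], 3) for m in report["fold_metrics"]])
print("\nmetric summary (mean +/- std over folds):")
for metric, stats in report["summary"].items():
    print(f"  {metric:5s} {stats['mean']:.3f} +/- {stats['std']:.3f}")
print("\nAUC well above 0.5 means the pipeline recovers the planted "
      "within-block association signal from held-out pairs.")
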