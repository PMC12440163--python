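"""Nested leave-one-subject-out evaluation with multi-view vote fusion.

Outer folds hold out one subject; selection, SMOTE and hyperparameter tuning
run inside each training fold only. Window predictions are majority-voted to
video labels, and windows from the frontal and sagittal videos of the same
walk are pooled into a fused vote. Expect video- and fused-level accuracy
above window-level: voting suppresses single-window mistakes.
"""

import mobilegait as mg

dataset = mg.simulate_dataset(mg.SimulationConfig(n_subjects=6, seed=11))
X, meta = mg.dataset_features(dataset)

spec = mg.ModelSpec(family="gradient-boosted-trees", budget=2, seed=0,
                    space={"n_estimators": ("int", 50, 110),
                           "max_depth": ("int", 3, 6)})
result = mg.nested_loso_evaluate(X, meta, spec, view="combined", trials=1,
                                 seed=0, max_features=500)

summary = result.summary()
print("accuracy (mean +/- 95% CI half-width) per aggregation level:")
for level in ("window", "video", "fused"):
    row = summary.loc[(level, "accuracy")]
    print(f"  {level:7s} {row['mean']:.3f} +/- {row['ci_half']:.3f}")

print("\nper-class one-vs-rest F1 from the pooled video confusion matrix:")
conf = result.confusions["video"]
for i, cls in enumerate(result.classes):
    tp = conf[i, i]
    prec = tp / conf[:, i].sum() if conf[:, i].sum() else 0.0
    rec = tp / conf[i].sum() if conf[i].sum() else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    print(f"  {cls}: F1 = {f1:.3f}")
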