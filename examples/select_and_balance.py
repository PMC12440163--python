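"""Relevance filtering with BY FDR control, then SMOTE class balancing.

Every feature is tested one-vs-rest per gait class (Mann-Whitney U); the
Benjamini-Yekutieli step-up controls the false discovery rate across the
whole feature x class p-value matrix. Slower gaits produce fewer windows per
video, so the surviving training set is rebalanced by SMOTE interpolation to
the majority (Parkinsonian) class count.
"""

import pandas as pd

import mobilegait as mg

dataset = mg.simulate_dataset(mg.SimulationConfig(n_subjects=4, seed=5))
X, meta = mg.dataset_features(dataset)
y = meta["label"].to_numpy()

sel = mg.fresh_select(X, y, q=0.05)
print(f"features: {X.shape[1]} candidates -> {sel.n_selected} selected "
      f"(FDR q = {sel.fdr_level})")
print("\nsurvivors per feature type (top 10):")
print(sel.survivors_per_type.sort_values(ascending=False).head(10).to_string())

print("\nwindow counts per class before balancing:")
print(pd.Series(y).value_counts().sort_index().to_string())

Xb, yb, _ = mg.smote_oversample(X[sel.selected], y, k=5, rng=0)
print("\nafter SMOTE:")
print(pd.Series(yb).value_counts().sort_index().to_string())
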