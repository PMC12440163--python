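"""Extract the time-series feature bank from analysis windows.

Each 1-second window yields 99 keypoint-channel series (33 landmarks x
x/y/z); every catalog entry is evaluated on each of them. The reduced
catalog (~82 entries/channel) is the modelling default; full-mirror mode
carries 783 entries/channel, i.e. 77,517 candidate features per window.
"""

import mobilegait as mg

dataset = mg.simulate_dataset(mg.SimulationConfig(n_subjects=2, seed=1))
windows = mg.dataset_windows(dataset)[:40]

catalog = mg.reduced_catalog()
X = mg.compute_feature_matrix(windows, catalog)
print(f"{len(windows)} windows -> feature matrix {X.shape[0]} x {X.shape[1]} "
      f"({len(catalog)} entries x 99 channels)")

full = mg.full_catalog()
print(f"full-mirror catalog: {len(full)} entries/channel -> "
      f"{len(full) * 99} candidate features")

name = "right_ankle_y__fft_coefficient__k=1__attr=abs"
print(f"\nexample feature {name}:")
print(X[name].describe().loc[["mean", "std", "min", "max"]].to_string())
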