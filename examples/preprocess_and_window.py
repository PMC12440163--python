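"""Run one pose video through the preprocessing chain, stage by stage.

Missing landmarks are interpolated, the 60 fps recording is downsampled to
30 fps, poses are centred on a rolling-median hip position, frontal views
are rescaled to a common stature, and the result is cut into 30-frame
windows with 50% overlap — the unit the classifier operates on.
"""

import mobilegait as mg
from mobilegait import preprocess as pp

dataset = mg.simulate_dataset(mg.SimulationConfig(n_subjects=2, seed=7))
seq = dataset.sequences["S00_CIR_frontal_left"]
print(f"raw: {seq.n_frames} frames @ {seq.fps:.0f} fps, "
      f"{seq.missing.sum()} missing landmark-frames")

seq = pp.drop_empty_frames(seq)
seq = pp.interpolate_missing(seq)
print(f"after gap filling: {seq.n_frames} frames, {seq.missing.sum()} missing")

seq = pp.resample_to_30fps(seq)
print(f"after resampling: {seq.n_frames} frames @ {seq.fps:.0f} fps")

seq = pp.hip_center(seq)
seq = pp.rescale_frontal(seq)
windows = pp.segment_windows(seq)
print(f"after normalization: {len(windows)} windows of "
      f"{windows[0].values.shape[0]} frames "
      f"(starts {[w.start_frame for w in windows[:4]]} ...)")
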