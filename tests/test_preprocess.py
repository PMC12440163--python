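"""Preprocessing: cleaning, resampling, normalization and windowing."""

import numpy as np
import pytest

import mobilegait as mg
from mobilegait.preprocess import _rolling_median
from mobilegait.skeleton import LANDMARK_INDEX as LM


def make_seq(values, fps=30.0, view="sagittal", missing=None):
    return mg.PoseSequence(values=values, fps=fps, video_id="v",
                           subject_id="s", view=view, direction="right",
                           label="NOR", missing=missing)


def test_drop_empty_frames_counts_and_order():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(100, 33, 3))
    empty = np.zeros(100, dtype=bool)
    empty[[3, 10, 11, 50, 51, 52, 80, 81, 97, 98]] = True
    values[empty] = np.nan
    seq = make_seq(values)
    out = mg.drop_empty_frames(seq)
    assert out.n_frames == 90
    kept = values[~empty]
    assert np.array_equal(out.values, kept)  # order of survivors preserved

    intact = make_seq(rng.normal(size=(20, 33, 3)))
    assert mg.drop_empty_frames(intact) is intact


def test_drop_empty_frames_all_empty_errors():
    values = np.full((5, 33, 3), np.nan)
    with pytest.raises(ValueError, match="no usable frames"):
        mg.drop_empty_frames(make_seq(values))


def test_interpolate_midpoint_and_edges():
    values = np.zeros((4, 33, 3))
    values[:, 0, 0] = [1.0, np.nan, 3.0, 4.0]
    values[:, 1, 0] = [np.nan, 5.0, 5.0, np.nan]
    seq = make_seq(values)
    out = mg.interpolate_missing(seq)
    assert np.allclose(out.values[:, 0, 0], [1, 2, 3, 4])
    assert np.allclose(out.values[:, 1, 0], [5, 5, 5, 5])  # nearest-value fill
    assert not out.missing.any()


def test_interpolate_never_observed_landmark_errors():
    values = np.zeros((10, 33, 3))
    values[:, LM["left_wrist"], :] = np.nan
    with pytest.raises(ValueError, match="left_wrist"):
        mg.interpolate_missing(make_seq(values))


def test_interpolation_error_within_theoretical_bound():
    """Linear interpolation error on a smooth signal is bounded by
    h^2 max|f''| / 8 with h the largest gap width."""
    rng = np.random.default_rng(42)
    n, omega = 300, 2 * np.pi / 40
    t = np.arange(n, dtype=float)
    truth = np.sin(omega * t)
    gaps = rng.random(n) < 0.1
    gaps[[0, -1]] = False
    values = np.zeros((n, 33, 3))
    values[:, 0, 0] = np.where(gaps, np.nan, truth)
    out = mg.interpolate_missing(make_seq(values))
    err = np.abs(out.values[:, 0, 0] - truth).max()
    # largest gap in samples -> h = gap + 1 sample spacings
    runs, cur = [], 0
    for g in gaps:
        cur = cur + 1 if g else 0
        runs.append(cur)
    h = max(runs) + 1
    bound = (h ** 2) * (omega ** 2) / 8  # max|f''| = omega^2
    assert err <= bound + 1e-12


def test_resample_identity_counts_and_linearity():
    rng = np.random.default_rng(1)
    v30 = rng.normal(size=(90, 33, 3))
    seq30 = make_seq(v30, fps=30.0)
    assert mg.resample_to_30fps(seq30) is seq30

    t = np.arange(120)
    v60 = np.zeros((120, 33, 3))
    v60[:, 5, 1] = 3.0 * t + 1.0
    out = mg.resample_to_30fps(make_seq(v60, fps=60.0))
    assert out.n_frames == 60
    assert out.fps == 30.0
    expect = 3.0 * np.arange(60) * 2 + 1.0  # same line on the coarser grid
    assert np.allclose(out.values[:, 5, 1], expect)

    with pytest.raises(ValueError, match="upsample"):
        mg.resample_to_30fps(make_seq(v30, fps=24.0))


def test_hip_center_constant_hip_goes_to_zero():
    rng = np.random.default_rng(2)
    values = rng.normal(size=(100, 33, 3))
    values[:, LM["left_hip"]] = [1.0, 2.0, 3.0]
    values[:, LM["right_hip"]] = [3.0, 4.0, 5.0]
    out = mg.hip_center(make_seq(values))
    hip_mid = 0.5 * (out.values[:, LM["left_hip"]] + out.values[:, LM["right_hip"]])
    assert np.allclose(hip_mid, 0.0, atol=1e-12)


def test_hip_center_matches_brute_force_sliding_median():
    """Ramp removed, sinusoid retained, against a direct per-frame median."""
    T = 200
    t = np.arange(T, dtype=float)
    hip_sig = 0.5 * t + 4 * np.sin(2 * np.pi * t / 20)
    values = np.zeros((T, 33, 3))
    values[:, LM["left_hip"], 0] = hip_sig
    values[:, LM["right_hip"], 0] = hip_sig
    values[:, 0, 0] = 7.0
    out = mg.hip_center(make_seq(values))

    brute = np.array([np.median(hip_sig[max(0, i - 30):i + 31])
                      for i in range(T)])
    assert np.allclose(out.values[:, LM["left_hip"], 0], hip_sig - brute)
    assert np.allclose(out.values[:, 0, 0], 7.0 - brute)
    # the fast sinusoid survives centring: most of its amplitude remains
    centred = out.values[:, LM["left_hip"], 0]
    assert centred[60:-60].std() > 0.6 * (4 / np.sqrt(2))


def test_hip_center_boundary_window_is_truncated():
    rng = np.random.default_rng(3)
    sig = rng.normal(size=100)
    med0 = _rolling_median(sig[:, None], 30)[0, 0]
    assert med0 == np.median(sig[0:31])  # frames [0, 30] at t = 0


def test_rescale_sagittal_passthrough_and_scale_invariance(small_dataset):
    sag = next(s for s in small_dataset.sequences.values()
               if s.view == "sagittal")
    sag = mg.resample_to_30fps(mg.interpolate_missing(mg.drop_empty_frames(sag)))
    assert mg.rescale_frontal(sag) is sag

    fro = next(s for s in small_dataset.sequences.values()
               if s.view == "frontal")
    fro = mg.resample_to_30fps(mg.interpolate_missing(mg.drop_empty_frames(fro)))
    a = mg.rescale_frontal(fro)
    b = mg.rescale_frontal(fro.with_values(fro.values * 2.0))
    assert np.allclose(a.values, b.values, atol=1e-9)


def test_rescale_frontal_rigid_approach_walk_constant_height():
    """Projection oracle: a rigid pose translated toward the camera doubles
    its apparent size; rescaling restores a constant stature within 1%."""
    from mobilegait.simulate import Anthropometry, _project, base_gait_cycle

    pose = base_gait_cycle(0.3, Anthropometry(1.7), stride=2.0)
    T = 120
    world = np.repeat(pose[None, :, :], T, axis=0)
    # march the rigid pose from 2x to 1x the camera distance
    world[..., 0] = world[..., 0] - world[..., 0].mean() \
        + np.linspace(4.0, 0.0, T)[:, None]
    values = _project(world, "frontal", 4.0, 10.0)
    seq = make_seq(values, view="frontal")

    h = np.abs(0.5 * (values[:, LM["left_ankle"], 1]
                      + values[:, LM["right_ankle"], 1])
               - values[:, LM["nose"], 1])
    assert h[-1] / h[0] > 1.8  # perspective growth before rescaling

    out = mg.rescale_frontal(seq)
    ho = np.abs(0.5 * (out.values[:, LM["left_ankle"], 1]
                       + out.values[:, LM["right_ankle"], 1])
                - out.values[:, LM["nose"], 1])
    core = ho[30:-30]  # truncated median windows bias the sequence ends
    assert np.abs(core / core.mean() - 1).max() < 0.01


def test_rescale_frontal_removes_perspective_growth(clean_config):
    """A real simulated approach walk keeps near-constant apparent stature."""
    subj = mg.make_subjects(clean_config)[0]
    seq = mg.render_sequence(subj, "NOR", "frontal", "left", clean_config,
                             np.random.default_rng(0))
    pre = mg.resample_to_30fps(mg.interpolate_missing(seq))
    heights_before = np.abs(
        0.5 * (pre.values[:, LM["left_ankle"], 1]
               + pre.values[:, LM["right_ankle"], 1])
        - pre.values[:, LM["nose"], 1])
    assert heights_before[-15] / heights_before[15] > 1.8

    out = mg.rescale_frontal(mg.hip_center(pre))
    heights = np.abs(
        0.5 * (out.values[:, LM["left_ankle"], 1]
               + out.values[:, LM["right_ankle"], 1])
        - out.values[:, LM["nose"], 1])
    core = heights[30:-30]
    # residual oscillation is the gait's own height fluctuation, not perspective
    assert core.max() / core.min() < 1.10


def test_segment_window_counts_and_starts():
    rng = np.random.default_rng(4)
    for T, expect in ((150, 9), (30, 1), (29, 0), (45, 2), (44, 1)):
        seq = make_seq(rng.normal(size=(max(T, 1), 33, 3)))
        wins = mg.segment_windows(seq)
        assert len(wins) == expect, T
        assert [w.start_frame for w in wins] == list(range(0, T - 29, 15))
        assert all(w.label == "NOR" and w.values.shape == (30, 33, 3)
                   for w in wins)


def test_hip_center_preserves_within_frame_distances():
    rng = np.random.default_rng(5)
    values = rng.normal(size=(80, 33, 3))
    seq = make_seq(values)
    out = mg.hip_center(seq)
    d_in = values[:, 4] - values[:, 20]
    d_out = out.values[:, 4] - out.values[:, 20]
    assert np.allclose(d_in, d_out, atol=1e-12)


def test_preprocess_idempotent(small_dataset):
    seq = next(s for s in small_dataset.sequences.values()
               if s.view == "frontal")
    once = mg.preprocess_sequence(seq)
    twice = mg.preprocess_sequence(once)
    assert twice.n_frames == once.n_frames
    core = slice(30, -30)
    # approximately idempotent: the stature estimate retains the gait's own
    # height oscillation, so a second rescale perturbs by < ~2% of scale
    scale = np.abs(once.values).max()
    assert np.abs(twice.values[core] - once.values[core]).max() < 0.03 * scale


def test_preprocessing_never_reads_label(small_dataset):
    """Relabelling a sequence changes nothing in the preprocessed values."""
    seq = next(iter(small_dataset.sequences.values()))
    relabelled = mg.PoseSequence(values=seq.values.copy(), fps=seq.fps,
                                 video_id=seq.video_id, subject_id=seq.subject_id,
                                 view=seq.view, direction=seq.direction,
                                 label="PAR", missing=seq.missing.copy())
    a = mg.preprocess_sequence(seq)
    b = mg.preprocess_sequence(relabelled)
    assert np.array_equal(a.values, b.values)
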