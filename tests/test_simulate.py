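"""Synthetic gait simulator: kinematic invariants and dataset structure."""

import numpy as np
import pytest

import mobilegait as mg
from mobilegait.simulate import (Anthropometry, GaitParams, WalkerControls,
                                 _project, apply_impairment, walker_poses)
from mobilegait.skeleton import LANDMARK_INDEX as LM
from mobilegait.skeleton import LEFT_RIGHT_PAIRS

ANTHRO = Anthropometry(height=1.72)
STRIDE = 2.1


def test_base_cycle_periodic_in_phase():
    p0 = mg.base_gait_cycle(0.0, ANTHRO, stride=STRIDE)
    eps = 1e-6
    p1 = mg.base_gait_cycle(1.0 - eps, ANTHRO, stride=STRIDE)
    # remove the one-stride forward advance before comparing
    p1 = p1.copy()
    p1[:, 0] -= STRIDE * (1.0 - eps)
    assert np.allclose(p0, p1, atol=1e-4)


def test_base_cycle_mirror_symmetry():
    """Left-side pose at phase p equals the mirrored right side at p + 1/2."""
    for p in (0.1, 0.37, 0.72):
        a = mg.base_gait_cycle(p, ANTHRO, stride=STRIDE)
        b = mg.base_gait_cycle(p + 0.5, ANTHRO, stride=STRIDE)
        b = b.copy()
        b[:, 0] -= STRIDE * 0.5      # forward advance between the two phases
        b[:, 2] *= -1                # mirror about the sagittal plane
        for left, right in LEFT_RIGHT_PAIRS:
            assert np.allclose(a[left], b[right], atol=1e-9), (left, right)


def test_bone_lengths_constant_over_cycle():
    phases = np.linspace(0, 3, 200)
    poses = walker_poses(phases, ANTHRO, STRIDE)
    # legs are sized for the stride but must then stay rigid
    for a, b, floor in [("left_hip", "left_knee", ANTHRO.thigh),
                        ("left_knee", "left_ankle", ANTHRO.shank),
                        ("right_hip", "right_knee", ANTHRO.thigh),
                        ("right_shoulder", "right_elbow", ANTHRO.upper_arm),
                        ("right_elbow", "right_wrist", ANTHRO.forearm)]:
        d = np.linalg.norm(poses[:, LM[a]] - poses[:, LM[b]], axis=1)
        assert d.std() / d.mean() < 1e-7, (a, b)
        assert d.mean() >= floor - 1e-9, (a, b)


def test_heel_height_one_maximum_per_cycle_and_cadence_peak():
    """DFT of the heel vertical channel peaks exactly at the cadence."""
    cycles = 8
    n = 64 * cycles
    phases = np.linspace(0, cycles, n, endpoint=False)
    heel_y = walker_poses(phases, ANTHRO, STRIDE)[:, LM["right_heel"], 1]
    spectrum = np.abs(np.fft.rfft(heel_y - heel_y.mean()))
    assert np.argmax(spectrum) == cycles  # fundamental = once per cycle
    # exactly one maximum per cycle: count strict local maxima
    interior = (heel_y[1:-1] > heel_y[:-2] + 1e-12) & \
               (heel_y[1:-1] > heel_y[2:] + 1e-12)
    assert interior.sum() == pytest.approx(cycles, abs=1)


def test_apply_impairment_nor_and_zero_magnitude_are_identity():
    base = WalkerControls()
    params = GaitParams()
    assert apply_impairment(base, "NOR", params, 0.7) == base
    outs = [apply_impairment(base, c, params, 0.0) for c in mg.GAIT_CLASSES]
    assert all(o == base for o in outs)


def test_apply_impairment_rejects_unknown_label():
    with pytest.raises(ValueError, match="unknown gait class"):
        apply_impairment(WalkerControls(), "LIMP", GaitParams(), 0.5)


def test_apply_impairment_modifier_monotone_in_magnitude():
    base = WalkerControls()
    params = GaitParams()
    circ = [apply_impairment(base, "CIR", params, m).circumduction
            for m in (0.0, 0.3, 0.6, 1.0)]
    assert circ == sorted(circ) and circ[0] == 0.0 and circ[-1] > 0


def test_per_class_cycle_ordering_matches_observed_means(small_dataset):
    """PAR walks 10 m in the most cycles, NOR in the fewest; full ordering
    follows the observed per-class means (ANT 7.6, CIR 5.8, CRO 7.2, NOR 4.6,
    PAR 10.4, TRE 6.4, VAU 5.4)."""
    from scipy.stats import spearmanr

    printed = {"ANT": 7.6, "CIR": 5.8, "CRO": 7.2, "NOR": 4.6, "PAR": 10.4,
               "TRE": 6.4, "VAU": 5.4}
    means = {}
    for lab in mg.GAIT_CLASSES:
        counts = [mg.count_gait_cycles(s) for s in small_dataset.sequences.values()
                  if s.label == lab and s.view == "sagittal"]
        means[lab] = float(np.mean(counts))
    assert means["PAR"] > means["NOR"]
    rho, _ = spearmanr([printed[c] for c in mg.GAIT_CLASSES],
                       [means[c] for c in mg.GAIT_CLASSES])
    assert rho > 0.85
    # the exact per-class targets hold in closed form: cycles = 10 / stride
    cfg = mg.SimulationConfig(n_subjects=3, seed=7)
    factors = cfg.gait_params.stride_scale
    mid = float(np.mean(cfg.stride_length))
    for lab, target in printed.items():
        assert 10.0 / (mid * factors[lab]) == pytest.approx(target, rel=0.02)


def test_sagittal_bone_pixel_length_near_constant(clean_config):
    subj = mg.make_subjects(clean_config)[0]
    seq = mg.render_sequence(subj, "NOR", "sagittal", "right", clean_config,
                             np.random.default_rng(0))
    px = seq.values[:, :, :2]
    d = np.linalg.norm(px[:, LM["left_hip"]] - px[:, LM["left_knee"]], axis=1)
    assert d.std() / d.mean() < 0.02


def test_frontal_pixel_height_halves_at_double_distance():
    """Pinhole identity: apparent size is inversely proportional to distance."""
    pose = mg.base_gait_cycle(0.25, ANTHRO, stride=STRIDE)[None, :, :]
    near = pose.copy()
    far = pose.copy()
    cam = 4.0
    near[..., 0] = pose[..., 0] - pose[..., 0].mean() + cam      # 2*cam from camera
    far[..., 0] = pose[..., 0] - pose[..., 0].mean() + cam + 2 * cam  # 4*cam
    h_near = np.ptp(_project(near, "frontal", cam, 10.0)[0, :, 1])
    h_far = np.ptp(_project(far, "frontal", cam, 10.0)[0, :, 1])
    assert h_near / h_far == pytest.approx(2.0, rel=0.02)


def test_occlusion_fraction_matches_binomial(small_config):
    cfg = mg.SimulationConfig(n_subjects=2, seed=11, occlusion_prob=0.1)
    subj = mg.make_subjects(cfg)[0]
    seq = mg.render_sequence(subj, "NOR", "sagittal", "right", cfg,
                             np.random.default_rng(5))
    n = seq.missing.size
    frac = seq.missing.mean()
    se = np.sqrt(0.1 * 0.9 / n)
    assert abs(frac - 0.1) < 3 * se


def test_dataset_structure_and_determinism(small_dataset, small_config):
    assert len(small_dataset.sequences) == 3 * 7 * 2 * 2
    assert len(small_dataset.manifest) == 84
    per_class = small_dataset.manifest.groupby("label").size()
    assert (per_class == 12).all()
    again = mg.simulate_dataset(small_config)
    assert mg.dataset_fingerprint(again) == mg.dataset_fingerprint(small_dataset)


def test_dataset_rejects_single_subject():
    with pytest.raises(ValueError, match="at least 2 subjects"):
        mg.simulate_dataset(mg.SimulationConfig(n_subjects=1))


def test_save_dataset_refuses_existing_dir(tmp_path, small_dataset):
    out = tmp_path / "ds"
    mg.save_dataset(small_dataset, out)
    with pytest.raises(FileExistsError):
        mg.save_dataset(small_dataset, out)
    mg.save_dataset(small_dataset, out, overwrite=True)  # explicit opt-in works


def test_pose_roundtrip(tmp_path, small_dataset):
    vid, seq = next(iter(small_dataset.sequences.items()))
    path = mg.write_pose_csv(seq, tmp_path / f"{vid}.csv")
    back = mg.read_pose_csv(path, fps=seq.fps, subject_id=seq.subject_id,
                            view=seq.view, direction=seq.direction,
                            label=seq.label)
    assert np.allclose(seq.values, back.values, atol=1e-5, equal_nan=True)
    assert (seq.missing == back.missing).all()


def test_count_cycles_pure_sinusoid():
    """A heel channel oscillating 5 times yields a count of 5 +/- 1."""
    fps, seconds, periods = 30.0, 6.0, 5
    t = np.arange(int(fps * seconds)) / fps
    values = np.zeros((len(t), 33, 3))
    values[:, :, 1] = 500.0
    values[:, LM["right_heel"], 1] = 500 - 20 * np.clip(
        np.sin(2 * np.pi * periods * t / seconds), 0, None)
    values[:, LM["nose"], 1] = 200.0
    seq = mg.PoseSequence(values=values, fps=fps, video_id="v", subject_id="s",
                          view="sagittal", direction="right", label="NOR")
    assert abs(mg.count_gait_cycles(seq) - periods) <= 1


def test_count_cycles_constant_channel_errors():
    values = np.ones((120, 33, 3))
    seq = mg.PoseSequence(values=values, fps=30.0, video_id="v", subject_id="s",
                          view="sagittal", direction="right", label="NOR")
    with pytest.raises(ValueError, match="no cycles detectable"):
        mg.count_gait_cycles(seq)


def test_nor_cycle_count_in_calibration_band(small_dataset):
    counts = [mg.count_gait_cycles(s) for s in small_dataset.sequences.values()
              if s.label == "NOR" and s.view == "sagittal"]
    assert 4.0 <= np.mean(counts) <= 7.0


def test_halving_stride_doubles_cycle_count():
    """Closed form: cycles = walk distance / stride length."""
    base = mg.SimulationConfig(n_subjects=2, seed=5, keypoint_jitter_sd=0.5,
                               occlusion_prob=0.0)
    short = mg.SimulationConfig(n_subjects=2, seed=5, keypoint_jitter_sd=0.5,
                                occlusion_prob=0.0,
                                stride_length=(2.05 / 2, 2.30 / 2))
    counts = []
    for cfg in (base, short):
        subj = mg.make_subjects(cfg)[0]
        seq = mg.render_sequence(subj, "NOR", "sagittal", "right", cfg,
                                 np.random.default_rng(2))
        counts.append(mg.count_gait_cycles(seq))
    assert counts[1] / counts[0] == pytest.approx(2.0, rel=0.25)


def test_render_rejects_zero_walk_distance():
    with pytest.raises(ValueError):
        mg.SimulationConfig(n_subjects=2, walk_distance=0.0)
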