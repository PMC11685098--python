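import numpy as np
import pandas as pd
import pytest

import curiomap as cm
from curiomap.simulate import LinearEffects, SimConfig, simulate_trajectory


def test_trajectory_determinism(occluded_room):
    cfg = SimConfig()
    a = simulate_trajectory(occluded_room, 0.5, 0.0, 10.0, cfg, seed=3)
    b = simulate_trajectory(occluded_room, 0.5, 0.0, 10.0, cfg, seed=3)
    pd.testing.assert_frame_equal(a, b)


def test_trajectory_sample_count_and_ranges(occluded_room):
    cfg = SimConfig()
    t = simulate_trajectory(occluded_room, 0.0, 0.0, 12.5, cfg, seed=1)
    assert len(t) == int(round(12.5 * cfg.hz))
    assert t["t"].iloc[0] == 0.0 and t["t"].is_monotonic_increasing
    assert t["yaw"].between(-180, 180 - 1e-9).all()
    assert t["pitch"].between(-90, 90).all()
    assert t["x"].between(0, 16).all() and t["y"].between(0, 16).all()


def test_step_length_bounded(occluded_room):
    cfg = SimConfig()
    t = simulate_trajectory(occluded_room, 0.8, 0.0, 20.0, cfg, seed=2)
    d = np.hypot(np.diff(t["x"]), np.diff(t["y"]))
    assert d.max() <= cfg.speed_mps / cfg.hz + 1e-9


def test_walker_never_in_inaccessible_cell(occluded_room):
    cfg = SimConfig()
    t = simulate_trajectory(occluded_room, 1.0, 0.5, 20.0, cfg, seed=4)
    hist = cm.bin_path(t, occluded_room)
    assert hist.n_samples_dropped == 0


def test_trajectory_preconditions(occluded_room):
    cfg = SimConfig()
    with pytest.raises(ValueError, match="duration_s"):
        simulate_trajectory(occluded_room, 0.0, 0.0, 0.0, cfg, seed=0)
    with pytest.raises(ValueError, match="finite"):
        simulate_trajectory(occluded_room, np.nan, 0.0, 5.0, cfg, seed=0)


def test_drive_raises_path_coverage(occluded_room):
    cfg = SimConfig()
    wins = 0
    for s in range(12):
        lo = simulate_trajectory(occluded_room, -1.5, 0.0, 30.0, cfg, seed=100 + s)
        hi = simulate_trajectory(occluded_room, +1.5, 0.0, 30.0, cfg, seed=100 + s)
        re_lo = cm.roaming_entropy(cm.bin_path(lo, occluded_room))
        re_hi = cm.roaming_entropy(cm.bin_path(hi, occluded_room))
        wins += re_hi > re_lo
    assert wins >= 10


def test_scan_rate_raises_head_coverage(occluded_room):
    cfg = SimConfig()
    wins = 0
    for s in range(12):
        lo = simulate_trajectory(occluded_room, 0.0, -1.5, 20.0, cfg, seed=200 + s)
        hi = simulate_trajectory(occluded_room, 0.0, +1.5, 20.0, cfg, seed=200 + s)
        wins += cm.roaming_entropy(cm.bin_head(hi)) > cm.roaming_entropy(cm.bin_head(lo))
    assert wins >= 10


def test_simconfig_validation():
    with pytest.raises(ValueError, match="hz"):
        SimConfig(hz=0)
    with pytest.raises(ValueError, match="latent_corr"):
        SimConfig(latent_corr=1.0)
    with pytest.raises(ValueError, match="rater_noise_sd"):
        SimConfig(rater_noise_sd=-0.1)


def test_cohort_shapes_and_validity(small_cohort):
    c = small_cohort
    n_trials = 6 * 4
    assert len(c.ratings) == n_trials
    assert len(c.sketch_scores) == 2 * n_trials
    assert len(c.traits) == 6
    assert c.ratings["curiosity"].between(1, 10).all()
    assert c.ratings["interest"].between(1, 10).all()
    for dim in ("OP", "SD", "RP", "SP"):
        v = c.sketch_scores[dim]
        assert v.between(1, 5).all()
        assert np.allclose(v * 2, np.round(v * 2))
    assert c.ground_truth["kind"] == "agent"


def test_cohort_deterministic():
    cfg = SimConfig(n_participants=2, n_rooms=2, duration_mean_s=8.0, seed=9)
    a = cm.generate_cohort(cfg)
    b = cm.generate_cohort(cfg)
    pd.testing.assert_frame_equal(a.trajectories, b.trajectories)
    pd.testing.assert_frame_equal(a.sketch_scores, b.sketch_scores)


def test_cohort_write_roundtrip(tmp_path, small_cohort):
    small_cohort.write(tmp_path / "ds")
    traj = cm.read_trajectories(tmp_path / "ds" / "trajectories.csv")
    assert set(traj["participant_id"]) == set(small_cohort.traits["participant_id"])
    masks = sorted((tmp_path / "ds" / "masks").glob("*.txt"))
    assert len(masks) == 4
    room = cm.read_mask(masks[0])
    assert np.array_equal(room.accessible, small_cohort.rooms[masks[0].stem].accessible)


def test_linear_cohort_ground_truth(linear_cohort):
    trials = linear_cohort["trials"]
    gt = linear_cohort["ground_truth"]
    assert len(trials) == 60 * 16
    assert gt["kind"] == "linear"
    assert gt["indirect_effect"] == pytest.approx(gt["b_cur_path"] * gt["b_path_map"])
    assert trials["path_re"].between(0.01, 0.99).all()
    assert trials["head_re"].between(0.01, 0.99).all()


def test_linear_cohort_generative_link():
    # regressing out the known structure should leave residuals at the recorded SD
    data = cm.generate_linear_cohort(40, 12, seed=8)
    trials, gt = data["trials"], data["ground_truth"]
    d = cm.build_design(trials, traits=data["traits"])
    resid = (
        d["path_re"]
        - gt["icpt_path"]
        - gt["b_cur_path"] * d["curiosity_w"]
        - gt["b_int_path"] * d["interest_w"]
        - gt["b_curm_path"] * d["curiosity_m"]
        - gt["b_dur_path"] * d["duration_c"]
    )
    # residual variance = random intercept + slope terms + noise; noise dominates
    assert resid.std() == pytest.approx(
        np.hypot(gt["sd_u_path"], gt["sd_e_path"]), rel=0.35
    )


def test_null_effects_zeroed():
    null = LinearEffects.null()
    assert null.b_cur_path == 0.0 and null.b_path_map == 0.0 and null.theta_st == 0.0
    assert null.sd_e_path == LinearEffects().sd_e_path  # noise scales untouched
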