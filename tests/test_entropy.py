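import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from curiomap.entropy import (
    HEAD_K,
    OccupancyHistogram,
    bin_head,
    bin_path,
    compute_trial_re,
    cumulative_re,
    re_table,
    roaming_entropy,
)
from curiomap.rooms import RoomGrid


def _hist(counts, k=None):
    counts = np.asarray(counts)
    return OccupancyHistogram(counts, k or counts.size, int(counts.sum()))


def _brute_force_re(counts, k):
    """Independent oracle: direct Shannon entropy over nonzero bins."""
    counts = np.asarray(counts, dtype=float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum() / np.log2(k))


def test_known_value_oracle():
    # counts [3, 1]: H = -(0.75 log2 0.75 + 0.25 log2 0.25) / log2 2
    assert roaming_entropy(_hist([3, 1])) == pytest.approx(0.8112781244591328, abs=1e-12)
    assert roaming_entropy(_hist([3, 1, 0, 0], k=4)) == pytest.approx(
        0.4056390622295664, abs=1e-12
    )


def test_uniform_is_one_single_bin_is_zero():
    assert roaming_entropy(_hist([5, 5, 5, 5])) == pytest.approx(1.0, abs=1e-12)
    assert roaming_entropy(_hist([7, 0, 0, 0], k=4)) == 0.0
    assert roaming_entropy(_hist([9], k=1)) == 0.0  # degenerate bin space


@given(st.lists(st.integers(0, 50), min_size=2, max_size=30).filter(lambda c: sum(c) > 0))
def test_matches_brute_force(counts):
    h = _hist(counts)
    assert roaming_entropy(h) == pytest.approx(_brute_force_re(counts, h.k), abs=1e-12)
    assert 0.0 <= roaming_entropy(h) <= 1.0 + 1e-12


@given(
    st.lists(st.integers(0, 50), min_size=2, max_size=30).filter(lambda c: sum(c) > 0),
    st.randoms(use_true_random=False),
)
def test_permutation_invariance(counts, rnd):
    shuffled = list(counts)
    rnd.shuffle(shuffled)
    assert roaming_entropy(_hist(counts)) == pytest.approx(
        roaming_entropy(_hist(shuffled)), abs=1e-12
    )


@given(st.lists(st.integers(1, 50), min_size=2, max_size=20))
def test_merging_bins_cannot_raise_unnormalised_entropy(counts):
    # merging the first two bins lowers (or keeps) -sum(p log p)
    k = len(counts)
    merged = [counts[0] + counts[1]] + list(counts[2:])
    h_full = roaming_entropy(_hist(counts)) * np.log2(k)
    h_merged = roaming_entropy(_hist(merged, k=max(2, k - 1))) * np.log2(max(2, k - 1))
    assert h_merged <= h_full + 1e-12


def test_histogram_invariants():
    with pytest.raises(ValueError, match="non-negative"):
        OccupancyHistogram(np.array([-1, 2]), 2, 1)
    with pytest.raises(ValueError, match="n_samples_used"):
        OccupancyHistogram(np.array([1, 2]), 2, 4)
    with pytest.raises(ValueError, match="k"):
        OccupancyHistogram(np.array([], dtype=int), 0, 0)
    with pytest.raises(ValueError, match="no samples"):
        roaming_entropy(OccupancyHistogram(np.zeros(3, dtype=int), 3, 0))


def test_bin_path_drops_inaccessible(open_room):
    mask = np.ones((32, 32), dtype=bool)
    mask[10, 10] = False
    room = RoomGrid("r", mask)
    samples = pd.DataFrame({"x": [5.25, 5.25, 1.0], "y": [5.25, 5.25, 1.0]})
    hist = bin_path(samples, room)
    assert hist.n_samples_dropped == 2  # cell (10, 10) is x=y=5.25
    assert hist.n_samples_used == 1
    assert hist.k == room.k_accessible == 1023


def test_bin_path_boundary_clamp(open_room):
    samples = pd.DataFrame({"x": [16.0], "y": [16.0]})
    hist = bin_path(samples, open_room)
    assert hist.n_samples_used == 1
    idx = open_room.flat_accessible_index()[31, 31]
    assert hist.counts[idx] == 1


def test_bin_path_rejects_out_of_room(open_room):
    with pytest.raises(ValueError, match="outside the room"):
        bin_path(pd.DataFrame({"x": [17.0], "y": [1.0]}), open_room)
    with pytest.raises(ValueError, match="no trajectory samples"):
        bin_path(pd.DataFrame({"x": [], "y": []}), open_room)


def test_bin_path_all_dropped_errors():
    mask = np.ones((4, 4), dtype=bool)
    mask[0, 0] = False
    room = RoomGrid("r", mask, side_m=2.0, cell_m=0.5)
    with pytest.raises(ValueError, match="inaccessible"):
        bin_path(pd.DataFrame({"x": [0.1], "y": [0.1]}), room)


def test_bin_head_k_and_clamp():
    samples = pd.DataFrame({"yaw": [-180.0, 0.0, 179.9], "pitch": [-90.0, 0.0, 90.0]})
    hist = bin_head(samples)
    assert hist.k == HEAD_K == 648
    assert hist.n_samples_used == 3
    # pitch exactly +90 clamps into the top row (17), yaw 179.9 -> col 35
    assert hist.counts[17 * 36 + 35] == 1
    assert hist.counts[0 * 36 + 0] == 1  # (-180, -90)
    assert hist.counts[9 * 36 + 18] == 1  # (0, 0)


def test_bin_head_rejects_out_of_range():
    with pytest.raises(ValueError, match="out of range"):
        bin_head(pd.DataFrame({"yaw": [180.0], "pitch": [0.0]}))
    with pytest.raises(ValueError, match="out of range"):
        bin_head(pd.DataFrame({"yaw": [0.0], "pitch": [91.0]}))


def test_head_re_rotation_invariance():
    # rotating all yaws by a multiple of the 10-degree bin width leaves RE unchanged
    rng = np.random.default_rng(0)
    yaw = rng.uniform(-180, 180, 500)
    pitch = rng.uniform(-90, 90, 500)
    base = roaming_entropy(bin_head(pd.DataFrame({"yaw": yaw, "pitch": pitch})))
    rot = (yaw + 180.0 + 90.0) % 360.0 - 180.0
    rotated = roaming_entropy(bin_head(pd.DataFrame({"yaw": rot, "pitch": pitch})))
    assert rotated == pytest.approx(base, abs=1e-12)


def test_compute_trial_re_and_percent(open_room):
    rng = np.random.default_rng(1)
    n = 400
    samples = pd.DataFrame(
        {
            "x": rng.uniform(0, 16, n),
            "y": rng.uniform(0, 16, n),
            "yaw": rng.uniform(-180, 179.9, n),
            "pitch": rng.uniform(-90, 90, n),
        }
    )
    res = compute_trial_re(samples, open_room)
    assert 0 < res.path_re < 1 and 0 < res.head_re < 1
    assert res.as_percent == (100 * res.path_re, 100 * res.head_re)


def test_cumulative_re_monotone_bin_count(open_room):
    # coverage of new cells cannot shrink, so early windows of a sweep have lower RE
    xs = np.linspace(0.25, 15.75, 240)
    samples = pd.DataFrame(
        {"x": xs, "y": np.full(240, 0.25), "yaw": np.zeros(240), "pitch": np.zeros(240)}
    )
    tab = cumulative_re(samples, open_room, every=60)
    assert list(tab["n_samples"]) == [60, 120, 180, 240]
    assert tab["path_re"].is_monotonic_increasing


def test_re_table_grouping_and_percent(open_room):
    traj = pd.DataFrame(
        {
            "participant_id": ["P1"] * 4 + ["P2"] * 4,
            "room_id": ["R1", "R1", "R2", "R2"] * 2,
            "t": [0.0, 1.0] * 4,
            "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            "y": [1.0] * 8,
            "yaw": [0.0, 10.0] * 4,
            "pitch": [0.0] * 8,
        }
    )
    rooms = {"R1": open_room, "R2": open_room}
    tab = re_table(traj, rooms)
    assert len(tab) == 4
    tab_pct = re_table(traj, rooms, percent=True)
    assert np.allclose(tab_pct["path_re"], 100 * tab["path_re"])
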