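"""Roaming entropy of trajectories and head directions.

Roaming entropy (RE) is the Shannon entropy of an agent's empirical occupancy
distribution over discrete bins, normalised by ``log2(k)`` so that 0 means all
time spent in a single bin and 1 means uniform coverage of all ``k`` bins.

Two variants are computed per trial:

* **path RE** — occupancy over the accessible cells of the room grid
  (``k`` = number of accessible 0.5 m cells);
* **head-direction RE** — occupancy over 10 deg x 10 deg yaw/pitch bins
  spanning yaw in [-180, 180) and pitch in [-90, 90], hence ``k`` = 648
  regardless of which bins are visited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rooms import RoomGrid

__all__ = [
    "HEAD_PITCH_BINS",
    "HEAD_YAW_BINS",
    "HEAD_K",
    "OccupancyHistogram",
    "REResult",
    "bin_path",
    "bin_head",
    "roaming_entropy",
    "compute_trial_re",
    "cumulative_re",
    "re_table",
]

HEAD_PITCH_BINS = 18
HEAD_YAW_BINS = 36
HEAD_K = HEAD_PITCH_BINS * HEAD_YAW_BINS  # 648 head-direction cells


@dataclass(frozen=True)
class OccupancyHistogram:
    """Counts of samples per bin plus the normalising bin count ``k``."""

    counts: np.ndarray
    k: int
    n_samples_used: int
    n_samples_dropped: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if np.any(counts < 0):
            raise ValueError("occupancy counts must be non-negative")
        if counts.sum() != self.n_samples_used:
            raise ValueError("sum(counts) must equal n_samples_used")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class REResult:
    """Path and head-direction roaming entropy of one trial."""

    path_re: float
    head_re: float
    path_hist: OccupancyHistogram
    head_hist: OccupancyHistogram

    @property
    def as_percent(self) -> tuple[float, float]:
        """(path, head) RE on the 0-100 scale."""
        return 100.0 * self.path_re, 100.0 * self.head_re


def roaming_entropy(hist: OccupancyHistogram) -> float:
    """Normalised Shannon entropy ``-sum(p log2 p) / log2 k`` of a histogram.

    Zero-count bins contribute nothing; a degenerate bin space (k == 1)
    returns 0 by convention since there is no roaming freedom.
    """
    if hist.n_samples_used < 1:
        raise ValueError("histogram holds no samples")
    if hist.k == 1:
        return 0.0
    counts = hist.counts[hist.counts > 0]
    p = counts / hist.n_samples_used
    h = -np.sum(p * np.log2(p))
    return float(h / np.log2(hist.k))


def bin_path(samples: pd.DataFrame, room: RoomGrid) -> OccupancyHistogram:
    """Project trajectory samples onto the room's accessible cells.

    ``samples`` needs columns ``x`` and ``y`` (metres, origin at the
    south-west corner).  Samples falling in inaccessible cells are dropped and
    reported in ``n_samples_dropped``; a coordinate exactly on the far wall is
    clamped into the last cell.
    """
    x = np.asarray(samples["x"], dtype=float)
    y = np.asarray(samples["y"], dtype=float)
    if x.size == 0:
        raise ValueError("no trajectory samples")
    if np.any(x < 0) or np.any(x > room.side_m) or np.any(y < 0) or np.any(y > room.side_m):
        bad = np.nonzero((x < 0) | (x > room.side_m) | (y < 0) | (y > room.side_m))[0]
        raise ValueError(f"coordinates outside the room at sample rows {bad[:5].tolist()}")
    n = room.n_cells_side
    col = np.minimum((x / room.cell_m).astype(int), n - 1)
    row = np.minimum((y / room.cell_m).astype(int), n - 1)
    flat = room.flat_accessible_index()
    idx = flat[row, col]
    used = idx >= 0
    n_dropped = int((~used).sum())
    if not used.any():
        raise ValueError("all samples fell in inaccessible cells; no usable occupancy")
    counts = np.bincount(idx[used], minlength=room.k_accessible)
    return OccupancyHistogram(counts, room.k_accessible, int(used.sum()), n_dropped)


def bin_head(samples: pd.DataFrame) -> OccupancyHistogram:
    """Project head-direction samples onto the 18 x 36 angular grid.

    ``yaw`` must lie in [-180, 180) (degrees, relative to the room's entry
    direction) and ``pitch`` in [-90, 90] (egocentric, 0 = forward); bin index
    is ``(floor((pitch+90)/10), floor((yaw+180)/10))`` with pitch exactly +90
    clamped into the top row.
    """
    yaw = np.asarray(samples["yaw"], dtype=float)
    pitch = np.asarray(samples["pitch"], dtype=float)
    if yaw.size == 0:
        raise ValueError("no head-direction samples")
    bad = (yaw < -180) | (yaw >= 180) | (pitch < -90) | (pitch > 90)
    if bad.any():
        rows = np.nonzero(bad)[0]
        raise ValueError(f"head direction out of range at sample rows {rows[:5].tolist()}")
    prow = np.minimum(((pitch + 90.0) / 10.0).astype(int), HEAD_PITCH_BINS - 1)
    ycol = ((yaw + 180.0) / 10.0).astype(int)
    idx = prow * HEAD_YAW_BINS + ycol
    counts = np.bincount(idx, minlength=HEAD_K)
    return OccupancyHistogram(counts, HEAD_K, int(yaw.size), 0)


def compute_trial_re(samples: pd.DataFrame, room: RoomGrid) -> REResult:
    """Path and head-direction RE of one trial, evaluated over the full trial."""
    path_hist = bin_path(samples, room)
    head_hist = bin_head(samples)
    return REResult(
        path_re=roaming_entropy(path_hist),
        head_re=roaming_entropy(head_hist),
        path_hist=path_hist,
        head_hist=head_hist,
    )


def cumulative_re(samples: pd.DataFrame, room: RoomGrid, every: int = 60) -> pd.DataFrame:
    """Path RE as a function of elapsed samples (one row per ``every`` samples).

    Not used by the default analyses, which evaluate one RE per room visit;
    provided for inspecting how coverage accrues within a trial.
    """
    out = []
    for stop in range(every, len(samples) + 1, every):
        hist = bin_path(samples.iloc[:stop], room)
        out.append({"n_samples": stop, "path_re": roaming_entropy(hist)})
    return pd.DataFrame(out)


def re_table(
    trajectories: pd.DataFrame,
    rooms: dict[str, RoomGrid],
    *,
    percent: bool = False,
) -> pd.DataFrame:
    """Per-trial RE table from a long trajectory frame.

    ``trajectories`` has columns participant_id, room_id, t, x, y, yaw, pitch.
    Returns one row per participant x room with path_re, head_re and the
    dropped-sample count; values are multiplied by 100 when ``percent``.
    """
    rows = []
    for (pid, rid), grp in trajectories.groupby(["participant_id", "room_id"], sort=True):
        room = rooms[str(rid)]
        res = compute_trial_re(grp, room)
        scale = 100.0 if percent else 1.0
        rows.append(
            {
                "participant_id": pid,
                "room_id": rid,
                "path_re": scale * res.path_re,
                "head_re": scale * res.head_re,
                "n_dropped": res.path_hist.n_samples_dropped,
            }
        )
    return pd.DataFrame(rows)
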