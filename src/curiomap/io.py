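"""On-disk formats: trajectory logs, ratings/traits/sketch tables, room masks.

All tables are UTF-8 comma-separated files with a header row and "." decimals.
Coordinates are metres with the origin at the south-west room corner (x east,
y north); yaw is in [-180, 180) relative to the room's entry direction and
pitch in [-90, 90] (egocentric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRAJ_COLUMNS = ["participant_id", "room_id", "t", "x", "y", "yaw", "pitch"]
RATING_COLUMNS = ["participant_id", "room_id", "room_label", "curiosity", "interest", "duration_s"]
TRAIT_COLUMNS = ["participant_id", "trait_JE", "trait_DS", "trait_ST", "trait_TS"]
SKETCH_COLUMNS = ["participant_id", "room_id", "rater_id", "OP", "SD", "RP", "SP"]

__all__ = [
    "Trial",
    "read_trajectories",
    "write_trajectories",
    "read_ratings",
    "read_traits",
    "read_sketch_scores",
    "read_tables",
    "assemble_trials",
]


@dataclass
class Trial:
    """One participant x room episode: ratings plus the trajectory samples."""

    participant_id: str
    room_id: str
    samples: pd.DataFrame  # columns t, x, y, yaw, pitch, time-sorted
    room_label: str = ""
    curiosity: int | None = None
    interest: int | None = None
    duration_s: float | None = None

    def __post_init__(self) -> None:
        for rating in (self.curiosity, self.interest):
            if rating is not None and not (1 <= rating <= 10):
                raise ValueError(f"ratings must be integers in [1, 10], got {rating}")


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def read_trajectories(path: str | Path, *, side_m: float = 16.0) -> pd.DataFrame:
    """Read and validate a trajectory log.

    Returns the long frame sorted by (participant_id, room_id, t).  Raises
    ``ValueError`` naming offending rows for missing columns, coordinates
    outside [0, side_m], out-of-range angles or non-monotone time within a
    trial.
    """
    df = pd.read_csv(path, comment="#")
    _require_columns(df, TRAJ_COLUMNS, f"{path}")
    df["participant_id"] = df["participant_id"].astype(str)
    df["room_id"] = df["room_id"].astype(str)

    bad = df.index[(df["yaw"] < -180) | (df["yaw"] >= 180)]
    if len(bad):
        raise ValueError(f"{path}: yaw outside [-180, 180) at rows {bad[:5].tolist()}")
    bad = df.index[(df["pitch"] < -90) | (df["pitch"] > 90)]
    if len(bad):
        raise ValueError(f"{path}: pitch outside [-90, 90] at rows {bad[:5].tolist()}")
    bad = df.index[(df[["x", "y"]] < 0).any(axis=1) | (df[["x", "y"]] > side_m).any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: coordinates outside [0, {side_m}] at rows {bad[:5].tolist()}")

    # validate time in file order (sorting afterwards would mask the defect)
    for (pid, rid), grp in df.groupby(["participant_id", "room_id"], sort=False):
        dt = np.diff(grp["t"].to_numpy())
        if np.any(dt < 0):
            raise ValueError(f"{path}: non-monotone time in trial ({pid}, {rid})")
    df = df.sort_values(["participant_id", "room_id", "t"], kind="stable").reset_index(drop=True)
    return df


def write_trajectories(df: pd.DataFrame, path: str | Path, *, header_note: str = "") -> None:
    """Write a trajectory frame; round-trips losslessly at 6-decimal precision."""
    _require_columns(df, TRAJ_COLUMNS, "trajectory frame")
    path = Path(path)
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, index=False, columns=TRAJ_COLUMNS, float_format="%.6f")


def read_ratings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, RATING_COLUMNS, f"{path}")
    df["participant_id"] = df["participant_id"].astype(str)
    df["room_id"] = df["room_id"].astype(str)
    for col in ("curiosity", "interest"):
        vals = df[col]
        bad = df.index[(vals < 1) | (vals > 10) | (vals != vals.round())]
        if len(bad):
            raise ValueError(f"{path}: {col} must be integers in [1, 10]; bad rows {bad[:5].tolist()}")
    _check_unique(df, ["participant_id", "room_id"], path)
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, TRAIT_COLUMNS, f"{path}")
    df["participant_id"] = df["participant_id"].astype(str)
    for col in TRAIT_COLUMNS[1:]:
        bad = df.index[(df[col] < 1) | (df[col] > 7) | ~np.isfinite(df[col])]
        if len(bad):
            raise ValueError(f"{path}: {col} must be finite in [1, 7]; bad rows {bad[:5].tolist()}")
    _check_unique(df, ["participant_id"], path)
    return df


def read_sketch_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, SKETCH_COLUMNS, f"{path}")
    df["participant_id"] = df["participant_id"].astype(str)
    df["room_id"] = df["room_id"].astype(str)
    df["rater_id"] = df["rater_id"].astype(str)
    for col in ("OP", "SD", "RP", "SP"):
        vals = df[col].to_numpy(dtype=float)
        on_grid = np.isclose(vals * 2, np.round(vals * 2))
        bad = df.index[(vals < 1) | (vals > 5) | ~on_grid]
        if len(bad):
            raise ValueError(
                f"{path}: {col} must be on the 0.5 grid in [1, 5]; bad rows {bad[:5].tolist()}"
            )
    _check_unique(df, ["participant_id", "room_id", "rater_id"], path)
    return df


def _check_unique(df: pd.DataFrame, keys: list[str], path) -> None:
    dup = df[df.duplicated(keys, keep=False)]
    if len(dup):
        pairs = dup[keys].drop_duplicates().to_records(index=False).tolist()
        raise ValueError(f"{path}: duplicate keys {pairs[:5]}")


def read_tables(
    ratings_path: str | Path,
    traits_path: str | Path | None = None,
    sketch_path: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Read the ratings table and optional traits / sketch-score tables."""
    out = {"ratings": read_ratings(ratings_path)}
    if traits_path is not None:
        out["traits"] = read_traits(traits_path)
    if sketch_path is not None:
        out["sketch"] = read_sketch_scores(sketch_path)
    return out


def assemble_trials(
    trajectories: pd.DataFrame,
    ratings: pd.DataFrame,
    *,
    duration_tol_s: float = 1.0,
) -> list[Trial]:
    """Join trajectory groups with their rating rows into ``Trial`` objects.

    Inner-join semantics on (participant_id, room_id); trials lacking ratings
    (or ratings lacking trajectories) are reported with a warning and excluded
    so downstream model stages see complete rows only.
    """
    traj_keys = set(map(tuple, trajectories[["participant_id", "room_id"]].drop_duplicates().values))
    rating_keys = set(map(tuple, ratings[["participant_id", "room_id"]].values))
    unmatched = traj_keys.symmetric_difference(rating_keys)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} participant x room keys lack a trajectory or rating "
            f"and are excluded: {sorted(unmatched)[:5]}",
            stacklevel=2,
        )
    rating_idx = ratings.set_index(["participant_id", "room_id"])
    trials = []
    for (pid, rid), grp in trajectories.groupby(["participant_id", "room_id"], sort=True):
        if (pid, rid) not in rating_keys:
            continue
        row = rating_idx.loc[(pid, rid)]
        samples = grp[["t", "x", "y", "yaw", "pitch"]].reset_index(drop=True)
        dur = float(row["duration_s"])
        if abs(samples["t"].iloc[-1] - dur) > duration_tol_s:
            warnings.warn(
                f"trial ({pid}, {rid}): last sample time {samples['t'].iloc[-1]:.2f}s "
                f"disagrees with stated duration {dur:.2f}s",
                stacklevel=2,
            )
        trials.append(
            Trial(
                participant_id=pid,
                room_id=rid,
                samples=samples,
                room_label=str(row["room_label"]),
                curiosity=int(row["curiosity"]),
                interest=int(row["interest"]),
                duration_s=dur,
            )
        )
    return trials
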