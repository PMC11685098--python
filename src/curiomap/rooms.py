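"""Room occupancy grids.

A room is a square arena discretised into a regular grid of cells (default
16 m x 16 m at 0.5 m resolution, i.e. 32 x 32 cells).  Cells occluded by
furniture are marked inaccessible; the count of accessible cells ``k`` is the
normalising constant of path roaming entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RoomGrid", "generate_room", "read_mask", "write_mask"]


@dataclass(frozen=True)
class RoomGrid:
    """Accessibility mask of one room on a metric grid.

    Attributes
    ----------
    room_id : str
        Identifier of the room.
    side_m : float
        Side length of the (square) room in metres.
    cell_m : float
        Cell edge length in metres.
    accessible : np.ndarray
        Boolean mask, shape ``(n_cells_side, n_cells_side)``; ``[row, col]``
        indexes ``(y, x)`` with the origin at the south-west corner.
    """

    room_id: str
    accessible: np.ndarray
    side_m: float = 16.0
    cell_m: float = 0.5
    entry_cell: tuple[int, int] | None = None  # (row, col) of the doorway

    def __post_init__(self) -> None:
        mask = np.asarray(self.accessible, dtype=bool)
        object.__setattr__(self, "accessible", mask)
        if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
            raise ValueError("accessibility mask must be square")
        n = mask.shape[0]
        if not np.isclose(n * self.cell_m, self.side_m):
            raise ValueError(
                f"grid geometry inconsistent: {n} cells x {self.cell_m} m "
                f"!= side {self.side_m} m"
            )
        if mask.sum() < 1:
            raise ValueError("room must contain at least one accessible cell")

    @property
    def n_cells_side(self) -> int:
        return self.accessible.shape[0]

    @property
    def k_accessible(self) -> int:
        """Number of accessible cells (the ``k`` of path roaming entropy)."""
        return int(self.accessible.sum())

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Map metric coordinates to a (row, col) cell.

        Cells are half-open; a coordinate exactly on the far wall is clamped
        into the last cell so boundary samples are never lost.
        """
        n = self.n_cells_side
        col = min(int(np.floor(x / self.cell_m)), n - 1)
        row = min(int(np.floor(y / self.cell_m)), n - 1)
        return row, col

    def flat_accessible_index(self) -> np.ndarray:
        """Map (row, col) -> position in the accessible-cell enumeration, -1 elsewhere."""
        flat = -np.ones(self.accessible.shape, dtype=int)
        flat[self.accessible] = np.arange(self.k_accessible)
        return flat


def _connected(mask: np.ndarray) -> bool:
    """True if the accessible region forms a single 4-connected component."""
    from scipy import ndimage

    if mask.sum() == 0:
        return False
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n_comp = ndimage.label(mask, structure=structure)
    return n_comp == 1


def _default_entry(n: int) -> tuple[int, int]:
    # doorway at the middle of the south wall
    return (0, n // 2)


def generate_room(
    seed: int | np.random.Generator,
    occlusion_fraction: float = 0.3,
    *,
    room_id: str = "room",
    n_cells_side: int = 32,
    cell_m: float = 0.5,
    max_tries: int = 200,
) -> RoomGrid:
    """Generate a room whose occluded cells form furniture-like rectangular blobs.

    Rectangles are placed by rejection sampling until roughly
    ``occlusion_fraction`` of the grid is occluded while the accessible region
    stays 4-connected and the entry cell stays free.

    Raises
    ------
    ValueError
        If ``occlusion_fraction`` is outside [0, 0.6].
    RuntimeError
        If a connected layout cannot be found within ``max_tries`` attempts.
    """
    if not 0.0 <= occlusion_fraction <= 0.6:
        raise ValueError(
            f"occlusion_fraction must be in [0, 0.6], got {occlusion_fraction}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = n_cells_side
    entry = _default_entry(n)
    side_m = n * cell_m

    if occlusion_fraction == 0.0:
        mask = np.ones((n, n), dtype=bool)
        return RoomGrid(room_id, mask, side_m, cell_m, entry)

    target = int(round(occlusion_fraction * n * n))
    for _ in range(max_tries):
        mask = np.ones((n, n), dtype=bool)
        occluded = 0
        stale = 0
        while occluded < target and stale < 400:
            h = int(rng.integers(1, max(2, n // 4)))
            w = int(rng.integers(1, max(2, n // 4)))
            r0 = int(rng.integers(0, n - h + 1))
            c0 = int(rng.integers(0, n - w + 1))
            trial = mask.copy()
            trial[r0 : r0 + h, c0 : c0 + w] = False
            if not trial[entry] or not _connected(trial):
                stale += 1
                continue
            gained = int(mask.sum() - trial.sum())
            if gained == 0:
                stale += 1
                continue
            mask = trial
            occluded += gained
        if occluded >= int(0.9 * target):
            return RoomGrid(room_id, mask, side_m, cell_m, entry)
    raise RuntimeError(
        f"could not occlude {occlusion_fraction:.0%} of the grid while keeping "
        "the accessible region connected; lower occlusion_fraction"
    )


def read_mask(path: str | Path, *, room_id: str | None = None, cell_m: float = 0.5) -> RoomGrid:
    """Read a plain-text 0/1 accessibility grid.

    Each line holds one grid row of whitespace-separated 0/1 tokens; row 0 is
    the south edge.  Raises ``ValueError`` on ragged rows or non-binary tokens.
    """
    path = Path(path)
    rows: list[list[int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        vals = []
        for tok in tokens:
            if tok not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: non-binary token {tok!r}")
            vals.append(int(tok))
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty mask file")
    width = len(rows[0])
    for i, r in enumerate(rows, start=1):
        if len(r) != width:
            raise ValueError(f"{path}: ragged row {i} (expected {width} columns, got {len(r)})")
    if len(rows) != width:
        raise ValueError(f"{path}: mask must be square, got {len(rows)} x {width}")
    mask = np.array(rows, dtype=bool)
    rid = room_id or path.stem.replace(".mask", "")
    return RoomGrid(rid, mask, side_m=width * cell_m, cell_m=cell_m)


def write_mask(room: RoomGrid, path: str | Path) -> None:
    """Write the 0/1 grid of ``room``; inverse of :func:`read_mask`."""
    path = Path(path)
    lines = [" ".join("1" if v else "0" for v in row) for row in room.accessible]
    path.write_text("\n".join(lines) + "\n")
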