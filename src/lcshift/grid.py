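"""Canonical Humphrey 24-2 test-point layout in right-eye orientation.

Points sit on a 6-degree lattice: rows at y = +/-3, +/-9, +/-15, +/-21 degrees
of visual angle, with the nasal edge column (x = -27; temporal field = +x for
a right eye) present only on the two rows straddling the horizontal meridian.
The two points at (+15, +/-3) cover the physiologic blind spot and are never
scored. That leaves 52 scoreable locations, 26 per hemifield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridPoint", "Grid242", "build_grid_242"]

_ROW_X = {
    21: (-9, -3, 3, 9),
    15: (-15, -9, -3, 3, 9, 15),
    9: (-21, -15, -9, -3, 3, 9, 15, 21),
    3: (-27, -21, -15, -9, -3, 3, 9, 15, 21),
}
_BLIND_SPOT = {(15, 3), (15, -3)}


@dataclass(frozen=True)
class GridPoint:
    index: int
    x_deg: int
    y_deg: int
    hemifield: str  # superior | inferior
    blind_spot: bool


@dataclass(frozen=True)
class Grid242:
    points: tuple[GridPoint, ...]

    @property
    def scoreable(self) -> tuple[GridPoint, ...]:
        return tuple(p for p in self.points if not p.blind_spot)

    def scoreable_indices(self, hemifield: str | None = None) -> list[int]:
        return [
            p.index
            for p in self.points
            if not p.blind_spot and (hemifield is None or p.hemifield == hemifield)
        ]

    def adjacency(self, connectivity: int = 8) -> dict[int, frozenset[int]]:
        """Neighbour map over scoreable points of one 24-2 exam.

        Neighbours are lattice points one 6-degree step apart; with
        ``connectivity=8`` diagonal steps count as well. Pairs never span the
        horizontal meridian and blind-spot points have no neighbours, so
        connected components of abnormal points are always confined to a
        single hemifield.
        """
        if connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        by_pos = {(p.x_deg, p.y_deg): p for p in self.points}
        if connectivity == 4:
            steps = [(-6, 0), (6, 0), (0, -6), (0, 6)]
        else:
            steps = [
                (dx, dy)
                for dx in (-6, 0, 6)
                for dy in (-6, 0, 6)
                if (dx, dy) != (0, 0)
            ]
        adj: dict[int, set[int]] = {p.index: set() for p in self.points if not p.blind_spot}
        for p in self.points:
            if p.blind_spot:
                continue
            for dx, dy in steps:
                q = by_pos.get((p.x_deg + dx, p.y_deg + dy))
                if q is None or q.blind_spot or q.hemifield != p.hemifield:
                    continue
                adj[p.index].add(q.index)
        return {i: frozenset(s) for i, s in adj.items()}


def build_grid_242() -> Grid242:
    """Deterministic 24-2 layout (54 points, 2 blind-spot, 26+26 scoreable)."""
    pts: list[GridPoint] = []
    idx = 0
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        for x in _ROW_X[abs(y)]:
            pts.append(
                GridPoint(
                    index=idx,
                    x_deg=x,
                    y_deg=y,
                    hemifield="superior" if y > 0 else "inferior",
                    blind_spot=(x, y) in _BLIND_SPOT,
                )
            )
            idx += 1
    grid = Grid242(points=tuple(pts))
    assert len(grid.points) == 54 and len(grid.scoreable) == 52
    return grid


def scoreable_column_names(grid: Grid242) -> list[str]:
    """CSV column names for the 52 scoreable points, e.g. ``pd_x-9_y+3``."""
    return [f"pd_x{p.x_deg:+d}_y{p.y_deg:+d}" for p in grid.scoreable]
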