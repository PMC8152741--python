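"""Rectangular tract tessellations with queen-contiguity adjacency.

The statistics downstream of the tessellation (spatial weights, Moran/Geary
indices, SAR fits) depend only on the adjacency structure, so a grid of unit
squares is a faithful stand-in for irregular administrative polygons.
Coordinates are abstract planar units, not geodetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from shapely.geometry import Polygon, mapping, shape

__all__ = ["Tessellation", "make_tessellation"]


@dataclass
class Tessellation:
    """A set of tract polygons plus queen adjacency.

    Attributes
    ----------
    tract_ids : list of int
        Integer labels, one per polygon.
    polygons : dict
        Maps tract id to a shapely ``Polygon``.
    adjacency : set of (int, int)
        Unordered neighbor pairs stored as sorted tuples; symmetric by
        construction and never reflexive.
    """

    tract_ids: list[int]
    polygons: dict[int, Polygon]
    adjacency: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for a, b in self.adjacency:
            if a == b:
                raise ValueError(f"self-neighbor pair ({a}, {b})")
            if a > b:
                raise ValueError("adjacency pairs must be stored as (low, high)")
        self._check_isolates()

    def _check_isolates(self) -> None:
        if len(self.tract_ids) < 2:
            return
        touched = {t for pair in self.adjacency for t in pair}
        isolates = set(self.tract_ids) - touched
        if isolates:
            raise ValueError(f"tracts without neighbors: {sorted(isolates)}")

    @property
    def n_tracts(self) -> int:
        return len(self.tract_ids)

    def neighbors(self, tract_id: int) -> list[int]:
        out = []
        for a, b in self.adjacency:
            if a == tract_id:
                out.append(b)
            elif b == tract_id:
                out.append(a)
        return sorted(out)

    def to_geojson(self, path: str | Path) -> None:
        """Write the polygons as a GeoJSON FeatureCollection with a
        ``tract_id`` property."""
        features = [
            {
                "type": "Feature",
                "properties": {"tract_id": int(tid)},
                "geometry": mapping(self.polygons[tid]),
            }
            for tid in self.tract_ids
        ]
        doc = {"type": "FeatureCollection", "features": features}
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "Tessellation":
        """Read polygons from GeoJSON and derive queen adjacency from
        polygon contact (shared boundary points)."""
        doc = json.loads(Path(path).read_text())
        polygons = {
            int(f["properties"]["tract_id"]): shape(f["geometry"])
            for f in doc["features"]
        }
        ids = sorted(polygons)
        adjacency = set()
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if polygons[a].intersects(polygons[b]):
                    adjacency.add((a, b))
        return cls(tract_ids=ids, polygons=polygons, adjacency=adjacency)

    def write_edgelist(self, path: str | Path) -> None:
        lines = [f"{a}\t{b}" for a, b in sorted(self.adjacency)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def adjacency_from_edgelist(cls, path: str | Path) -> set[tuple[int, int]]:
        pairs = set()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            a, b = (int(tok) for tok in line.split())
            pairs.add((min(a, b), max(a, b)))
        return pairs


def make_tessellation(rows: int, cols: int) -> Tessellation:
    """Build a ``rows`` x ``cols`` grid of unit-square tracts.

    Tract ids run row-major from 0. Adjacency follows the queen rule: two
    cells are neighbors if they share an edge or a corner.

    Raises
    ------
    ValueError
        If either dimension is non-positive.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {rows}x{cols}")
    ids = list(range(rows * cols))
    polygons = {}
    adjacency: set[tuple[int, int]] = set()
    for r in range(rows):
        for c in range(cols):
            tid = r * cols + c
            polygons[tid] = Polygon(
                [(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)]
            )
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        nid = rr * cols + cc
                        adjacency.add((min(tid, nid), max(tid, nid)))
    return Tessellation(tract_ids=ids, polygons=polygons, adjacency=adjacency)
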