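"""Polygonal tissue mesh on a doubly periodic domain.

A :class:`TissueState` stores vertices, cells (as oriented vertex cycles)
and derives the junction set from the cycles.  All geometry respects the
torus topology: polygon areas, perimeters and centroids are computed after
minimum-image unwrapping of each cell's cycle, so cells remain contiguous
even when they straddle the periodic seam.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

# Mechanical cell classes.  "outside" cells are generic cells beyond the
# sensory region; "top_boundary" cells are relabelled outside cells that
# border the OHC region once the compaction stage has finished.
CELL_CLASSES = ("HC", "SC", "IHC", "pillar", "top_boundary", "outside")

# Classes treated as borders when selecting HCs for statistics: a HC
# touching any of these is excluded from order-parameter aggregates.
BOUNDARY_CLASSES = frozenset({"pillar", "IHC", "top_boundary", "outside"})

# cell classes eligible for T2 by default (delaminations are restricted
# to cells with SC morphology; HC removal is opt-in)
T2_DEFAULT_CLASSES = frozenset({"SC", "outside", "top_boundary"})
# junctions touching these classes never intercalate (fixed boundary rows)
T1_PROTECTED_CLASSES = frozenset({"pillar", "IHC"})


class TopologyError(RuntimeError):
    """Raised when a mesh operation would corrupt the cell complex."""


@dataclass
class Domain:
    """Rectangular doubly periodic box ``[0, Lx) x [0, Ly)``."""

    Lx: float
    Ly: float

    @property
    def size(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly])

    def wrap(self, p: np.ndarray) -> np.ndarray:
        return np.mod(p, self.size)

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Displacement(s) mapped into ``[-L/2, L/2)`` per axis."""
        L = self.size
        return d - L * np.round(d / L)


@dataclass
class Cell:
    vertices: list[int]
    cls: str = "SC"
    alive: bool = True
    region: str | None = None


def edge_key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class TissueState:
    """The mutable polygonal mesh advanced by the simulator.

    ``gamma_overrides`` (per physical junction), ``a0_overrides`` and
    ``contractility_overrides`` (per cell) let protocols perturb single
    elements (lattice disordering, ablation) without touching the global
    parameter set.
    """

    vertices: dict[int, np.ndarray]
    cells: dict[int, Cell]
    domain: Domain
    pillar_y: float = 0.0
    gamma_overrides: dict[tuple[int, int], float] = field(default_factory=dict)
    a0_overrides: dict[int, float] = field(default_factory=dict)
    contractility_overrides: dict[int, float] = field(default_factory=dict)

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    def alive_cells(self) -> dict[int, Cell]:
        return {cid: c for cid, c in self.cells.items() if c.alive}

    def junctions(self) -> dict[tuple[int, int], list[int]]:
        """Map each physical junction to the (two) incident cell ids."""
        out: dict[tuple[int, int], list[int]] = {}
        for cid, cell in self.cells.items():
            if not cell.alive:
                continue
            vs = cell.vertices
            for a, b in zip(vs, vs[1:] + vs[:1]):
                out.setdefault(edge_key(a, b), []).append(cid)
        return out

    def junction_length(self, key: tuple[int, int]) -> float:
        d = self.domain.min_image(self.vertices[key[1]] - self.vertices[key[0]])
        return float(np.hypot(*d))

    def cell_polygon(self, cid: int) -> np.ndarray:
        """Unwrapped (contiguous) vertex coordinates of a cell, shape (k, 2)."""
        cell = self.cells[cid]
        vs = cell.vertices
        if len(vs) < 3:
            raise TopologyError(f"cell {cid} has a degenerate cycle of {len(vs)} vertices")
        pts = np.empty((len(vs), 2))
        pts[0] = self.vertices[vs[0]]
        for k in range(1, len(vs)):
            step = self.domain.min_image(self.vertices[vs[k]] - self.vertices[vs[k - 1]])
            pts[k] = pts[k - 1] + step
        return pts

    def cell_area(self, cid: int) -> float:
        pts = self.cell_polygon(cid)
        x, y = pts[:, 0], pts[:, 1]
        a = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        return float(abs(a))

    def cell_signed_area(self, cid: int) -> float:
        pts = self.cell_polygon(cid)
        x, y = pts[:, 0], pts[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def cell_perimeter(self, cid: int) -> float:
        pts = self.cell_polygon(cid)
        d = np.roll(pts, -1, axis=0) - pts
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def cell_centroid(self, cid: int, wrap: bool = True) -> np.ndarray:
        """Arithmetic mean of the cell's (unwrapped) vertex positions."""
        c = self.cell_polygon(cid).mean(axis=0)
        return self.domain.wrap(c) if wrap else c

    def neighbors(self, cid: int) -> list[int]:
        """Cells sharing at least one junction with ``cid``."""
        mine = set()
        vs = self.cells[cid].vertices
        for a, b in zip(vs, vs[1:] + vs[:1]):
            mine.add(edge_key(a, b))
        out = []
        for other, cell in self.cells.items():
            if other == cid or not cell.alive:
                continue
            ovs = cell.vertices
            for a, b in zip(ovs, ovs[1:] + ovs[:1]):
                if edge_key(a, b) in mine:
                    out.append(other)
                    break
        return out

    def adjacency(self) -> dict[int, set[int]]:
        """Junction-sharing adjacency over all alive cells (single pass)."""
        adj: dict[int, set[int]] = {cid: set() for cid in self.alive_cells()}
        for cells in self.junctions().values():
            if len(cells) == 2:
                a, b = cells
                adj[a].add(b)
                adj[b].add(a)
        return adj

    def vertex_cells(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for cid, cell in self.alive_cells().items():
            for v in cell.vertices:
                out.setdefault(v, []).append(cid)
        return out

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def audit(self) -> None:
        """Validate the closed-2-complex invariants; raise TopologyError."""
        juncs = self.junctions()
        for key, cells in juncs.items():
            if len(cells) != 2:
                raise TopologyError(f"junction {key} shared by {len(cells)} cells")
        nV = len({v for c in self.alive_cells().values() for v in c.vertices})
        nE = len(juncs)
        nF = len(self.alive_cells())
        if nV - nE + nF != 0:
            raise TopologyError(f"Euler relation violated: V-E+F = {nV - nE + nF}")
        for cid, cell in self.alive_cells().items():
            if len(cell.vertices) < 3:
                raise TopologyError(f"cell {cid} has <3 vertices")
            if len(set(cell.vertices)) != len(cell.vertices):
                raise TopologyError(f"cell {cid} repeats a vertex")
            if self.cell_signed_area(cid) <= 0:
                raise TopologyError(f"cell {cid} has non-positive signed area")
            closure = np.zeros(2)
            vs = cell.vertices
            for a, b in zip(vs, vs[1:] + vs[:1]):
                closure += self.domain.min_image(self.vertices[b] - self.vertices[a])
            if np.abs(closure).max() > 1e-6:
                raise TopologyError(f"cell {cid} cycle does not close on the torus")

    # ------------------------------------------------------------------
    # bookkeeping
    # ------------------------------------------------------------------
    def copy(self) -> "TissueState":
        return TissueState(
            vertices={v: p.copy() for v, p in self.vertices.items()},
            cells={cid: Cell(list(c.vertices), c.cls, c.alive, c.region)
                   for cid, c in self.cells.items()},
            domain=Domain(self.domain.Lx, self.domain.Ly),
            pillar_y=self.pillar_y,
            gamma_overrides=dict(self.gamma_overrides),
            a0_overrides=dict(self.a0_overrides),
            contractility_overrides=dict(self.contractility_overrides),
        )

    def new_vertex_id(self) -> int:
        return max(self.vertices) + 1 if self.vertices else 0

    def drop_unused_vertices(self) -> None:
        used = {v for c in self.alive_cells().values() for v in c.vertices}
        for v in list(self.vertices):
            if v not in used:
                del self.vertices[v]

    # ------------------------------------------------------------------
    # serialization (plain dict; JSON writing lives in corti_vertex.io)
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "domain": {"Lx": self.domain.Lx, "Ly": self.domain.Ly},
            "pillar_y": self.pillar_y,
            "vertices": {str(v): [float(p[0]), float(p[1])]
                         for v, p in self.vertices.items()},
            "cells": {
                str(cid): {
                    "vertices": list(map(int, c.vertices)),
                    "cls": c.cls,
                    "alive": bool(c.alive),
                    "region": c.region,
                }
                for cid, c in self.cells.items()
            },
            "gamma_overrides": [[int(a), int(b), float(g)]
                                for (a, b), g in self.gamma_overrides.items()],
            "a0_overrides": {str(c): float(v) for c, v in self.a0_overrides.items()},
            "contractility_overrides": {str(c): float(v)
                                        for c, v in self.contractility_overrides.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueState":
        state = cls(
            vertices={int(v): np.asarray(p, dtype=float)
                      for v, p in d["vertices"].items()},
            cells={int(cid): Cell(list(cd["vertices"]), cd["cls"],
                                  cd.get("alive", True), cd.get("region"))
                   for cid, cd in d["cells"].items()},
            domain=Domain(float(d["domain"]["Lx"]), float(d["domain"]["Ly"])),
            pillar_y=float(d.get("pillar_y", 0.0)),
            gamma_overrides={(int(a), int(b)): float(g)
                             for a, b, g in d.get("gamma_overrides", [])},
            a0_overrides={int(c): float(v)
                          for c, v in d.get("a0_overrides", {}).items()},
            contractility_overrides={int(c): float(v)
                                     for c, v in d.get("contractility_overrides", {}).items()},
        )
        for cd in state.cells.values():
            for v in cd.vertices:
                if v not in state.vertices:
                    raise ValueError(f"cell references missing vertex {v}")
        return state
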