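"""Deterministic canonical fixtures for tests and examples.

All fixtures are built programmatically; none are read from disk.
"""

from __future__ import annotations

import math

import numpy as np

from .analysis import CentroidSet
from .initial import hexagonal_lattice
from .mesh import Cell, Domain, TissueState
from .params import RegionSpec


def make_fixture(kind: str, **kw):
    """Dispatch on fixture kind: hex | checkerboard-strip | pinwheel |
    stretched-hexagon | spiral-arc."""
    builders = {
        "hex": hex_lattice,
        "checkerboard-strip": checkerboard_strip,
        "pinwheel": pinwheel,
        "stretched-hexagon": stretched_hexagon,
        "spiral-arc": spiral_arc,
    }
    if kind not in builders:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return builders[kind](**kw)


def hex_lattice(rows: int = 6, cols: int = 6, side: float = 1.0) -> TissueState:
    """Plain periodic hexagonal lattice of SC cells (no region stripes)."""
    spec = RegionSpec.model_construct(rows=rows, cols=cols, side=side,
                                      outside_bottom=1, ihc_rows=1,
                                      pillar_rows=1,
                                      ohc_rows=max(0, rows - 4))
    return hexagonal_lattice(spec)


def checkerboard_strip(cols: int = 8, side: float = 1.0) -> TissueState:
    """Perfect checkerboard on a periodic square grid.

    Six cell rows: pillar | three checkerboard OHC rows | top boundary |
    outside.  Middle-row HCs have exactly four SC neighbours by
    construction.  Vertices are 4-valent; the fixture is for analysis
    functions, not for T1/T2 dynamics.
    """
    if cols % 2:
        raise ValueError("cols must be even for a periodic checkerboard")
    rows = 6
    s = side
    vid = lambda r, c: (r % rows) * cols + (c % cols)
    vertices = {vid(r, c): np.array([c * s, r * s])
                for r in range(rows) for c in range(cols)}
    cells: dict[int, Cell] = {}
    for r in range(rows):
        for c in range(cols):
            cyc = [vid(r, c), vid(r, c + 1), vid(r + 1, c + 1), vid(r + 1, c)]
            if r == 0:
                cls, region = "pillar", "pillar"
            elif r in (1, 2, 3):
                cls = "HC" if (r + c) % 2 == 0 else "SC"
                region = "OHC"
            elif r == 4:
                cls, region = "top_boundary", "outside_top"
            else:
                cls, region = "outside", "outside_top"
            cells[r * cols + c] = Cell(vertices=cyc, cls=cls, region=region)
    state = TissueState(vertices=vertices, cells=cells,
                        domain=Domain(cols * s, rows * s),
                        pillar_y=1.0 * s)
    state.audit()
    return state


def pinwheel(side: float = 1.0) -> tuple[TissueState, tuple[int, int]]:
    """A periodic hexagonal patch plus a designated interior junction whose
    four surrounding cells are distinct: the canonical T1 test case."""
    state = hex_lattice(rows=4, cols=4, side=side)
    juncs = state.junctions()
    vcells = state.vertex_cells()
    for key, owners in sorted(juncs.items()):
        around = set(owners)
        for v in key:
            around.update(vcells[v])
        if len(around) == 4:
            return state, key
    raise RuntimeError("no pinwheel junction found")  # pragma: no cover


def stretched_hexagon(r: float = 1.8, spacing: float = 1.0,
                      jitter: float = 0.0,
                      rng: np.random.Generator | None = None) -> CentroidSet:
    """A central HC and six HC neighbours on a regular hexagon stretched
    by ``r`` along x (the row axis); optional isotropic jitter.

    The two same-row neighbours and the centre carry the OHC2 label, so
    the main-axis line fit recovers the stretch axis.
    """
    ang = np.arange(6) * math.pi / 3.0
    pts = np.column_stack([np.cos(ang), np.sin(ang)]) * spacing
    pts[:, 0] *= r
    pts = np.vstack([[0.0, 0.0], pts])
    if jitter > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        pts = pts + rng.normal(0.0, jitter, pts.shape)
    row = np.array(["OHC2", "OHC2", "OHC3", "OHC3", "OHC2", "OHC1", "OHC1"],
                   dtype=object)
    return CentroidSet(ids=np.arange(7), cls=np.array(["HC"] * 7, dtype=object),
                       xy=pts, row=row)


def spiral_arc(n: int = 40, radius: float = 40.0,
               arc_spacing: float = 1.0) -> CentroidSet:
    """HC centroids on a circular arc with fixed arc-length spacing; the
    straightening routine should map them onto the x-axis.  The subtended
    angle must stay below 90 degrees so the base-to-apex walk is monotone
    in x."""
    dtheta = arc_spacing / radius
    theta = np.arange(n) * dtheta
    xy = np.column_stack([radius * np.sin(theta),
                          radius * (1.0 - np.cos(theta))])
    return CentroidSet(ids=np.arange(n),
                       cls=np.array(["HC"] * n, dtype=object),
                       xy=xy,
                       row=np.array(["OHC2"] * n, dtype=object))
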