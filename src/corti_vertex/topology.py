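"""T1 (intercalation) and T2 (delamination) transitions.

A T1 initiates when a junction shrinks below the threshold length: the
junction collapses to its midpoint and re-extends perpendicular at a
length slightly above the threshold, swapping the neighbour relationship
of the four surrounding cells.  A freshly transitioned junction is locked
out of further T1s for a relaxation window.  A T2 removes a cell whose
area falls below the threshold area; polygons are first shrunk to
triangles through forced T1s, then the triangle's vertices merge at its
centroid.  On the 3-valent meshes produced here, both moves preserve
3-valence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import (
    T1_PROTECTED_CLASSES as _T1_PROTECTED_CLASSES,
    T2_DEFAULT_CLASSES as _T2_DEFAULT_CLASSES,
    TissueState,
    TopologyError,
    edge_key,
)
from .params import ModelParams


@dataclass
class TopologyEvent:
    kind: str                       # "T1" | "T2" | "differentiation"
    step: int
    cells: tuple[int, ...]
    junction: tuple[int, int] | None
    cell: int | None
    location: tuple[float, float]


def find_t1_candidates(state: TissueState, params: ModelParams,
                       lockouts: dict[tuple[int, int], int] | None = None,
                       step: int = 0) -> list[tuple[int, int]]:
    """Sub-threshold junctions eligible for a T1, shortest first."""
    lockouts = lockouts or {}
    out = []
    for key, cells in state.junctions().items():
        if lockouts.get(key, -1) > step:
            continue
        if any(state.cells[c].cls in _T1_PROTECTED_CLASSES for c in cells):
            continue
        l = state.junction_length(key)
        if l < params.thresholds.l_min:
            out.append((l, key))
    return [key for _, key in sorted(out)]


def find_t2_candidates(state: TissueState, params: ModelParams) -> list[int]:
    """Sub-threshold-area cells eligible for delamination, smallest first."""
    eligible = set(_T2_DEFAULT_CLASSES)
    if params.thresholds.hc_t2_allowed:
        eligible.add("HC")
    out = []
    for cid, cell in state.alive_cells().items():
        if cell.cls not in eligible:
            continue
        a = state.cell_area(cid)
        if a < params.thresholds.A_min:
            out.append((a, cid))
    return [cid for _, cid in sorted(out)]


def _vertex_valence(state: TissueState, v: int) -> int:
    return sum(v in c.vertices for c in state.alive_cells().values())


def _has_edge(cycle: list[int], a: int, b: int) -> bool:
    k = len(cycle)
    for i in range(k):
        if {cycle[i], cycle[(i + 1) % k]} == {a, b}:
            return True
    return False


def _replace_vertex_pair(cycle: list[int], x: int, y: int, w: int) -> list[int]:
    """Replace the cyclically consecutive pair (x, y) (either order) by w."""
    k = len(cycle)
    for i in range(k):
        if {cycle[i], cycle[(i + 1) % k]} == {x, y}:
            rot = cycle[i:] + cycle[:i]
            return [w] + rot[2:]
    raise TopologyError(f"pair ({x},{y}) not consecutive in cycle")


def apply_t1(state: TissueState, junction: tuple[int, int],
             params: ModelParams, step: int = 0) -> TopologyEvent | None:
    """Execute a T1 on ``junction``; returns the event, or None if skipped.

    Both endpoints must be 3-valent; higher-valence endpoints are skipped
    with a warning.  The four surrounding polygons are validated after the
    rewiring; if either topological assignment inverts a polygon the move
    is rolled back and skipped.
    """
    a, b = junction
    key = edge_key(a, b)
    vcells = state.vertex_cells()
    owners = [c for c in vcells.get(a, ()) if c in vcells.get(b, ())
              and _has_edge(state.cells[c].vertices, a, b)]
    if len(owners) != 2:
        raise TopologyError(f"junction {key} is not an interior junction")
    P, Q = owners
    if len(vcells[a]) != 3 or len(vcells[b]) != 3:
        warnings.warn(f"T1 on {key} skipped: endpoint valence != 3")
        return None
    C = next(c for c in vcells[a] if c not in (P, Q))
    D = next(c for c in vcells[b] if c not in (P, Q))
    if C == D:
        warnings.warn(f"T1 on {key} skipped: flanking cells coincide")
        return None

    dom = state.domain
    pa, pb = state.vertices[a], state.vertices[b]
    d = dom.min_image(pb - pa)
    ln = np.hypot(*d)
    if ln == 0:
        dhat = np.array([1.0, 0.0])
    else:
        dhat = d / ln
    phat = np.array([-dhat[1], dhat[0]])
    m = pa + d / 2
    h0 = 0.5 * params.thresholds.l_new_factor * params.thresholds.l_min

    cP = dom.min_image(state.cell_centroid(P, wrap=False) - m)
    kp = a if float(np.dot(cP, phat)) >= 0 else b  # vertex a sits at +phat

    saved = {cid: list(state.cells[cid].vertices) for cid in (P, Q, C, D)}
    saved_pos = {a: state.vertices[a].copy(), b: state.vertices[b].copy()}

    p_edges = set()
    vsP = saved[P]
    for x, y in zip(vsP, vsP[1:] + vsP[:1]):
        p_edges.add(edge_key(x, y))

    def rewire(kp_: int, h: float) -> bool:
        kq_ = b if kp_ == a else a
        new_pa, new_pb = m + h * phat, m - h * phat
        state.vertices[a] = dom.wrap(new_pa)
        state.vertices[b] = dom.wrap(new_pb)
        state.cells[P].vertices = [v for v in saved[P] if v != kq_]
        state.cells[Q].vertices = [v for v in saved[Q] if v != kp_]
        for flank, old in ((C, a), (D, b)):
            cyc = list(saved[flank])
            i = cyc.index(old)
            u = cyc[i - 1]
            first = kp_ if edge_key(u, old) in p_edges else kq_
            second = kq_ if first == kp_ else kp_
            state.cells[flank].vertices = cyc[:i] + [first, second] + cyc[i + 1:]
        try:
            for cid in (P, Q, C, D):
                cyc = state.cells[cid].vertices
                if len(set(cyc)) != len(cyc) or len(cyc) < 3:
                    return False
                if state.cell_signed_area(cid) <= 0:
                    return False
        except TopologyError:
            return False
        return True

    # inside thin cells the full re-extension can poke through a flank;
    # retry with successively shorter new junctions before giving up
    ok = False
    for h in (h0, h0 / 2, h0 / 4):
        if rewire(kp, h) or rewire(b if kp == a else a, h):
            ok = True
            break
    if not ok:
        for cid, cyc in saved.items():
            state.cells[cid].vertices = cyc
        for v, p in saved_pos.items():
            state.vertices[v] = p
        warnings.warn(f"T1 on {key} skipped: both rewirings invert a polygon")
        return None

    loc = dom.wrap(m)
    return TopologyEvent(kind="T1", step=step, cells=(P, Q, C, D),
                         junction=key, cell=None,
                         location=(float(loc[0]), float(loc[1])))


def apply_t2(state: TissueState, cell: int, step: int = 0) -> TopologyEvent | None:
    """Remove a triangular cell, merging its vertices at the centroid.

    Returns the event, or None if removal is deferred because a neighbour
    would be left with fewer than three vertices.
    """
    cd = state.cells[cell]
    if len(cd.vertices) != 3:
        raise TopologyError(f"T2 requires a triangle; cell {cell} has "
                            f"{len(cd.vertices)} vertices")
    vs = list(cd.vertices)
    juncs = state.junctions()
    neighbor_of_edge = {}
    for x, y in zip(vs, vs[1:] + vs[:1]):
        owners = juncs[edge_key(x, y)]
        other = owners[0] if owners[1] == cell else owners[1]
        neighbor_of_edge[edge_key(x, y)] = other
    neighbors = list(neighbor_of_edge.values())
    if any(len(state.cells[n].vertices) < 4 for n in neighbors):
        return None  # defer until the neighbour has relaxed

    c = state.cell_centroid(cell)
    w = state.new_vertex_id()
    state.vertices[w] = state.domain.wrap(c.copy())
    saved = {n: list(state.cells[n].vertices) for n in neighbors}
    for (x, y), n in neighbor_of_edge.items():
        state.cells[n].vertices = _replace_vertex_pair(
            state.cells[n].vertices, x, y, w)
    # merging to the centroid may flip a thin neighbour: roll back and defer
    bad = False
    for n in set(neighbors):
        try:
            if state.cell_signed_area(n) <= 0:
                bad = True
                break
        except TopologyError:
            bad = True
            break
    if bad:
        for n, cyc in saved.items():
            state.cells[n].vertices = cyc
        del state.vertices[w]
        return None
    # 3-valent meshes have no corner-only neighbours, but guard anyway
    for other, oc in state.alive_cells().items():
        if other == cell:
            continue
        oc.vertices = [w if v in vs else v for v in oc.vertices]
        dedup = []
        for v in oc.vertices:
            if not dedup or dedup[-1] != v:
                dedup.append(v)
        if len(dedup) > 1 and dedup[0] == dedup[-1]:
            dedup.pop()
        oc.vertices = dedup
    cd.alive = False
    cd.vertices = []
    for v in vs:
        state.vertices.pop(v, None)
    state.a0_overrides.pop(cell, None)
    state.contractility_overrides.pop(cell, None)
    return TopologyEvent(kind="T2", step=step, cells=tuple(neighbors),
                         junction=None, cell=cell,
                         location=(float(c[0]), float(c[1])))
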