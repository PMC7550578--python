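"""Initial conditions: hexagonal lattice, disordering, region stripes,
lateral inhibition, and the ongoing differentiation rule.

The starting point is a regular hexagonal tiling of a periodic box.  The
boundary rows (IHC and pillar) are pre-formed; the lattice is then melted
into a disordered mosaic by repeatedly re-drawing junction tensions and
preferred areas while relaxing (with T1s active), after which lateral
inhibition assigns HC fate in the OHC stripe as a random-sequential
maximal independent set of the adjacency graph.
"""

from __future__ import annotations

import math

import numpy as np

from .mesh import Cell, Domain, TissueState, edge_key
from .params import ModelParams, ProtocolConfig, RegionSpec

# CCW corner offsets of a pointy-top unit hexagon, in integer units of
# (sqrt(3)/2 * side, side/2)
_CORNERS = [(0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1), (1, 1)]


def hexagonal_lattice(spec: RegionSpec) -> TissueState:
    """Regular hexagonal tiling of the torus; every vertex 3-valent."""
    R, C, s = spec.rows, spec.cols, spec.side
    if R < 4 or C < 4:
        raise ValueError("lattice needs rows, cols >= 4")
    if R % 2:
        raise ValueError("rows must be even for periodic tiling")
    ux, uy = math.sqrt(3.0) * s / 2.0, s / 2.0
    nx, ny = 2 * C, 3 * R

    vid_of: dict[tuple[int, int], int] = {}
    vertices: dict[int, np.ndarray] = {}
    cells: dict[int, Cell] = {}
    for r in range(R):
        for c in range(C):
            cx, cy = 2 * c + (r % 2), 3 * r
            cyc = []
            for dx, dy in _CORNERS:
                key = ((cx + dx) % nx, (cy + dy) % ny)
                if key not in vid_of:
                    vid_of[key] = len(vid_of)
                    vertices[vid_of[key]] = np.array([key[0] * ux, key[1] * uy])
                cyc.append(vid_of[key])
            cells[r * C + c] = Cell(vertices=cyc, cls="SC")
    state = TissueState(vertices=vertices, cells=cells,
                        domain=Domain(nx * ux, ny * uy))
    state.audit()
    return state


def assign_regions(state: TissueState, spec: RegionSpec) -> TissueState:
    """Label cell classes/regions by the centroid stripe along y.

    Pillar/non-pillar junctions acquire the high-tension junction class
    through the class-based tension lookup, so subsequent relaxation
    straightens the pillar boundary.  The IHC stripe alternates IHC/SC
    along x.
    """
    bounds = spec.stripe_bounds()
    ylo = bounds["outside_bottom"][0]
    Ly = state.domain.Ly
    ihc_cells = []
    for cid, cell in state.alive_cells().items():
        y = float(state.cell_centroid(cid)[1])
        y = (y - ylo) % Ly + ylo  # shift into [ylo, ylo + Ly)
        for name, (lo, hi) in bounds.items():
            if lo <= y < hi:
                cell.region = name
                if name == "pillar":
                    cell.cls = "pillar"
                elif name == "IHC":
                    ihc_cells.append(cid)
                elif name == "OHC":
                    cell.cls = "SC"
                else:
                    cell.cls = "outside"
                break
        else:
            raise ValueError(f"cell {cid} centroid outside all stripes")
    ihc_cells.sort(key=lambda cid: float(state.cell_centroid(cid)[0]))
    for k, cid in enumerate(ihc_cells):
        state.cells[cid].cls = "IHC" if k % 2 == 0 else "SC"
        state.cells[cid].region = "IHC"
    state.pillar_y = spec.pillar_interface_y
    return state


def disorder_lattice(state: TissueState, params: ModelParams,
                     rng: np.random.Generator, n_cycles: int,
                     redraw_every: int = 20,
                     gamma_range: tuple[float, float] = (0.5, 1.5),
                     a0_range: tuple[float, float] = (0.5, 1.5)) -> TissueState:
    """Melt the lattice: re-draw tensions and preferred areas every few
    steps while relaxing with T1 transitions active.

    Junctions touching the pre-formed pillar/IHC rows keep their class
    tension; those rows also keep their preferred areas.
    """
    from .dynamics import Simulation

    if n_cycles == 0:
        return state
    mean_area = float(np.mean([state.cell_area(c)
                               for c in state.alive_cells()]))
    g0 = params.tensions["default"]
    sim = Simulation(state, params, rng)
    protected = {"pillar", "IHC"}
    for _ in range(n_cycles):
        sim.sync()
        state.gamma_overrides.clear()
        for key, owners in state.junctions().items():
            if any(state.cells[c].cls in protected for c in owners):
                continue
            state.gamma_overrides[key] = g0 * rng.uniform(*gamma_range)
        for cid, cell in state.alive_cells().items():
            if cell.cls in protected:
                continue
            state.a0_overrides[cid] = mean_area * rng.uniform(*a0_range)
        sim.invalidate()
        sim.run(redraw_every)
    state.gamma_overrides.clear()
    state.a0_overrides.clear()
    return state


def _hc_count(state: TissueState) -> int:
    return sum(1 for c in state.alive_cells().values()
               if c.cls == "HC" and c.region == "OHC")


def lateral_inhibition(state: TissueState, rng: np.random.Generator,
                       hc_cap: int | None = None) -> TissueState:
    """Random sequential HC fate assignment in the OHC stripe.

    Picks random SCs without HC neighbours until none remain (a maximal
    independent set of the zone adjacency graph), or until ``hc_cap`` HCs
    exist.
    """
    adj = state.adjacency()
    zone = [cid for cid, c in state.alive_cells().items()
            if c.region == "OHC" and c.cls == "SC"]
    eligible = set(zone)
    n_hc = _hc_count(state)
    while eligible:
        if hc_cap is not None and n_hc >= hc_cap:
            break
        cid = int(rng.choice(sorted(eligible)))
        state.cells[cid].cls = "HC"
        n_hc += 1
        eligible.discard(cid)
        eligible -= adj[cid]
    return state


def maybe_differentiate(state: TissueState, rng: np.random.Generator,
                        hc_cap: int | None = None,
                        min_hc_distance: float = 0.0) -> int | None:
    """Ongoing lateral-inhibition rule: convert at most one OHC-zone SC
    with no HC neighbour, unless the HC count has reached ``hc_cap``.

    ``min_hc_distance`` additionally requires clearance from every HC
    centroid (the nuclear-layer packing constraint: a cell squeezed
    between repelling HC nuclei cannot adopt HC fate).  Returns the
    converted cell id, or None.
    """
    if hc_cap is not None and _hc_count(state) >= hc_cap:
        return None
    adj = state.adjacency()
    cands = sorted(
        cid for cid, c in state.alive_cells().items()
        if c.region == "OHC" and c.cls == "SC"
        and not any(state.cells[n].cls == "HC" for n in adj[cid]))
    if not cands:
        return None
    if min_hc_distance > 0:
        hc_xy = np.array([state.cell_centroid(c)
                          for c, cd in state.alive_cells().items()
                          if cd.cls == "HC"])
        if len(hc_xy):
            kept = []
            for cid in cands:
                d = state.domain.min_image(hc_xy - state.cell_centroid(cid))
                if np.hypot(d[:, 0], d[:, 1]).min() >= min_hc_distance:
                    kept.append(cid)
            cands = kept
    if not cands:
        return None
    cid = int(rng.choice(cands))
    state.cells[cid].cls = "HC"
    return cid


def label_top_boundary(state: TissueState) -> TissueState:
    """Relabel outside cells bordering the OHC zone as top-boundary cells."""
    adj = state.adjacency()
    for cid, cell in state.alive_cells().items():
        if cell.cls in ("outside", "top_boundary"):
            touches = any(state.cells[n].region == "OHC" for n in adj[cid])
            cell.cls = "top_boundary" if touches else "outside"
    return state


def init_tissue(spec: RegionSpec, params: ModelParams, cfg: ProtocolConfig,
                rng: np.random.Generator) -> TissueState:
    """Full initial condition: lattice -> boundary rows -> disorder ->
    relaxation -> lateral inhibition."""
    from .dynamics import Simulation

    r_disorder, r_relax, r_li = rng.spawn(3)
    state = hexagonal_lattice(spec)
    assign_regions(state, spec)
    disorder_lattice(state, params, r_disorder,
                     n_cycles=cfg.disorder.cycles,
                     redraw_every=cfg.disorder.redraw_every,
                     gamma_range=cfg.disorder.gamma_range,
                     a0_range=cfg.disorder.a0_range)
    if cfg.relax_steps:
        Simulation(state, params, r_relax).run(cfg.relax_steps)
    lateral_inhibition(state, r_li, hc_cap=spec.hc_cap)
    state.audit()
    return state
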