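"""Order parameters and event statistics for tissue states and centroid
tables.

Implements the quantification pipeline used on both simulation output and
(externally segmented) epithelia:

* SC-neighbour counts of hair cells (mesh junctions, or Voronoi adjacency
  for bare centroid tables);
* the bond-orientational order parameter psi6 and its stretched variant
  psi6*, which compresses neighbour positions by a fitted ellipse axis
  ratio along the local row axis before scoring hexagonal order;
* HC/SC apical area ratios;
* OHC row classification (pillar-facing OHC1, middle OHC2, border OHC3);
* the structure factor S(q) of HC centroids, with the iterative
  straightening that removes large-scale curvature of the row axis;
* intercalation/delamination rates and displacement profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .mesh import BOUNDARY_CLASSES, Domain, TissueState


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class CentroidSet:
    """Typed 2D point pattern: one row per cell."""

    ids: np.ndarray            # (N,) int
    cls: np.ndarray            # (N,) str ("HC", "SC", ...)
    xy: np.ndarray             # (N, 2) float
    row: np.ndarray | None = None     # optional "OHC1"/"OHC2"/"OHC3"
    area: np.ndarray | None = None
    domain: Domain | None = None      # set => periodic adjacency

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.cls = np.asarray(self.cls, dtype=object)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("cell ids must be unique")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("positions must be finite")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, mask: np.ndarray) -> "CentroidSet":
        return CentroidSet(
            ids=self.ids[mask], cls=self.cls[mask], xy=self.xy[mask],
            row=None if self.row is None else self.row[mask],
            area=None if self.area is None else self.area[mask],
            domain=self.domain)

    def hc(self) -> "CentroidSet":
        return self.subset(self.cls == "HC")

    @classmethod
    def from_state(cls, state: TissueState) -> "CentroidSet":
        cids = sorted(state.alive_cells())
        return cls(
            ids=np.array(cids),
            cls=np.array([state.cells[c].cls for c in cids], dtype=object),
            xy=np.array([state.cell_centroid(c) for c in cids]),
            area=np.array([state.cell_area(c) for c in cids]),
            domain=state.domain)

    def to_dataframe(self) -> pd.DataFrame:
        d = {"id": self.ids, "class": self.cls,
             "x": self.xy[:, 0], "y": self.xy[:, 1]}
        if self.row is not None:
            d["row"] = self.row
        if self.area is not None:
            d["area"] = self.area
        return pd.DataFrame(d)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       domain: Domain | None = None) -> "CentroidSet":
        return cls(
            ids=df["id"].to_numpy(), cls=df["class"].to_numpy(dtype=object),
            xy=df[["x", "y"]].to_numpy(float),
            row=df["row"].to_numpy(dtype=object) if "row" in df else None,
            area=df["area"].to_numpy(float) if "area" in df else None,
            domain=domain)


@dataclass
class HexOrderResult:
    cell: int
    psi6: float            # |psi6| of the rescaled neighbour positions
    psi6_raw: float        # |psi6| of the unrescaled positions
    r_e: float             # fitted major/minor axis ratio, >= 1
    angle: float           # main-axis angle (radians)
    neighbors: list[int] = field(default_factory=list)


@dataclass
class StructureFactorField:
    qx: np.ndarray   # (nq,)
    qy: np.ndarray   # (nq,)
    S: np.ndarray    # (nq, nq) real


# ----------------------------------------------------------------------
# neighbour graphs
# ----------------------------------------------------------------------
def _delaunay_adjacency(xy: np.ndarray) -> set[tuple[int, int]]:
    tri = Delaunay(xy)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            edges.add((min(a, b), max(a, b)))
    return edges


def hc_neighbor_graph(pts: CentroidSet) -> tuple[dict[int, set[int]], set[int]]:
    """Voronoi (Delaunay-dual) adjacency over the HC centroids.

    Returns (adjacency over HC ids, set of boundary ids).  With a periodic
    domain the pattern is tiled 3x3 and no cell is a boundary cell;
    without one, convex-hull points are flagged as boundary (their Voronoi
    regions are unbounded) and should be excluded from psi6* aggregates.
    """
    hc = pts.hc()
    if hc.n < 3:
        raise ValueError("need at least 3 HCs for a neighbour graph")
    ids = hc.ids
    adj: dict[int, set[int]] = {int(i): set() for i in ids}
    if pts.domain is not None:
        L = pts.domain.size
        shifts = [np.array([ix * L[0], iy * L[1]])
                  for ix in (-1, 0, 1) for iy in (-1, 0, 1)]
        tiled = np.vstack([hc.xy + s for s in shifts])
        try:
            edges = _delaunay_adjacency(tiled)
        except QhullError as e:
            raise ValueError("degenerate (collinear) HC centroids") from e
        n = hc.n
        center = range(4 * n, 5 * n)  # shift (0,0) is the 5th block
        for a, b in edges:
            if a in center or b in center:
                ia, ib = int(ids[a % n]), int(ids[b % n])
                if ia != ib:
                    adj[ia].add(ib)
                    adj[ib].add(ia)
        return adj, set()
    try:
        edges = _delaunay_adjacency(hc.xy)
    except QhullError as e:
        raise ValueError("degenerate (collinear) HC centroids") from e
    for a, b in edges:
        adj[int(ids[a])].add(int(ids[b]))
        adj[int(ids[b])].add(int(ids[a]))
    hull = Delaunay(hc.xy).convex_hull
    boundary = {int(ids[i]) for i in np.unique(hull)}
    return adj, boundary


# ----------------------------------------------------------------------
# psi6 and psi6*
# ----------------------------------------------------------------------
def psi6(center: np.ndarray, neighbors: np.ndarray) -> float:
    """|1/N sum_k exp(6 i theta_k)| over the neighbour bond angles."""
    center = np.asarray(center, float)
    nb = np.atleast_2d(np.asarray(neighbors, float))
    if len(nb) < 1:
        raise ValueError("psi6 needs at least one neighbour")
    d = nb - center
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r == 0):
        raise ValueError("neighbour coincides with the centre point")
    theta = np.arctan2(d[:, 1], d[:, 0])
    return float(abs(np.mean(np.exp(6j * theta))))


def _fit_axis_angle(points: np.ndarray) -> float:
    """Total-least-squares line direction (first principal component)."""
    p = points - points.mean(axis=0)
    cov = p.T @ p
    w, v = np.linalg.eigh(cov)
    d = v[:, -1]
    return float(math.atan2(d[1], d[0]))


_RE_MAX = 3.0  # cap on the fitted stretch ratio; beyond this the conic
               # fit has degenerated and the second-moment fallback is used


def _ellipse_axis_ratio(points: np.ndarray, angle: float) -> float:
    """Major/minor axis ratio of an ellipse through ``points`` (>= 1).

    Uses a direct least-squares ellipse fit when there are enough points;
    falls back to the second-moment ratio in the main-axis frame.  Ratios
    beyond a physiologically plausible cap are treated as fit failures.
    """
    if len(points) >= 5:
        try:
            from skimage.measure import EllipseModel
            model = EllipseModel.from_estimate(np.asarray(points))
            if model:
                a, b = model.axis_lengths
                if a > 0 and b > 0 and np.isfinite(a) and np.isfinite(b):
                    ratio = float(max(a, b) / min(a, b))
                    if ratio <= _RE_MAX:
                        return ratio
        except Exception:
            pass
    c, s = math.cos(angle), math.sin(angle)
    rot = np.asarray(points) - np.mean(points, axis=0)
    major = rot @ np.array([c, s])
    minor = rot @ np.array([-s, c])
    sm, sn = np.std(major), np.std(minor)
    if sn == 0:
        return 1.0
    return float(np.clip(sm / sn, 1.0, _RE_MAX))


def psi6_star(cell: int, pts: CentroidSet,
              graph: tuple[dict, set] | None = None) -> HexOrderResult | None:
    """Stretch-corrected hexagonal order of one HC.

    The local row axis comes from a line fit through the cell and its
    OHC2-labelled Voronoi neighbours (x-axis fallback when labels are
    missing); the stretch ratio from an ellipse fit to the neighbour
    centroids.  Neighbour positions are compressed by the ratio along the
    axis and scored with psi6.  Returns None (excluded from aggregates)
    for cells with fewer than 3 neighbours or flagged as boundary.
    """
    adj, boundary = hc_neighbor_graph(pts) if graph is None else graph
    if cell not in adj or cell in boundary:
        return None
    nb_ids = sorted(adj[cell])
    if len(nb_ids) < 3:
        return None
    index = {int(i): k for k, i in enumerate(pts.ids)}
    c0 = pts.xy[index[cell]]
    nxy = np.array([pts.xy[index[i]] for i in nb_ids])
    if pts.domain is not None:
        nxy = c0 + pts.domain.min_image(nxy - c0)

    if pts.row is not None:
        axis_pts = [c0] + [pts.xy[index[i]] for i in nb_ids
                           if pts.row[index[i]] == "OHC2"]
        if pts.domain is not None:
            axis_pts = [c0 + pts.domain.min_image(np.asarray(p) - c0)
                        for p in axis_pts]
        angle = _fit_axis_angle(np.array(axis_pts)) if len(axis_pts) >= 2 else 0.0
    else:
        angle = 0.0

    raw = psi6(c0, nxy)
    r_e = _ellipse_axis_ratio(nxy, angle)
    ca, sa = math.cos(angle), math.sin(angle)
    R = np.array([[ca, sa], [-sa, ca]])
    local = (nxy - c0) @ R.T
    local[:, 0] /= r_e
    rescored = psi6(np.zeros(2), local)
    return HexOrderResult(cell=cell, psi6=rescored, psi6_raw=raw,
                          r_e=r_e, angle=angle, neighbors=nb_ids)


# ----------------------------------------------------------------------
# mesh-based counts and ratios
# ----------------------------------------------------------------------
def analyzed_hcs(state: TissueState) -> list[int]:
    """HCs eligible for statistics: touching neither the pillar row nor
    the top/outside border."""
    adj = state.adjacency()
    out = []
    for cid, cell in state.alive_cells().items():
        if cell.cls != "HC":
            continue
        if any(state.cells[n].cls in BOUNDARY_CLASSES for n in adj[cid]):
            continue
        out.append(cid)
    return sorted(out)


def sc_neighbor_count(state: TissueState, cell: int) -> int:
    """Number of junction-sharing SC neighbours of a hair cell."""
    cd = state.cells[cell]
    if not cd.alive or cd.cls != "HC":
        raise ValueError(f"cell {cell} is not an alive HC")
    return sum(state.cells[n].cls == "SC" for n in state.neighbors(cell))


def sc_neighbor_counts(state: TissueState,
                       cells: list[int] | None = None) -> dict[int, int]:
    adj = state.adjacency()
    cells = analyzed_hcs(state) if cells is None else cells
    return {c: sum(state.cells[n].cls == "SC" for n in adj[c]) for c in cells}


def area_ratio(state: TissueState) -> float:
    """Mean over (analysed HC, adjacent SC) pairs of area(HC)/area(SC)."""
    adj = state.adjacency()
    ratios = []
    for cid in analyzed_hcs(state):
        a_hc = state.cell_area(cid)
        for n in adj[cid]:
            if state.cells[n].cls == "SC":
                ratios.append(a_hc / state.cell_area(n))
    return float(np.mean(ratios)) if ratios else float("nan")


# ----------------------------------------------------------------------
# rows
# ----------------------------------------------------------------------
def _median_nn_distance(xy: np.ndarray, domain: Domain | None) -> float:
    d = xy[:, None, :] - xy[None, :, :]
    if domain is not None:
        d = domain.min_image(d)
    R = np.hypot(d[..., 0], d[..., 1])
    np.fill_diagonal(R, np.inf)
    return float(np.median(R.min(axis=1)))


def _row_tilt(xy: np.ndarray, domain: Domain | None, nn: float) -> float:
    """Median angle of near-horizontal nearest-neighbour bonds (radians).

    Under periodic boundary conditions sustained shear can tilt the whole
    HC lattice into a helical state whose rows have no gaps in raw y;
    subtracting the collective tilt before banding recovers the physical
    rows.  Bonds steeper than 35 degrees are not row bonds and are
    ignored; with no near-horizontal bonds the tilt is zero.
    """
    d = xy[:, None, :] - xy[None, :, :]
    if domain is not None:
        d = domain.min_image(d)
    R = np.hypot(d[..., 0], d[..., 1])
    iu = np.triu_indices(len(xy), k=1)
    sel = R[iu] < 1.4 * nn
    dx, dy = d[..., 0][iu][sel], d[..., 1][iu][sel]
    ang = np.arctan2(dy, dx)
    ang = np.where(ang > math.pi / 2, ang - math.pi, ang)
    ang = np.where(ang < -math.pi / 2, ang + math.pi, ang)
    row_bonds = np.abs(ang) < math.radians(35.0)
    if not np.any(row_bonds):
        return 0.0
    return float(np.median(ang[row_bonds]))


def _refine_tilt(xy: np.ndarray, t0: float, span_deg: float = 4.0,
                 steps: int = 33) -> float:
    """Fit the helical pitch: pick the tilt near ``t0`` whose projection
    decomposes most cleanly into bands (largest second-largest gap).

    The bond-angle estimate is only good to a degree or two, and on a
    20-cell-wide box a one-degree error smears the projected bands by
    about half a cell — enough to close the inter-row gaps.
    """
    best_t, best_sep = t0, -1.0
    for dt in np.linspace(-math.radians(span_deg), math.radians(span_deg),
                          steps):
        t = t0 + dt
        ys = np.sort(xy[:, 1] - math.tan(t) * xy[:, 0])
        gaps = np.sort(np.diff(ys))
        sep = float(gaps[-2]) if len(gaps) >= 2 else 0.0
        if sep > best_sep:
            best_sep, best_t = sep, t
    return best_t


def classify_rows(pts: CentroidSet,
                  state: TissueState | None = None) -> tuple[dict[int, str], int]:
    """Label HCs OHC1/OHC2/OHC3 and count the HC rows.

    Row count comes from 1D gap clustering of HC y-centroids (gap
    threshold = 0.5x the median HC nearest-neighbour spacing) after
    removing the collective shear tilt of the lattice.  With a mesh,
    OHC1 are HCs bordering pillar cells and OHC3 HCs bordering the
    top/outside border; without one the bottom/top bands take those roles.
    """
    hc = pts.hc()
    if hc.n == 0:
        return {}, 0
    if hc.n < 3:
        labels = {int(c): "OHC1" for c in hc.ids}
        return labels, 1
    nn = _median_nn_distance(hc.xy, pts.domain)
    tilt = _refine_tilt(hc.xy, _row_tilt(hc.xy, pts.domain, nn))
    ys = hc.xy[:, 1] - math.tan(tilt) * hc.xy[:, 0]
    order = np.argsort(ys)
    gap = 0.5 * nn
    bands = np.zeros(hc.n, dtype=int)
    b = 0
    for k in range(1, hc.n):
        if ys[order[k]] - ys[order[k - 1]] > gap:
            b += 1
        bands[order[k]] = b
    n_rows = b + 1

    labels: dict[int, str] = {}
    if state is not None:
        adj = state.adjacency()
        for i, cid in enumerate(hc.ids):
            ncls = {state.cells[n].cls for n in adj[int(cid)]}
            if "pillar" in ncls:
                labels[int(cid)] = "OHC1"
            elif ncls & {"top_boundary", "outside"}:
                labels[int(cid)] = "OHC3"
            else:
                labels[int(cid)] = "OHC2"
    else:
        for i, cid in enumerate(hc.ids):
            if n_rows == 1:
                labels[int(cid)] = "OHC1"
            elif bands[i] == 0:
                labels[int(cid)] = "OHC1"
            elif bands[i] == n_rows - 1:
                labels[int(cid)] = "OHC3"
            else:
                labels[int(cid)] = "OHC2"
    return labels, n_rows


# ----------------------------------------------------------------------
# straightening and the structure factor
# ----------------------------------------------------------------------
def straighten_centroids(pts: CentroidSet,
                         backbone: list[int] | None = None) -> CentroidSet:
    """Iteratively rotate out the large-scale curvature of the HC rows.

    Walking the OHC2 backbone base-to-apex: set the origin at the current
    backbone cell, estimate the local tilt from the mean position of its
    apex-ward HC neighbours, rotate all apex-ward HCs by the negative
    tilt, then advance.  Distances among the rotated set are preserved at
    every step (each move is a rigid rotation of that subset).
    """
    hc = pts.hc()
    out = hc.xy.copy()
    index = {int(i): k for k, i in enumerate(hc.ids)}
    if backbone is None:
        if hc.row is not None:
            backbone = [int(i) for i in hc.ids[hc.row == "OHC2"]]
        else:
            backbone = [int(i) for i in hc.ids]
        backbone.sort(key=lambda cid: out[index[cid], 0])
    def neighbor_graph(xy: np.ndarray) -> dict[int, set[int]]:
        """Voronoi adjacency, or a 2-nearest-neighbour chain for
        (near-)collinear configurations Qhull cannot triangulate."""
        try:
            aperiodic = CentroidSet(ids=hc.ids, cls=hc.cls, xy=xy, domain=None)
            return hc_neighbor_graph(aperiodic)[0]
        except (ValueError, QhullError):
            adj: dict[int, set[int]] = {int(i): set() for i in hc.ids}
            d = xy[:, None, :] - xy[None, :, :]
            R = np.hypot(d[..., 0], d[..., 1])
            np.fill_diagonal(R, np.inf)
            for k, i in enumerate(hc.ids):
                for j in np.argsort(R[k])[:2]:
                    adj[int(i)].add(int(hc.ids[j]))
                    adj[int(hc.ids[j])].add(int(i))
            return adj

    for cid in backbone:
        k = index[cid]
        origin = out[k].copy()
        adj = neighbor_graph(out)
        cutoff = 2.0 * _median_nn_distance(out, None)
        apexward = [index[n] for n in adj[cid]
                    if out[index[n], 0] > origin[0]
                    and np.hypot(*(out[index[n]] - origin)) <= cutoff]
        if not apexward:
            continue
        rel = out[apexward] - origin
        mean = rel.mean(axis=0)
        ang = math.atan2(mean[1], mean[0])
        c, s = math.cos(-ang), math.sin(-ang)
        R = np.array([[c, -s], [s, c]])
        sel = out[:, 0] > origin[0]
        out[sel] = (out[sel] - origin) @ R.T + origin
    return CentroidSet(ids=hc.ids, cls=hc.cls, xy=out,
                       row=hc.row, area=hc.area, domain=None)


def structure_factor(pts: CentroidSet, qx: np.ndarray | None = None,
                     qy: np.ndarray | None = None,
                     n_grid: int = 128) -> StructureFactorField:
    """S(q) = (1/N) |sum_j exp(-i q . r_j)|^2 on a square q-grid.

    The default grid spans +/- 4x the first reciprocal-lattice magnitude
    2*pi / (median nearest-neighbour spacing).
    """
    xy = pts.xy
    N = len(xy)
    if qx is None or qy is None:
        a = _median_nn_distance(xy, pts.domain)
        qmax = 4.0 * 2.0 * math.pi / a
        qx = np.linspace(-qmax, qmax, n_grid)
        qy = np.linspace(-qmax, qmax, n_grid)
    phase_x = np.exp(-1j * np.outer(qx, xy[:, 0]))   # (nqx, N)
    phase_y = np.exp(-1j * np.outer(qy, xy[:, 1]))   # (nqy, N)
    amp = np.einsum("xn,yn->xy", phase_x, phase_y)
    S = (amp * np.conj(amp)).real / N
    return StructureFactorField(qx=qx, qy=qy, S=S)


# ----------------------------------------------------------------------
# events and tracking
# ----------------------------------------------------------------------
def count_events(events, kind: str, n_cells: int, duration: float,
                 region: tuple[float, float] | None = None) -> float:
    """Event rate per cell per unit time.

    ``events`` is an iterable of TopologyEvent (or a Trajectory); an
    optional ``region`` restricts to events whose y-location falls in the
    interval."""
    if hasattr(events, "events"):
        events = events.events
    if n_cells <= 0 or duration <= 0:
        raise ValueError("n_cells and duration must be positive")
    n = 0
    for ev in events:
        if ev.kind != kind:
            continue
        if region is not None and not (region[0] <= ev.location[1] < region[1]):
            continue
        n += 1
    return n / (n_cells * duration)


def displacement_profiles(trajectory) -> pd.DataFrame:
    """Group-mean centroid displacements in the pillar-row frame.

    Cells are grouped {HC, SC} x {medial, lateral} by their initial
    half of the OHC zone; the rigid drift of the pillar row is subtracted
    from every displacement at every time point.
    """
    snaps = trajectory.snapshots
    if not snaps:
        raise ValueError("trajectory holds no snapshots")
    step0, s0 = snaps[0]
    dom = s0.domain
    pillar = [c for c, cd in s0.alive_cells().items() if cd.cls == "pillar"]
    zone = [c for c, cd in s0.alive_cells().items() if cd.region == "OHC"]
    y0 = {c: float(s0.cell_centroid(c)[1]) for c in zone}
    ymid = float(np.median(list(y0.values())))
    group_of = {}
    for c in zone:
        half = "medial" if y0[c] <= ymid else "lateral"
        group_of[c] = (s0.cells[c].cls, half)
    p0 = {c: s0.cell_centroid(c) for c in zone + pillar}

    rows = []
    for step, st in snaps:
        alive = st.alive_cells()
        pd_disp = [dom.min_image(st.cell_centroid(c) - p0[c])
                   for c in pillar if c in alive]
        frame = np.mean(pd_disp, axis=0) if pd_disp else np.zeros(2)
        disp = {}
        for c in zone:
            if c not in alive or st.cells[c].cls != group_of[c][0]:
                continue
            disp[c] = dom.min_image(st.cell_centroid(c) - p0[c]) - frame
        for (cls, half) in {("HC", "medial"), ("HC", "lateral"),
                            ("SC", "medial"), ("SC", "lateral")}:
            vals = np.array([disp[c] for c in zone
                             if c in disp and group_of[c] == (cls, half)])
            if len(vals) == 0:
                continue
            rows.append({
                "step": step, "class": cls, "half": half, "n": len(vals),
                "mean_dx": float(vals[:, 0].mean()),
                "mean_dy": float(vals[:, 1].mean()),
                "sem_dx": float(vals[:, 0].std(ddof=1) / math.sqrt(len(vals)))
                if len(vals) > 1 else 0.0,
                "sem_dy": float(vals[:, 1].std(ddof=1) / math.sqrt(len(vals)))
                if len(vals) > 1 else 0.0,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# per-state metric bundle used by the protocols
# ----------------------------------------------------------------------
def state_metrics(state: TissueState) -> dict:
    """Order parameters of one tissue state (analysed HCs only)."""
    pts = CentroidSet.from_state(state)
    labels, n_rows = classify_rows(pts, state)
    if labels:
        row = np.array([labels.get(int(i), "") for i in pts.ids], dtype=object)
        pts.row = row
    counts = sc_neighbor_counts(state)
    hc_pts = pts.hc()
    psis, psis_raw = [], []
    if hc_pts.n >= 4:
        try:
            graph = hc_neighbor_graph(pts)
            for cid in analyzed_hcs(state):
                res = psi6_star(cid, pts, graph=graph)
                if res is not None:
                    psis.append(res.psi6)
                    psis_raw.append(res.psi6_raw)
        except ValueError:
            pass
    vals = list(counts.values())
    modal = int(np.bincount(vals).argmax()) if vals else -1
    return {
        "n_hc": int(np.sum(pts.cls == "HC")),
        "n_analyzed": len(counts),
        "mean_sc_neighbors": float(np.mean(vals)) if vals else float("nan"),
        "modal_sc_neighbors": modal,
        "mean_psi6_star": float(np.mean(psis)) if psis else float("nan"),
        "mean_psi6": float(np.mean(psis_raw)) if psis_raw else float("nan"),
        "area_ratio": area_ratio(state),
        "hc_rows": n_rows,
    }
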