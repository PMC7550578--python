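"""Vertex-model energy, analytic gradient and external/noise forces.

The energy per cell is

    E_n = alpha_n/2 (A_n - A0_n)^2 + sum_ij gamma_n^ij l_n^ij
          + Gamma_n/2 L_n^2 + sum_{m != n} sigma_nm (D / R_nm)^kappa,

summed over alive cells; the junction sum runs per cell so each physical
junction is counted once per owner.  The repulsion term couples HC
centroid pairs only.  External shear/compression forces act on every
vertex of every HC:

    F_i = eta * y_cm * x_hat + zeta * y_cm * grad_i(y_cm),

with grad_i(y_cm) = y_hat / N_vertices for the vertex-mean centroid and
y_cm measured from the pillar-row interface (periodic minimum image).

For speed the ragged mesh is flattened once into "slot" arrays (one slot
per directed cell edge); positions can then be advanced thousands of
steps without touching Python-level mesh dictionaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TissueState
from .params import ModelParams


class SingularityError(ArithmeticError):
    """Two HC centroids coincide: the repulsion energy diverges."""


@dataclass
class ForceField:
    """Per-vertex 2D force, aligned with the flattened position vector."""

    ids: list[int]
    F: np.ndarray  # (Nv, 2)

    def as_dict(self) -> dict[int, np.ndarray]:
        return {v: self.F[k] for k, v in enumerate(self.ids)}


class MeshArrays:
    """Flattened, index-based view of a TissueState for fast evaluation.

    The structure (cycles, classes, tensions) is frozen at construction;
    only ``pos`` changes between topology events.
    """

    def __init__(self, state: TissueState, params: ModelParams):
        self.state = state
        self.params = params
        self.L = state.domain.size.astype(float)
        self.pillar_y = float(state.pillar_y)

        self.vids = sorted(state.vertices)
        vindex = {v: k for k, v in enumerate(self.vids)}
        self.pos = np.array([state.vertices[v] for v in self.vids], dtype=float)

        cells = state.alive_cells()
        self.cell_ids = sorted(cells)
        nC = len(self.cell_ids)

        cyc, cell_of_slot, cell_start = [], [], []
        for ci, cid in enumerate(self.cell_ids):
            cell_start.append(len(cyc))
            for v in cells[cid].vertices:
                cyc.append(vindex[v])
                cell_of_slot.append(ci)
        self.cyc = np.asarray(cyc, dtype=np.intp)
        self.cell_of_slot = np.asarray(cell_of_slot, dtype=np.intp)
        self.cell_start = np.asarray(cell_start, dtype=np.intp)
        self.n_verts = np.asarray(
            [len(cells[cid].vertices) for cid in self.cell_ids], dtype=float)
        nS = len(self.cyc)

        nxt = np.arange(1, nS + 1, dtype=np.intp)
        prv = np.arange(-1, nS - 1, dtype=np.intp)
        ends = np.append(self.cell_start[1:], nS) - 1
        nxt[ends] = self.cell_start
        prv[self.cell_start] = ends
        self.next_slot, self.prev_slot = nxt, prv

        classes = sorted({c.cls for c in cells.values()})
        class_index = {cls: k for k, cls in enumerate(classes)}
        cls_code = np.array([class_index[cells[cid].cls]
                             for cid in self.cell_ids], dtype=np.intp)
        self.alpha = np.empty(nC)
        self.A0 = np.empty(nC)
        self.Gamma = np.empty(nC)
        for ci, cid in enumerate(self.cell_ids):
            cp = params.cell_params(cells[cid].cls)
            self.alpha[ci] = cp.alpha
            self.A0[ci] = state.a0_overrides.get(cid, cp.A0)
            self.Gamma[ci] = state.contractility_overrides.get(cid, cp.Gamma)
        self.is_hc = cls_code == class_index.get("HC", -1)
        self.hc_cells = np.flatnonzero(self.is_hc)

        # pair up the two slots of each physical junction
        va, vb = self.cyc, self.cyc[self.next_slot]
        lo, hi = np.minimum(va, vb), np.maximum(va, vb)
        keys = lo * (hi.max() + 1 if nS else 1) + hi
        order = np.argsort(keys, kind="stable")
        partner = np.arange(nS, dtype=np.intp)  # self-paired for toy meshes
        eq = keys[order][:-1] == keys[order][1:] if nS > 1 else np.array([], bool)
        partner[order[:-1][eq]] = order[1:][eq]
        partner[order[1:][eq]] = order[:-1][eq]
        self.slot_other_cell = self.cell_of_slot[partner]
        vid_arr = np.asarray(self.vids, dtype=np.int64)
        self.slot_vid_a = vid_arr[lo]
        self.slot_vid_b = vid_arr[hi]

        # per-slot junction tension via a class-pair table, plus overrides
        gtable = np.empty((len(classes), len(classes)))
        for i, ca in enumerate(classes):
            for j, cb in enumerate(classes):
                gtable[i, j] = params.gamma_for(ca, cb)
        self.slot_gamma = gtable[cls_code[self.cell_of_slot],
                                 cls_code[self.slot_other_cell]]
        if state.gamma_overrides:
            slot_of = {}
            for s in range(nS):
                slot_of.setdefault(
                    (int(self.slot_vid_a[s]), int(self.slot_vid_b[s])),
                    []).append(s)
            for key, g in state.gamma_overrides.items():
                for s in slot_of.get(key, ()):
                    self.slot_gamma[s] = g

        self.hc_slot_mask = self.is_hc[self.cell_of_slot]

        # static per-topology masks used by the transition detectors
        from .mesh import T1_PROTECTED_CLASSES, T2_DEFAULT_CLASSES
        prot = np.array([cls in T1_PROTECTED_CLASSES for cls in classes])
        elig = np.array([cls in T2_DEFAULT_CLASSES for cls in classes])
        prot_cell = prot[cls_code]
        self.protected_slot = prot_cell[self.cell_of_slot] \
            | prot_cell[self.slot_other_cell]
        self.t2_eligible = elig[cls_code]
        self.region_ohc = np.array(
            [cells[cid].region == "OHC" for cid in self.cell_ids], dtype=bool)
        self.cls_code = cls_code
        self.class_index = class_index

    # ------------------------------------------------------------------
    def min_image(self, d: np.ndarray) -> np.ndarray:
        return d - self.L * np.round(d / self.L)

    def geometry(self, pos: np.ndarray | None = None):
        """Edge steps, lengths, unwrapped coords, areas, perimeters, centroids."""
        pos = self.pos if pos is None else pos
        p = pos[self.cyc]
        d = self.min_image(pos[self.cyc[self.next_slot]] - p)
        lengths = np.hypot(d[:, 0], d[:, 1])

        cs = np.vstack([np.zeros(2), np.cumsum(d, axis=0)[:-1]])
        base = cs[self.cell_start][self.cell_of_slot]
        first = p[self.cell_start][self.cell_of_slot]
        u = first + cs - base
        un = u + d

        cross = u[:, 0] * un[:, 1] - un[:, 0] * u[:, 1]
        nC = len(self.cell_ids)
        areas = 0.5 * np.bincount(self.cell_of_slot, weights=cross, minlength=nC)
        perims = np.bincount(self.cell_of_slot, weights=lengths, minlength=nC)
        cx = np.bincount(self.cell_of_slot, weights=u[:, 0], minlength=nC)
        cy = np.bincount(self.cell_of_slot, weights=u[:, 1], minlength=nC)
        centroids = np.column_stack([cx, cy]) / self.n_verts[:, None]
        return d, lengths, u, areas, perims, centroids

    # ------------------------------------------------------------------
    def _repulsion_terms(self, centroids: np.ndarray):
        """Pairwise HC separation vectors/distances (minimum image)."""
        rp = self.params.repulsion
        hc = self.hc_cells
        if len(hc) < 2 or rp.sigma == 0.0:
            return None
        c = np.mod(centroids[hc], self.L)
        diff = c[:, None, :] - c[None, :, :]
        if rp.minimum_image:
            diff = self.min_image(diff)
        R = np.hypot(diff[..., 0], diff[..., 1])
        iu = ~np.eye(len(hc), dtype=bool)
        if np.any(R[iu] == 0.0):
            raise SingularityError("coincident HC centroids in repulsion term")
        np.fill_diagonal(R, np.inf)  # diagonal contributes nothing below
        return diff, R, iu

    def energy(self, pos: np.ndarray | None = None) -> float:
        _, lengths, _, areas, perims, centroids = self.geometry(pos)
        e = 0.5 * np.sum(self.alpha * (areas - self.A0) ** 2)
        e += np.sum(self.slot_gamma * lengths)
        e += 0.5 * np.sum(self.Gamma * perims ** 2)
        e += self.repulsion_energy_from_centroids(centroids)
        return float(e)

    def repulsion_energy_from_centroids(self, centroids: np.ndarray) -> float:
        rp = self.params.repulsion
        terms = self._repulsion_terms(centroids)
        if terms is None:
            return 0.0
        _, R, _ = terms
        return float(rp.sigma * np.sum((rp.D / R) ** rp.kappa))

    def gradient(self, pos: np.ndarray | None = None,
                 geo: tuple | None = None) -> np.ndarray:
        """dE/dpos, shape (Nv, 2)."""
        pos = self.pos if pos is None else pos
        d, lengths, u, areas, perims, centroids = geo or self.geometry(pos)
        grad = np.zeros_like(pos)

        # area term: dA/dv_k = ((y_next - y_prev)/2, (x_prev - x_next)/2)
        coeff = (self.alpha * (areas - self.A0))[self.cell_of_slot]
        up, un = u[self.prev_slot], u[self.next_slot]
        ga = np.column_stack([un[:, 1] - up[:, 1], up[:, 0] - un[:, 0]]) * (0.5 * coeff[:, None])
        np.add.at(grad, self.cyc, ga)

        # tension + perimeter terms share the edge-length derivative
        w = self.slot_gamma + (self.Gamma * perims)[self.cell_of_slot]
        with np.errstate(invalid="ignore", divide="ignore"):
            dhat = np.where(lengths[:, None] > 0, d / np.where(lengths == 0, 1.0, lengths)[:, None], 0.0)
        ge = w[:, None] * dhat
        np.add.at(grad, self.cyc, -ge)
        np.add.at(grad, self.cyc[self.next_slot], ge)

        # HC-HC repulsion, acting through the vertex-mean centroids
        rp = self.params.repulsion
        terms = self._repulsion_terms(centroids)
        if terms is not None:
            diff, R, _ = terms
            mag = -2.0 * rp.sigma * rp.kappa * rp.D ** rp.kappa / R ** (rp.kappa + 2)
            gc = np.einsum("ij,ijk->ik", mag, diff)  # dE/d centroid_i
            per_vertex = gc / self.n_verts[self.hc_cells, None]
            sel = self.hc_slot_mask
            hc_index = np.full(len(self.cell_ids), -1, dtype=np.intp)
            hc_index[self.hc_cells] = np.arange(len(self.hc_cells))
            np.add.at(grad, self.cyc[sel],
                      per_vertex[hc_index[self.cell_of_slot[sel]]])
        return grad

    def external(self, pos: np.ndarray | None = None,
                 geo: tuple | None = None) -> np.ndarray:
        """External shear/compression force field, shape (Nv, 2)."""
        pos = self.pos if pos is None else pos
        sh = self.params.shear
        F = np.zeros_like(pos)
        if sh.eta == 0.0 and sh.zeta == 0.0:
            return F
        *_, centroids = geo or self.geometry(pos)
        ycm = centroids[:, 1] - self.pillar_y
        ycm -= self.L[1] * np.round(ycm / self.L[1])
        fx = sh.eta * ycm
        fy = sh.zeta * ycm / self.n_verts
        sel = self.hc_slot_mask
        ci = self.cell_of_slot[sel]
        per_slot = np.column_stack([fx[ci], fy[ci]])
        np.add.at(F, self.cyc[sel], per_slot)
        return F

    def forces(self, pos: np.ndarray | None = None,
               geo: tuple | None = None) -> np.ndarray:
        """-grad E + F_ext, computing the geometry once."""
        pos = self.pos if pos is None else pos
        if geo is None:
            geo = self.geometry(pos)
        return -self.gradient(pos, geo=geo) + self.external(pos, geo=geo)

    # ------------------------------------------------------------------
    def writeback(self) -> None:
        """Copy the working position array back into the TissueState."""
        for k, v in enumerate(self.vids):
            self.state.vertices[v] = self.pos[k].copy()


# ----------------------------------------------------------------------
# functional API over TissueState
# ----------------------------------------------------------------------
def total_energy(state: TissueState, params: ModelParams) -> float:
    """Total mechanical energy of the tissue."""
    return MeshArrays(state, params).energy()


def repulsion_energy(state: TissueState, params: ModelParams) -> float:
    """HC-HC steric repulsion energy (ordered-pair sum)."""
    m = MeshArrays(state, params)
    *_, centroids = m.geometry()
    return m.repulsion_energy_from_centroids(centroids)


def energy_gradient(state: TissueState, params: ModelParams) -> ForceField:
    """The conservative force -dE/dx on every vertex."""
    m = MeshArrays(state, params)
    return ForceField(ids=m.vids, F=-m.gradient())


def external_force(state: TissueState, params: ModelParams) -> ForceField:
    """Shear/compression forces on HC vertices (zero elsewhere)."""
    m = MeshArrays(state, params)
    return ForceField(ids=m.vids, F=m.external())


def noise_force(rng: np.random.Generator, state: TissueState,
                params: ModelParams) -> ForceField:
    """I.i.d. uniform per-component fluctuation forces on all vertices."""
    vids = sorted(state.vertices)
    a = params.noise.amplitude
    F = rng.uniform(-a, a, size=(len(vids), 2)) if a > 0 else np.zeros((len(vids), 2))
    return ForceField(ids=vids, F=F)
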