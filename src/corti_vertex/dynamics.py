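"""Gradient-descent time stepping and the simulation engine.

Vertex positions advance by explicit gradient descent,

    x_{t+1} = x_t + eps * (-grad E + F_ext + F_noise),

with all vertices displaced simultaneously and wrapped into the periodic
box.  A step that would invert a cell is retried with a halved step size
a bounded number of times.  The :class:`Simulation` engine interleaves
the mechanics with T1/T2 transitions (at most one topological event per
step, shortest junction first), the post-T1 lockout, and the ongoing
lateral-inhibition differentiation rule.
"""

from __future__ import annotations

import numpy as np

from .mesh import TissueState
from .mechanics import MeshArrays
from .params import ModelParams
from .topology import TopologyEvent, apply_t1, apply_t2

_MAX_HALVINGS = 8


def _advance(mesh: MeshArrays, eps: float, F: np.ndarray) -> np.ndarray:
    """One explicit update with inversion guard; returns new positions.

    The step size is halved while any cell would invert; if halving alone
    does not help (a cell already degenerate at entry), the vertices of
    the offending cells are frozen for this step so the rest of the
    tissue keeps relaxing.
    """
    L = mesh.L
    # a cell already degenerate at entry (e.g. one crushed against a
    # deferred T2) cannot be rescued by any step size; it must not block
    # the update of the rest of the tissue
    ok = mesh.geometry(mesh.pos)[3] > 0
    for _ in range(_MAX_HALVINGS + 1):
        trial = np.mod(mesh.pos + eps * F, L)
        areas = mesh.geometry(trial)[3]
        if np.all(areas[ok] > 0):
            return trial
        eps *= 0.5
    F = F.copy()
    for _ in range(_MAX_HALVINGS + 1):
        trial = np.mod(mesh.pos + eps * F, L)
        areas = mesh.geometry(trial)[3]
        if np.all(areas[ok] > 0):
            return trial
        bad = np.flatnonzero((areas <= 0) & ok)
        sel = np.isin(mesh.cell_of_slot, bad)
        F[mesh.cyc[sel]] = 0.0
    raise RuntimeError("cell inversion persists after step-size halving")


def step(state: TissueState, params: ModelParams,
         rng: np.random.Generator | None = None) -> TissueState:
    """Single mechanics step on ``state`` (topology untouched), in place.

    The noise force is drawn fresh from ``rng`` when given; the
    held-between-refreshes semantics live in :class:`Simulation`.
    """
    mesh = MeshArrays(state, params)
    F = -mesh.gradient() + mesh.external()
    if rng is not None and params.noise.amplitude > 0:
        F = F + rng.uniform(-params.noise.amplitude, params.noise.amplitude,
                            size=mesh.pos.shape)
    mesh.pos = _advance(mesh, params.epsilon, F)
    mesh.writeback()
    return state


class Simulation:
    """Advance a tissue through mechanics, topology and differentiation."""

    def __init__(self, state: TissueState, params: ModelParams,
                 rng: np.random.Generator, *,
                 start_step: int = 0,
                 topology_enabled: bool = True,
                 differentiation: bool = False,
                 hc_cap: int | None = None,
                 differentiate_every: int = 5,
                 lockouts: dict | None = None,
                 events: list[TopologyEvent] | None = None):
        self.state = state
        self.params = params
        self.rng = rng
        self.step_index = start_step
        self.topology_enabled = topology_enabled
        self.differentiation = differentiation
        self.hc_cap = hc_cap
        self.differentiate_every = differentiate_every
        self.lockouts: dict[tuple[int, int], int] = lockouts if lockouts is not None else {}
        self.events: list[TopologyEvent] = events if events is not None else []
        self._mesh: MeshArrays | None = None
        self._noise: np.ndarray | None = None
        self._noise_age = 10 ** 9

    # ------------------------------------------------------------------
    @property
    def mesh(self) -> MeshArrays:
        if self._mesh is None:
            self._mesh = MeshArrays(self.state, self.params)
        return self._mesh

    def sync(self) -> None:
        """Write working positions back into the TissueState dicts."""
        if self._mesh is not None:
            self._mesh.writeback()

    def invalidate(self) -> None:
        self.sync()
        self._mesh = None

    def set_params(self, params: ModelParams) -> None:
        self.invalidate()
        self.params = params

    # ------------------------------------------------------------------
    # topology pass: at most one event per step
    # ------------------------------------------------------------------
    def _attempt_t1(self, key: tuple[int, int]) -> bool:
        self.invalidate()
        ev = apply_t1(self.state, key, self.params, step=self.step_index)
        if ev is None:
            return False
        self.events.append(ev)
        self.lockouts[key] = self.step_index + self.params.thresholds.t1_lockout
        return True

    def _topology_pass(self, geo) -> None:
        mesh = self.mesh
        th = self.params.thresholds
        lengths, areas = geo[1], geo[3]

        # --- T2: smallest sub-threshold eligible cell first
        elig = mesh.t2_eligible.copy()
        if th.hc_t2_allowed:
            elig |= mesh.is_hc
        small = np.flatnonzero(elig & (areas < th.A_min))
        if len(small):
            ci = small[np.argmin(areas[small])]
            cid = mesh.cell_ids[ci]
            if mesh.n_verts[ci] == 3:
                self.invalidate()
                ev = apply_t2(self.state, cid, step=self.step_index)
                if ev is not None:
                    self.events.append(ev)
                    return
            else:
                # shrink toward a triangle: force a T1 on its shortest
                # unprotected, unlocked junction
                slots = np.flatnonzero(
                    (mesh.cell_of_slot == ci) & ~mesh.protected_slot)
                cand = sorted(
                    (lengths[s], (int(mesh.slot_vid_a[s]), int(mesh.slot_vid_b[s])))
                    for s in slots)
                for _, key in cand:
                    if self.lockouts.get(key, -1) > self.step_index:
                        continue
                    if self._attempt_t1(key):
                        return
        # --- regular T1: shortest sub-threshold junction first
        sub = np.flatnonzero((lengths < th.l_min) & ~mesh.protected_slot)
        if len(sub):
            seen = set()
            for s in sub[np.argsort(lengths[sub])]:
                key = (int(mesh.slot_vid_a[s]), int(mesh.slot_vid_b[s]))
                if key in seen or self.lockouts.get(key, -1) > self.step_index:
                    continue
                seen.add(key)
                if self._attempt_t1(key):
                    return

    # ------------------------------------------------------------------
    def _differentiation_pass(self) -> None:
        """Array-based equivalent of :func:`initial.maybe_differentiate`."""
        mesh = self.mesh
        if self.hc_cap is not None and \
                int(np.sum(mesh.is_hc & mesh.region_ohc)) >= self.hc_cap:
            return
        sc_code = mesh.class_index.get("SC")
        if sc_code is None:
            return
        cand = (mesh.cls_code == sc_code) & mesh.region_ohc
        if not cand.any():
            return
        nb_hc = np.zeros(len(mesh.cell_ids), dtype=bool)
        sel = mesh.is_hc[mesh.slot_other_cell]
        nb_hc[mesh.cell_of_slot[sel]] = True
        cand &= ~nb_hc
        if not cand.any():
            return
        min_d = self.params.repulsion.D
        if min_d > 0 and len(mesh.hc_cells):
            centroids = np.mod(mesh.geometry()[5], mesh.L)
            hc_xy = centroids[mesh.hc_cells]
            for ci in np.flatnonzero(cand):
                d = mesh.min_image(hc_xy - centroids[ci])
                if np.hypot(d[:, 0], d[:, 1]).min() < min_d:
                    cand[ci] = False
            if not cand.any():
                return
        cands = [mesh.cell_ids[i] for i in np.flatnonzero(cand)]
        cid = int(self.rng.choice(cands))
        self.sync()
        self.state.cells[cid].cls = "HC"
        c = self.state.cell_centroid(cid)
        self.events.append(TopologyEvent(
            kind="differentiation", step=self.step_index,
            cells=(cid,), junction=None, cell=cid,
            location=(float(c[0]), float(c[1]))))
        self.invalidate()

    # ------------------------------------------------------------------
    def step_once(self) -> None:
        mesh = self.mesh
        geo = mesh.geometry()
        if self.topology_enabled:
            self._topology_pass(geo)
        if (self.differentiation
                and self.step_index % self.differentiate_every == 0):
            self._differentiation_pass()
        if self._mesh is not mesh:  # a topology/fate event rebuilt the mesh
            mesh = self.mesh
            geo = mesh.geometry()

        amp = self.params.noise.amplitude
        if amp > 0:
            if (self._noise is None or self._noise.shape != mesh.pos.shape
                    or self._noise_age >= self.params.noise.refresh_every):
                self._noise = self.rng.uniform(-amp, amp, size=mesh.pos.shape)
                self._noise_age = 0
            noise = self._noise
            self._noise_age += 1
        else:
            noise = 0.0
        F = mesh.forces(geo=geo) + noise
        mesh.pos = _advance(mesh, self.params.epsilon, F)
        self.step_index += 1

    def run(self, n_steps: int, *, callback=None, callback_every: int = 0) -> None:
        """Advance ``n_steps``; optionally call ``callback(self)`` on a cadence
        (the state is synced before each callback)."""
        for _ in range(n_steps):
            if callback is not None and callback_every > 0 \
                    and self.step_index % callback_every == 0:
                self.sync()
                callback(self)
            self.step_once()
        self.sync()
        if callback is not None:
            callback(self)
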